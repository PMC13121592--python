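"""H&E stain vectors and Beer-Lambert optical-density transforms.

Uses the classic published hematoxylin/eosin absorption vectors (Ruifrok &
Johnston style, as shipped with scikit-image).  Forward model for a pixel with
stain concentrations ``c`` (OD units): ``I = I0 * 10**(-c @ M)`` where rows of
``M`` are unit stain OD vectors.  ``od_to_concentrations`` is the exact linear
inverse, so phantom renders round-trip through color deconvolution.
"""

from __future__ import annotations

import numpy as np

# unit-norm OD vectors: hematoxylin, eosin, and an orthogonal residual row
HEMATOXYLIN = np.array([0.65, 0.70, 0.29])
EOSIN = np.array([0.07, 0.99, 0.11])
_res = np.cross(HEMATOXYLIN, EOSIN)
RESIDUAL = _res / np.linalg.norm(_res)

STAIN_MATRIX = np.stack([
    HEMATOXYLIN / np.linalg.norm(HEMATOXYLIN),
    EOSIN / np.linalg.norm(EOSIN),
    RESIDUAL,
])
STAIN_MATRIX_INV = np.linalg.inv(STAIN_MATRIX)

_EPS = 1e-6


def rgb_from_concentrations(conc: np.ndarray) -> np.ndarray:
    """(..., 3) stain concentrations (H, E, residual) -> RGB in [0, 1]."""
    od = conc @ STAIN_MATRIX
    return np.power(10.0, -od)


def rgb_to_od(rgb: np.ndarray, i0: float = 1.0) -> np.ndarray:
    """Per-channel optical density -log10(I / I0); rgb clipped away from 0."""
    i = np.clip(np.asarray(rgb, dtype=float) / i0, _EPS, 1.0)
    return -np.log10(i)


def od_to_concentrations(rgb: np.ndarray, i0: float = 1.0) -> np.ndarray:
    """Color deconvolution: RGB -> (H, E, residual) concentrations."""
    return rgb_to_od(rgb, i0) @ STAIN_MATRIX_INV
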