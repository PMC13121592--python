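"""Statistics for blinded reader evaluation of virtual vs chemical staining.

A score table holds one row per scored image: the pair id, the modality
(vHE or HE), the reader, and four histologic feature scores on a 4-point
scale (1 unacceptable ... 4 excellent).  The module provides

* paired Wilcoxon signed-rank tests per feature (exact two-sided p for small
  n by convolving the signed mid-rank-sum null; tie-corrected normal
  approximation otherwise),
* 4x4 score concordance matrices (vHE rows x HE columns) with the fraction
  of pairs scoring vHE >= HE, and
* a two-scenario ROC asking whether modality can be recovered from scores:
  the composite (mean of the four features) is binarized at the scenario
  threshold (>=3 "Good", >=4 "Excellent") and used as the classifier score
  for vHE-vs-HE; AUC follows the tie-corrected Mann-Whitney rank formula, so
  an AUC near 0.5 certifies clinical indistinguishability.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy import stats

FEATURES = ("nuclear", "cytoplasm", "matrix", "overall")
MODALITIES = ("vHE", "HE")


class ContractError(ValueError):
    pass


class DegenerateDataError(ValueError):
    """All paired differences are zero; the test statistic is undefined."""


# ---------------------------------------------------------------------------
# score table
# ---------------------------------------------------------------------------

def validate_scores(table: pd.DataFrame) -> pd.DataFrame:
    required = {"image_pair_id", "modality", "reader_id", *FEATURES}
    missing = required - set(table.columns)
    if missing:
        raise ContractError(f"missing columns: {sorted(missing)}")
    for f in FEATURES:
        vals = table[f]
        if not ((vals >= 1) & (vals <= 4) & (vals == vals.round())).all():
            raise ContractError(f"{f} scores must be integers in 1..4")
    if not table["modality"].isin(MODALITIES).all():
        raise ContractError("modality must be 'vHE' or 'HE'")
    return table


def complete_pairs(table: pd.DataFrame, feature: str) -> pd.DataFrame:
    """One row per (pair, reader) holding both modalities' scores for one
    feature; incomplete pairs are dropped."""
    wide = table.pivot_table(index=["image_pair_id", "reader_id"],
                             columns="modality", values=feature,
                             aggfunc="first")
    return wide.dropna().rename(columns={"vHE": "vhe", "HE": "he"})


def simulate_score_table(n_pairs: int = 18, n_readers: int = 5,
                         vhe_shift: float = 0.0, seed: int = 0
                         ) -> pd.DataFrame:
    """Synthetic reader-study scores: per-pair latent quality plus reader
    leniency, discretized to 1-4; ``vhe_shift`` biases the vHE modality."""
    rng = np.random.default_rng(seed)
    rows = []
    quality = rng.normal(3.2, 0.6, size=n_pairs)
    leniency = rng.normal(0.0, 0.25, size=n_readers)
    for p in range(n_pairs):
        for r in range(n_readers):
            for modality in MODALITIES:
                shift = vhe_shift if modality == "vHE" else 0.0
                row = {"image_pair_id": p, "modality": modality,
                       "reader_id": r}
                for f in FEATURES:
                    s = quality[p] + leniency[r] + shift + rng.normal(0, 0.45)
                    row[f] = int(np.clip(round(s), 1, 4))
                rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank
# ---------------------------------------------------------------------------

def _signed_ranks(diffs: np.ndarray) -> tuple:
    """Mid-ranks of |d| for nonzero d; returns (ranks, signs)."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise DegenerateDataError("all differences are zero")
    ranks = stats.rankdata(np.abs(d))
    return ranks, np.sign(d)


def _exact_two_sided_p(ranks: np.ndarray, w_pos: float) -> float:
    """Exact p over the 2^n equiprobable sign assignments, computed by
    convolution over doubled (integer) mid-ranks."""
    r2 = np.rint(ranks * 2).astype(int)
    total = r2.sum()
    pmf = np.zeros(total + 1, dtype=float)
    pmf[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:pmf.size - r]
        pmf = 0.5 * (pmf + shifted)
    w2 = int(round(w_pos * 2))
    mu = total / 2.0
    dev = abs(w2 - mu)
    support = np.arange(total + 1)
    return float(pmf[np.abs(support - mu) >= dev - 1e-9].sum())


def wilcoxon_signed_rank(diffs, exact_max_n: int = 25) -> tuple:
    """Paired Wilcoxon signed-rank test.

    Zero differences are discarded (classic treatment); W is the positive
    rank sum with mid-ranks for ties.  Two-sided p is exact for n <=
    ``exact_max_n``, otherwise a tie-corrected normal approximation.
    Returns (W, p).
    """
    ranks, signs = _signed_ranks(np.asarray(diffs))
    n = len(ranks)
    w_pos = float(ranks[signs > 0].sum())
    if n <= exact_max_n:
        return w_pos, _exact_two_sided_p(ranks, w_pos)
    mu = n * (n + 1) / 4.0
    # tie correction: sum over tie groups of (t^3 - t) / 48
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = ((counts ** 3 - counts).sum()) / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    z = (w_pos - mu) / sigma
    return w_pos, float(2.0 * stats.norm.sf(abs(z)))


def wilcoxon_by_feature(table: pd.DataFrame) -> pd.DataFrame:
    """W and two-sided p per histologic feature (vHE minus HE differences)."""
    validate_scores(table)
    rows = []
    for f in FEATURES:
        pairs = complete_pairs(table, f)
        w, p = wilcoxon_signed_rank(pairs["vhe"] - pairs["he"])
        rows.append({"feature": f, "n_pairs": len(pairs), "W": w, "p": p})
    return pd.DataFrame(rows).set_index("feature")


# ---------------------------------------------------------------------------
# concordance matrix
# ---------------------------------------------------------------------------

def concordance_matrix(table: pd.DataFrame, feature: str) -> tuple:
    """4x4 count matrix (rows vHE score, columns HE score) over complete
    (pair, reader) observations, and the fraction with vHE >= HE."""
    if feature not in FEATURES:
        raise ContractError(f"unknown feature {feature!r}")
    validate_scores(table)
    pairs = complete_pairs(table, feature)
    mat = np.zeros((4, 4), dtype=int)
    for v, h in zip(pairs["vhe"].astype(int), pairs["he"].astype(int)):
        mat[v - 1, h - 1] += 1
    frac = float(np.triu(mat.T).sum() / mat.sum()) if mat.sum() else np.nan
    return mat, frac


# ---------------------------------------------------------------------------
# modality ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocScenario:
    name: str            # "poor_vs_good" or "good_vs_excellent"
    threshold: int       # composite >= 3 ("Good") or >= 4 ("Excellent")

    def __post_init__(self):
        if self.threshold not in (3, 4):
            raise ContractError("threshold must be 3 or 4")

    @classmethod
    def poor_vs_good(cls):
        return cls("poor_vs_good", 3)

    @classmethod
    def good_vs_excellent(cls):
        return cls("good_vs_excellent", 4)


def composite_score(table: pd.DataFrame, mode: str = "mean") -> pd.Series:
    feats = table[list(FEATURES)]
    if mode == "mean":
        return feats.mean(axis=1)
    if mode == "sum":
        return feats.sum(axis=1)
    if mode in FEATURES:
        return table[mode].astype(float)
    raise ContractError(f"unknown composite mode {mode!r}")


def auc_rank(scores: np.ndarray, positive: np.ndarray) -> float:
    """Mann-Whitney AUC with tie correction (mid-ranks)."""
    scores = np.asarray(scores, dtype=float)
    positive = np.asarray(positive, dtype=bool)
    n1, n0 = positive.sum(), (~positive).sum()
    if n1 == 0 or n0 == 0:
        raise ContractError("ROC needs both classes present")
    ranks = stats.rankdata(scores)
    u = ranks[positive].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def modality_roc(table: pd.DataFrame, scenario: RocScenario,
                 composite: str = "mean") -> dict:
    """ROC for recovering modality from scores under one grading scenario.

    The classifier score is the scenario's quality indicator
    1[composite >= threshold]; vHE is the positive class.  Reports the
    tie-corrected rank AUC, the ROC curve, and sensitivity/specificity at
    the indicator's operating point (also the Youden-optimal point of this
    one-threshold classifier).
    """
    validate_scores(table)
    comp = composite_score(table, composite)
    indicator = (comp >= scenario.threshold).to_numpy()
    positive = (table["modality"] == "vHE").to_numpy()
    if positive.all() or not positive.any():
        raise ContractError("both modalities required")
    auc = auc_rank(indicator.astype(float), positive)
    sens = float(indicator[positive].mean())
    spec = float((~indicator[~positive]).mean())
    curve = [(0.0, 0.0), (1.0 - spec, sens), (1.0, 1.0)]
    return {"scenario": scenario.name, "auc": auc,
            "sensitivity": sens, "specificity": spec, "curve": curve}
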