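"""FID/KID against independent linear-algebra and kernel-sum oracles."""

import numpy as np
import pytest
from scipy import linalg

from vstain import gen_metrics as gm
from vstain import phantom


class _MeanPixelExtractor:
    """Stub embedder: per-image channel means."""

    input_size = 8
    id = "mean-pixel"

    def __call__(self, batch01):
        return batch01.mean(axis=(2, 3))


@pytest.fixture(scope="module")
def embedder():
    return gm.RandomConvEmbedder(dim=64, seed=0, input_size=64)


class TestEmbed:
    def test_deterministic(self, rng, embedder):
        imgs = [rng.random((32, 32, 3)) for _ in range(4)]
        a = gm.embed(imgs, embedder)
        b = gm.embed(imgs, embedder)
        assert np.array_equal(a.features, b.features)

    def test_per_image_independence(self, rng, embedder):
        imgs = [rng.random((32, 32, 3)) for _ in range(3)]
        single = gm.embed(imgs, embedder)
        doubled = gm.embed(imgs + imgs, embedder)
        assert np.allclose(doubled.features[:3], single.features)
        assert np.allclose(doubled.features[3:], single.features)

    def test_stub_extractor_gives_pixel_means(self):
        img = np.zeros((8, 8, 3))
        img[..., 0] = 0.25
        img[..., 1] = 0.5
        img[..., 2] = 1.0
        es = gm.embed([img], _MeanPixelExtractor())
        assert np.allclose(es.features[0], [0.25, 0.5, 1.0])

    def test_empty_set_rejected(self):
        with pytest.raises(gm.ContractError):
            gm.embed([])


class TestFid:
    def test_self_comparison_is_zero(self, rng):
        es = gm.EmbeddingSet(rng.normal(size=(50, 8)), "t")
        assert gm.fid(es, es) == pytest.approx(0.0, abs=1e-6)

    def test_one_dimensional_closed_form(self, rng):
        """Unit-variance Gaussians with means 0 and 1: FID -> (delta mu)^2."""
        a = gm.EmbeddingSet(rng.normal(0, 1, (20000, 1)), "t")
        b = gm.EmbeddingSet(rng.normal(1, 1, (20000, 1)), "t")
        assert gm.fid(a, b) == pytest.approx(1.0, abs=0.1)

    def test_matches_scipy_sqrtm_oracle(self, rng):
        fa = rng.normal(size=(30, 6))
        fb = rng.normal(size=(30, 6)) + 0.3
        jit = 1e-6 * np.eye(6)
        sa = np.cov(fa, rowvar=False) + jit
        sb = np.cov(fb, rowvar=False) + jit
        mu = fa.mean(0) - fb.mean(0)
        oracle = float(np.sum(mu ** 2)
                       + np.trace(sa + sb - 2 * linalg.sqrtm(sa @ sb).real))
        got = gm.fid(gm.EmbeddingSet(fa, "t"), gm.EmbeddingSet(fb, "t"))
        assert got == pytest.approx(oracle, rel=1e-8)

    def test_symmetric(self, rng):
        a = gm.EmbeddingSet(rng.normal(size=(25, 5)), "t")
        b = gm.EmbeddingSet(rng.normal(size=(25, 5)) + 1, "t")
        assert gm.fid(a, b) == pytest.approx(gm.fid(b, a), rel=1e-9)

    def test_invariant_under_shared_dimension_permutation(self, rng):
        a = rng.normal(size=(40, 6))
        b = rng.normal(size=(40, 6)) + 0.5
        perm = rng.permutation(6)
        f1 = gm.fid(gm.EmbeddingSet(a, "t"), gm.EmbeddingSet(b, "t"))
        f2 = gm.fid(gm.EmbeddingSet(a[:, perm], "t"),
                    gm.EmbeddingSet(b[:, perm], "t"))
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_rank_deficient_covariance_is_finite(self, rng):
        flat = np.tile(rng.normal(size=(1, 8)), (10, 1))  # zero covariance
        other = gm.EmbeddingSet(rng.normal(size=(10, 8)), "t")
        assert np.isfinite(gm.fid(gm.EmbeddingSet(flat, "t"), other))


class TestKid:
    def test_matches_hand_expanded_kernel_sums(self):
        a = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        b = np.array([[0.5, 0.5], [1.0, 0.0], [0.0, 0.0]])

        def k(x, y):
            return (x @ y / 2 + 1) ** 3

        kxx = sum(k(a[i], a[j]) for i in range(3) for j in range(3)
                  if i != j) / 6
        kyy = sum(k(b[i], b[j]) for i in range(3) for j in range(3)
                  if i != j) / 6
        kxy = np.mean([k(a[i], b[j]) for i in range(3) for j in range(3)])
        hand = kxx + kyy - 2 * kxy
        mean, _ = gm.kid(gm.EmbeddingSet(a, "t"), gm.EmbeddingSet(b, "t"),
                         n_subsets=4, subset_size=3)
        assert mean == pytest.approx(hand, rel=1e-12)

    def test_null_case_near_zero(self, rng):
        a = gm.EmbeddingSet(rng.normal(size=(200, 4)), "t")
        b = gm.EmbeddingSet(rng.normal(size=(200, 4)), "t")
        mean, sd = gm.kid(a, b, seed=1)
        assert abs(mean) < 3 * max(sd, 1e-3)

    def test_scaling_follows_kernel_closed_form(self, rng):
        """For same-scale inputs, k(cx, cy) = (c^2 x.y/d + 1)^3; verify the
        estimator tracks the transformed kernel exactly."""
        a = rng.normal(size=(6, 3))
        b = rng.normal(size=(6, 3)) + 1
        c = 2.0

        def mmd(x, y, scale=1.0):
            def k(u, v):
                return (scale ** 2 * (u @ v) / 3 + 1) ** 3
            m = len(x)
            kxx = sum(k(x[i], x[j]) for i in range(m) for j in range(m)
                      if i != j) / (m * (m - 1))
            kyy = sum(k(y[i], y[j]) for i in range(m) for j in range(m)
                      if i != j) / (m * (m - 1))
            kxy = np.mean([k(x[i], y[j]) for i in range(m)
                           for j in range(m)])
            return kxx + kyy - 2 * kxy

        scaled, _ = gm.kid(gm.EmbeddingSet(c * a, "t"),
                           gm.EmbeddingSet(c * b, "t"),
                           n_subsets=2, subset_size=6)
        assert scaled == pytest.approx(mmd(a, b, scale=c), rel=1e-10)

    def test_subset_size_bounds(self, rng):
        a = gm.EmbeddingSet(rng.normal(size=(5, 3)), "t")
        with pytest.raises(gm.ContractError):
            gm.kid(a, a, subset_size=1)
        with pytest.raises(gm.ContractError):
            gm.kid(a, a, subset_size=10)


class TestEvaluatePair:
    def test_self_comparison_near_zero(self, rng, embedder):
        imgs = [rng.random((32, 32, 3)) for _ in range(10)]
        rep = gm.evaluate_pair(imgs, imgs, extractor=embedder,
                               kid_subset_size=8)
        assert rep.fid_mean == pytest.approx(0.0, abs=1e-6)
        assert abs(rep.kid_mean) < 0.05

    def test_disjoint_phantom_styles_strictly_positive(self, embedder):
        """Two visually different phantom styles separate in FID and KID."""
        dense = phantom.PhantomSpec(image_size=64, nuclei_rate=14,
                                    nucleus_axes=(7, 5, 1), seed=1)
        sparse = phantom.PhantomSpec(image_size=64, nuclei_rate=2,
                                     nucleus_axes=(4, 3, 0.5),
                                     stroma_texture=(3.0, 0.3), seed=2)
        a = [phantom.render_he(phantom.sample_layout(dense, i), dense, i).rgb
             for i in range(8)]
        b = [phantom.render_he(phantom.sample_layout(sparse, i), sparse,
                               i).rgb for i in range(8)]
        rep = gm.evaluate_pair(a, b, extractor=embedder, kid_subset_size=6)
        assert rep.fid_mean > 0.01
        assert rep.kid_mean > 0


class TestAblationHarness:
    def test_all_channels_is_identity_configuration(self, rng):
        maf = rng.random((3, 16, 16))
        assert gm.select_channels(maf, "all") is maf

    def test_single_channel_replicates_plane(self, rng):
        maf = rng.random((3, 16, 16))
        sel = gm.select_channels(maf, "SpOr")
        assert sel.shape == maf.shape
        for c in range(3):
            assert np.array_equal(sel[c], maf[2])

    def test_unknown_channel_rejected(self, rng):
        with pytest.raises(gm.ContractError):
            gm.select_channels(rng.random((3, 8, 8)), "FITC")

    def test_harness_collects_reports_per_variant(self):
        results = gm.ablation_harness(lambda ch: {"channel": ch})
        assert set(results) == set(gm.ABLATION_CHANNELS)


def test_relative_improvement_percentage():
    assert gm.relative_improvement(20.0, 15.0) == pytest.approx(25.0)
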