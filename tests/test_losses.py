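"""Loss components against brute-force elementwise oracles (<= 8x8 inputs)."""

import numpy as np
import pytest

from vstain import losses as L
from vstain import phantom


# ---------------------------------------------------------------------------
# adversarial
# ---------------------------------------------------------------------------

class TestAdversarial:
    def test_perfect_discriminator_approaches_zero(self):
        eps = 1e-9
        val = L.adversarial_loss(np.full((2, 5, 5), 1 - eps),
                                 np.full((2, 5, 5), eps))
        assert abs(val) < 1e-5

    def test_uninformative_discriminator_closed_form(self):
        val = L.adversarial_loss(np.full(7, 0.5), np.full(7, 0.5))
        assert val == pytest.approx(2 * np.log(0.5), abs=1e-12)

    def test_matches_scalar_bruteforce(self, rng):
        pr = rng.uniform(0.05, 0.95, size=(2, 4, 4))
        pf = rng.uniform(0.05, 0.95, size=(2, 4, 4))
        oracle = (sum(np.log(v) for v in pr.ravel()) / pr.size
                  + sum(np.log(1 - v) for v in pf.ravel()) / pf.size)
        assert L.adversarial_loss(pr, pf) == pytest.approx(oracle, rel=1e-12)

    def test_degenerate_probabilities_clamped_not_nan(self):
        val = L.adversarial_loss(np.array([1.0, 0.0]), np.array([0.0, 1.0]))
        assert np.isfinite(val)


# ---------------------------------------------------------------------------
# cycle
# ---------------------------------------------------------------------------

class TestCycle:
    def test_identity_reconstruction_is_zero(self, rng):
        x = rng.normal(size=(2, 3, 8, 8))
        y = rng.normal(size=(2, 3, 8, 8))
        assert L.cycle_loss(x, x, y, y) == 0.0

    def test_constant_offset(self, rng):
        x = rng.normal(size=(1, 3, 8, 8))
        y = rng.normal(size=(1, 3, 8, 8))
        assert L.cycle_loss(x, x + 0.1, y, y) == pytest.approx(0.1, abs=1e-9)

    def test_matches_elementwise_bruteforce(self, rng):
        x, xc = rng.normal(size=(2, 2, 4, 4)), rng.normal(size=(2, 2, 4, 4))
        y, yc = rng.normal(size=(2, 2, 4, 4)), rng.normal(size=(2, 2, 4, 4))
        oracle = (sum(abs(a - b) for a, b in zip(xc.ravel(), x.ravel()))
                  / x.size
                  + sum(abs(a - b) for a, b in zip(yc.ravel(), y.ravel()))
                  / y.size)
        assert L.cycle_loss(x, xc, y, yc) == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(L.ContractError):
            L.cycle_loss(np.zeros((1, 3, 4, 4)), np.zeros((1, 3, 8, 8)),
                         np.zeros((1, 3, 4, 4)), np.zeros((1, 3, 4, 4)))


# ---------------------------------------------------------------------------
# feature consistency
# ---------------------------------------------------------------------------

class _IdentityExtractor:
    """Stub returning its input as the single feature layer."""

    def forward_taps(self, x):
        return {"id": np.asarray(x, dtype=np.float64)}, None


class TestFeatureLoss:
    def test_identical_images_give_zero(self, rng):
        ex = L.FeatureExtractor(L.FeatureExtractorSpec(
            layer_set=("relu1_1",), seed=3))
        x = (rng.normal(size=(1, 3, 16, 16)) * 0.3).astype(np.float32)
        y = (rng.normal(size=(1, 3, 16, 16)) * 0.3).astype(np.float32)
        assert L.feature_loss(x, x, y, y, ex) == 0.0

    def test_constant_offset_under_identity_stub(self, rng):
        x = rng.normal(size=(1, 2, 4, 4))
        y = rng.normal(size=(1, 2, 4, 4))
        c = 0.37
        val = L.feature_loss(x, x + c, y, y, _IdentityExtractor())
        assert val == pytest.approx(c ** 2, rel=1e-9)

    def test_matches_independent_recomputation(self, rng):
        """Layer-by-layer oracle re-computation via scipy correlate."""
        from scipy.ndimage import correlate

        spec = L.FeatureExtractorSpec(layer_set=("relu1_1",), seed=5)
        ex = L.FeatureExtractor(spec)
        x = (rng.normal(size=(1, 3, 8, 8)) * 0.4).astype(np.float32)
        xt = (rng.normal(size=(1, 3, 8, 8)) * 0.4).astype(np.float32)

        def oracle_features(img):
            h = ex._normalize(img)[0].astype(np.float64)
            conv = ex.layers[0][1]
            w, b = conv.weight.data, conv.bias.data
            out = np.zeros((w.shape[0], 8, 8))
            for o in range(w.shape[0]):
                acc = np.zeros((8, 8))
                for ci in range(3):
                    acc += correlate(h[ci], w[o, ci], mode="constant")
                out[o] = acc + b[o]
            return np.maximum(out, 0)

        fa, fb = oracle_features(x), oracle_features(xt)
        oracle = ((fa - fb) ** 2).sum() / fa.size
        got = L._feat_term(*[d for d, _ in (ex.forward_taps(x),
                                            ex.forward_taps(xt))], "l2")
        assert got == pytest.approx(oracle, rel=1e-4)

    def test_empty_layer_set_rejected(self):
        with pytest.raises(L.ContractError):
            L.FeatureExtractorSpec(layer_set=())

    def test_direction_grad_matches_finite_difference(self, rng):
        ex = L.FeatureExtractor(L.FeatureExtractorSpec(
            layer_set=("relu1_1",), seed=2))
        x = (rng.normal(size=(1, 3, 8, 8)) * 0.4).astype(np.float32)
        t = (rng.normal(size=(1, 3, 8, 8)) * 0.4).astype(np.float32)
        _, grad = L.feature_loss_direction_grad(x, t, ex)
        eps = 1e-3
        for idx in [(0, 0, 2, 2), (0, 2, 6, 3)]:
            tp, tm = t.copy(), t.copy()
            tp[idx] += eps
            tm[idx] -= eps
            num = (L._feat_term(ex.forward_taps(x)[0],
                                ex.forward_taps(tp)[0], "l2")
                   - L._feat_term(ex.forward_taps(x)[0],
                                  ex.forward_taps(tm)[0], "l2")) / (2 * eps)
            assert grad[idx] == pytest.approx(num, abs=5e-4)


# ---------------------------------------------------------------------------
# saliency
# ---------------------------------------------------------------------------

def bruteforce_open_close(mask):
    """Manual 3x3 erosion/dilation with same-as-edge border handling."""
    def erode(m):
        p = np.pad(m, 1, constant_values=1)
        out = np.ones_like(m)
        for di in (0, 1, 2):
            for dj in (0, 1, 2):
                out &= p[di:di + m.shape[0], dj:dj + m.shape[1]]
        return out

    def dilate(m):
        p = np.pad(m, 1, constant_values=0)
        out = np.zeros_like(m)
        for di in (0, 1, 2):
            for dj in (0, 1, 2):
                out |= p[di:di + m.shape[0], dj:dj + m.shape[1]]
        return out

    return erode(dilate(dilate(erode(mask))))


class TestSaliencyMap:
    def test_uniform_above_threshold_all_ones(self):
        img = np.full((8, 8), 200, dtype=np.uint8)
        assert L.saliency_map(img, L.SaliencyOperatorSpec.for_af()).all()

    def test_uniform_below_threshold_all_zeros(self):
        img = np.full((8, 8), 100, dtype=np.uint8)
        assert not L.saliency_map(img, L.SaliencyOperatorSpec.for_af()).any()

    def test_isolated_pixel_removed_by_opening(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[4, 4] = 250
        assert not L.saliency_map(img).any()

    def test_matches_bruteforce_morphology_oracle(self, rng):
        spec = L.SaliencyOperatorSpec.for_af()
        for _ in range(20):
            img = (rng.random((8, 8)) * 255).astype(np.uint8)
            got = L.saliency_map(img, spec).astype(bool)
            want = bruteforce_open_close(img >= 170)
            assert np.array_equal(got, want)

    def test_dark_polarity_inverts_before_threshold(self):
        img = np.full((8, 8, 3), 30, dtype=np.uint8)  # dark H&E nuclei
        assert L.saliency_map(img, L.SaliencyOperatorSpec.for_he()).all()

    def test_idempotent_under_reapplied_morphology(self, rng):
        for _ in range(10):
            img = (rng.random((12, 12)) * 255).astype(np.uint8)
            m = L.saliency_map(img).astype(bool)
            assert np.array_equal(L._open_close(m), m)


class TestSaliencyLoss:
    def test_mask_preserving_translation_is_zero(self):
        img = np.zeros((16, 16), dtype=np.uint8)
        img[4:12, 4:12] = 255
        af = np.stack([img, img, img]) / 255.0
        he = 1.0 - np.stack([img, img, img], axis=-1) / 255.0
        val = L.saliency_loss(af, he, he, af)
        assert val == 0.0

    def test_half_disagreement_gives_half(self):
        a = np.full((8, 8), 255, dtype=np.uint8)  # all salient
        b = np.zeros((8, 8), dtype=np.uint8)
        b[:4] = 255  # half salient
        # same (bright) polarity both domains: direction 1 masks differ on
        # half the pixels, direction 2 is identical
        bright = L.SaliencyOperatorSpec.for_af()
        val = L.saliency_loss(a, b, a, a, bright, bright)
        assert val == pytest.approx(0.5)

    def test_paired_phantoms_beat_shuffled_pairs(self):
        """Shared-layout MAF/H&E pairs agree in saliency more than
        mismatched pairs, for every generated fixture."""
        specs = [phantom.PhantomSpec(image_size=64, nuclei_rate=8.0,
                                     nucleus_axes=(6.0, 4.5, 1.0), seed=s)
                 for s in range(4)]
        layouts = [phantom.sample_layout(s) for s in specs]
        mafs = [phantom.render_maf(l, s).planes
                for l, s in zip(layouts, specs)]
        hes = [phantom.render_he(l, s).rgb for l, s in zip(layouts, specs)]
        for i in range(4):
            paired = L.saliency_loss(mafs[i], hes[i], hes[i], mafs[i])
            j = (i + 1) % 4
            mismatched = L.saliency_loss(mafs[i], hes[j], hes[j], mafs[i])
            assert paired < mismatched


# ---------------------------------------------------------------------------
# total
# ---------------------------------------------------------------------------

class TestTotalLoss:
    def test_zero_components(self):
        rep = L.LossReport(0, 0, 0, 0, 0, 0)
        assert L.total_loss(rep, L.LossWeights()) == 0.0

    def test_unit_components_with_default_weights(self):
        rep = L.LossReport(1, 1, 1, 1, 1, 0)
        assert L.total_loss(rep, L.LossWeights(10, 1, 1)) == 14.0

    def test_linear_in_cycle_weight(self):
        rep = L.LossReport(0.3, 0.4, 2.0, 0.5, 0.6, 0)
        base = L.total_loss(rep, L.LossWeights(10, 1, 1))
        doubled = L.total_loss(rep, L.LossWeights(20, 1, 1))
        assert doubled - base == pytest.approx(10 * rep.l_cyc)

    def test_nonfinite_component_raises_divergence(self):
        rep = L.LossReport(np.nan, 0, 0, 0, 0, 0)
        with pytest.raises(L.DivergenceError):
            L.total_loss(rep, L.LossWeights())

    def test_report_self_consistency_check(self):
        rep = L.LossReport(1, 1, 1, 1, 1, 999.0)
        with pytest.raises(L.ContractError):
            rep.check(L.LossWeights())

    def test_negative_weights_rejected(self):
        with pytest.raises(L.ContractError):
            L.LossWeights(lambda_cyc=-1)
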