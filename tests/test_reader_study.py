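"""Reader-study statistics against enumeration and all-pairs oracles."""

import numpy as np
import pytest
from scipy import stats

from vstain import reader_study as rs


class TestWilcoxon:
    def test_three_positive_differences(self):
        """All-positive (1,2,3): W = 6 and exact two-sided p = 2/8."""
        w, p = rs.wilcoxon_signed_rank([1, 2, 3])
        assert w == 6.0
        assert p == pytest.approx(0.25)

    def test_antisymmetric_differences_give_p_one(self):
        _, p = rs.wilcoxon_signed_rank([-2, -1, 1, 2])
        assert p == pytest.approx(1.0)

    def test_all_zero_differences_degenerate(self):
        with pytest.raises(rs.DegenerateDataError):
            rs.wilcoxon_signed_rank([0, 0, 0])

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_scipy_without_ties(self, seed):
        rng = np.random.default_rng(seed)
        mags = rng.choice(np.arange(1, 40), size=10, replace=False)
        d = mags * rng.choice([-1, 1], size=10)
        _, p = rs.wilcoxon_signed_rank(d)
        assert p == pytest.approx(stats.wilcoxon(d, mode="exact").pvalue,
                                  abs=1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_exact_matches_sign_enumeration_with_ties(self, seed):
        """DP convolution vs the full 2^n enumeration for n <= 12."""
        rng = np.random.default_rng(100 + seed)
        d = rng.integers(-3, 4, size=12)
        d = d[d != 0]
        w, p = rs.wilcoxon_signed_rank(d)
        ranks = stats.rankdata(np.abs(d))
        mu = ranks.sum() / 2
        n = len(d)
        ws = np.array([
            ranks[[(m >> i) & 1 == 1 for i in range(n)]].sum()
            for m in range(2 ** n)
        ])
        p_oracle = np.mean(np.abs(ws - mu) >= abs(w - mu) - 1e-9)
        assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_large_n_matches_permutation_oracle(self):
        """Tie-corrected normal approximation vs a random-sign resampling
        oracle at n = 30."""
        rng = np.random.default_rng(7)
        d = rng.integers(-5, 6, size=30)
        d = d[d != 0]
        w, p = rs.wilcoxon_signed_rank(d)
        ranks = stats.rankdata(np.abs(d))
        mu = ranks.sum() / 2
        draws = rng.choice([-1.0, 1.0], size=(200_000, len(d)))
        ws = (ranks * (draws > 0)).sum(axis=1)
        p_mc = np.mean(np.abs(ws - mu) >= abs(w - mu) - 1e-9)
        assert p == pytest.approx(p_mc, abs=0.02)

    def test_by_feature_report_shape(self):
        table = rs.simulate_score_table(10, 3, seed=2)
        rep = rs.wilcoxon_by_feature(table)
        assert list(rep.index) == list(rs.FEATURES)
        assert (rep.p <= 1).all() and (rep.p > 0).all()


class TestConcordanceMatrix:
    def _table(self, pairs):
        rows = []
        for i, (v, h) in enumerate(pairs):
            for modality, score in (("vHE", v), ("HE", h)):
                rows.append({"image_pair_id": i, "modality": modality,
                             "reader_id": 0, "nuclear": score,
                             "cytoplasm": score, "matrix": score,
                             "overall": score})
        import pandas as pd
        return pd.DataFrame(rows)

    def test_perfect_agreement(self):
        mat, frac = rs.concordance_matrix(self._table([(4, 4)] * 5), "overall")
        assert mat[3, 3] == 5 and mat.sum() == 5
        assert frac == 1.0

    def test_counting_fraction(self):
        pairs = [(4, 3), (3, 3), (4, 2), (3, 2), (4, 4), (2, 3)]
        mat, frac = rs.concordance_matrix(self._table(pairs), "overall")
        assert frac == pytest.approx(5 / 6)

    def test_total_equals_complete_pairs(self):
        table = rs.simulate_score_table(12, 4, seed=5)
        mat, _ = rs.concordance_matrix(table, "nuclear")
        assert mat.sum() == len(rs.complete_pairs(table, "nuclear"))

    def test_marginals_reproduce_score_histograms(self):
        table = rs.simulate_score_table(15, 3, seed=8)
        mat, _ = rs.concordance_matrix(table, "cytoplasm")
        pairs = rs.complete_pairs(table, "cytoplasm")
        vhe_hist = np.bincount(pairs["vhe"].astype(int), minlength=5)[1:]
        he_hist = np.bincount(pairs["he"].astype(int), minlength=5)[1:]
        assert np.array_equal(mat.sum(axis=1), vhe_hist)
        assert np.array_equal(mat.sum(axis=0), he_hist)


class TestModalityRoc:
    def test_identical_distributions_auc_half(self):
        table = rs.simulate_score_table(40, 5, vhe_shift=0.0, seed=3)
        roc = rs.modality_roc(table, rs.RocScenario.poor_vs_good())
        assert abs(roc["auc"] - 0.5) < 0.1

    def test_perfect_separation(self):
        import pandas as pd
        rows = []
        for i in range(10):
            rows.append({"image_pair_id": i, "modality": "vHE",
                         "reader_id": 0, "nuclear": 4, "cytoplasm": 4,
                         "matrix": 4, "overall": 4})
            rows.append({"image_pair_id": i, "modality": "HE",
                         "reader_id": 0, "nuclear": 1, "cytoplasm": 1,
                         "matrix": 1, "overall": 1})
        roc = rs.modality_roc(pd.DataFrame(rows),
                              rs.RocScenario.poor_vs_good())
        assert roc["auc"] == 1.0
        assert roc["sensitivity"] == 1.0 and roc["specificity"] == 1.0

    def test_auc_matches_all_pairs_oracle(self):
        table = rs.simulate_score_table(10, 1, vhe_shift=0.4, seed=11)
        scenario = rs.RocScenario.good_vs_excellent()
        roc = rs.modality_roc(table, scenario)
        comp = rs.composite_score(table)
        score = (comp >= scenario.threshold).to_numpy().astype(float)
        pos = (table.modality == "vHE").to_numpy()
        concordant = 0.0
        n_pairs = 0
        for sv in score[pos]:
            for sh in score[~pos]:
                n_pairs += 1
                concordant += 1.0 if sv > sh else (0.5 if sv == sh else 0.0)
        assert roc["auc"] == pytest.approx(concordant / n_pairs, abs=1e-12)

    def test_auc_complement_identity(self, rng):
        scores = rng.random(30)
        pos = rng.random(30) > 0.5
        assert rs.auc_rank(scores, pos) + rs.auc_rank(scores, ~pos) == \
            pytest.approx(1.0)

    def test_single_class_rejected(self):
        import pandas as pd
        rows = [{"image_pair_id": 0, "modality": "vHE", "reader_id": 0,
                 "nuclear": 3, "cytoplasm": 3, "matrix": 3, "overall": 3}]
        with pytest.raises(rs.ContractError):
            rs.modality_roc(pd.DataFrame(rows), rs.RocScenario.poor_vs_good())


def test_score_validation_rejects_out_of_range():
    table = rs.simulate_score_table(4, 1, seed=0)
    table.loc[0, "nuclear"] = 5
    with pytest.raises(rs.ContractError):
        rs.validate_scores(table)
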