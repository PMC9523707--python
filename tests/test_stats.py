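"""Chemometric layer: %RSD, Fisher sieve, PCA, correlations, two-way ANOVA."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats as sps

import gcxfp as g
from gcxfp.align import FeatureTable
from gcxfp.chroma import SampleMeta


def toy_table(matrix, class_labels, feature_ids=None):
    matrix = np.asarray(matrix, dtype=float)
    ids = feature_ids or [f"F{i:03d}" for i in range(matrix.shape[0])]
    cols = [f"s{i}" for i in range(matrix.shape[1])]
    meta = [SampleMeta(c, lab, i) for i, (c, lab) in
            enumerate(zip(cols, class_labels), 1)]
    resp = pd.DataFrame(matrix, index=ids, columns=cols)
    feats = pd.DataFrame({
        "feature_id": ids, "kind": "untargeted", "identity": "",
        "chem_class": "", "rt1_min": 10.0, "rt2_s": 1.0, "origin": "peak",
    }).set_index("feature_id", drop=False)
    empty = pd.DataFrame(False, index=ids, columns=cols)
    return FeatureTable(features=feats, responses=resp, normalized=resp,
                        missing=empty, meta=meta)


class TestRsd:
    def test_constant_values_have_zero_rsd(self):
        assert g.rsd([10, 10, 10]) == 0.0

    def test_two_point_sample_sd_formula(self):
        assert g.rsd([9, 11]) == pytest.approx(14.14, abs=0.01)

    @settings(derandomize=True, max_examples=50)
    @given(c=st.floats(0.1, 100.0))
    def test_scale_invariance(self, c):
        base = np.array([3.0, 5.0, 9.0, 4.0])
        assert g.rsd(base * c) == pytest.approx(g.rsd(base), rel=1e-9)

    def test_zero_mean_flagged_undefined(self):
        assert math.isnan(g.rsd([-1.0, 1.0]))


class TestFisherRatio:
    def test_hand_worked_two_group_anova(self):
        assert g.fisher_ratio([1, 2, 3, 4, 5, 6],
                              ["a", "a", "a", "b", "b", "b"]) == \
            pytest.approx(13.5)

    def test_equal_class_means_give_zero(self):
        y = [1.0, 3.0, 1.0, 3.0]  # identical means, nonzero within-variance
        assert g.fisher_ratio(y, ["a", "a", "b", "b"]) == pytest.approx(0.0)

    def test_affine_invariance(self):
        y = np.array([1.0, 2.0, 3.0, 7.0, 8.0, 10.0])
        lab = ["a", "a", "a", "b", "b", "b"]
        assert g.fisher_ratio(3.2 * y + 11, lab) == \
            pytest.approx(g.fisher_ratio(y, lab))

    def test_zero_within_variance_flags_infinity(self):
        assert math.isinf(g.fisher_ratio([1, 1, 2, 2], ["a", "a", "b", "b"]))


class TestFCritical:
    def test_reference_value_for_4_and_8_df(self):
        assert round(g.f_critical(4, 8, 0.05), 2) == 3.84

    def test_z_squared_limit_for_one_numerator_df(self):
        assert g.f_critical(1, 10_000_000, 0.05) == \
            pytest.approx(sps.norm.ppf(0.975) ** 2, rel=1e-3)

    def test_median_quantile_against_density_quadrature(self):
        crit = g.f_critical(4, 8, 0.5)
        mass, _ = integrate.quad(lambda x: sps.f.pdf(x, 4, 8), 0, crit)
        assert mass == pytest.approx(0.5, abs=1e-6)

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            g.f_critical(0, 8, 0.05)
        with pytest.raises(ValueError):
            g.f_critical(4, 8, 1.5)


class TestSieve:
    def _table(self):
        rng = np.random.default_rng(0)
        labels = ["a"] * 4 + ["b"] * 4 + ["c"] * 4
        null = rng.normal(100, 5, size=(90, 12))
        effect = rng.normal(100, 5, size=(10, 12))
        effect[:, 4:8] += 60.0  # strong class-b shift
        return toy_table(np.vstack([effect, null]), labels)

    def test_planted_discriminators_pass_nulls_mostly_fail(self):
        table = self._table()
        kept = g.sieve(table, threshold=g.f_critical(2, 9, 0.05))
        kept_ids = set(kept.features.index)
        planted = {f"F{i:03d}" for i in range(10)}
        assert len(planted & kept_ids) >= 9
        assert len(kept_ids - planted) <= 10

    def test_threshold_zero_keeps_all_finite(self):
        table = self._table()
        assert len(g.sieve(table, threshold=0.0).features) == 100

    def test_infinite_threshold_empties_the_table(self):
        table = self._table()
        assert len(g.sieve(table, threshold=math.inf).features) == 0

    def test_monotone_in_threshold(self):
        table = self._table()
        prev = None
        for thr in (0.0, 1.0, 3.84, 10.0, 100.0):
            kept = set(g.sieve(table, threshold=thr).features.index)
            if prev is not None:
                assert kept <= prev
            prev = kept


class TestPca:
    def _separated(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, size=(20, 10))
        b = rng.normal(6, 1, size=(20, 10))
        X = np.hstack([a, b])  # 20 features × 20 samples
        return pd.DataFrame(X, index=[f"F{i}" for i in range(20)],
                            columns=[f"s{i}" for i in range(20)])

    def test_two_planted_classes_separate_on_first_components(self):
        from sklearn.metrics import silhouette_score
        res = g.pca(self._separated())
        labels = [0] * 10 + [1] * 10
        assert silhouette_score(res.scores.iloc[:, :2], labels) > 0.5

    def test_scores_are_centered(self):
        res = g.pca(self._separated())
        assert np.allclose(res.scores.mean(axis=0), 0.0, atol=1e-9)

    def test_explained_variance_fractions_sum_to_one(self):
        res = g.pca(self._separated())
        assert res.explained_variance_ratio.sum() == pytest.approx(1.0)

    def test_constant_features_dropped_with_warning(self):
        df = self._separated()
        df.loc["F0"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            res = g.pca(df)
        assert "F0" in res.dropped_features


class TestCorrelationClustering:
    def _frame(self, rows):
        return pd.DataFrame(rows, index=[f"F{i}" for i in range(len(rows))],
                            columns=[f"s{i}" for i in range(len(rows[0]))])

    def test_proportional_features_correlate_perfectly(self):
        x = np.arange(1.0, 11.0)
        cc = g.correlation_clustered_heatmap(self._frame([x, 2 * x, -x]))
        assert cc.correlation.loc["F0", "F1"] == pytest.approx(1.0)
        assert cc.correlation.loc["F0", "F2"] == pytest.approx(-1.0)
        assert {"F0", "F1"} == set(
            cc.strong_pairs[["feature_a", "feature_b"]].iloc[0])

    def test_zscore_rows_standardized(self):
        rng = np.random.default_rng(2)
        cc = g.correlation_clustered_heatmap(
            self._frame(rng.normal(50, 9, size=(5, 12))))
        assert np.allclose(cc.zscores.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(cc.zscores.std(axis=1, ddof=1), 1.0, atol=1e-9)

    def test_latent_factor_pair_recovered_at_study_size(self):
        # an acid and its ester driven by one biosynthetic factor, n = 35
        rng = np.random.default_rng(3)
        latent = rng.lognormal(0.0, 1.0, size=35)
        acid = latent * np.exp(rng.normal(0, 0.12, 35))
        ester = 0.4 * latent * np.exp(rng.normal(0, 0.12, 35))
        cc = g.correlation_clustered_heatmap(
            self._frame([acid, ester, rng.normal(10, 1, 35)]))
        assert cc.correlation.loc["F0", "F1"] >= 0.9
        assert (("F0", "F1") in
                {tuple(r) for r in
                 cc.strong_pairs[["feature_a", "feature_b"]].to_numpy()})

    def test_zero_variance_rows_excluded_with_warning(self):
        x = np.arange(1.0, 11.0)
        with pytest.warns(UserWarning, match="zero-variance"):
            cc = g.correlation_clustered_heatmap(
                self._frame([x, np.full(10, 3.0)]))
        assert list(cc.correlation.index) == ["F0"]


class TestResponseRatio:
    def test_identical_class_means_ratio_one(self):
        table = toy_table([[5, 5, 5, 5]], ["a", "a", "b", "b"])
        assert g.response_ratio(table, "a", "b").iloc[0] == pytest.approx(1.0)

    def test_zero_denominator_flags_infinity(self):
        table = toy_table([[5, 5, 0, 0]], ["a", "a", "b", "b"])
        assert math.isinf(g.response_ratio(table, "a", "b").iloc[0])

    def test_both_zero_flags_undefined(self):
        table = toy_table([[0, 0, 0, 0]], ["a", "a", "b", "b"])
        assert math.isnan(g.response_ratio(table, "a", "b").iloc[0])

    def test_unknown_class_rejected(self):
        table = toy_table([[1, 2, 3, 4]], ["a", "a", "b", "b"])
        with pytest.raises(KeyError):
            g.response_ratio(table, "a", "nope")


class TestTwoWayAnova:
    def _balanced(self):
        # 2 DM levels × 3 inocula × 3 replicates
        rng = np.random.default_rng(4)
        rows = []
        for ai, a in enumerate(["low", "high"]):
            for bj, b in enumerate(["con", "lbuc", "lpar"]):
                for _ in range(3):
                    rows.append((a, b, 10 + 2 * ai + 5 * bj
                                 + rng.normal(0, 1.0)))
        fa, fb, y = zip(*rows)
        return np.array(y), np.array(fa), np.array(fb)

    def test_additive_noise_free_data_has_zero_interaction(self):
        y, fa, fb = [], [], []
        for ai, a in enumerate(["low", "high"]):
            for bj, b in enumerate(["con", "lbuc", "lpar"]):
                for _ in range(2):
                    y.append(1.0 + 2 * ai + 3 * bj)
                    fa.append(a)
                    fb.append(b)
        res = g.two_way_anova(y, fa, fb)
        assert res.ss["DxL"] == pytest.approx(0.0, abs=1e-9)

    def test_sum_of_squares_decomposition_is_exact(self):
        y, fa, fb = self._balanced()
        res = g.two_way_anova(y, fa, fb)
        assert res.ss["total"] == pytest.approx(
            res.ss["D"] + res.ss["L"] + res.ss["DxL"] + res.ss["error"])

    def test_agrees_with_statsmodels_oracle(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        y, fa, fb = self._balanced()
        res = g.two_way_anova(y, fa, fb)
        frame = pd.DataFrame({"y": y, "a": fa, "b": fb})
        fit = ols("y ~ C(a) * C(b)", data=frame).fit()
        tbl = sm.stats.anova_lm(fit, typ=2)
        assert res.ss["D"] == pytest.approx(tbl.loc["C(a)", "sum_sq"])
        assert res.ss["L"] == pytest.approx(tbl.loc["C(b)", "sum_sq"])
        assert res.ss["DxL"] == pytest.approx(tbl.loc["C(a):C(b)", "sum_sq"])
        assert res.p["L"] == pytest.approx(tbl.loc["C(b)", "PR(>F)"])

    def test_strong_inoculum_effect_separates_letter_groups(self):
        y, fa, fb = self._balanced()
        res = g.two_way_anova(y, fa, fb)
        assert res.letters["con"] != res.letters["lpar"]

    def test_all_equal_responses_single_letter_group(self):
        y = [5.0] * 12
        fa = ["low", "high"] * 6
        fb = (["con"] * 2 + ["lbuc"] * 2 + ["lpar"] * 2) * 2
        res = g.two_way_anova(y, fa, fb)
        assert math.isnan(res.f["L"])
        assert len(set(res.letters.values())) == 1

    def test_empty_cell_rejected(self):
        with pytest.raises(ValueError, match="cell"):
            g.two_way_anova([1, 2, 3, 4], ["a", "a", "b", "b"],
                            ["x", "y", "x", "x"])


class TestTTest:
    def test_identical_groups_give_unit_p(self):
        t, p = g.t_test_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_worked_pooled_t(self):
        t, p = g.t_test_unpaired([1, 2, 3], [4, 5, 6])
        assert t == pytest.approx(-3.674, abs=1e-3)

    def test_swapping_groups_flips_sign(self):
        t1, _ = g.t_test_unpaired([1, 2, 3], [4, 5, 6])
        t2, _ = g.t_test_unpaired([4, 5, 6], [1, 2, 3])
        assert t1 == pytest.approx(-t2)

    def test_zero_pooled_variance_flagged(self):
        t, p = g.t_test_unpaired([1.0, 1.0], [1.0, 1.0])
        assert math.isnan(t) and math.isnan(p)
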