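"""One-way random-effects ICC estimator, its CI, and the feature filters."""

import numpy as np
import pandas as pd
import pytest

from _oracles import icc1_via_f_oneway
from radrepeat.repeatability import (
    RepeatPanel,
    agreement_table,
    feature_icc_table,
    icc_one_way,
    repeatability_filter,
    univariate_significance,
    volume_dependence_filter,
)


def simulate_panel(rng, n=20, k=5, sigma_b=2.0, sigma_w=1.0):
    s = rng.normal(0, sigma_b, size=(n, 1))
    return RepeatPanel([f"s{i}" for i in range(n)],
                       s + rng.normal(0, sigma_w, size=(n, k)))


class TestICC:
    def test_identical_repeats_give_one(self):
        panel = RepeatPanel(list("abc"), np.array([[1.0, 1, 1], [2, 2, 2], [5, 5, 5]]))
        est = icc_one_way(panel)
        assert est.icc == 1.0
        assert est.ci95 == (1.0, 1.0)

    def test_matches_f_oneway_oracle_on_random_panels(self):
        """Estimator equals the ICC derived from scipy's one-way ANOVA F
        statistic on 100 random panels to 1e-10."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 30))
            k = int(rng.integers(2, 10))
            panel = simulate_panel(rng, n, k, rng.uniform(0.1, 3), rng.uniform(0.1, 3))
            est = icc_one_way(panel)
            assert est.icc == pytest.approx(icc1_via_f_oneway(panel.values), abs=1e-10)

    def test_matches_pingouin_point_and_ci(self):
        """Cross-check point estimate and 95% CI against pingouin ICC1."""
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        for _ in range(5):
            panel = simulate_panel(rng, n=15, k=4)
            est = icc_one_way(panel)
            long = pd.DataFrame({
                "subject": np.repeat(panel.subject_ids, panel.k_repeats),
                "rater": np.tile(np.arange(panel.k_repeats), panel.n_subjects),
                "value": panel.values.reshape(-1),
            })
            res = pingouin.intraclass_corr(long, "subject", "rater", "value")
            ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
            row = res[res["Type"].str.startswith(("ICC1", "ICC(1,1)"))].iloc[0]
            assert est.icc == pytest.approx(row["ICC"], abs=1e-8)
            # pingouin rounds the CI to two decimals
            assert est.ci95[0] == pytest.approx(row[ci_col][0], abs=0.011)
            assert est.ci95[1] == pytest.approx(row[ci_col][1], abs=0.011)

    def test_pure_noise_centers_on_zero(self):
        """Subjects identical, repeats pure noise: mean ICC over 500
        panels within +/-0.05 of 0."""
        rng = np.random.default_rng(2)
        vals = [icc_one_way(simulate_panel(rng, 12, 4, sigma_b=0.0)).icc
                for _ in range(500)]
        assert abs(np.mean(vals)) < 0.05

    def test_recovery_of_variance_ratio(self):
        """sigma_b^2=4, sigma_w^2=1, n=100, k=40: mean estimate within
        +/-0.02 of the closed-form 0.8 over 200 seeds."""
        rng = np.random.default_rng(3)
        vals = [icc_one_way(simulate_panel(rng, 100, 40, 2.0, 1.0)).icc
                for _ in range(200)]
        assert abs(np.mean(vals) - 0.8) < 0.02

    def test_ci_coverage_near_nominal(self):
        """~95% of CIs cover the true ICC (+/-3% over 500 panels)."""
        rng = np.random.default_rng(4)
        cover = 0
        for _ in range(500):
            est = icc_one_way(simulate_panel(rng, 30, 5, 2.0, 1.0))
            cover += est.ci95[0] <= 0.8 <= est.ci95[1]
        assert abs(cover / 500 - 0.95) < 0.03

    def test_affine_invariance(self):
        rng = np.random.default_rng(5)
        panel = simulate_panel(rng)
        base = icc_one_way(panel).icc
        shifted = RepeatPanel(panel.subject_ids, panel.values + 100.0)
        scaled = RepeatPanel(panel.subject_ids, panel.values * 3.5)
        assert icc_one_way(shifted).icc == pytest.approx(base, abs=1e-10)
        assert icc_one_way(scaled).icc == pytest.approx(base, abs=1e-10)

    def test_zero_variance_degenerate(self):
        panel = RepeatPanel(list("ab"), np.full((2, 3), 7.0))
        est = icc_one_way(panel)
        assert est.degenerate and np.isnan(est.icc)

    def test_k_plus_1_denominator_variant(self):
        """The audit flag reproduces the printed (k+1) denominator."""
        rng = np.random.default_rng(6)
        panel = simulate_panel(rng, 10, 4)
        std = icc_one_way(panel)
        strict = icc_one_way(panel, k_plus_1_denominator=True)
        y = panel.values
        n, k = y.shape
        ms_r = k * ((y.mean(1) - y.mean()) ** 2).sum() / (n - 1)
        ms_w = ((y - y.mean(1, keepdims=True)) ** 2).sum() / (n * (k - 1))
        assert strict.icc == pytest.approx((ms_r - ms_w) / (ms_r + (k + 1) * ms_w), abs=1e-12)
        assert strict.icc < std.icc


class TestFeatureICCTable:
    def _table(self, values, ids, k):
        idx = pd.MultiIndex.from_product([ids, range(k)], names=["subject", "repeat"])
        return pd.DataFrame(values, index=idx)

    def test_zero_noise_all_one(self):
        ids = [f"s{i}" for i in range(6)]
        base = np.arange(6.0).repeat(3)
        tab = self._table({"f1": base, "f2": base * 2 + 1}, ids, 3)
        icc = feature_icc_table(tab)
        assert np.allclose(icc["icc"], 1.0)

    def test_graded_noise_group_recovery(self):
        """Three feature groups with target ICCs 0.3/0.7/0.95: group-mean
        estimates recover the targets within +/-0.05."""
        rng = np.random.default_rng(7)
        n, k = 120, 20
        ids = [f"s{i}" for i in range(n)]
        cols = {}
        for target, tag in ((0.3, "lo"), (0.7, "mid"), (0.95, "hi")):
            sigma_w = np.sqrt((1 - target) / target)
            for j in range(10):
                s = rng.normal(0, 1, size=(n, 1))
                cols[f"{tag}{j}"] = (s + rng.normal(0, sigma_w, size=(n, k))).reshape(-1)
        tab = self._table(cols, ids, k)
        icc = feature_icc_table(tab)
        for target, tag in ((0.3, "lo"), (0.7, "mid"), (0.95, "hi")):
            got = icc.loc[[c for c in icc.index if c.startswith(tag)], "icc"].mean()
            assert abs(got - target) < 0.05

    def test_repeat_order_exchangeable(self):
        rng = np.random.default_rng(8)
        n, k = 15, 6
        ids = [f"s{i}" for i in range(n)]
        vals = rng.normal(size=(n, k))
        tab = self._table({"f": vals.reshape(-1)}, ids, k)
        shuffled = np.stack([rng.permutation(row) for row in vals])
        tab2 = self._table({"f": shuffled.reshape(-1)}, ids, k)
        a = feature_icc_table(tab).loc["f", "icc"]
        b = feature_icc_table(tab2).loc["f", "icc"]
        assert a == pytest.approx(b, abs=1e-12)

    def test_incomplete_subjects_dropped_with_log(self, caplog):
        ids = [f"s{i}" for i in range(5)]
        idx = pd.MultiIndex.from_product([ids, range(3)], names=["subject", "repeat"])
        tab = pd.DataFrame({"f": np.random.default_rng(0).normal(size=15)}, index=idx)
        tab = tab.drop(("s4", 2))
        import logging

        with caplog.at_level(logging.WARNING):
            icc = feature_icc_table(tab)
        assert icc.loc["f", "n"] == 4
        assert "dropping 1 subject" in caplog.text


class TestFilters:
    def test_mesh_volume_filters_itself(self):
        rng = np.random.default_rng(9)
        vols = rng.uniform(100, 1000, size=50)
        tab = pd.DataFrame({"vol_copy": vols, "noise": rng.normal(size=50)})
        kept = volume_dependence_filter(tab, vols, 0.6)
        assert "vol_copy" not in kept and "noise" in kept

    def test_independent_noise_retained(self):
        rng = np.random.default_rng(10)
        vols = rng.uniform(100, 1000, size=200)
        tab = pd.DataFrame({f"n{i}": rng.normal(size=200) for i in range(20)})
        kept = volume_dependence_filter(tab, vols, 0.6)
        assert len(kept) == 20

    def test_threshold_zero_retains_all_non_degenerate(self):
        icc = pd.DataFrame({"icc": [0.1, -0.2, 0.9, np.nan],
                            "degenerate": [False, False, False, True]},
                           index=list("abcd"))
        assert repeatability_filter(icc, 0.0) == ["a", "c"]

    def test_hand_table_and_nesting(self):
        icc = pd.DataFrame({"icc": [0.96, 0.91, 0.5],
                            "degenerate": [False] * 3}, index=list("abc"))
        assert repeatability_filter(icc, 0.9) == ["a", "b"]
        prev = None
        for thr in (0.95, 0.9, 0.5, 0.0):
            cur = set(repeatability_filter(icc, thr))
            if prev is not None:
                assert prev <= cur
            prev = cur


class TestAgreement:
    def _icc(self, d):
        return pd.DataFrame({"icc": list(d.values()),
                             "degenerate": [False] * len(d)}, index=list(d))

    def test_identical_tables_diagonal(self):
        t = self._icc({"a": 0.95, "b": 0.4, "c": 0.8})
        counts = agreement_table(t, t, 0.75)
        assert counts == {"P+/TR+": 2, "P+/TR-": 0, "P-/TR+": 0, "P-/TR-": 1}

    def test_hand_assignment(self):
        p = self._icc({"a": 0.9, "b": 0.9, "c": 0.2, "d": 0.2})
        t = self._icc({"a": 0.9, "b": 0.2, "c": 0.9, "d": 0.2})
        counts = agreement_table(p, t, 0.5)
        assert counts == {"P+/TR+": 1, "P+/TR-": 1, "P-/TR+": 1, "P-/TR-": 1}
        assert sum(counts.values()) == 4

    def test_mismatched_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            agreement_table(self._icc({"a": 1.0}), self._icc({"b": 1.0}), 0.5)


class TestUnivariate:
    def test_perfect_separation_tiny_p(self):
        y = np.array([0] * 10 + [1] * 10)
        assert univariate_significance(y.astype(float), y) < 1e-8

    def test_matches_t_transform_closed_form(self):
        """p equals the textbook t transform of r at n=12."""
        from scipy import stats

        rng = np.random.default_rng(11)
        x = rng.normal(size=12)
        y = np.array([0, 1] * 6)
        p = univariate_significance(x, y)
        r = np.corrcoef(x, y)[0, 1]
        t = r * np.sqrt(10 / (1 - r**2))
        expected = 2 * stats.t.sf(abs(t), 10)
        assert p == pytest.approx(expected, abs=1e-12)

    def test_null_p_values_uniform(self):
        """Independent feature: p-values uniform on (0,1) (KS test)."""
        from scipy import stats

        rng = np.random.default_rng(12)
        y = np.array([0] * 30 + [1] * 20)
        ps = [univariate_significance(rng.normal(size=50), y) for _ in range(1000)]
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_flagged(self):
        y = np.array([0, 1, 0, 1])
        with pytest.warns(UserWarning):
            assert univariate_significance(np.ones(4), y) == 1.0
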