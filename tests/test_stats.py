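"""Unit and property tests for the inference chain."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sstats
from scipy.special import gamma as gamma_fn

from coldwave import stats as S

RNG = np.random.default_rng


class TestIntervalReference:
    def _series(self, t, sbp, dbp=None, hr=None):
        n = len(t)
        return pd.DataFrame({
            "t": t, "SBP": sbp,
            "DBP": dbp if dbp is not None else [70.0] * n,
            "HR": hr if hr is not None else [60.0] * n})

    def test_odd_count_median(self):
        s = self._series([1.0, 2.0, 3.0], [118.0, 120.0, 122.0])
        assert S.interval_reference(s, 0.0)["SBP"] == 120.0

    def test_pulse_pressure_beatwise_before_median(self):
        s = self._series([1.0, 2.0], [120.0, 130.0], dbp=[80.0, 85.0])
        out = S.interval_reference(s, 0.0)
        assert out["PP"] == pytest.approx(42.5)

    def test_single_beat(self):
        s = self._series([5.0], [117.0])
        assert S.interval_reference(s, 0.0)["SBP"] == 117.0

    def test_empty_window_gives_nan(self):
        s = self._series([50.0], [120.0])
        out = S.interval_reference(s, 0.0)
        assert math.isnan(out["SBP"]) and math.isnan(out["PP"])


class TestRmAnova:
    @staticmethod
    def _bruteforce(x):
        """Independent sums-of-squares oracle: two-way decomposition with
        subject and condition effects, no interaction term."""
        n, k = x.shape
        grand = x.mean()
        ss_cond = sum(n * (x[:, j].mean() - grand) ** 2 for j in range(k))
        ss_subj = sum(k * (x[i].mean() - grand) ** 2 for i in range(n))
        ss_tot = ((x - grand) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_subj
        F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
        p = sstats.f.sf(F, k - 1, (k - 1) * (n - 1))
        return F, p

    def test_matches_bruteforce_oracle_on_random_tables(self):
        rng = RNG(0)
        for _ in range(100):
            x = rng.normal(size=(6, 3))
            res = S.rm_anova(x)
            F, p = self._bruteforce(x)
            assert res.F == pytest.approx(F, abs=1e-10, rel=1e-10)
            assert res.p == pytest.approx(p, abs=1e-10)

    def test_matches_statsmodels_anovarm(self):
        """Independent cross-check against the reference implementation."""
        from statsmodels.stats.anova import AnovaRM

        rng = RNG(1)
        x = rng.normal(size=(8, 3))
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(8), 3),
            "interval": np.tile(["BL", "ST1", "ST2"], 8),
            "value": x.ravel()})
        ref = AnovaRM(df, "value", "subject", within=["interval"]).fit()
        res = S.rm_anova(x)
        assert res.F == pytest.approx(
            float(ref.anova_table["F Value"].iloc[0]), rel=1e-10)

    def test_zero_error_variance_edge(self):
        """Values i + s per interval shift i and subject offset s: the error
        term vanishes and F is reported infinite."""
        shifts = np.array([0.0, 1.0, 2.0])
        x = shifts[None, :] + np.arange(4)[:, None]
        res = S.rm_anova(x)
        assert np.isinf(res.F)
        assert res.p == 0.0
        assert res.df_error == 6

    def test_power_at_large_effect(self):
        """A 2-sd interval effect at n = 35 is detected essentially always."""
        rng = RNG(2)
        hits = 0
        for _ in range(200):
            x = rng.normal(size=(35, 3))
            x[:, 1] += 2.0
            if S.rm_anova(x).p < 0.05:
                hits += 1
        assert hits >= 190


class TestPairedT:
    def test_identical_samples(self):
        x = np.arange(5.0)
        t, df, p = S.paired_t(x, x.copy())
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        """Differences [1, 2, 3]: t = 2 / (1 / sqrt(3)) = 2 sqrt(3)."""
        y = np.array([0.0, 0.0, 0.0])
        x = np.array([1.0, 2.0, 3.0])
        t, df, p = S.paired_t(x, y)
        assert t == pytest.approx(2.0 * math.sqrt(3.0), rel=1e-12)
        assert df == 2

    def test_antisymmetry(self):
        rng = RNG(3)
        x, y = rng.normal(size=10), rng.normal(size=10)
        t1, _, p1 = S.paired_t(x, y)
        t2, _, p2 = S.paired_t(y, x)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_null_p_values_uniform(self):
        """Under the null, paired-t p-values are Uniform(0, 1)."""
        rng = RNG(4)
        ps = [S.paired_t(rng.normal(size=12), rng.normal(size=12))[2]
              for _ in range(10_000)]
        assert sstats.kstest(ps, "uniform").pvalue > 0.01


class TestHolmBonferroni:
    def test_worked_example(self):
        np.testing.assert_allclose(
            S.holm_bonferroni([0.01, 0.02, 0.04]), [0.03, 0.04, 0.04])

    def test_equal_ps(self):
        np.testing.assert_allclose(
            S.holm_bonferroni([0.3, 0.3, 0.3]), [0.9, 0.9, 0.9])

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(S.holm_bonferroni([0.2]), [0.2])

    def test_cap_at_one(self):
        out = S.holm_bonferroni([0.5, 0.6, 0.9])
        assert out.max() <= 1.0

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = RNG(5)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 8))
            ref = multipletests(p, method="holm")[1]
            np.testing.assert_allclose(S.holm_bonferroni(p), ref,
                                       atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=10),
           st.randoms(use_true_random=False))
    def test_order_invariance(self, ps, rnd):
        """Adjusted values travel with their raw p's under permutation."""
        ps = list(ps)
        perm = list(range(len(ps)))
        rnd.shuffle(perm)
        out = S.holm_bonferroni(ps)
        out_perm = S.holm_bonferroni([ps[i] for i in perm])
        for j, i in enumerate(perm):
            assert out_perm[j] == pytest.approx(out[i], abs=1e-12)


class TestHedgesG:
    def test_bias_correction_closed_form(self):
        """J(4) = Gamma(2) / (sqrt(2) Gamma(1.5))."""
        expected = gamma_fn(2.0) / (math.sqrt(2.0) * gamma_fn(1.5))
        assert S.bias_correction(4) == pytest.approx(expected, abs=1e-12)

    def test_worked_example(self):
        """x=[1,2,3], y=[2,3,4]: pooled s = 1, df = 4, g = -J(4)."""
        g, lo, hi = S.hedges_g([1, 2, 3], [2, 3, 4])
        expected = -gamma_fn(2.0) / (math.sqrt(2.0) * gamma_fn(1.5))
        assert g == pytest.approx(expected, abs=1e-12)
        assert lo < g < hi

    def test_zero_for_identical(self):
        g, _, _ = S.hedges_g([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert g == 0.0

    def test_exact_antisymmetry(self):
        rng = RNG(6)
        x, y = rng.normal(size=9), rng.normal(1.0, 2.0, size=7)
        g1, lo1, hi1 = S.hedges_g(x, y)
        g2, lo2, hi2 = S.hedges_g(y, x)
        assert g1 == -g2
        assert lo1 == pytest.approx(-hi2, abs=1e-12)

    def test_correction_approaches_one_from_below(self):
        """J(df) < 1, increasing, and close to 1 - 3/(4 df - 1)."""
        dfs = np.arange(2, 200)
        js = np.array([S.bias_correction(d) for d in dfs])
        assert (js < 1.0).all()
        assert (np.diff(js) > 0).all()
        # the classical large-df approximation holds to ~1e-3 from df = 5 on
        approx = 1.0 - 3.0 / (4.0 * dfs - 1.0)
        assert np.abs(js - approx)[dfs >= 5].max() < 2e-3

    def test_noncentral_t_ci_contains_g(self):
        rng = RNG(7)
        x = rng.normal(0.5, 1.0, size=20)
        y = rng.normal(0.0, 1.0, size=20)
        g, lo, hi = S.hedges_g(x, y, ci_method="noncentral-t")
        assert lo < g < hi

    def test_zero_pooled_sd_raises(self):
        with pytest.raises(ValueError):
            S.hedges_g([1.0, 1.0], [1.0, 1.0])


class TestOutliersAndNormalization:
    def test_tukey_fence_example(self):
        assert S.count_outliers([1, 2, 3, 4, 100]) == 1

    def test_constant_vector(self):
        assert S.count_outliers([5.0] * 10) == 0

    def test_symmetric_data_no_outliers(self):
        assert S.count_outliers(np.linspace(-1, 1, 21)) == 0

    def test_normalize_triplet(self):
        np.testing.assert_allclose(S.normalize_for_plot([1.0, 2.0, 3.0]),
                                   [0.5, 1.0, 1.5])
        np.testing.assert_allclose(S.normalize_for_plot([2.0, 2.0, 2.0]),
                                   [1.0, 1.0, 1.0])

    def test_normalize_scale_invariant(self):
        v = np.array([0.8, 1.1, 1.4])
        np.testing.assert_allclose(S.normalize_for_plot(v),
                                   S.normalize_for_plot(10.0 * v))

    def test_zero_mean_flagged(self):
        with pytest.raises(ValueError):
            S.normalize_for_plot([-1.0, 0.0, 1.0])


def _null_table(rng, n=35):
    return pd.DataFrame({
        "subject": np.repeat([f"S{i}" for i in range(n)], 3),
        "site": "finger",
        "feature": "amplitude",
        "interval": np.tile(["BL", "ST1", "ST2"], n),
        "value": rng.normal(size=3 * n)})


class TestAnalyzeStudy:
    def test_gate_blocks_posthoc_but_reports_g(self):
        rng = RNG(8)
        # null data: usually a non-significant ANOVA
        for _ in range(20):
            table = _null_table(rng)
            anova, effects = S.analyze_study(table)
            if anova.iloc[0].p >= 0.05:
                assert effects.p_adj.isna().all()
                assert effects.g.notna().all()
                return
        pytest.fail("no non-significant ANOVA in 20 null draws")

    def test_injected_persistent_effect_pattern(self):
        """A drop at both stimulation intervals: BL contrasts significant,
        ST1-ST2 not."""
        rng = RNG(9)
        n = 35
        base = rng.normal(10.0, 2.0, size=n)
        vals = np.column_stack([
            base, base - 3.0 + rng.normal(0, 0.5, n),
            base - 3.0 + rng.normal(0, 0.5, n)])
        table = pd.DataFrame({
            "subject": np.repeat([f"S{i}" for i in range(n)], 3),
            "site": "finger", "feature": "amplitude",
            "interval": np.tile(["BL", "ST1", "ST2"], n),
            "value": vals.ravel()})
        _, effects = S.analyze_study(table)
        eff = effects.set_index("contrast")
        assert eff.loc["BL-ST1", "p_adj"] < 0.001
        assert eff.loc["BL-ST2", "p_adj"] < 0.001
        assert eff.loc["ST1-ST2", "p_adj"] > 0.05
        assert eff.loc["BL-ST1", "g"] < 0

    def test_incomplete_subject_dropped(self):
        rng = RNG(10)
        table = _null_table(rng, n=10)
        table = table[~((table.subject == "S3")
                        & (table.interval == "ST2"))]
        anova, _ = S.analyze_study(table)
        assert anova.iloc[0]["n"] == 9

    def test_contrast_sign_convention(self):
        """For contrast A-B, g is signed as (B - A): an increase from BL
        to ST1 yields positive g."""
        n = 20
        rng = RNG(11)
        base = rng.normal(0.0, 1.0, size=n)
        vals = np.column_stack([base,
                                base + 5.0 + rng.normal(0, 0.1, n),
                                base + rng.normal(0, 0.1, n)])
        table = pd.DataFrame({
            "subject": np.repeat([f"S{i}" for i in range(n)], 3),
            "site": "s", "feature": "f",
            "interval": np.tile(["BL", "ST1", "ST2"], n),
            "value": vals.ravel()})
        _, effects = S.analyze_study(table)
        eff = effects.set_index("contrast")
        assert eff.loc["BL-ST1", "g"] > 0
        assert eff.loc["ST1-ST2", "g"] < 0
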