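"""Cohort statistics: descriptives, RM-ANOVA, Holm-Sidak, correlations, OLS."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import rm_anova_oracle
from vfwave.stats import (
    baseline_variability_correlations,
    descriptives,
    holm_sidak,
    pairwise_vs_reference,
    pearson,
    rm_anova,
    rm_anova_null_rejection_rate,
    simple_linregress,
)


def _wide(values, subjects=None, timepoints=None):
    values = np.asarray(values, dtype=float)
    n, k = values.shape
    return pd.DataFrame(
        values,
        index=subjects or [f"s{i}" for i in range(n)],
        columns=timepoints or [f"t{j}" for j in range(k)],
    )


class TestDescriptives:
    def test_small_column(self):
        d = descriptives(_wide([[1.0], [2.0], [3.0]]))
        assert d.loc["t0", "mean"] == pytest.approx(2.0)
        assert d.loc["t0", "sd"] == pytest.approx(1.0)
        assert d.loc["t0", "sem"] == pytest.approx(1 / np.sqrt(3))
        assert d.loc["t0", "n"] == 3

    def test_constant_column_zero_sd(self):
        d = descriptives(_wide([[5.0], [5.0], [5.0]]))
        assert d.loc["t0", "sd"] == 0.0

    def test_hand_computed_sd(self):
        # sd of (2, 4, 4, 6) with n-1 denominator: sqrt((4+0+0+4)/3)
        d = descriptives(_wide([[2.0], [4.0], [4.0], [6.0]]))
        assert d.loc["t0", "sd"] == pytest.approx(np.sqrt(8 / 3), abs=1e-12)

    def test_single_observation_sd_missing(self):
        d = descriptives(_wide([[1.0, 2.0]])._append(
            pd.Series({"t0": 3.0, "t1": np.nan}, name="s1")))
        assert d.loc["t1", "n"] == 1
        assert np.isnan(d.loc["t1", "sd"])
        assert d.loc["t1", "mean"] == pytest.approx(2.0)


class TestRmAnova:
    def test_matches_textbook_oracle(self, rng):
        x = rng.standard_normal((5, 3))
        res = rm_anova(_wide(x))
        f, df_e, df_r = rm_anova_oracle(x)
        assert res.F == pytest.approx(f, abs=1e-10)
        assert (res.df_effect, res.df_error) == (df_e, df_r)

    def test_no_time_effect(self):
        """Subjects differ but are flat over time: F = 0, p = 1."""
        res = rm_anova(_wide([[1, 1, 1], [2, 2, 2], [5, 5, 5]]))
        assert res.F == 0.0
        assert res.p == 1.0

    def test_degenerate_zero_error_variance(self):
        """Identical within-subject differences leave no residual variance."""
        res = rm_anova(_wide([[1, 2], [2, 3], [3, 4]]))
        assert np.isinf(res.F)
        assert res.p == 0.0
        assert res.degenerate

    def test_listwise_exclusion_reported(self, rng):
        x = _wide(rng.standard_normal((5, 3)))
        x.iloc[2, 1] = np.nan
        res = rm_anova(x)
        assert res.n_subjects == 4
        assert res.excluded_subjects == ("s2",)

    def test_invariant_to_subject_and_global_shifts(self, rng):
        x = rng.standard_normal((6, 4))
        base = rm_anova(_wide(x)).F
        shifted = x + rng.standard_normal((6, 1)) * 10 + 3.0
        assert rm_anova(_wide(shifted)).F == pytest.approx(base, rel=1e-9)

    def test_matches_pingouin(self, rng):
        """Independent cross-check against a published RM-ANOVA implementation."""
        pg = pytest.importorskip("pingouin")
        x = rng.standard_normal((8, 4))
        long = _wide(x).reset_index().melt(id_vars="index")
        aov = pg.rm_anova(data=long, dv="value", within="variable", subject="index")
        res = rm_anova(_wide(x))
        assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.p == pytest.approx(float(aov["p_unc"].iloc[0]), rel=1e-9)

    def test_null_rejection_rate_near_alpha(self):
        rate = rm_anova_null_rejection_rate(16, 4, reps=2000, alpha=0.05, seed=11)
        assert 0.03 <= rate <= 0.07


class TestHolmSidak:
    def test_single_p_reduces_to_unadjusted(self):
        [res] = holm_sidak([0.03], alpha=0.05)
        assert res.step_alpha == pytest.approx(0.05)
        assert res.significant

    def test_two_p_step_down(self):
        """First tested at 1 - 0.95^(1/2) ~ 0.02532, second at 0.05."""
        results = holm_sidak([0.01, 0.04], alpha=0.05)
        assert results[0].step_alpha == pytest.approx(1 - 0.95**0.5)
        assert results[1].step_alpha == pytest.approx(0.05)
        assert all(r.significant for r in results)

    def test_all_ones_nothing_significant(self):
        results = holm_sidak([1.0, 1.0, 1.0])
        assert all(r.adjusted_p == 1.0 and not r.significant for r in results)

    def test_adjusted_p_direct_enumeration(self):
        """Adjusted p = monotone max of 1 - (1 - p)^(m - i + 1)."""
        ps = [0.002, 0.04, 0.01, 0.3]
        results = holm_sidak(ps)
        order = np.argsort(ps)
        expect = {}
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, 1 - (1 - ps[idx]) ** (len(ps) - rank))
            expect[idx] = min(1.0, running)
        for i, r in enumerate(results):
            assert r.adjusted_p == pytest.approx(expect[i], abs=1e-12)

    def test_step_down_stops_at_first_failure(self):
        results = holm_sidak([0.001, 0.9, 0.002], alpha=0.05)
        # 0.9 fails its step; anything larger would fail too, smaller ones pass
        assert results[0].significant and results[2].significant
        assert not results[1].significant

    def test_empty_input(self):
        assert holm_sidak([]) == []

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_between_bonferroni_and_unadjusted(self, ps):
        """Rejections: superset of Bonferroni, subset of unadjusted tests."""
        alpha = 0.05
        results = holm_sidak(ps, alpha=alpha)
        m = len(ps)
        for p, r in zip(ps, results):
            if p <= alpha / m:  # Bonferroni rejects
                assert r.significant
            if r.significant:
                assert p <= alpha


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(5.0)
        assert pearson(x, 2 * x + 1).r == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.arange(5.0)
        assert pearson(x, -x).r == pytest.approx(-1.0)

    def test_matches_definitional_formula(self):
        x = np.array([1, 2, 3, 4, 5.0])
        y = np.array([2, 1, 4, 3, 5.0])
        r_def = (np.mean(x * y) - x.mean() * y.mean()) / (
            np.sqrt(np.mean(x**2) - x.mean() ** 2) * np.sqrt(np.mean(y**2) - y.mean() ** 2)
        )
        res = pearson(x, y)
        assert res.r == pytest.approx(r_def, abs=1e-12)
        # two-sided p via t on n-2 df
        from scipy import stats as sps

        t = res.r * np.sqrt((res.n - 2) / (1 - res.r**2))
        assert res.p == pytest.approx(2 * sps.t.sf(abs(t), res.n - 2), rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant input"):
            pearson([1, 1, 1, 1], [1, 2, 3, 4])

    def test_affine_invariance(self, rng):
        x = rng.standard_normal(20)
        y = rng.standard_normal(20)
        base = pearson(x, y).r
        assert pearson(3 * x + 7, y).r == pytest.approx(base, abs=1e-12)
        assert pearson(x, 0.5 * y - 2).r == pytest.approx(base, abs=1e-12)


class TestBaselineVariabilityCorrelations:
    def test_anchor_constant_rows_record_error(self, rng):
        table = _wide(rng.standard_normal((6, 3)), timepoints=["m1", "m8", "m14"])
        table["m1"] = 1.0
        out = baseline_variability_correlations(table, "m1", ["m8", "m14"])
        assert (out["error"] == "constant input").all()
        assert np.isnan(out["r"]).all()

    def test_rows_independent(self, rng):
        table = _wide(rng.standard_normal((8, 3)), timepoints=["m1", "m8", "m14"])
        table["m8"] = 2.0  # one bad target must not abort the other
        out = baseline_variability_correlations(table, "m1", ["m8", "m14"])
        assert out.loc[out["target"] == "m8", "error"].iloc[0] != ""
        assert np.isfinite(out.loc[out["target"] == "m14", "r"].iloc[0])


class TestSimpleLinregress:
    def test_exact_line(self):
        x = np.arange(5.0)
        res = simple_linregress(x, 3 * x - 1)
        assert res.slope == pytest.approx(3.0)
        assert res.intercept == pytest.approx(-1.0)
        assert res.r == pytest.approx(1.0)

    def test_constant_y(self):
        res = simple_linregress(np.arange(5.0), np.full(5, 2.0))
        assert res.slope == 0.0
        assert res.r == 0.0

    def test_matches_normal_equations(self, rng):
        x = rng.standard_normal(5)
        y = rng.standard_normal(5)
        a = np.vstack([np.ones(5), x]).T
        beta = np.linalg.solve(a.T @ a, a.T @ y)
        res = simple_linregress(x, y)
        assert res.intercept == pytest.approx(beta[0], abs=1e-10)
        assert res.slope == pytest.approx(beta[1], abs=1e-10)

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            simple_linregress(np.full(5, 1.0), np.arange(5.0))


class TestPairwiseVsReference:
    def test_family_labels_and_detection(self, rng):
        x = rng.standard_normal((10, 3))
        x[:, 2] += 3.0  # strong effect at the third timepoint
        table = _wide(x, timepoints=["BL", "VF10", "VF16"])
        results = pairwise_vs_reference(table, "BL")
        labels = [r.comparison for r in results]
        assert labels == ["VF10 vs BL", "VF16 vs BL"]
        by = dict(zip(labels, results))
        assert by["VF16 vs BL"].significant
        assert by["VF16 vs BL"].significant_05

    def test_missing_reference_rejected(self, rng):
        table = _wide(rng.standard_normal((4, 2)))
        with pytest.raises(KeyError):
            pairwise_vs_reference(table, "BL")
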