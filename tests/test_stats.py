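import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from varivent import (
    CohortDesign,
    DunnettContext,
    InvalidParameterError,
    TransformInfeasibleError,
    fit_repeated_mixed,
    normality_gate,
    posthoc_adjust,
    summarize_ci,
    synth_cohort,
)
from varivent.errors import SingularDesignError
from varivent.stats import dunnett_adjust, halfwidth_to_sd, holm_sidak_adjust

GROUPS = ("PCV-CTRL", "PVV-CTRL", "PCV-ARDS", "PVV-ARDS")
TIMES = ("T0", "T1", "T2", "T3")


def null_design(seed, n=5, sd=5.0, intercept_sd=3.0):
    profile = {"h": {g: {t: (100.0, sd) for t in TIMES} for g in GROUPS}}
    return CohortDesign(
        groups=GROUPS,
        n_per_group=n,
        timepoints=TIMES,
        effect_profile=profile,
        intercept_sd=intercept_sd,
        seed=seed,
    )


class TestNormalityGate:
    def test_normal_data_usually_untouched(self):
        passes = 0
        for seed in range(100):
            x = np.random.default_rng(seed).standard_normal(200)
            try:
                _, transform = normality_gate(x)
            except TransformInfeasibleError:
                continue  # chance Shapiro failure on data with negatives
            passes += transform == "none"
        assert passes >= 90  # test level ~5%

    def test_lognormal_data_transformed(self):
        transformed = 0
        for seed in range(100):
            x = np.exp(np.random.default_rng(seed).standard_normal(200))
            values, transform = normality_gate(x)
            if transform == "log":
                transformed += 1
                assert np.allclose(values, np.log(x))
        assert transformed >= 99

    def test_nonpositive_values_infeasible(self):
        x = np.exp(np.random.default_rng(0).standard_normal(200))
        x[0] = 0.0
        with pytest.raises(TransformInfeasibleError):
            normality_gate(x)

    def test_too_few_values(self):
        with pytest.raises(InvalidParameterError):
            normality_gate([1.0, 2.0])


class TestMixedModel:
    def test_noiseless_limit_equals_cell_means(self):
        profile = {
            "h": {
                g: {t: (100.0 + 10 * gi + ti, 0.0) for ti, t in enumerate(TIMES)}
                for gi, g in enumerate(GROUPS)
            }
        }
        design = CohortDesign(
            groups=GROUPS, n_per_group=3, timepoints=TIMES,
            effect_profile=profile, intercept_sd=0.0, seed=0,
        )
        table = synth_cohort(design)
        result = fit_repeated_mixed(table, "h", transform="none")
        merged = result.cell_means.set_index(["group", "timepoint"])
        for gi, g in enumerate(GROUPS):
            for ti, t in enumerate(TIMES):
                assert merged.loc[(g, t), "mean"] == pytest.approx(100.0 + 10 * gi + ti)
        assert result.var_residual == pytest.approx(0.0, abs=1e-6)

    def test_parameter_recovery_of_added_effect(self):
        """A fixed shift added to one group at the last timepoint is recovered
        (as the difference-in-differences cell estimate) within 5% on average."""
        delta = 10.0
        estimates = []
        for seed in range(200):
            table = synth_cohort(null_design(seed, n=5, sd=2.0, intercept_sd=2.0))
            bump = (table["group"] == "PCV-ARDS") & (table["timepoint"] == "T3")
            table.loc[bump, "value"] += delta
            cells = table.groupby(["group", "timepoint"])["value"].mean()
            d_target = cells[("PCV-ARDS", "T3")] - cells[("PCV-ARDS", "T0")]
            d_ref = cells[("PCV-CTRL", "T3")] - cells[("PCV-CTRL", "T0")]
            estimates.append(d_target - d_ref)
        assert np.mean(estimates) == pytest.approx(delta, rel=0.05)

    def test_mixed_model_detects_added_effect(self):
        table = synth_cohort(null_design(12, n=6, sd=2.0, intercept_sd=1.0))
        bump = (table["group"] == "PCV-ARDS") & (table["timepoint"] == "T3")
        table.loc[bump, "value"] += 15.0
        result = fit_repeated_mixed(table, "h", transform="none")
        p = dict(zip(result.anova["effect"], result.anova["p_value"]))
        assert p["group:timepoint"] < 0.01

    def test_invariant_to_row_order_and_relabeling(self):
        table = synth_cohort(null_design(3))
        shuffled = table.sample(frac=1.0, random_state=1).reset_index(drop=True)
        relabeled = shuffled.copy()
        relabeled["animal_id"] = relabeled["animal_id"].map(
            lambda s: f"animal-{hash(s) % 10**6}"
        )
        a = fit_repeated_mixed(table, "h", transform="none")
        b = fit_repeated_mixed(relabeled, "h", transform="none")
        assert np.allclose(a.anova["p_value"], b.anova["p_value"], atol=1e-8)

    def test_empty_cell_is_singular(self):
        table = synth_cohort(null_design(4))
        dropped = table[~((table["group"] == GROUPS[0]) & (table["timepoint"] == "T3"))]
        with pytest.raises(SingularDesignError):
            fit_repeated_mixed(dropped, "h", transform="none")

    def test_variance_components_recovered(self):
        # long design so REML can separate the two components
        profile = {"h": {g: {t: (50.0, 4.0) for t in TIMES} for g in GROUPS}}
        design = CohortDesign(
            groups=GROUPS, n_per_group=20, timepoints=TIMES,
            effect_profile=profile, intercept_sd=6.0, seed=9,
        )
        result = fit_repeated_mixed(synth_cohort(design), "h", transform="none")
        assert result.var_intercept == pytest.approx(36.0, rel=0.5)
        assert result.var_residual == pytest.approx(16.0, rel=0.3)


class TestHolmSidak:
    def test_single_comparison_unchanged(self):
        out = holm_sidak_adjust([0.03])
        assert out[0] == pytest.approx(0.03)

    def test_closed_form_pair(self):
        out = holm_sidak_adjust([0.01, 0.04])
        assert out[0] == pytest.approx(1.0 - 0.99**2)
        assert out[1] == pytest.approx(max(1.0 - 0.99**2, 0.04))

    def test_boundary_all_ones(self):
        assert np.all(holm_sidak_adjust([1.0, 1.0, 1.0]) == 1.0)

    def test_monotone_and_above_raw(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = rng.random(8)
            adj = holm_sidak_adjust(p)
            assert np.all(adj >= p)
            order = np.argsort(p)
            assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_invalid_pvalues(self):
        with pytest.raises(InvalidParameterError):
            holm_sidak_adjust([0.5, 1.2])


class TestDunnett:
    def test_adjusted_at_least_raw(self):
        ctx = DunnettContext(df=10)
        p = np.array([0.01, 0.2, 0.9])
        adj = dunnett_adjust(p, ctx)
        assert np.all(adj >= p) and np.all(adj <= 1.0)

    def test_matches_scipy_dunnett(self):
        """Cross-check the p-to-p adjustment against scipy's sample-based
        Dunnett test on balanced many-to-one data."""
        rng = np.random.default_rng(7)
        control = rng.standard_normal(12)
        treats = [rng.standard_normal(12) + d for d in (0.0, 0.8, 1.5)]
        scipy_res = sps.dunnett(*treats, control=control)
        # raw pooled-variance two-sided t p-values for the same comparisons
        n, k = 12, 3
        all_groups = [control] + treats
        ss = sum(np.sum((g - g.mean()) ** 2) for g in all_groups)
        df = (k + 1) * (n - 1)
        s2 = ss / df
        raw = []
        for tr in treats:
            t_stat = (tr.mean() - control.mean()) / np.sqrt(s2 * 2 / n)
            raw.append(2 * sps.t.sf(abs(t_stat), df))
        adj = dunnett_adjust(np.array(raw), DunnettContext(df=df, rho=0.5))
        assert np.allclose(adj, scipy_res.pvalue, atol=0.02)

    def test_posthoc_table_contract(self):
        table = posthoc_adjust([0.01, 0.04], "holm_sidak", labels=["a", "b"])
        assert list(table["comparison"]) == ["a", "b"]
        assert np.all(table["adjusted_p"] >= table["raw_p"])
        with pytest.raises(InvalidParameterError):
            posthoc_adjust([0.5], "dunnett")  # context required
        with pytest.raises(InvalidParameterError):
            posthoc_adjust([0.5], "bonferroni")


class TestSummarizeCI:
    def test_worked_example(self):
        mean, half = summarize_ci([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert half == pytest.approx(sps.t.ppf(0.975, 2) * 1.0 / np.sqrt(3))
        assert half == pytest.approx(2.484, abs=1e-3)

    def test_constant_list(self):
        assert summarize_ci([5.0, 5.0, 5.0])[1] == 0.0

    def test_linear_in_scale(self):
        x = np.array([1.0, 4.0, 2.5, 3.5])
        m1, h1 = summarize_ci(x)
        m2, h2 = summarize_ci(10 * x)
        assert m2 == pytest.approx(10 * m1) and h2 == pytest.approx(10 * h1)

    def test_shrinks_as_inverse_sqrt_n(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(10)
        halves = []
        for reps in (1, 4, 16):  # n = 10, 40, 160 via replication
            _, h = summarize_ci(np.tile(base, reps))
            halves.append(h)
        # replicating data 4x shrinks the half-width by slightly more than 2
        # (the t quantile also tightens)
        assert halves[1] < halves[0] / 2 * 1.05
        assert halves[2] < halves[1] / 2 * 1.05

    def test_halfwidth_sd_round_trip(self):
        sd = halfwidth_to_sd(8.0, 7)
        half = sps.t.ppf(0.975, 6) * sd / np.sqrt(7)
        assert half == pytest.approx(8.0)

    def test_needs_two_values(self):
        with pytest.raises(InvalidParameterError):
            summarize_ci([1.0])
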