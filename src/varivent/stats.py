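"""Longitudinal statistics for the four-group repeated-measures design.

The analysis chain mirrors common practice in experimental respiratory
physiology:

1. **Normality gate.**  Each outcome variable is screened with the
   Shapiro-Wilk test (alpha = 0.05); on failure the variable is
   natural-log-transformed before modelling (infeasible when values are
   non-positive, which is reported rather than silently skipped).

2. **Repeated-measures ANOVA via a linear mixed-effects model**, estimated by
   REML: fixed effects group x timepoint (both categorical; group either as a
   single 4-level factor or as ventilation-mode x lung-condition), and a
   Gaussian random intercept per animal to absorb between-animal
   heterogeneity.  Per-effect F tests use between-within (containment)
   denominator degrees of freedom — n_animals - g for the between-subject
   group effect and (n_animals - g)(t - 1) for within-subject effects — which
   are exact for the balanced compound-symmetric design the cohort generator
   emits and a standard finite-sample approximation otherwise.

3. **Post-hoc adjustment.**  Many-to-one comparisons against a reference
   timepoint use Dunnett's test, whose critical surface over the
   equicorrelated multivariate t distribution is approximated by seeded
   Monte-Carlo; general families use the closed-form Holm-Sidak step-down.

Summaries follow the mean +/- half-width of the 95% confidence interval
convention, half_width = t(0.975, n-1) * sd / sqrt(n).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import (
    InvalidParameterError,
    SingularDesignError,
    TransformInfeasibleError,
)

__all__ = [
    "GROUP_LEVELS",
    "TIMEPOINT_LEVELS",
    "MixedModelResult",
    "DunnettContext",
    "normality_gate",
    "fit_repeated_mixed",
    "posthoc_adjust",
    "holm_sidak_adjust",
    "dunnett_adjust",
    "summarize_ci",
]

#: Declared factor levels of the study design.
GROUP_LEVELS: tuple[str, ...] = ("PCV-CTRL", "PVV-CTRL", "PCV-ARDS", "PVV-ARDS")
TIMEPOINT_LEVELS: tuple[str, ...] = ("BL", "T0", "T1", "T2", "T3", "T4", "T5")


def normality_gate(
    values: np.ndarray, alpha: float = 0.05
) -> tuple[np.ndarray, str]:
    """Shapiro-Wilk screen with natural-log fallback.

    Returns ``(values', transform)`` where ``transform`` is "none" when the
    test passes and "log" when the values were log-transformed.  Raises
    :class:`TransformInfeasibleError` when the transform is required but the
    data contain non-positive values.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InvalidParameterError("normality test requires n >= 3")
    if not np.all(np.isfinite(x)):
        raise InvalidParameterError("values must be finite")
    if not 0 < alpha < 1:
        raise InvalidParameterError("alpha must lie in (0, 1)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # shapiro warns for n > 5000
        p = sps.shapiro(x).pvalue
    if p >= alpha or np.ptp(x) == 0:
        return x, "none"
    if np.any(x <= 0):
        raise TransformInfeasibleError(
            "normality failed but values contain non-positive entries; "
            "log transform infeasible"
        )
    return np.log(x), "log"


@dataclass
class MixedModelResult:
    """REML mixed-model output for one variable."""

    variable: str
    fixed_effects: pd.DataFrame  # term, estimate, se
    anova: pd.DataFrame  # effect, df_num, df_den, f_value, p_value
    var_intercept: float
    var_residual: float
    transform_applied: str = "none"
    cell_means: pd.DataFrame | None = None

    def __post_init__(self):
        if self.var_intercept < -1e-12 or self.var_residual < 0:
            raise InvalidParameterError("variance components must be >= 0")


def _validate_cohort(table: pd.DataFrame, variable: str) -> pd.DataFrame:
    required = {"animal_id", "group", "timepoint", "variable", "value"}
    missing = required - set(table.columns)
    if missing:
        raise InvalidParameterError(f"cohort table missing columns: {sorted(missing)}")
    data = table[table["variable"] == variable].copy()
    if data.empty:
        raise InvalidParameterError(f"no rows for variable {variable!r}")
    dup = data.duplicated(subset=["animal_id", "timepoint"])
    if dup.any():
        raise InvalidParameterError(
            "each (animal, timepoint) must appear at most once per variable"
        )
    cells = data.groupby(["group", "timepoint"], observed=True).size().unstack()
    if cells.isna().any().any() or (cells == 0).any().any():
        raise SingularDesignError(
            "singular design: at least one group-by-timepoint cell is empty"
        )
    return data


def fit_repeated_mixed(
    table: pd.DataFrame,
    variable: str,
    parameterization: str = "group",
    transform: str = "auto",
) -> MixedModelResult:
    """Repeated-measures ANOVA through a REML linear mixed-effects model.

    Parameters
    ----------
    table
        Long-format cohort table (animal_id, group, timepoint, variable, value).
    variable
        Outcome to analyze.
    parameterization
        "group" fits a single 4-level group factor crossed with time;
        "factorial" fits ventilation mode x lung condition x time (requires
        ``mode`` and ``condition`` columns).
    transform
        "auto" applies :func:`normality_gate`; "none"/"log" force the choice.

    The random structure is an intercept per animal.  Deterministic given the
    data: REML has no stochastic component.
    """
    data = _validate_cohort(table, variable)
    n_animals = data["animal_id"].nunique()
    groups = sorted(data["group"].unique())
    times = [t for t in TIMEPOINT_LEVELS if t in set(data["timepoint"])]
    if n_animals < 2 * len(groups):
        raise InvalidParameterError("need >= 2 animals per group")
    if len(times) < 2:
        raise InvalidParameterError("need >= 2 timepoints")

    applied = "none"
    if transform == "auto":
        values, applied = normality_gate(data["value"].to_numpy())
        data["value"] = values
    elif transform == "log":
        if np.any(data["value"] <= 0):
            raise TransformInfeasibleError("log transform of non-positive values")
        data["value"] = np.log(data["value"])
        applied = "log"
    elif transform != "none":
        raise InvalidParameterError(f"unknown transform {transform!r}")

    data["timepoint"] = pd.Categorical(data["timepoint"], categories=times, ordered=True)
    # Sum-to-zero contrasts make each term slice a marginal (time-averaged)
    # effect, so the between/within error strata stay separate and the
    # containment F tests are exact under balance.
    if parameterization == "group":
        data["group"] = pd.Categorical(data["group"], categories=groups)
        formula = "value ~ C(group, Sum) * C(timepoint, Sum)"
        between_terms = ["C(group, Sum)"]
    elif parameterization == "factorial":
        if not {"mode", "condition"} <= set(data.columns):
            raise InvalidParameterError("factorial parameterization needs mode/condition")
        formula = "value ~ C(mode, Sum) * C(condition, Sum) * C(timepoint, Sum)"
        between_terms = [
            "C(mode, Sum)",
            "C(condition, Sum)",
            "C(mode, Sum):C(condition, Sum)",
        ]
    else:
        raise InvalidParameterError(f"unknown parameterization {parameterization!r}")

    # Degenerate noiseless limit: values equal their cell means exactly, so
    # REML has nothing to estimate.  Fall back to OLS on the same design
    # (identical estimates) with zero variance components; effects that are
    # exactly present get p = 0, absent ones p = 1.
    cell_resid = data["value"] - data.groupby(
        ["group", "timepoint"], observed=True
    )["value"].transform("mean")
    noiseless = bool(np.allclose(cell_resid, 0.0, atol=1e-12))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary variance estimates are fine
        model = smf.mixedlm(formula, data, groups=data["animal_id"])
        fit = None
        if not noiseless:
            for method in ("lbfgs", "powell", "nm"):
                try:
                    fit = model.fit(reml=True, method=method)
                    break
                except np.linalg.LinAlgError:
                    continue  # near-singular profiled likelihood; try a
                    # derivative-free optimizer
            if fit is None:
                raise SingularDesignError(
                    "REML optimization failed for every optimizer; the profiled "
                    "likelihood is singular (often an empty or collinear design)"
                )

    k_fe = model.k_fe
    design_info = model.data.design_info
    if noiseless:
        ols = smf.ols(formula, data).fit()
        beta = np.asarray(ols.params)[:k_fe]
        cov = np.zeros((k_fe, k_fe))
        var_intercept, var_residual = 0.0, 0.0
    else:
        beta = np.asarray(fit.fe_params)
        cov = np.asarray(fit.cov_params())[:k_fe, :k_fe]
        var_intercept = float(np.asarray(fit.cov_re).ravel()[0])
        var_residual = float(fit.scale)

    g = len(groups)
    t = len(times)
    n_obs = len(data)
    ddf_between = n_animals - g
    ddf_within = n_obs - n_animals - (k_fe - g)
    if ddf_between <= 0 or ddf_within <= 0:
        raise SingularDesignError("not enough animals/timepoints for the F tests")

    def _clean(term: str) -> str:
        return term.replace("C(", "").replace(", Sum)", "")

    rows = []
    for term, sl in design_info.term_name_slices.items():
        if term == "Intercept":
            continue
        idx = np.arange(k_fe)[sl]
        q = idx.size
        b = beta[idx]
        ddf = ddf_between if term in between_terms else ddf_within
        if noiseless:
            f_value = np.inf if np.max(np.abs(b)) > 1e-8 else 0.0
        else:
            v = cov[np.ix_(idx, idx)]
            try:
                stat = float(b @ np.linalg.solve(v, b))
            except np.linalg.LinAlgError:
                raise SingularDesignError(f"singular covariance for term {term}")
            f_value = stat / q
        rows.append(
            {
                "effect": _clean(term),
                "df_num": q,
                "df_den": ddf,
                "f_value": f_value,
                "p_value": float(sps.f.sf(f_value, q, ddf)),
            }
        )
    anova = pd.DataFrame(rows)

    fixed = pd.DataFrame(
        {
            "term": list(design_info.column_names),
            "estimate": beta,
            "se": np.sqrt(np.diag(cov)),
        }
    )
    cell_means = (
        data.groupby(["group", "timepoint"], observed=True)["value"]
        .mean()
        .rename("mean")
        .reset_index()
    )
    return MixedModelResult(
        variable=variable,
        fixed_effects=fixed,
        anova=anova,
        var_intercept=var_intercept,
        var_residual=var_residual,
        transform_applied=applied,
        cell_means=cell_means,
    )


def holm_sidak_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Holm-Sidak step-down: adjusted p_(i) = max_{j<=i} 1 - (1 - p_(j))^(m-j+1)."""
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


@dataclass(frozen=True)
class DunnettContext:
    """Context for the Dunnett adjustment of many-to-one comparisons.

    df
        Error degrees of freedom shared by the comparisons.
    rho
        Common correlation among the comparison statistics (0.5 for equal
        group sizes against one shared reference).
    n_mc, seed
        Monte-Carlo sample size and seed for the multivariate-t surface.
    """

    df: int
    rho: float = 0.5
    n_mc: int = 50_000
    seed: int = 987654321

    def __post_init__(self):
        if self.df < 1:
            raise InvalidParameterError("df must be >= 1")
        if not 0 <= self.rho < 1:
            raise InvalidParameterError("rho must lie in [0, 1)")


def dunnett_adjust(pvalues: np.ndarray, context: DunnettContext) -> np.ndarray:
    """Dunnett two-sided adjustment of raw t-test p-values.

    Raw p-values are mapped back to |t| statistics at ``context.df``; the
    adjusted p is P(max_j |T_j| >= |t|) under the k-variate equicorrelated t
    distribution, approximated with a fixed-seed Monte-Carlo sample (accuracy
    ~ 1/sqrt(n_mc), i.e. ~0.005 at the default 50,000 draws).
    """
    p = np.asarray(pvalues, dtype=float)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidParameterError("p-values must lie in [0, 1]")
    k = p.size
    if k == 0:
        return p.copy()
    t_obs = sps.t.isf(np.clip(p, 1e-300, 1.0) / 2.0, context.df)
    rng = np.random.default_rng(context.seed)
    z0 = rng.standard_normal(context.n_mc)
    eps = rng.standard_normal((context.n_mc, k))
    z = np.sqrt(context.rho) * z0[:, None] + np.sqrt(1.0 - context.rho) * eps
    chi = np.sqrt(rng.chisquare(context.df, context.n_mc) / context.df)
    max_abs_t = np.max(np.abs(z), axis=1) / chi
    adj = np.array([np.mean(max_abs_t >= t) for t in t_obs])
    return np.minimum(np.maximum(adj, p), 1.0)  # adjusted >= raw, <= 1


def posthoc_adjust(
    pvalues: np.ndarray,
    method: str,
    context: DunnettContext | None = None,
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Adjust a family of raw p-values; returns a tidy table
    (comparison, raw_p, adjusted_p, method)."""
    p = np.asarray(pvalues, dtype=float)
    if method == "holm_sidak":
        adj = holm_sidak_adjust(p)
    elif method == "dunnett":
        if context is None:
            raise InvalidParameterError("dunnett adjustment requires a DunnettContext")
        adj = dunnett_adjust(p, context)
    else:
        raise InvalidParameterError(f"unknown post-hoc method {method!r}")
    if labels is None:
        labels = [f"c{i}" for i in range(p.size)]
    return pd.DataFrame(
        {"comparison": labels, "raw_p": p, "adjusted_p": adj, "method": method}
    )


def summarize_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Mean and half-width of the two-sided confidence interval:
    half_width = t(1-(1-level)/2, n-1) * sd / sqrt(n)."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidParameterError("summarize_ci requires n >= 2")
    if not 0 < level < 1:
        raise InvalidParameterError("confidence level must lie in (0, 1)")
    n = x.size
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    half = float(sps.t.ppf(1.0 - (1.0 - level) / 2.0, n - 1) * sd / np.sqrt(n))
    return mean, half


def halfwidth_to_sd(half_width: float, n: int, level: float = 0.95) -> float:
    """Invert the mean +/- CI-half-width convention: SD = hw * sqrt(n) / t."""
    if n < 2:
        raise InvalidParameterError("need n >= 2")
    if half_width < 0:
        raise InvalidParameterError("half-width must be >= 0")
    return half_width * np.sqrt(n) / sps.t.ppf(1.0 - (1.0 - level) / 2.0, n - 1)
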