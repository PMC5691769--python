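"""Univariate statistics: age residualization, sex-stratified testing with
Fisher combination, number-weighted descriptives, FDR, and adjusted logistic
models, plus the small epidemiological rate helpers used in reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import SEX_LEVELS
from .errors import SeparationError, ValidationError

# --------------------------------------------------------------------------
# Rates (descriptive arithmetic used by reports)
# --------------------------------------------------------------------------

def prevalence_percent(cases: int, controls: int) -> float:
    """Prevalence of cases in a case-control subset, in percent."""
    total = cases + controls
    if total <= 0:
        raise ValidationError("empty subset")
    return 100.0 * cases / total


def cumulative_incidence_percent(cases: int, at_risk: int) -> float:
    """Cumulative incidence over the follow-up window, in percent."""
    if at_risk <= 0:
        raise ValidationError("at_risk must be positive")
    return 100.0 * cases / at_risk


def incidence_rate_per_1000py(cases: int, at_risk: int, years: float) -> float:
    """Incidence rate per 1000 person-years (every at-risk person contributes
    the full follow-up duration)."""
    if at_risk <= 0 or years <= 0:
        raise ValidationError("at_risk and years must be positive")
    return 1000.0 * cases / (at_risk * years)


# --------------------------------------------------------------------------
# Building blocks
# --------------------------------------------------------------------------

def residualize_age(values, age):
    """Remove linear age covariation, preserving the overall mean.

    Returns OLS residuals of ``values ~ age`` plus the mean of ``values``.
    Constant age passes the input through with a warning.
    """
    values = np.asarray(values, dtype=float)
    age = np.asarray(age, dtype=float)
    if values.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.ptp(age) == 0:
        warnings.warn("constant age; residualization is the identity")
        return values.copy()
    ac = age - age.mean()
    slope = ac @ (values - values.mean()) / (ac @ ac)
    return values - slope * ac


def fisher_combine(pvals) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-squared with 2k df."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values to combine")
    if np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn("p-value of 0 clipped to smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    x = -2.0 * np.sum(np.log(p))
    return float(sps.chi2.sf(x, 2 * p.size))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, within [p, 1])."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value list")
    return multipletests(p, method="fdr_bh")[1]


# --------------------------------------------------------------------------
# Trait comparison
# --------------------------------------------------------------------------

@dataclass
class TraitComparison:
    """One row of a univariate comparison table."""

    trait: str
    group_means: dict[int, tuple[float, float, int]]  # group -> (mean, sd, n)
    p_by_stratum: dict[str, float]
    p_combined: float
    age_adjusted: bool
    q_value: float | None = None


def _weighted_group_stats(parts: list[tuple[float, float, int]]):
    """Number-weighted mean and pooled sd across sex strata."""
    ns = np.array([n for _, _, n in parts], dtype=float)
    means = np.array([m for m, _, _ in parts])
    sds = np.array([s for _, s, _ in parts])
    total = ns.sum()
    if total == 0:
        return np.nan, np.nan, 0
    mean = float((ns * means).sum() / total)
    var = float((ns * (sds ** 2 + (means - mean) ** 2)).sum() / total)
    return mean, float(np.sqrt(var)), int(total)


def compare_trait(cohort: pd.DataFrame, trait: str, outcome: str,
                  *, binary: bool = False, adjust_age: bool = True,
                  test: str = "welch") -> TraitComparison:
    """Sex-stratified univariate association of a trait with a binary outcome.

    Quantitative traits are age-residualized within each sex stratum (unless
    ``adjust_age=False``) and compared between outcome groups with a Welch
    t-test (Mann-Whitney behind ``test="mannwhitney"``). Binary traits are
    tested by logistic regression of the outcome on the trait (plus age as a
    covariate when adjusting). Stratum p-values are combined with Fisher's
    method; descriptives are number-weighted across strata. Strata with an
    empty outcome group are skipped.
    """
    if test not in ("welch", "mannwhitney"):
        raise ValidationError(f"unknown two-sample test: {test!r}")
    p_by_stratum: dict[str, float] = {}
    descriptives: dict[int, list[tuple[float, float, int]]] = {0: [], 1: []}
    for stratum in SEX_LEVELS:
        sub = cohort[cohort["sex"] == stratum]
        if sub.empty:
            continue
        y = sub[outcome].to_numpy(dtype=float)
        x = sub[trait].to_numpy(dtype=float)
        age = sub["age"].to_numpy(dtype=float)
        keep = np.isfinite(y) & np.isfinite(x) & np.isfinite(age)
        y, x, age = y[keep], x[keep], age[keep]
        groups = {g: x[y == g] for g in (0, 1)}
        for g in (0, 1):
            vals = groups[g]
            if vals.size:
                descriptives[g].append(
                    (float(vals.mean()),
                     float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                     int(vals.size)))
        if groups[0].size == 0 or groups[1].size == 0:
            continue  # degenerate stratum: skipped from the combination
        if binary:
            from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
            design = np.column_stack([np.ones_like(x), x] +
                                     ([age] if adjust_age else []))
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    warnings.simplefilter("error",
                                          category=PerfectSeparationWarning)
                    fit = sm.Logit(y, design).fit(disp=0)
                p = float(fit.pvalues[1])
            except (PerfectSeparationError, PerfectSeparationWarning,
                    np.linalg.LinAlgError):
                # a perfectly separating trait is maximally significant
                p = np.finfo(float).tiny
        else:
            xa = residualize_age(x, age) if adjust_age else x
            a, b = xa[y == 1], xa[y == 0]
            if test == "welch":
                from .matching import welch_p
                p = welch_p(a, b)
            else:
                p = float(sps.mannwhitneyu(a, b,
                                           alternative="two-sided").pvalue)
        p_by_stratum[stratum] = p
    if not p_by_stratum:
        raise ValidationError(
            f"no stratum with both outcome groups for trait {trait!r}")
    group_means = {g: _weighted_group_stats(parts)
                   for g, parts in descriptives.items()}
    return TraitComparison(
        trait=trait, group_means=group_means, p_by_stratum=p_by_stratum,
        p_combined=fisher_combine(list(p_by_stratum.values())),
        age_adjusted=adjust_age)


def compare_traits(cohort: pd.DataFrame, traits, outcome: str,
                   binary_traits=(), unadjusted_traits=(),
                   test: str = "welch") -> pd.DataFrame:
    """Run :func:`compare_trait` over a trait family and attach BH q-values."""
    rows = []
    for trait in traits:
        cmp_ = compare_trait(
            cohort, trait, outcome,
            binary=trait in set(binary_traits),
            adjust_age=trait not in set(unadjusted_traits), test=test)
        m0, s0, n0 = cmp_.group_means[0]
        m1, s1, n1 = cmp_.group_means[1]
        rows.append({
            "trait": trait,
            "mean_control": m0, "sd_control": s0, "n_control": n0,
            "mean_case": m1, "sd_case": s1, "n_case": n1,
            "p_female": cmp_.p_by_stratum.get("female", np.nan),
            "p_male": cmp_.p_by_stratum.get("male", np.nan),
            "p_combined": cmp_.p_combined,
            "age_adjusted": cmp_.age_adjusted,
        })
    table = pd.DataFrame(rows)
    table["q_value"] = bh_fdr(table["p_combined"].to_numpy())
    table["significant_fdr05"] = table["q_value"] < 0.05
    return table


# --------------------------------------------------------------------------
# Adjusted logistic model
# --------------------------------------------------------------------------

def fit_adjusted_logistic(cohort: pd.DataFrame, outcome: str,
                          predictors) -> pd.DataFrame:
    """Maximum-likelihood logistic fit with odds ratios and Wald 95% CIs.

    Categorical predictors are dummy-coded (first level dropped). Perfect or
    quasi-perfect separation raises :class:`SeparationError`.
    """
    predictors = list(predictors)
    y = cohort[outcome].to_numpy(dtype=float)
    blocks = []
    for var in predictors:
        col = cohort[var]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=var, drop_first=True)
            blocks.append(dummies.astype(float))
        else:
            blocks.append(col.astype(float).to_frame(var))
    x = pd.concat(blocks, axis=1)
    # identically-zero predictors carry no information: report OR 1 directly
    zero_cols = [c for c in x.columns if (x[c] == 0).all()]
    x = x.drop(columns=zero_cols)
    design = sm.add_constant(x, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValidationError("perfect collinearity among predictors")
    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=RuntimeWarning)
            warnings.simplefilter("error", category=PerfectSeparationWarning)
            warnings.simplefilter("ignore", category=FutureWarning)
            fit = sm.Logit(y, design).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, RuntimeWarning,
            np.linalg.LinAlgError) as exc:
        raise SeparationError(f"separation detected in logistic fit: {exc}")
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError("logistic fit failed to converge "
                              "(possible quasi-separation)")
    if np.any(np.abs(fit.params[1:]) > 15):
        raise SeparationError(
            "implausibly large coefficient(s); suspected separation: "
            f"{design.columns[1:][np.abs(fit.params[1:]) > 15].tolist()}")
    ci = fit.conf_int()
    table = pd.DataFrame({
        "coef": fit.params,
        "odds_ratio": np.exp(fit.params),
        "or_ci_low": np.exp(ci[0]),
        "or_ci_high": np.exp(ci[1]),
        "p_value": fit.pvalues,
    })
    for col in zero_cols:
        table.loc[col] = [0.0, 1.0, np.nan, np.nan, 1.0]
    table.index.name = "term"
    return table
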