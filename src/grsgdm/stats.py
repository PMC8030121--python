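"""Inferential layer: group contrasts, score-glucose regressions, power.

Case groups are compared with controls by unpaired t-test (pooled
variance by default, Welch by flag) for approximately normal variables —
the genetic scores — and by Wilcoxon rank-sum for skewed clinical
variables (which the reports summarise as median/IQR).  Each glucose
measure is regressed on each genetic score by OLS, unadjusted and
adjusted for the other two glucose measures; ANCOVA (score ~ group +
covariates) provides the BMI/age sensitivity analysis.  P values are
Bonferroni-corrected with multipliers that are explicit configuration
(24 for the clinical layer, 16 for the score-contrast layer), not
inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm


@dataclass(frozen=True)
class ComparisonResult:
    variable: str
    group: str
    test: str            # "t_test" or "wilcoxon"
    statistic: float
    p_raw: float
    m: int
    p_bonferroni: float
    n_case: int
    n_control: int


@dataclass(frozen=True)
class RegressionResult:
    outcome: str
    predictor: str
    covariates: tuple[str, ...]
    beta: float
    ci_low: float
    ci_high: float
    p_raw: float
    p_bonferroni: float
    n: int


def bonferroni(p: float, m: int) -> float:
    """min(1, m * p)."""
    if not 0 <= p <= 1:
        raise ValueError(f"p = {p} outside [0, 1]")
    if m < 1:
        raise ValueError(f"m = {m} must be >= 1")
    return min(1.0, m * p)


def two_group_test(x: Sequence[float], y: Sequence[float],
                   test: Literal["t_test", "wilcoxon"] = "t_test",
                   welch: bool = False, m: int = 1,
                   variable: str = "", group: str = "",
                   ) -> ComparisonResult:
    """Two-sided unpaired comparison of x (cases) against y (controls).

    t_test: two-sample t, pooled variance unless ``welch``.  Two identical
    zero-variance groups give statistic 0, p = 1 rather than NaN.
    wilcoxon: rank-sum, exact when the pooled sample is small (< 20) and
    untied, otherwise normal approximation with continuity and tie
    correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if test == "t_test":
        if len(x) < 2 or len(y) < 2:
            raise ValueError("t-test needs n >= 2 in both groups")
        if np.var(x, ddof=1) == 0 and np.var(y, ddof=1) == 0:
            stat, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (np.inf, 0.0)
        else:
            stat, p = sps.ttest_ind(x, y, equal_var=not welch)
    elif test == "wilcoxon":
        if len(x) < 1 or len(y) < 1:
            raise ValueError("rank-sum test needs n >= 1 in both groups")
        pooled = np.concatenate([x, y])
        exact = len(pooled) < 20 and len(np.unique(pooled)) == len(pooled)
        res = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="exact" if exact else "asymptotic",
                               use_continuity=True)
        stat, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(variable=variable, group=group, test=test,
                            statistic=float(stat), p_raw=float(p), m=m,
                            p_bonferroni=bonferroni(float(p), m),
                            n_case=len(x), n_control=len(y))


def _check_collinear(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(float)])
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # identify offending columns: those whose removal restores full rank
        names = []
        for j, col in enumerate(X.columns):
            reduced = np.delete(arr, j + 1, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                names.append(col)
        raise ValueError(f"collinear covariates in design: {names or list(X.columns)}")


def glucose_on_gs_regression(outcome: Sequence[float], gs: Sequence[float],
                             adjust_for: Optional[Mapping[str, Sequence[float]]] = None,
                             outcome_name: str = "glucose",
                             predictor_name: str = "GS",
                             m: int = 1) -> RegressionResult:
    """OLS of a glucose measure on a genetic score, optionally adjusted.

    Complete cases only; the reported beta (mmol/L per score unit), its
    t-based 95% CI and two-sided p refer to the score coefficient.
    """
    data = {predictor_name: np.asarray(gs, float)}
    for name, vals in (adjust_for or {}).items():
        data[name] = np.asarray(vals, float)
    X = pd.DataFrame(data)
    y = pd.Series(np.asarray(outcome, float), name=outcome_name)
    keep = ~(X.isna().any(axis=1) | y.isna())
    X, y = X[keep], y[keep]
    if len(y) <= X.shape[1] + 1:
        raise ValueError(f"n = {len(y)} too small for {X.shape[1]} parameters")
    _check_collinear(X)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    ci = fit.conf_int(alpha=0.05).loc[predictor_name]
    p = float(fit.pvalues[predictor_name])
    return RegressionResult(
        outcome=outcome_name, predictor=predictor_name,
        covariates=tuple(n for n in X.columns if n != predictor_name),
        beta=float(fit.params[predictor_name]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_raw=p, p_bonferroni=bonferroni(p, m), n=int(fit.nobs))


def ancova_gs_by_group(gs: Sequence[float], group: Sequence[int],
                       covariates: Optional[Mapping[str, Sequence[float]]] = None,
                       m: int = 1, variable: str = "gs",
                       group_name: str = "case") -> ComparisonResult:
    """Covariate-adjusted case-control contrast of a score.

    Fits GS ~ group + covariates by OLS on complete cases and reports the
    group coefficient's t statistic and two-sided p.
    """
    g = np.asarray(group, float)
    levels = np.unique(g[~np.isnan(g)])
    if len(levels) < 2:
        raise ValueError("group indicator is constant")
    if len(levels) > 2:
        raise ValueError("group must be binary case/control")
    data = {"group": (g == levels.max()).astype(float)}
    for name, vals in (covariates or {}).items():
        data[name] = np.asarray(vals, float)
    X = pd.DataFrame(data)
    y = pd.Series(np.asarray(gs, float), name=variable)
    keep = ~(X.isna().any(axis=1) | y.isna()) & ~np.isnan(g)
    X, y = X[keep], y[keep]
    _check_collinear(X)
    fit = sm.OLS(y, sm.add_constant(X)).fit()
    p = float(fit.pvalues["group"])
    n_case = int(X["group"].sum())
    return ComparisonResult(variable=variable, group=group_name,
                            test="ancova", statistic=float(fit.tvalues["group"]),
                            p_raw=p, m=m, p_bonferroni=bonferroni(p, m),
                            n_case=n_case, n_control=int(len(y) - n_case))


def power_variance_explained(n: int, r2: float, alpha: float) -> float:
    """Power of the single-predictor OLS slope test at a given R².

    Uses the noncentral F distribution with 1 and n-2 df and
    noncentrality n * f², f² = r² / (1 - r²).  At r² = 0 the power equals
    the test size alpha.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    if not 0 <= r2 < 1:
        raise ValueError("r2 must lie in [0, 1)")
    if r2 == 0:
        return float(alpha)
    lam = n * r2 / (1 - r2)
    crit = sps.f.isf(alpha, 1, n - 2)
    return float(sps.ncf.sf(crit, 1, n - 2, lam))


# ---------------------------------------------------------------------------
# report layers

GLUCOSE_MEASURES = {"fpg": "Fasting", "glu_1h": "1-hr", "glu_2h": "2-hr"}


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def table3_like(phenotypes: pd.DataFrame, categories: pd.Series,
                scores: pd.DataFrame, m_clinical: int = 24,
                m_gs: int = 16) -> pd.DataFrame:
    """Per-group clinical and score contrasts against controls.

    Clinical variables (median/IQR in the summary) are tested with the
    rank-sum test and Bonferroni multiplier ``m_clinical``; scores with the
    pooled t-test and multiplier ``m_gs``.  One row per variable x case
    group, with significance stars at raw p < 0.05/0.01/0.001 and a
    Bonferroni-survival flag.
    """
    from .classify import CASE_GROUPS, _CLINICAL, _SCORES

    df = phenotypes.merge(scores, on="sample_id", how="left")
    df["category"] = categories.values
    controls = df[df["category"] == "control"]
    rows = []
    for var in _CLINICAL + _SCORES:
        if var not in df.columns:
            continue
        is_score = var in _SCORES
        test = "t_test" if is_score else "wilcoxon"
        mult = m_gs if is_score else m_clinical
        ctrl_vals = controls[var].dropna()
        for grp in CASE_GROUPS:
            case_vals = df.loc[df["category"] == grp, var].dropna()
            if len(case_vals) < 2 or len(ctrl_vals) < 2:
                rows.append({"variable": var, "group": grp, "test": test,
                             "n_case": len(case_vals), "n_control": len(ctrl_vals),
                             "statistic": np.nan, "p_raw": np.nan,
                             "p_bonferroni": np.nan, "stars": "",
                             "bonferroni_significant": False})
                continue
            res = two_group_test(case_vals, ctrl_vals, test=test, m=mult,
                                 variable=var, group=grp)
            rows.append({"variable": var, "group": grp, "test": test,
                         "n_case": res.n_case, "n_control": res.n_control,
                         "statistic": res.statistic, "p_raw": res.p_raw,
                         "p_bonferroni": res.p_bonferroni,
                         "stars": _stars(res.p_raw),
                         "bonferroni_significant": res.p_bonferroni < 0.05})
    return pd.DataFrame(rows)


def table4_like(phenotypes: pd.DataFrame, scores: pd.DataFrame,
                m: int = 24) -> pd.DataFrame:
    """Score-glucose regression grid: measure x score x adjustment.

    For each glucose measure and each score, the unadjusted OLS slope and
    the slope adjusted for the two other glucose measures, with 95% CI and
    raw/Bonferroni p.
    """
    df = phenotypes.merge(scores, on="sample_id", how="left")
    rows = []
    for gs_col in ("fpg_gs", "t2d_gs"):
        if gs_col not in df.columns:
            continue
        for meas, label in GLUCOSE_MEASURES.items():
            others = [o for o in GLUCOSE_MEASURES if o != meas]
            for adjusted in (False, True):
                adjust = {o: df[o] for o in others} if adjusted else None
                res = glucose_on_gs_regression(
                    df[meas], df[gs_col], adjust_for=adjust,
                    outcome_name=meas, predictor_name=gs_col, m=m)
                rows.append({
                    "glucose_measure": label, "score": gs_col.upper(),
                    "adjusted_for_other_glucose": adjusted,
                    "beta": res.beta, "ci_low": res.ci_low,
                    "ci_high": res.ci_high, "p_raw": res.p_raw,
                    "p_bonferroni": res.p_bonferroni, "n": res.n,
                    "stars": _stars(res.p_raw),
                })
    return pd.DataFrame(rows)


def figure3_like(categories: pd.Series, scores: pd.DataFrame,
                 m_gs: int = 16) -> pd.DataFrame:
    """Group mean score with 95% CI and case-vs-control significance markers."""
    from .classify import CASE_GROUPS, GdmCategory

    df = scores.copy()
    df["category"] = categories.values
    rows = []
    order = [c.value for c in GdmCategory]
    for gs_col in ("fpg_gs", "t2d_gs"):
        ctrl = df.loc[df["category"] == "control", gs_col].dropna()
        for cat in order:
            vals = df.loc[df["category"] == cat, gs_col].dropna()
            n = len(vals)
            mean = float(vals.mean()) if n else np.nan
            if n > 1:
                half = float(sps.t.ppf(0.975, n - 1) * vals.std(ddof=1)
                             / np.sqrt(n))
            else:
                half = np.nan
            row = {"score": gs_col.upper(), "category": cat, "n": n,
                   "mean": mean, "ci_low": mean - half, "ci_high": mean + half,
                   "p_raw": np.nan, "p_bonferroni": np.nan, "stars": "",
                   "bonferroni_significant": False}
            if cat in CASE_GROUPS and n >= 2 and len(ctrl) >= 2:
                res = two_group_test(vals, ctrl, test="t_test", m=m_gs,
                                     variable=gs_col, group=cat)
                row.update(p_raw=res.p_raw, p_bonferroni=res.p_bonferroni,
                           stars=_stars(res.p_raw),
                           bonferroni_significant=res.p_bonferroni < 0.05)
            rows.append(row)
    return pd.DataFrame(rows)
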