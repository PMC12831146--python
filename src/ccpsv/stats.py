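"""Cohort statistics: Spearman screens, nested mixed models, VIF, ICC, power.

Eyes from one subject and PSVs from one eye are not independent, so every
regression here is a linear mixed model with nested random intercepts —
one per subject and one per eye within subject — fitted by maximum
likelihood.  Fixed effects are summarized with Wald 95% CIs and p-values;
model performance is reported as marginal R² (fixed-effects variance over
total variance).

Repeatability uses the two-way, absolute-agreement, single-measurement
intraclass correlation (ICC(A,1)); post-hoc power for a single coefficient
uses the noncentral t-distribution with the subject-level effective sample
size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "TermEstimate",
    "ModelResult",
    "PowerInput",
    "spearman_screen",
    "fit_mixed",
    "vif",
    "icc_repeatability",
    "posthoc_power",
]


@dataclass(frozen=True)
class TermEstimate:
    """One fixed-effect (or correlation) estimate with CI and p-value."""

    name: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float


@dataclass
class ModelResult:
    """Summary of one mixed-effects fit."""

    terms: list[TermEstimate]
    var_subject: float
    var_eye: float
    var_resid: float
    r2: float
    n_obs: int
    n_subjects: int
    n_eyes: int
    converged: bool = True
    boundary_fit: bool = False
    warnings: list[str] = field(default_factory=list)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.name,
                    "estimate": t.estimate,
                    "ci_low": t.ci_low,
                    "ci_high": t.ci_high,
                    "p_value": t.p_value,
                }
                for t in self.terms
            ]
        )


def spearman_screen(
    table: pd.DataFrame, response: str, predictors: list[str]
) -> list[TermEstimate]:
    """Spearman rank correlations of each predictor with the response.

    Tie-corrected ρ and p-values from :func:`scipy.stats.spearmanr` on
    complete pairs.  A constant column has no defined rank correlation and
    is reported with NaN estimate and p-value rather than dropped.
    CI bounds are Fisher-z approximate 95% intervals.
    """
    out: list[TermEstimate] = []
    for pred in predictors:
        sub = table[[pred, response]].dropna()
        x, y = sub[pred].to_numpy(), sub[response].to_numpy()
        if len(sub) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            out.append(TermEstimate(pred, np.nan, np.nan, np.nan, np.nan))
            continue
        rho, p = sps.spearmanr(x, y)
        n = len(sub)
        if abs(rho) < 1 and n > 3:
            z = np.arctanh(rho)
            hw = 1.959963984540054 / np.sqrt(n - 3)
            lo, hi = np.tanh(z - hw), np.tanh(z + hw)
        else:
            lo = hi = rho
        out.append(TermEstimate(pred, float(rho), float(lo), float(hi), float(p)))
    return out


def fit_mixed(
    table: pd.DataFrame,
    response: str,
    fixed_terms: list[str],
    grouping: tuple[str, str] = ("subject_id", "eye_id"),
) -> ModelResult:
    """Linear mixed model with nested random intercepts, fitted by ML.

    ``response ~ 1 + fixed_terms`` with a random intercept per subject and
    a variance-component intercept per eye within subject.  Fixed effects
    get Wald 95% CIs and p-values.  ``r2`` is marginal R²:
    var(Xβ̂) / (var(Xβ̂) + σ²_subject + σ²_eye + σ²_resid).

    A singular (boundary) fit — a variance component estimated at zero —
    is flagged on the result (``boundary_fit``), not raised.
    """
    subj_col, eye_col = grouping
    if table[subj_col].nunique() < 2:
        raise ValueError("at least 2 subjects are required for a mixed fit")
    bad = table.groupby(eye_col)[subj_col].nunique()
    if (bad > 1).any():
        raise ValueError("grouping is not nested: an eye ID maps to >1 subject")
    rhs = " + ".join(fixed_terms) if fixed_terms else "1"
    formula = f"{response} ~ {rhs}"
    vc = {"eye": f"0 + C({eye_col})"}
    caught: list[str] = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(
            formula, table, groups=table[subj_col], re_formula="1", vc_formula=vc
        )
        fit = model.fit(reml=False, method=["lbfgs", "cg"])
        caught = [str(w.message) for w in wlist]

    params = fit.fe_params
    ci = fit.conf_int().loc[params.index]
    pvals = fit.pvalues.loc[params.index]
    terms = [
        TermEstimate(
            name, float(params[name]), float(ci.loc[name, 0]),
            float(ci.loc[name, 1]), float(pvals[name]),
        )
        for name in params.index
    ]
    var_subject = float(np.asarray(fit.cov_re)[0, 0])
    var_eye = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    var_resid = float(fit.scale)
    X = model.exog
    fitted_fixed = X @ params.to_numpy()
    var_fixed = float(np.var(fitted_fixed))
    denom = var_fixed + var_subject + var_eye + var_resid
    r2 = var_fixed / denom if denom > 0 else np.nan
    boundary = min(var_subject, var_eye) <= 1e-8 * max(var_resid, 1e-12) or any(
        "singular" in m.lower() or "boundary" in m.lower() for m in caught
    )
    return ModelResult(
        terms=terms,
        var_subject=var_subject,
        var_eye=var_eye,
        var_resid=var_resid,
        r2=r2,
        n_obs=int(len(table)),
        n_subjects=int(table[subj_col].nunique()),
        n_eyes=int(table[eye_col].nunique()),
        converged=bool(fit.converged),
        boundary_fit=bool(boundary),
        warnings=caught,
    )


def vif(table: pd.DataFrame, predictors: list[str]) -> list[tuple[str, float]]:
    """Variance inflation factors: VIF_j = 1 / (1 − R²_j).

    R²_j comes from the OLS regression of predictor j on the remaining
    predictors (with intercept).  Perfect collinearity yields ``inf``.
    """
    if len(table) < len(predictors) + 2:
        raise ValueError("need at least len(predictors) + 2 rows for VIF")
    out: list[tuple[str, float]] = []
    for j, pred in enumerate(predictors):
        others = [p for p in predictors if p != pred]
        if not others:
            out.append((pred, 1.0))
            continue
        X = sm.add_constant(table[others].to_numpy(dtype=float))
        y = table[pred].to_numpy(dtype=float)
        r2 = sm.OLS(y, X).fit().rsquared
        out.append((pred, float("inf") if r2 >= 1.0 - 1e-14 else 1.0 / (1.0 - r2)))
    return out


def icc_repeatability(
    session1: np.ndarray | pd.Series, session2: np.ndarray | pd.Series
) -> tuple[float, float, float]:
    """Intra-grader repeatability ICC for two measurement sessions.

    Two-way, absolute-agreement, single-measurement form (ICC(A,1) /
    "ICC2") with its F-based 95% CI, computed via pingouin.  Requires at
    least 5 items.  Returns (icc, ci_low, ci_high); a degenerate design
    with zero between-item variance returns NaNs.
    """
    s1 = np.asarray(session1, dtype=float)
    s2 = np.asarray(session2, dtype=float)
    if s1.shape != s2.shape or s1.ndim != 1:
        raise ValueError("sessions must be equal-length 1-D arrays")
    n = len(s1)
    if n < 5:
        raise ValueError("need at least 5 items for a stable ICC")
    between_var = np.var((s1 + s2) / 2.0)
    if between_var == 0:
        return (float("nan"), float("nan"), float("nan"))
    long = pd.DataFrame(
        {
            "item": np.tile(np.arange(n), 2),
            "session": np.repeat([1, 2], n),
            "value": np.concatenate([s1, s2]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = pg.intraclass_corr(
            data=long, targets="item", raters="session", ratings="value"
        )
    res = res.set_index("Type")
    row = res.loc["ICC(A,1)"] if "ICC(A,1)" in res.index else res.loc["ICC2"]
    ci_col = "CI95" if "CI95" in res.columns else "CI95%"
    lo, hi = row[ci_col]
    return (float(row["ICC"]), float(lo), float(hi))


@dataclass(frozen=True)
class PowerInput:
    """Inputs for post-hoc power of one regression coefficient.

    ``se`` may be derived from a reported 95% CI as half-width / 1.96.
    ``n_eff`` is the subject-level effective sample size (independent
    units), not the PSV count; ``n_predictors`` is the number of fixed
    effects k in the model, giving df = n_eff − k − 1.
    """

    beta_hat: float
    se: float
    n_eff: int
    alpha: float = 0.05
    n_predictors: int = 1

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


def posthoc_power(inp: PowerInput) -> float:
    """Two-sided post-hoc power from the noncentral t-distribution.

    With noncentrality ncp = β̂/se and df = n_eff − k − 1, power is
    P(T_ncp > t_crit) + P(T_ncp < −t_crit) at the two-sided critical value
    t_crit of level alpha.  At β̂ = 0 this equals alpha exactly.
    """
    df = inp.n_eff - inp.n_predictors - 1
    if df <= 0:
        raise ValueError("degrees of freedom must be positive")
    ncp = inp.beta_hat / inp.se
    t_crit = sps.t.ppf(1.0 - inp.alpha / 2.0, df)
    power = sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp)
    if not np.isfinite(power):
        # scipy's noncentral t loses accuracy at extreme noncentrality;
        # fall back to the asymptotic normal shift.
        power = sps.norm.sf(t_crit - ncp) + sps.norm.cdf(-t_crit - ncp)
    return float(power)
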