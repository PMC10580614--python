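"""Distributed-lag conditional-logistic inference.

The model: within stratum *i* (one case day + 3-4 referent days),

    logit P(case | x) = alpha_i + beta' x

where x holds the 7 linear PM2.5 lag terms (lags 0..6) and a quadratic
B-spline basis (4 df, equally spaced knots) of temperature.  The
stratum intercepts alpha_i cancel from the conditional likelihood

    L(beta) = prod_i exp(x_case' beta) / sum_rows exp(x_row' beta),

which is maximised by Newton-Raphson with step-halving.  Effect
summaries are reported as the percent increase in the odds of death per
10 ug/m3 higher PM2.5: 100 (exp(10 b) - 1), with Wald 95% intervals;
cumulative windows (lag01 = lags 0-1, lag06 = lags 0-6) sum the lag
coefficients and use the delta-method variance of the sum.

Departures from nonlinearity in the PM2.5 concentration-response are
screened by a likelihood-ratio test comparing the linear lag terms to
per-lag fixed-df quadratic B-spline expansions (a nested pair, so the
statistic is chi-squared under linearity).  Effect modification between
two strata of a covariate is judged by the 95% CI of the difference of
log-odds coefficients, (E1 - E2) +/- 1.96 sqrt(se1^2 + se2^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.stats import chi2, norm

__all__ = [
    "ModelSpec",
    "FitResult",
    "EffectEstimate",
    "ModifierComparison",
    "bspline_basis",
    "spline_columns",
    "conditional_loglik",
    "fit_conditional_logistic",
    "cumulative_effect",
    "single_lag_effect",
    "linearity_lrt",
    "compare_strata",
    "stratified_analysis",
    "MODIFIER_LEVELS",
]

Z95 = float(norm.ppf(0.975))


@dataclass(frozen=True)
class ModelSpec:
    """Covariate specification for the conditional-logistic fit.

    Parameters
    ----------
    pm_lags
        Which exposure lags enter as linear terms (default 0..6).
    temp_df, temp_degree
        Temperature spline: quadratic B-spline with ``temp_df``
        informative columns (default 4; the stratum-constant direction
        of the full partition-of-unity basis is dropped).
    temp_structure
        ``"mean"`` — one basis of the mean temperature over lags 0..6
        (default); ``"per-lag"`` — a separate basis per lag; ``None`` —
        no temperature adjustment.
    pm_constraint
        ``"cumulative"`` collapses the lag terms into one summed-
        exposure column (used to cross-check the delta method).
    pm_spline_df
        When set, each linear PM lag term is replaced by a quadratic
        B-spline expansion with this many columns (the nonlinearity
        test's alternative model).
    """

    pm_lags: tuple[int, ...] = (0, 1, 2, 3, 4, 5, 6)
    temp_df: int = 4
    temp_degree: int = 2
    temp_structure: str | None = "mean"
    pm_constraint: str | None = None
    pm_spline_df: int | None = None


@dataclass
class FitResult:
    beta: np.ndarray
    cov: np.ndarray
    loglik: float
    n_strata: int
    converged: bool
    iterations: int
    colnames: list[str]
    noninformative: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def coef(self, name: str) -> float:
        return float(self.beta[self.colnames.index(name)])


@dataclass(frozen=True)
class EffectEstimate:
    """Percent increase in odds per 10 ug/m3 PM2.5, with Wald 95% CI."""

    window: str
    percent: float
    ci_low: float
    ci_high: float
    beta_sum: float
    se_sum: float


@dataclass(frozen=True)
class ModifierComparison:
    stratum1_name: str
    E1: float
    se1: float
    stratum2_name: str
    E2: float
    se2: float
    diff: float
    ci_low: float
    ci_high: float
    modification_flag: bool


# ---------------------------------------------------------------- splines


def bspline_basis(
    x: np.ndarray, df: int = 4, degree: int = 2, xrange: tuple[float, float] | None = None
) -> np.ndarray:
    """Full clamped B-spline basis with equally spaced interior knots.

    Returns an ``(n, df + 1)`` matrix whose columns sum to 1 at every x
    (partition of unity).  ``df - degree`` interior knots are placed at
    equal offsets inside ``xrange``; x outside the range is clamped to
    it.  The informative basis used in designs drops one column (the
    stratum-absorbed constant direction), leaving ``df`` columns.
    """
    x = np.asarray(x, dtype=float)
    if xrange is None:
        xrange = (float(np.min(x)), float(np.max(x)))
    lo, hi = map(float, xrange)
    if not hi > lo:
        raise ValueError(f"degenerate spline range [{lo}, {hi}]")
    n_interior = df - degree
    if n_interior < 0:
        raise ValueError(f"df={df} too small for degree={degree}")
    interior = lo + (hi - lo) * np.arange(1, n_interior + 1) / (n_interior + 1)
    knots = np.concatenate([[lo] * (degree + 1), interior, [hi] * (degree + 1)])
    xc = np.clip(x, lo, hi)
    # evaluate just inside the right end so the last basis function is 1 at hi
    B = BSpline.design_matrix(
        np.minimum(xc, np.nextafter(hi, lo)), knots, degree
    ).toarray()
    B[xc == hi, -1] = 1.0
    return B


def spline_columns(
    x: np.ndarray,
    df: int,
    degree: int = 2,
    xrange: tuple[float, float] | None = None,
    prefix: str = "s",
) -> tuple[np.ndarray, list[str]]:
    """Informative spline columns (full basis minus its first column)."""
    B = bspline_basis(x, df=df, degree=degree, xrange=xrange)
    names = [f"{prefix}_bs{j}" for j in range(1, B.shape[1])]
    return B[:, 1:], names


# ------------------------------------------------- conditional likelihood


def _group_counts(starts: np.ndarray, n: int) -> np.ndarray:
    return np.diff(np.append(starts, n))


def conditional_loglik(beta, X, is_case, starts, order: int = 2):
    """Conditional log-likelihood with analytic gradient and Hessian.

    ``sum_i [eta_case - log sum_rows exp(eta_row)]`` over strata whose
    rows are the contiguous blocks delimited by ``starts``.  Stabilised
    by per-stratum max subtraction.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    n = X.shape[0]
    counts = _group_counts(starts, n)
    eta = X @ beta
    if not np.all(np.isfinite(eta)):
        bad = int(np.searchsorted(starts, np.flatnonzero(~np.isfinite(eta))[0], "right")) - 1
        raise FloatingPointError(f"non-finite linear predictor in stratum block {bad}")
    m = np.maximum.reduceat(eta, starts)
    e = np.exp(eta - np.repeat(m, counts))
    S = np.add.reduceat(e, starts)
    ll = float(eta[is_case == 1].sum() - (np.log(S) + m).sum())
    if order == 0:
        return ll
    w = e / np.repeat(S, counts)
    grad = X[is_case == 1].sum(axis=0) - X.T @ w
    if order == 1:
        return ll, grad
    wX = w[:, None] * X
    M = np.add.reduceat(wX, starts, axis=0)  # per-stratum weighted mean * 1
    hess = -(X.T @ wX - M.T @ M)
    return ll, grad, hess


def _informative_columns(X, starts, counts) -> np.ndarray:
    mean = np.add.reduceat(X, starts, axis=0) / counts[:, None]
    dev = X - np.repeat(mean, counts, axis=0)
    scale = np.maximum(np.abs(X).max(axis=0), 1.0)
    return (np.abs(dev).max(axis=0) / scale) > 1e-12


def fit_conditional_logistic(
    design,
    model_spec: ModelSpec | None = None,
    max_iter: int = 100,
    grad_tol: float = 1e-8,
    ll_tol: float = 1e-10,
) -> FitResult:
    """Newton-Raphson fit of the conditional-logistic model.

    Starts at beta = 0 with step-halving (max 50 halvings); converged
    when the max absolute gradient drops below ``grad_tol`` or the
    relative log-likelihood change below ``ll_tol``.  The covariance is
    the inverse negative Hessian at the optimum.  Columns with no
    within-stratum variation are non-informative (their coefficient is
    reported as 0 with NaN variance); a very large coefficient norm is
    flagged as possible separation.
    """
    X, is_case, starts = design.X, design.is_case, design.starts
    colnames = list(design.colnames)
    n, p = X.shape
    counts = _group_counts(starts, n)
    info = _informative_columns(X, starts, counts)
    messages: list[str] = []
    noninf = [c for c, ok in zip(colnames, info) if not ok]
    if not info.any():
        raise ValueError("no informative strata: all columns stratum-constant")
    Xi = X[:, info]

    beta = np.zeros(int(info.sum()))
    ll, grad, hess = conditional_loglik(beta, Xi, is_case, starts)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            w, v = np.linalg.eigh(-hess)
            bad = [colnames[j] for j in np.flatnonzero(np.abs(v[:, 0]) > 0.3)]
            raise np.linalg.LinAlgError(
                f"singular Hessian; collinear columns likely among {bad}"
            )
        scale = 1.0
        for _ in range(50):
            cand = beta + scale * step
            ll_new = conditional_loglik(cand, Xi, is_case, starts, order=0)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll_prev = ll
        ll, grad, hess = conditional_loglik(beta, Xi, is_case, starts)
        if np.max(np.abs(grad)) < grad_tol or abs(ll - ll_prev) <= ll_tol * (
            abs(ll_prev) + 1e-12
        ):
            converged = True
            break
    if np.max(np.abs(beta), initial=0.0) > 30:
        messages.append("possible separation: unbounded likelihood suspected")
        converged = False
    try:
        cov_i = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov_i = np.full((Xi.shape[1],) * 2, np.nan)
        messages.append("singular Hessian at optimum; covariance unreliable")
    cov_i = (cov_i + cov_i.T) / 2.0

    beta_full = np.zeros(p)
    beta_full[info] = beta
    cov_full = np.full((p, p), np.nan)
    cov_full[np.ix_(info, info)] = cov_i
    return FitResult(
        beta=beta_full,
        cov=cov_full,
        loglik=ll,
        n_strata=len(starts),
        converged=converged,
        iterations=it,
        colnames=colnames,
        noninformative=noninf,
        messages=messages,
    )


# ------------------------------------------------------- effect summaries


def _percent_ci(beta_sum: float, se_sum: float, scale: float, window: str) -> EffectEstimate:
    pct = (np.exp(scale * beta_sum) - 1.0) * 100.0
    lo = (np.exp(scale * (beta_sum - Z95 * se_sum)) - 1.0) * 100.0
    hi = (np.exp(scale * (beta_sum + Z95 * se_sum)) - 1.0) * 100.0
    return EffectEstimate(
        window=window,
        percent=float(pct),
        ci_low=float(lo),
        ci_high=float(hi),
        beta_sum=float(beta_sum),
        se_sum=float(se_sum),
    )


def cumulative_effect(
    fit: FitResult, lag_set=(0, 1, 2, 3, 4, 5, 6), scale: float = 10.0
) -> EffectEstimate:
    """Cumulative percent increase per ``scale`` ug/m3 over a lag window.

    beta_sum = 1' beta over the window's lag columns; se via the delta
    method on the linear combination, se = sqrt(1' Cov 1).
    """
    if not fit.converged:
        warnings.warn("cumulative effect from a non-converged fit")
    idx = []
    for l in lag_set:
        name = f"pm25_lag{l}"
        if name not in fit.colnames:
            raise ValueError(f"lag {l} not in fitted model")
        idx.append(fit.colnames.index(name))
    beta_sum = float(fit.beta[idx].sum())
    se_sum = float(np.sqrt(fit.cov[np.ix_(idx, idx)].sum()))
    window = f"lag{min(lag_set)}{max(lag_set)}"
    return _percent_ci(beta_sum, se_sum, scale, window)


def single_lag_effect(fit: FitResult, lag: int, scale: float = 10.0) -> EffectEstimate:
    name = f"pm25_lag{lag}"
    j = fit.colnames.index(name)
    return _percent_ci(float(fit.beta[j]), float(np.sqrt(fit.cov[j, j])), scale, f"lag{lag}")


# -------------------------------------------------------- linearity test


def linearity_lrt(rows: pd.DataFrame, model_spec: ModelSpec | None = None,
                  spline_df: int = 3) -> dict:
    """Likelihood-ratio screen for nonlinear PM2.5 concentration-response.

    Compares the linear-lag fit to one where each lag term is expanded
    in a quadratic B-spline with ``spline_df`` columns.  The spline
    span (plus the stratum constants) contains every linear function,
    so the models are nested and the statistic is non-negative;
    p-values come from the chi-squared tail with df = added columns.
    """
    from .design import build_design_matrix

    if model_spec is None:
        model_spec = ModelSpec()
    if model_spec.pm_constraint or model_spec.pm_spline_df:
        raise ValueError("linearity test requires a plain linear-lag null spec")
    lin = fit_conditional_logistic(build_design_matrix(rows, model_spec))
    alt_spec = ModelSpec(
        pm_lags=model_spec.pm_lags,
        temp_df=model_spec.temp_df,
        temp_degree=model_spec.temp_degree,
        temp_structure=model_spec.temp_structure,
        pm_spline_df=spline_df,
    )
    alt = fit_conditional_logistic(build_design_matrix(rows, alt_spec))
    stat = max(0.0, 2.0 * (alt.loglik - lin.loglik))
    df = (spline_df - 1) * len(model_spec.pm_lags)
    return {"stat": stat, "df": df, "p": float(chi2.sf(stat, df)),
            "loglik_linear": lin.loglik, "loglik_spline": alt.loglik}


# --------------------------------------------------- effect modification


def compare_strata(E1: float, se1: float, E2: float, se2: float,
                   name1: str = "stratum1", name2: str = "stratum2") -> ModifierComparison:
    """95% CI of the difference of two log-odds coefficients.

    ``(E1 - E2) +/- 1.96 sqrt(se1^2 + se2^2)``; modification is flagged
    when the interval excludes 0.
    """
    if not (np.isfinite([E1, se1, E2, se2]).all()):
        raise ValueError("non-finite inputs to strata comparison")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    diff = E1 - E2
    half = 1.96 * np.sqrt(se1**2 + se2**2)
    return ModifierComparison(
        stratum1_name=name1, E1=E1, se1=se1,
        stratum2_name=name2, E2=E2, se2=se2,
        diff=diff, ci_low=diff - half, ci_high=diff + half,
        modification_flag=bool(diff - half > 0 or diff + half < 0),
    )


#: Dichotomies used by the subgroup (effect-modification) analyses.
MODIFIER_LEVELS = {
    "age-group": ("adults", "elderly"),
    "sex": ("male", "female"),
    "education": ("no-education", "basic-or-more"),
    "insurance": ("social-security", "no-social-security"),
    "employment": ("employed", "not-employed"),
}


def _modifier_mask(records: pd.DataFrame, modifier: str, level: str) -> pd.Series:
    age = pd.to_numeric(records["age_years"], errors="coerce")
    if modifier == "age-group":
        return age.between(18, 64) if level == "adults" else age >= 65
    if modifier == "sex":
        return records["sex"] == level
    if modifier == "education":
        if level == "no-education":
            return records["education"] == "none"
        return records["education"].isin(["primary", "mid-high", "college"])
    if modifier == "insurance":
        return records["insurance"] == (
            "social-security" if level == "social-security" else "none"
        )
    if modifier == "employment":
        if level == "employed":
            return ~records["job_category"].isin(["not-employed", "unspecified"])
        return records["job_category"] == "not-employed"
    raise ValueError(f"unknown modifier {modifier!r}")


def stratified_analysis(
    records: pd.DataFrame,
    modifier: str,
    series,
    model_spec: ModelSpec | None = None,
    window=(0, 1, 2, 3, 4, 5, 6),
    employment_period=("2013-01-01", "2019-12-31"),
) -> dict:
    """Subgroup analysis: rerun the full fit per modifier level and
    contrast the cumulative log-odds coefficients.

    Levels are the standard dichotomies (adults 18-64 vs elderly >= 65;
    male/female; no education vs basic-or-more; social-security
    affiliation vs none; employed vs not-employed, with 'unspecified'
    dropped).  Employment analyses are restricted to a configurable
    sub-period.  Returns per-level fits/effects and the pairwise
    comparison (None when a level is empty).
    """
    from .design import build_design_matrix, build_strata_table

    if model_spec is None:
        model_spec = ModelSpec()
    if modifier == "employment":
        d = pd.to_datetime(records["death_date"])
        records = records[
            (d >= pd.Timestamp(employment_period[0]))
            & (d <= pd.Timestamp(employment_period[1]))
        ]
    levels = MODIFIER_LEVELS[modifier]
    out: dict = {"modifier": modifier, "levels": {}, "comparison": None}
    effs = {}
    for level in levels:
        sub = records[_modifier_mask(records, modifier, level)]
        if len(sub) == 0:
            out["levels"][level] = {"n_records": 0, "fit": None, "effect": None}
            continue
        rows, drops = build_strata_table(sub, series)
        if len(rows) == 0:
            out["levels"][level] = {"n_records": len(sub), "fit": None, "effect": None}
            continue
        fit = fit_conditional_logistic(build_design_matrix(rows, model_spec))
        eff = cumulative_effect(fit, lag_set=window)
        out["levels"][level] = {
            "n_records": len(sub),
            "n_strata": fit.n_strata,
            "n_dropped": len(drops),
            "fit": fit,
            "effect": eff,
        }
        effs[level] = eff
    if len(effs) == 2:
        (n1, e1), (n2, e2) = effs.items()
        out["comparison"] = compare_strata(
            e1.beta_sum, e1.se_sum, e2.beta_sum, e2.se_sum, n1, n2
        )
    return out
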