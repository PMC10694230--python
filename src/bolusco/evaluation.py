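"""Cohort-level evaluation statistics.

Implements the statistical pipeline used to judge the estimators: the
relative-difference accuracy metric, Pearson correlation with the
conventional strength bins, summary rows with t-based confidence intervals,
pooled-variance group contrasts, Kolmogorov-Smirnov (Lilliefors) normality
flags, rank-based n-tile stratification, an iterative variance-inflation
screen for collinear covariates, and the end-to-end comparison experiment
(both estimators on complete versus start-clipped cohorts).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors

from .compartment import CalibrationConstant
from .errors import (
    BoluscoError,
    InsufficientDataError,
    StratificationError,
    UndefinedCorrelationError,
    ValidationError,
)
from .estimation import estimate_co_ttp
from .stewart_hamilton import fit_gamma_variate, stewart_hamilton_co
from .synthetic import CohortSpec, generate_cohort

__all__ = [
    "SummaryRow", "GroupContrast", "VIFScreenResult",
    "relative_difference", "classify_r", "pearson_with_class",
    "t_interval", "summarize", "contrast_interval", "gender_contrast",
    "normality_flag", "ntile_stratify", "vif_screen",
    "run_comparison_experiment",
]

#: Correlation-strength bins; a boundary value belongs to the upper class.
_R_CLASSES = ((0.3, "none"), (0.5, "weak"), (0.7, "moderate"),
              (0.9, "strong"), (1.0 + 1e-12, "very_strong"))


@dataclass(frozen=True)
class SummaryRow:
    variable: str
    mean: float
    median: float
    sd: float
    ci_low: float
    ci_high: float
    ci_level: float
    n: int


@dataclass(frozen=True)
class GroupContrast:
    difference: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    df: int


@dataclass(frozen=True)
class VIFScreenResult:
    retained: list[str]
    coefficients: dict[str, float]
    p_values: dict[str, float]
    dropped: list[tuple[str, str]]   # (name, reason)


def relative_difference(co_est: float, co_ref: float) -> float:
    """(estimate - reference) / reference; the signed accuracy metric."""
    if co_ref <= 0:
        raise ValidationError("reference CO must be > 0")
    return (co_est - co_ref) / co_ref


def classify_r(r: float) -> str:
    """Conventional strength label for a correlation coefficient."""
    a = abs(r)
    if a > 1.0 + 1e-9 or not math.isfinite(a):
        raise ValidationError(f"|r|={a} outside [0, 1]")
    for upper, label in _R_CLASSES:
        if a < upper:
            return label
    return "very_strong"


def pearson_with_class(x, y) -> tuple[float, str, float]:
    """Pearson r with strength label and two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance in an input vector")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    return r, classify_r(r), float(res.pvalue)


def t_interval(mean: float, sd: float, n: int,
               ci_level: float = 0.95) -> tuple[float, float]:
    """Two-sided t-interval mean +/- t_{1-a/2, n-1} * sd / sqrt(n)."""
    if n < 2:
        raise InsufficientDataError("t-interval needs n >= 2")
    half = stats.t.ppf(0.5 + ci_level / 2.0, n - 1) * sd / math.sqrt(n)
    return mean - half, mean + half


def summarize(values, variable: str = "", ci_level: float = 0.95) -> SummaryRow:
    """Mean, median, sample SD and t-based CI of one variable."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise InsufficientDataError("summary needs n >= 2")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    lo, hi = t_interval(mean, sd, v.size, ci_level)
    return SummaryRow(variable=variable, mean=mean, median=float(np.median(v)),
                      sd=sd, ci_low=lo, ci_high=hi, ci_level=ci_level,
                      n=int(v.size))


def contrast_interval(difference: float, se: float, df: int,
                      ci_level: float = 0.95) -> tuple[float, float]:
    """CI of a group difference given its standard error and t-df."""
    half = stats.t.ppf(0.5 + ci_level / 2.0, df) * se
    return difference - half, difference + half


def gender_contrast(a, b, ci_level: float = 0.95) -> GroupContrast:
    """Pooled-variance two-sample t contrast (group A minus group B)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InsufficientDataError("each group needs n >= 2")
    na, nb = a.size, b.size
    df = na + nb - 2
    sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / df
    se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = float(np.mean(a) - np.mean(b))
    lo, hi = contrast_interval(diff, se, df, ci_level)
    tstat = diff / se if se > 0 else 0.0
    p = 2.0 * float(stats.t.sf(abs(tstat), df)) if se > 0 else 1.0
    return GroupContrast(difference=diff, se=se, ci_low=lo, ci_high=hi,
                         p_value=p, df=df)


def normality_flag(values, alpha: float = 0.05) -> str:
    """Lilliefors-corrected KS test against a fitted normal.

    Returns ``"normal"`` or ``"non_normal"``; a constant vector is flagged
    non-normal (degenerate distribution).  Advisory only -- used to decide
    whether a variable is reported as mean or median.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 5:
        raise InsufficientDataError("normality test needs n >= 5")
    if np.std(v) == 0:
        return "non_normal"
    _, p = lilliefors(v, dist="norm", pvalmethod="table")
    return "non_normal" if p < alpha else "normal"


def ntile_stratify(values, k: int) -> np.ndarray:
    """Rank-based k-tile labels 1..k (SPSS "Ntiles" convention).

    Observation with (average) rank ``r`` gets label ``ceil(r * k / n)``;
    ties share the label of their mean rank.
    """
    v = np.asarray(values, dtype=float)
    if k < 2:
        raise ValidationError("k must be >= 2")
    if k > v.size:
        raise StratificationError(f"k={k} exceeds n={v.size}")
    ranks = stats.rankdata(v, method="average")
    labels = np.ceil(ranks * k / v.size).astype(int)
    return np.clip(labels, 1, k)


def _vif_values(x: pd.DataFrame) -> pd.Series:
    """VIF_j = 1 / (1 - R^2_j) of each column regressed on the others.

    Rank-deficient auxiliary regressions are solved by least squares
    (pseudo-inverse), so perfectly collinear columns get infinite VIF with a
    warning rather than a crash.
    """
    out = {}
    cols = list(x.columns)
    for j, name in enumerate(cols):
        others = [c for c in cols if c != name]
        yj = x[name].to_numpy(dtype=float)
        if not others:
            out[name] = 1.0
            continue
        design = np.column_stack([np.ones(len(x))] +
                                 [x[c].to_numpy(dtype=float) for c in others])
        coef, *_ = np.linalg.lstsq(design, yj, rcond=None)
        resid = yj - design @ coef
        tss = float(np.sum((yj - yj.mean()) ** 2))
        r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 1.0
        if r2 >= 1.0 - 1e-12:
            warnings.warn(f"predictor {name!r} is perfectly collinear",
                          stacklevel=3)
            out[name] = math.inf
        else:
            out[name] = 1.0 / (1.0 - r2)
    return pd.Series(out)


def _ols_pvalues(y: np.ndarray, x: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
    model = sm.OLS(y, sm.add_constant(x.to_numpy(dtype=float))).fit()
    params = pd.Series(model.params[1:], index=x.columns)
    pvals = pd.Series(model.pvalues[1:], index=x.columns)
    return params, pvals


def vif_screen(response, predictors: pd.DataFrame,
               vif_threshold: float = 5.0,
               alpha: float = 0.05) -> VIFScreenResult:
    """Iterative collinearity-then-significance variable elimination.

    Phase 1: while any predictor's VIF exceeds ``vif_threshold``, drop the
    one with the highest VIF (ties broken by the larger regression p-value)
    and refit.  Phase 2: while any retained predictor has p >= ``alpha``,
    drop the one with the largest p-value and refit.  An empty final set is a
    valid outcome.
    """
    y = np.asarray(response, dtype=float)
    x = predictors.copy()
    if len(y) <= x.shape[1] + 1:
        raise InsufficientDataError(
            "need n > number of predictors + 1 observations")
    dropped: list[tuple[str, str]] = []

    while x.shape[1] > 0:
        vifs = _vif_values(x)
        if vifs.max() <= vif_threshold:
            break
        worst = vifs.max()
        candidates = vifs.index[vifs >= worst - 1e-12]
        if len(candidates) > 1:
            _, pvals = _ols_pvalues(y, x)
            victim = pvals[candidates].idxmax()
        else:
            victim = candidates[0]
        dropped.append((victim, f"VIF={vifs[victim]:.3g}"))
        x = x.drop(columns=[victim])

    while x.shape[1] > 0:
        params, pvals = _ols_pvalues(y, x)
        if pvals.max() < alpha:
            break
        victim = pvals.idxmax()
        dropped.append((victim, f"p={pvals[victim]:.3g}"))
        x = x.drop(columns=[victim])

    if x.shape[1] > 0:
        params, pvals = _ols_pvalues(y, x)
        coefficients = params.to_dict()
        p_values = pvals.to_dict()
    else:
        coefficients, p_values = {}, {}
    return VIFScreenResult(retained=list(x.columns), coefficients=coefficients,
                           p_values=p_values, dropped=dropped)


def run_comparison_experiment(spec: CohortSpec,
                              regimes: tuple[str, ...] = ("complete",
                                                          "clipped_start"),
                              calib: CalibrationConstant | None = None,
                              bracket: tuple[float, float] = (2.0, 12.0),
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Both estimators on the same cohort under each acquisition regime.

    Returns ``(report, per_subject)``.  The report has one row per
    method x regime with the subject count, failure count, Pearson r against
    the true CO, its strength class, and the mean relative difference.
    Estimator failures are recorded per subject and excluded from the
    statistics, never silently dropped.
    """
    calib = calib if calib is not None else CalibrationConstant()
    rows = []
    for regime in regimes:
        cohort = generate_cohort(replace(spec, regime=regime), calib=calib)
        for subj in cohort:
            for method in ("compartment_ttp", "stewart_hamilton"):
                co_est, error = float("nan"), ""
                try:
                    if method == "compartment_ttp":
                        est = estimate_co_ttp(subj.tdc, subj.profile, subj.body,
                                              subj.injection, calib,
                                              bracket=bracket)
                    else:
                        fit = fit_gamma_variate(subj.tdc,
                                                default_baseline_hu=calib.baseline_hu)
                        est = stewart_hamilton_co(fit, subj.injection, calib)
                    co_est = est.co_l_min
                except BoluscoError as err:
                    error = f"{type(err).__name__}: {err}"
                rows.append({
                    "id": subj.profile.id, "regime": regime, "method": method,
                    "co_true": subj.co_true_l_min, "co_est": co_est,
                    "rel_diff": (relative_difference(co_est, subj.co_true_l_min)
                                 if error == "" else float("nan")),
                    "error": error,
                })
    per_subject = pd.DataFrame(rows)

    report_rows = []
    for (method, regime), grp in per_subject.groupby(["method", "regime"],
                                                     sort=True):
        ok = grp[grp["error"] == ""]
        if len(ok) >= 3 and ok["co_est"].std() > 0:
            r, r_class, p = pearson_with_class(ok["co_est"], ok["co_true"])
        else:
            r, r_class, p = float("nan"), "undefined", float("nan")
        report_rows.append({
            "method": method, "regime": regime, "n": len(ok),
            "n_failed": int(len(grp) - len(ok)), "r": r, "r_class": r_class,
            "p_value": p, "mean_rel_diff": float(ok["rel_diff"].mean()),
            "mean_abs_rel_diff": float(ok["rel_diff"].abs().mean()),
        })
    report = pd.DataFrame(report_rows)
    return report, per_subject
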