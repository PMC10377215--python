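"""Cohort statistics: agreement, correlation, group tests, regression.

This module wraps the standard estimators the cohort reports need —
Pearson correlation with Fisher-z confidence intervals, pixel-wise Cohen's
kappa between observer masks, Mann-Whitney U, a Lilliefors-corrected
Kolmogorov-Smirnov normality check, ordinary least squares with partial
correlations, and descriptive summary rows.  Kappa is chance-corrected
agreement computed from the pooled 2x2 pixel-label contingency table; by
default the pipeline scores it inside the segmentation ROI so vast
agreed-on background cannot inflate it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
from statsmodels.stats.diagnostic import lilliefors

from .errors import CompletenessError, UndefinedKappaError, ValidationError
from .morphometry import SubjectMorphometry

__all__ = [
    "CorrelationResult",
    "KappaResult",
    "RegressionTable",
    "SummaryRow",
    "pearson_r_ci",
    "cohen_kappa",
    "kappa_from_counts",
    "mann_whitney_u",
    "ks_normality",
    "multiple_regression",
    "cohort_summary",
    "average_over_observers",
]


@dataclass(frozen=True)
class CorrelationResult:
    n: int
    r: float
    ci_low: float
    ci_high: float
    p: float


@dataclass(frozen=True)
class KappaResult:
    observer_pair: tuple[str, str]
    kappa: float
    ci_low: float
    ci_high: float
    n: int  # pixels scored


@dataclass
class RegressionTable:
    """OLS results: per-predictor rows plus model-level fit statistics."""

    table: pd.DataFrame  # index: const + predictors; cols: coef, se, partial_r, t, p
    r_squared: float
    f_stat: float
    f_pvalue: float
    nobs: int


@dataclass(frozen=True)
class SummaryRow:
    label: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    sem: float
    median: float
    min: float
    max: float


def _check_finite(x: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite values")


def pearson_r_ci(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson product-moment r with Fisher-z CI and two-sided t test p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1D arrays of equal length")
    n = x.size
    if n < 3:
        raise ValidationError("Pearson correlation needs n >= 3")
    _check_finite(x, "x")
    _check_finite(y, "y")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    res = sps.pearsonr(x, y)
    ci = res.confidence_interval(confidence_level=1 - alpha)
    return CorrelationResult(
        n=n, r=float(res.statistic), ci_low=float(ci.low), ci_high=float(ci.high),
        p=float(res.pvalue),
    )


def kappa_from_counts(a: int, b: int, c: int, d: int,
                      pair: tuple[str, str] = ("A", "B")) -> KappaResult:
    """Cohen's kappa from a 2x2 contingency table.

    a = both positive, b = first only, c = second only, d = both negative.
    kappa = (p_o - p_e) / (1 - p_e); CI from the standard large-sample SE
    sqrt(p_o (1 - p_o) / (n (1 - p_e)^2)).
    """
    n = a + b + c + d
    if n == 0:
        raise ValidationError("empty contingency table")
    p_o = (a + d) / n
    p_e = ((a + b) * (a + c) + (c + d) * (b + d)) / (n * n)
    if p_e == 1.0:
        raise UndefinedKappaError(
            "expected agreement is 1 (both raters constant and identical)"
        )
    kappa = (p_o - p_e) / (1 - p_e)
    se = np.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))
    z = sps.norm.ppf(0.975)
    return KappaResult(
        observer_pair=pair,
        kappa=float(kappa),
        ci_low=float(kappa - z * se),
        ci_high=float(min(1.0, kappa + z * se)),
        n=int(n),
    )


def cohen_kappa(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    domain: np.ndarray | None = None,
    pair: tuple[str, str] = ("A", "B"),
) -> KappaResult:
    """Pixel-wise Cohen's kappa between two binary masks.

    ``domain`` restricts scoring to a pixel subset (e.g. the segmentation
    ROI); by construction kappa is invariant to swapping the two labels.
    """
    a_arr = np.asarray(mask_a, dtype=bool)
    b_arr = np.asarray(mask_b, dtype=bool)
    if a_arr.shape != b_arr.shape:
        raise ValidationError("masks must have equal shapes")
    if domain is not None:
        domain = np.asarray(domain, dtype=bool)
        if domain.shape != a_arr.shape:
            raise ValidationError("domain must match mask shape")
        a_arr = a_arr[domain]
        b_arr = b_arr[domain]
    a = int(np.count_nonzero(a_arr & b_arr))
    b = int(np.count_nonzero(a_arr & ~b_arr))
    c = int(np.count_nonzero(~a_arr & b_arr))
    d = int(np.count_nonzero(~a_arr & ~b_arr))
    return kappa_from_counts(a, b, c, d, pair=pair)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (statistic of the first group) and two-sided p.

    Exact enumeration when both samples are small (nA * nB <= 400) and
    tie-free; otherwise the normal approximation with midrank tie
    correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    _check_finite(a, "group_a")
    _check_finite(b, "group_b")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def ks_normality(x) -> tuple[float, float]:
    """Kolmogorov-Smirnov normality test with Lilliefors correction.

    The reference normal's mean and SD are estimated from the sample, so
    the plain KS table would be anti-conservative; Lilliefors' corrected
    p-values account for the estimation.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValidationError("normality test needs n >= 4")
    _check_finite(x, "x")
    if np.std(x) == 0:
        raise ValidationError("zero variance: normality test undefined")
    d, p = lilliefors(x, dist="norm")
    return float(d), float(p)


def multiple_regression(y, X: pd.DataFrame) -> RegressionTable:
    """Ordinary least squares of y on the predictor table (plus intercept).

    Reports per-predictor coefficient, SE, partial correlation
    (t / sqrt(t^2 + df_resid)), t and two-sided p, along with R^2, the F
    ratio and its p-value.  A rank-deficient design raises with the names
    of the collinear columns.
    """
    y = np.asarray(y, dtype=float)
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
    n, p = X.shape
    if y.size != n:
        raise ValidationError("y length does not match design rows")
    if n <= p + 1:
        raise ValidationError(f"need n > p + 1 observations (n={n}, p={p})")
    design = sm.add_constant(X.astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        collinear = _collinear_columns(design)
        raise ValidationError(f"rank-deficient design; collinear columns: {collinear}")

    fit = sm.OLS(y, design).fit()
    df_resid = fit.df_resid
    partial = fit.tvalues / np.sqrt(fit.tvalues**2 + df_resid)
    table = pd.DataFrame(
        {
            "coef": fit.params,
            "se": fit.bse,
            "partial_r": partial,
            "t": fit.tvalues,
            "p": fit.pvalues,
        }
    )
    table.loc["const", ["partial_r"]] = np.nan
    return RegressionTable(
        table=table,
        r_squared=float(fit.rsquared),
        f_stat=float(fit.fvalue),
        f_pvalue=float(fit.f_pvalue),
        nobs=int(fit.nobs),
    )


def _collinear_columns(design: pd.DataFrame) -> list[str]:
    """Columns involved in the smallest singular direction of the design."""
    arr = design.to_numpy(dtype=float)
    arr = arr / np.maximum(np.linalg.norm(arr, axis=0), 1e-300)
    _, _, vt = np.linalg.svd(arr, full_matrices=False)
    weights = np.abs(vt[-1])
    involved = weights > 0.1 * weights.max()
    return [c for c, flag in zip(design.columns, involved) if flag]


def cohort_summary(values, label: str) -> SummaryRow:
    """Descriptive row: N, mean, sample SD, 95% t-CI of the mean, SEM,
    median (midpoint convention), min, max."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("summary needs n >= 2")
    _check_finite(x, label)
    n = x.size
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    sem = sd / np.sqrt(n)
    tcrit = float(sps.t.ppf(0.975, n - 1))
    return SummaryRow(
        label=label,
        n=n,
        mean=mean,
        sd=sd,
        ci_low=mean - tcrit * sem,
        ci_high=mean + tcrit * sem,
        sem=float(sem),
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
    )


def average_over_observers(
    morphs: list[SubjectMorphometry],
) -> dict[str, float]:
    """Mean ARI per subject across observers.

    Every subject must be measured by the same observer set; a missing
    subject/observer combination raises :class:`CompletenessError`.
    """
    if not morphs:
        raise ValidationError("no morphometry records")
    by_subject: dict[str, dict[str, float]] = {}
    for m in morphs:
        by_subject.setdefault(m.subject_id, {})[m.observer_id] = m.ari
    observer_sets = {frozenset(v.keys()) for v in by_subject.values()}
    if len(observer_sets) > 1:
        raise CompletenessError(
            "observers do not cover all subjects: "
            + ", ".join(sorted(str(set(s)) for s in observer_sets))
        )
    return {sid: float(np.mean(list(v.values()))) for sid, v in by_subject.items()}
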