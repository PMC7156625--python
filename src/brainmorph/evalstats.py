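"""Agreement, reliability and clinical-significance statistics.

The evaluation contract of the morphometry regressor: per-target agreement
between prediction ``y`` and silver-standard reference ``g`` via

* the coefficient of determination R² = 1 − Σ(y−g)² / Σ(g−ḡ)²,
* Pearson's r = cov(y, g)/(σ_y σ_g) (blind to a fixed bias: r = 1 for
  y = 2g or y = g + 1),
* the intraclass correlation ICC(2,1) — two-way, absolute agreement, single
  measurement (Shrout–Fleiss), which *does* penalize bias — with its
  F-based 95% confidence interval and Cicchetti interpretation band,
* Bland–Altman mean difference and ±1.96·SD limits of agreement,

plus cohort-level analyses: per-category relative deviation, age/sex-adjusted
Cohen's d group comparisons with one-sided t-tests, linear/quadratic age
trends with Bonferroni correction, and scan–rescan standard deviations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .targets import TargetRegistry, build_registry

__all__ = [
    "PairedSeries",
    "AnovaSquares",
    "ICCResult",
    "AgreementResult",
    "GroupComparison",
    "AgeTrend",
    "r_squared",
    "pearson_r",
    "icc_2_1",
    "cicchetti_band",
    "bland_altman",
    "relative_deviation",
    "cohen_d_adjusted",
    "age_trend",
    "bonferroni_threshold",
    "rescan_sd",
    "rescan_summary",
    "evaluate_pairs",
]


@dataclass
class PairedSeries:
    """Per-target (prediction, reference) pairs across N subjects."""

    y: np.ndarray
    g: np.ndarray

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.y.shape != self.g.shape or self.y.ndim != 1:
            raise ValueError("y and g must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return len(self.y)


def _series(y, g=None) -> PairedSeries:
    return y if isinstance(y, PairedSeries) else PairedSeries(y, g)


def r_squared(y, g=None) -> float:
    """Coefficient of determination of ``y`` against reference ``g``.

    1 for a perfect fit, 0 for a model predicting the reference mean; NaN if
    the reference is constant (undefined).
    """
    s = _series(y, g)
    ss_tot = float(((s.g - s.g.mean()) ** 2).sum())
    if ss_tot == 0:
        return float("nan")
    return 1.0 - float(((s.y - s.g) ** 2).sum()) / ss_tot


def pearson_r(y, g=None) -> float:
    """Pearson correlation; NaN when either series is constant."""
    s = _series(y, g)
    if s.y.std() == 0 or s.g.std() == 0:
        return float("nan")
    return float(np.corrcoef(s.y, s.g)[0, 1])


@dataclass
class AnovaSquares:
    """Two-way ANOVA mean squares for an n-subject × k-rater table."""

    ms_r: float  # rows (subjects)
    ms_c: float  # columns (raters)
    ms_e: float  # residual
    n: int
    k: int


@dataclass
class ICCResult:
    value: float
    ci95: tuple[float, float]
    anova: AnovaSquares
    band: str


def _two_way_squares(table: np.ndarray) -> AnovaSquares:
    n, k = table.shape
    grand = table.mean()
    rows = table.mean(axis=1)
    cols = table.mean(axis=0)
    ss_r = k * ((rows - grand) ** 2).sum()
    ss_c = n * ((cols - grand) ** 2).sum()
    resid = table - rows[:, None] - cols[None, :] + grand
    ss_e = (resid**2).sum()
    return AnovaSquares(
        ms_r=ss_r / (n - 1),
        ms_c=ss_c / (k - 1),
        ms_e=ss_e / ((n - 1) * (k - 1)),
        n=n,
        k=k,
    )


def icc_2_1(y, g=None, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way, absolute-agreement, single-measurement intraclass
    correlation of predictions against the reference.

    Point estimate (Shrout–Fleiss, the form computed by the R package *irr*):

        ICC = (MS_R − MS_E) / (MS_R + (k−1)·MS_E + k/n·(MS_C − MS_E))

    The confidence interval is the standard F-based construction with
    Satterthwaite degrees of freedom for the lower/upper bounds.

    Returns NaN (with a low-variability diagnostic) when the between-subject
    variance vanishes, where the ratio of true to total variance is
    undefined.
    """
    s = _series(y, g)
    if s.n < 3:
        raise ValueError("ICC needs at least 3 subjects")
    table = np.column_stack([s.y, s.g])
    sq = _two_way_squares(table)
    n, k = sq.n, sq.k
    denom = sq.ms_r + (k - 1) * sq.ms_e + (k / n) * (sq.ms_c - sq.ms_e)
    if sq.ms_r <= 1e-30 or denom <= 0:
        warnings.warn(
            "ICC undefined: no between-subject variability (a low ICC can "
            "reflect a lack of variability rather than poor agreement)"
        )
        return ICCResult(float("nan"), (float("nan"), float("nan")), sq, "undefined")
    icc = (sq.ms_r - sq.ms_e) / denom

    a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
    b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
    if np.isfinite(a) and sq.ms_e > 0:
        v = (a * sq.ms_c + b * sq.ms_e) ** 2 / (
            (a * sq.ms_c) ** 2 / (k - 1) + (b * sq.ms_e) ** 2 / ((n - 1) * (k - 1))
        )
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lower = n * (sq.ms_r - f_l * sq.ms_e) / (
            f_l * (k * sq.ms_c + (k * n - k - n) * sq.ms_e) + n * sq.ms_r
        )
        upper = n * (f_u * sq.ms_r - sq.ms_e) / (
            k * sq.ms_c + (k * n - k - n) * sq.ms_e + n * f_u * sq.ms_r
        )
        ci = (float(lower), float(upper))
    else:
        ci = (1.0, 1.0) if icc == 1 else (float("nan"), float("nan"))
    return ICCResult(float(icc), ci, sq, cicchetti_band(float(icc)))


def cicchetti_band(icc: float) -> str:
    """Clinical-significance interpretation band for an ICC value."""
    if not np.isfinite(icc):
        return "undefined"
    if icc < 0.40:
        return "poor"
    if icc < 0.60:
        return "fair"
    if icc < 0.75:
        return "good"
    return "excellent"


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float


def bland_altman(y, g=None) -> BlandAltman:
    """Mean difference (y − g) and ±1.96·SD limits of agreement."""
    s = _series(y, g)
    d = s.y - s.g
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if s.n > 1 else 0.0
    return BlandAltman(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd)


def relative_deviation(
    predictions: np.ndarray,
    references: np.ndarray,
    registry: TargetRegistry | None = None,
    mask: np.ndarray | None = None,
) -> dict[str, tuple[float, float]]:
    """Per-category relative deviation, mean ± SD percent across subjects.

    For each subject: the mean over the category's targets of
    100·(y−g)/g; zero-reference entries are excluded with a warning.
    """
    registry = registry or build_registry()
    predictions = np.atleast_2d(np.asarray(predictions, float))
    references = np.atleast_2d(np.asarray(references, float))
    if predictions.shape != references.shape:
        raise ValueError("prediction/reference shape mismatch")
    out: dict[str, tuple[float, float]] = {}
    for category in ("volume", "thickness", "curvature"):
        idx = np.array([d.index for d in registry if d.category == category])
        if mask is not None:
            idx = idx[mask[idx]]
        if idx.size == 0:
            continue
        g = references[:, idx]
        y = predictions[:, idx]
        valid = g != 0
        if not valid.all():
            warnings.warn(f"{(~valid).sum()} zero-reference entries excluded ({category})")
        rel = np.where(valid, 100.0 * (y - g) / np.where(valid, g, 1.0), np.nan)
        per_subject = np.nanmean(rel, axis=1)
        sd = float(per_subject.std(ddof=1)) if len(per_subject) > 1 else 0.0
        out[category] = (float(per_subject.mean()), sd)
    return out


@dataclass
class GroupComparison:
    cohen_d: float
    p_one_sided: float
    direction: str  # greater | less (patient vs control)
    n_control: int
    n_patient: int


def cohen_d_adjusted(
    values: np.ndarray,
    group: Sequence[str],
    age: Sequence[float] | None = None,
    sex: Sequence[str] | None = None,
    direction: str = "greater",
) -> GroupComparison:
    """Age/sex-adjusted Cohen's d between patients and controls.

    Values are residualized on age and a sex indicator by pooled least
    squares; d is the patient−control mean difference of the residuals over
    their pooled SD.  Significance is a one-sided two-sample t-test on the
    residuals in the configured direction (``greater``: patients larger, as
    for ventricle volumes; ``less``: patients smaller, as for cortical
    thickness).
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    is_pat = group == "patient"
    is_con = group == "control"
    if is_pat.sum() < 2 or is_con.sum() < 2:
        raise ValueError("need at least 2 subjects per group")

    cols = [np.ones(len(values))]
    for cov, name in ((age, "age"), (sex, "sex")):
        if cov is None:
            continue
        x = np.asarray(cov)
        if x.dtype.kind in "UO":
            x = (x == "M").astype(float)
        else:
            x = x.astype(float)
        if np.ptp(x) == 0:
            warnings.warn(f"constant covariate {name!r} dropped from adjustment")
            continue
        cols.append(x)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta

    a, b = resid[is_pat], resid[is_con]
    pooled = np.sqrt(
        ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
        / (len(a) + len(b) - 2)
    )
    d = float((a.mean() - b.mean()) / pooled) if pooled > 0 else 0.0
    alternative = {"greater": "greater", "less": "less"}[direction]
    t = stats.ttest_ind(a, b, alternative=alternative)
    return GroupComparison(d, float(t.pvalue), direction, int(is_con.sum()), int(is_pat.sum()))


@dataclass
class AgeTrend:
    slope: float  # mm/year (order-1 linear coefficient)
    slope_se: float
    slope_ci95: tuple[float, float]
    pearson_r: float
    p: float
    coefficients: tuple[float, ...]  # highest order first
    peak_age: float | None = None  # stationary point, order-2 fits only


def age_trend(values, ages, order: int = 1) -> AgeTrend:
    """Least-squares polynomial age trend of a morphometric.

    Order 1 reports the slope with SE/CI95 and the p-value of the slope;
    order 2 additionally reports the stationary (peak) age −b/(2a).  The
    reported p is for the highest-order coefficient.
    """
    values = np.asarray(values, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    n = len(values)
    if n < order + 2:
        raise ValueError("too few observations for the requested order")
    design = np.vander(ages, order + 1)  # columns: age^order ... 1
    beta, *_ = np.linalg.lstsq(design, values, rcond=None)
    resid = values - design @ beta
    dof = n - (order + 1)
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(design.T @ design)

    # the linear-in-age coefficient is column order-1 of the Vandermonde
    lin_i = order - 1 if order == 1 else 1
    slope = float(beta[lin_i])
    slope_se = float(np.sqrt(cov[lin_i, lin_i]))
    tcrit = stats.t.ppf(0.975, dof)
    ci = (slope - tcrit * slope_se, slope + tcrit * slope_se)
    top_se = float(np.sqrt(cov[0, 0]))
    tstat = beta[0] / top_se if top_se > 0 else np.inf
    p = 2.0 * float(stats.t.sf(abs(tstat), dof))
    peak = None
    if order == 2 and beta[0] != 0:
        peak = float(-beta[1] / (2.0 * beta[0]))
    return AgeTrend(slope, slope_se, ci, pearson_r(values, ages), p, tuple(beta), peak)


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Multiple-comparison-corrected per-test significance level alpha/m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return alpha / m


def rescan_sd(values: Sequence[float]) -> tuple[float, float]:
    """Mean and sample SD (n−1 denominator) of one subject's rescans."""
    v = np.asarray(values, dtype=float)
    if len(v) < 2:
        raise ValueError("per-subject SD needs at least 2 scans")
    return float(v.mean()), float(v.std(ddof=1))


def rescan_summary(
    values_by_subject: Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Per-subject rescan mean/SD plus the SD across all scans pooled.

    Single-scan subjects are excluded from the per-subject rows but kept in
    the pooled row (labelled ``__all__``).
    """
    rows = []
    pooled: list[float] = []
    for subject, vals in values_by_subject.items():
        v = np.asarray(vals, dtype=float)
        pooled.extend(v.tolist())
        if len(v) >= 2:
            m, sd = rescan_sd(v)
            rows.append({"subject_id": subject, "n_scans": len(v), "mean": m, "sd": sd})
    allv = np.asarray(pooled)
    rows.append(
        {
            "subject_id": "__all__",
            "n_scans": len(allv),
            "mean": float(allv.mean()),
            "sd": float(allv.std(ddof=1)) if len(allv) > 1 else 0.0,
        }
    )
    return pd.DataFrame(rows)


def evaluate_pairs(
    predictions: np.ndarray,
    references: np.ndarray,
    registry: TargetRegistry | None = None,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Full per-target agreement report.

    ``predictions``/``references`` are (n_subjects, n_targets) matrices in
    registry order; ``mask`` restricts to populated targets.  Returns one row
    per target with R², Pearson r, ICC(2,1)+CI+band and Bland–Altman stats.
    """
    registry = registry or build_registry()
    predictions = np.atleast_2d(np.asarray(predictions, float))
    references = np.atleast_2d(np.asarray(references, float))
    rows = []
    for d in registry:
        if mask is not None and not mask[d.index]:
            continue
        s = PairedSeries(predictions[:, d.index], references[:, d.index])
        icc = icc_2_1(s) if s.n >= 3 and s.g.std() > 0 else None
        ba = bland_altman(s)
        rows.append(
            {
                "name": d.name,
                "category": d.category,
                "hemisphere": d.hemisphere,
                "units": d.units,
                "r_squared": r_squared(s),
                "pearson_r": pearson_r(s),
                "icc": icc.value if icc else float("nan"),
                "icc_ci_low": icc.ci95[0] if icc else float("nan"),
                "icc_ci_high": icc.ci95[1] if icc else float("nan"),
                "band": icc.band if icc else "undefined",
                "ba_mean_diff": ba.mean_diff,
                "ba_sd_diff": ba.sd_diff,
                "ba_loa_low": ba.loa_low,
                "ba_loa_high": ba.loa_high,
            }
        )
    return pd.DataFrame(rows)
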