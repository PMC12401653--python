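"""Weighted linear calibration fitting and model diagnostics.

Calibration curves relate the IS-normalized response (analyte peak area /
internal-standard peak area, y) to the spiked plasma concentration (x,
ng/mL) by a straight line y = a·x + b fitted by weighted least squares.
Candidate weights 1, 1/x, 1/x², 1/y, 1/y² compensate the heteroscedastic
variance typical of LC-MS responses, where noise grows with concentration.

The module provides:

* :func:`fit_weighted_linear` — WLS fit under one weighting label;
* :func:`mandel_test` — Mandel's F-test of linearity (linear vs quadratic
  residual variance);
* :func:`select_weighting` — data-driven choice of the weighting model from
  replicate curves, by the smallest summed squared relative
  back-calculation error;
* :func:`backcalc_check` — the EMA per-level back-calculation acceptance
  rule (±15%, ±20% at the LLOQ, at least 75% of levels passing);
* :func:`heteroscedasticity_ftest` — variance-ratio diagnostic comparing
  response scatter at the lowest vs highest calibrator.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .panel_io import AcceptanceThresholds, WEIGHTING_LABELS, \
    canonical_weighting

__all__ = [
    "CalPoint",
    "CalibrationFit",
    "MandelResult",
    "BackcalcReport",
    "WeightingSelection",
    "fit_weighted_linear",
    "mandel_test",
    "select_weighting",
    "backcalc_check",
    "heteroscedasticity_ftest",
]

#: Tie-break preference: simpler weighting wins on equal total SSR.
_SIMPLICITY_ORDER = {lbl: k for k, lbl in enumerate(WEIGHTING_LABELS)}


@dataclass(frozen=True)
class CalPoint:
    """One calibrator observation: concentration x, area ratio y."""

    conc: float
    ratio: float

    def __post_init__(self):
        if self.conc <= 0:
            raise ValueError("calibrator concentration must be positive")
        if not math.isfinite(self.ratio):
            raise ValueError("area ratio must be finite")


@dataclass(frozen=True)
class CalibrationFit:
    """A fitted weighted linear calibration y = slope·x + intercept."""

    slope: float
    intercept: float
    weighting_label: str
    ssr_relative: float
    n_points: int
    residuals: tuple[float, ...]

    def backcalc(self, ratio: float) -> float:
        """Concentration read back from a response ratio."""
        return (ratio - self.intercept) / self.slope


@dataclass(frozen=True)
class MandelResult:
    """Mandel linearity test: does a quadratic term significantly reduce
    the residual variance of the calibration fit?"""

    sse_linear: float
    sse_quadratic: float
    f_statistic: float
    p_value: float
    linear_accepted: bool
    alpha: float


@dataclass(frozen=True)
class BackcalcReport:
    """Per-level back-calculation accuracy against the EMA rule."""

    per_level_bias_pct: tuple[float, ...]
    per_level_pass: tuple[bool, ...]
    n_pass: int
    overall_pass: bool
    min_required: int


@dataclass(frozen=True)
class WeightingSelection:
    """Outcome of data-driven weighting-model selection."""

    label: str
    total_ssr: dict[str, float]
    excluded: tuple[str, ...] = ()


def _weights(label: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    if label == "equal":
        return np.ones_like(x)
    if label == "1/x":
        return 1.0 / x
    if label == "1/x2":
        return 1.0 / x**2
    if (y <= 0).any():
        raise ValueError(
            f"weighting {label} requires strictly positive ratios")
    if label == "1/y":
        return 1.0 / y
    if label == "1/y2":
        return 1.0 / y**2
    raise ValueError(f"unknown weighting label: {label!r}")


def fit_weighted_linear(points: Sequence[CalPoint],
                        weighting_label: str) -> CalibrationFit:
    """Fit y = a·x + b minimizing Σ wᵢ(yᵢ − a·xᵢ − b)².

    ``weighting_label`` is any accepted spelling of equal, 1/x, 1/x², 1/y,
    1/y² (see :func:`toxscreen.panel_io.canonical_weighting`).  The fit
    quality carried in ``ssr_relative`` is the sum of squared relative
    back-calculation errors Σ((x̂ᵢ − xᵢ)/xᵢ)², a scale-free figure that is
    comparable across weighting models and concentration ranges.
    """
    label = canonical_weighting(weighting_label)
    if len(points) < 3:
        raise ValueError("calibration fit needs at least 3 points")
    x = np.array([p.conc for p in points], dtype=float)
    y = np.array([p.ratio for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("singular design: all concentrations equal")
    w = _weights(label, x, y)
    # np.polyfit minimizes sum((w_i * (y_i - f(x_i)))**2) for weights w,
    # so pass sqrt of the WLS weights.
    slope, intercept = np.polyfit(x, y, 1, w=np.sqrt(w))
    resid = y - (slope * x + intercept)
    backcalc = (y - intercept) / slope
    ssr_rel = float(np.sum(((backcalc - x) / x) ** 2))
    return CalibrationFit(slope=float(slope), intercept=float(intercept),
                          weighting_label=label, ssr_relative=ssr_rel,
                          n_points=len(points),
                          residuals=tuple(float(r) for r in resid))


def mandel_test(points: Sequence[CalPoint],
                alpha: float = 0.05) -> MandelResult:
    """Mandel's fitting test of calibration linearity.

    Fits the calibration points with an unweighted straight line and an
    unweighted quadratic and compares residual variances:

        F = (SSE_linear − SSE_quadratic) / (SSE_quadratic / (n − 3))

    referred to F(1, n − 3).  The linear model is accepted when
    p ≥ alpha, i.e. the quadratic term does not significantly improve the
    fit.  With only five calibrators the denominator has 2 degrees of
    freedom, so the test has low power; a warning is emitted for n ≤ 5.
    """
    n = len(points)
    if n < 4:
        raise ValueError("Mandel test needs at least 4 points "
                         "(quadratic fit leaves no residual df below 4)")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if n <= 5:
        warnings.warn(
            f"Mandel test with n={n} calibrators has only {n - 3} "
            f"denominator df; low power to detect curvature",
            stacklevel=2)
    x = np.array([p.conc for p in points], dtype=float)
    y = np.array([p.ratio for p in points], dtype=float)
    sse_lin = float(np.sum((y - np.polyval(np.polyfit(x, y, 1), x)) ** 2))
    sse_quad = float(np.sum((y - np.polyval(np.polyfit(x, y, 2), x)) ** 2))
    sse_quad = min(sse_quad, sse_lin)  # guard numerical round-off on nesting
    df = n - 3
    if sse_quad == 0.0:
        f_stat, p = math.inf, 0.0
    else:
        f_stat = (sse_lin - sse_quad) / (sse_quad / df)
        p = float(stats.f.sf(f_stat, 1, df))
    return MandelResult(sse_linear=sse_lin, sse_quadratic=sse_quad,
                        f_statistic=f_stat, p_value=p,
                        linear_accepted=p >= alpha, alpha=alpha)


def _replicate_scatter_heteroscedastic(
        replicate_curves: Sequence[Sequence[CalPoint]]) -> Optional[bool]:
    """Does replicate scatter grow with concentration?

    Pools the response ratios observed at each concentration across the
    replicate curves and compares, by Gaussian maximum likelihood, the two
    extreme variance models for the within-level scatter: Var(y) = σ²
    (homoscedastic) against Var(y) = σ²·x² (constant relative sd).
    Returns True for the heteroscedastic model, False for the
    homoscedastic one, and None when the scatter carries no information
    (no replicated level, or zero scatter as in noiseless data).
    """
    by_conc: dict[float, list[float]] = {}
    for curve in replicate_curves:
        for p in curve:
            by_conc.setdefault(p.conc, []).append(p.ratio)
    ss_hom = ss_het = 0.0
    log_w = 0.0
    df = 0
    for conc, ys in by_conc.items():
        if len(ys) < 2:
            continue
        y = np.asarray(ys)
        d2 = float(((y - y.mean()) ** 2).sum())
        ss_hom += d2
        ss_het += d2 / conc**2
        log_w += (len(ys) - 1) * math.log(1.0 / conc**2)
        df += len(ys) - 1
    if df < 2 or ss_hom == 0.0:
        return None
    score_hom = df * math.log(ss_hom / df)
    score_het = df * math.log(ss_het / df) - log_w
    return score_het < score_hom


def _lowest_total(totals: dict[str, float]) -> str:
    # ties (within floating-point resolution of the smallest total) break
    # toward the simpler weighting
    smallest = min(totals.values())
    tol = 1e-9 * smallest + 1e-15
    tied = [lbl for lbl, t in totals.items() if t <= smallest + tol]
    return min(tied, key=_SIMPLICITY_ORDER.__getitem__)


def select_weighting(
        replicate_curves: Sequence[Sequence[CalPoint]],
        labels: Sequence[str] = WEIGHTING_LABELS,
        criterion: str = "scatter_ml") -> WeightingSelection:
    """Choose the weighting model from replicate calibration curves.

    The default ``scatter_ml`` criterion decides in two stages.  First it
    asks whether the replicate scatter grows with concentration, by a
    maximum-likelihood comparison of a homoscedastic against a
    constant-relative-sd variance model on the pooled within-level
    deviations (:func:`_replicate_scatter_heteroscedastic`).  Equal
    weighting is kept when the scatter is homoscedastic; otherwise the
    weighted label (1/x, 1/x², 1/y, 1/y²) with the smallest total squared
    relative back-calculation error across replicates is chosen.  The
    simpler ``relative_ssr`` criterion skips the variance gate and takes
    the smallest total over all five labels; note that relative errors are
    dominated by the lowest calibrators, so it favors 1/x²-style
    weightings even for homoscedastic noise.

    Ties break toward the simpler model in the order
    equal > 1/x > 1/x² > 1/y > 1/y².  A label that cannot be fitted on
    some replicate (e.g. a zero ratio under a 1/y weighting) is excluded
    with a warning; if every label is excluded an error is raised.  The
    per-label SSR totals are returned alongside the winning label.
    """
    if len(replicate_curves) < 2:
        raise ValueError("weighting selection needs >= 2 replicate curves")
    if criterion not in ("scatter_ml", "relative_ssr"):
        raise ValueError(f"unknown selection criterion {criterion!r}")
    totals: dict[str, float] = {}
    excluded: list[str] = []
    for raw in labels:
        label = canonical_weighting(raw)
        try:
            totals[label] = sum(
                fit_weighted_linear(curve, label).ssr_relative
                for curve in replicate_curves)
        except ValueError as exc:
            warnings.warn(f"weighting {label} excluded: {exc}", stacklevel=2)
            excluded.append(label)
    if not totals:
        raise ValueError("no weighting model could be fitted")
    hetero = (None if criterion == "relative_ssr"
              else _replicate_scatter_heteroscedastic(replicate_curves))
    if hetero is False and "equal" in totals:
        best = "equal"
    elif hetero and any(lbl != "equal" for lbl in totals):
        best = _lowest_total({lbl: t for lbl, t in totals.items()
                              if lbl != "equal"})
    else:
        best = _lowest_total(totals)
    return WeightingSelection(label=best, total_ssr=totals,
                              excluded=tuple(excluded))


def backcalc_check(fit: CalibrationFit, points: Sequence[CalPoint],
                   lloq: float,
                   thresholds: AcceptanceThresholds = AcceptanceThresholds(),
                   ) -> BackcalcReport:
    """EMA back-calculation acceptance of a fitted calibration.

    Each calibrator is read back through the fitted line; the relative bias
    100·(x̂ − x)/x must lie within ±15% (±20% at the LLOQ level).  The
    calibration passes when at least 75% of the levels pass — with five
    calibrators, four out of five.
    """
    bias = []
    passed = []
    for p in points:
        if p.conc == 0:
            raise ValueError("nominal 0 gives undefined relative bias")
        b = 100.0 * (fit.backcalc(p.ratio) - p.conc) / p.conc
        limit = (thresholds.backcalc_lloq_pct if p.conc == lloq
                 else thresholds.backcalc_pct)
        bias.append(b)
        passed.append(abs(b) <= limit)
    n = len(points)
    min_required = math.ceil(thresholds.backcalc_pass_fraction * n)
    n_pass = sum(passed)
    return BackcalcReport(per_level_bias_pct=tuple(bias),
                          per_level_pass=tuple(passed),
                          n_pass=n_pass,
                          overall_pass=n_pass >= min_required,
                          min_required=min_required)


def heteroscedasticity_ftest(
        replicate_curves: Sequence[Sequence[CalPoint]]) -> tuple[float, float]:
    """Variance-ratio diagnostic for heteroscedastic calibration noise.

    Compares the variance of the response ratios at the highest calibrator
    against the lowest across replicate curves: F = s²_high / s²_low with
    (n_high − 1, n_low − 1) degrees of freedom; the upper-tail p-value is
    returned.  A small p indicates variance growing with concentration,
    i.e. support for a 1/x-family weighting.  Reported as a diagnostic
    only; it does not drive :func:`select_weighting`.
    """
    if len(replicate_curves) < 2:
        raise ValueError("need >= 2 replicate curves")
    lows, highs = [], []
    for curve in replicate_curves:
        ordered = sorted(curve, key=lambda p: p.conc)
        lows.append(ordered[0].ratio)
        highs.append(ordered[-1].ratio)
    var_low = float(np.var(lows, ddof=1))
    var_high = float(np.var(highs, ddof=1))
    if var_low == 0:
        return math.inf, 0.0
    f_stat = var_high / var_low
    p = float(stats.f.sf(f_stat, len(highs) - 1, len(lows) - 1))
    return f_stat, p
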