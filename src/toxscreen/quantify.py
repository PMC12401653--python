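"""Stored-calibration quantification, interpretation and QC monitoring.

Routine case samples are quantified against the electronically stored
5-point calibration: concentration = (area ratio − intercept) / slope,
where the slope in use is the mean of the stored 5-point slope and any
1-point recalibration slopes accumulated since (see
:func:`one_point_recalibrate`).  Results outside [LLOQ, ULOQ] are censored
rather than reported numerically, and quantifiable results are banded
against literature therapeutic/toxic ranges.

Stored-calibration stability is monitored with a fresh QC-high sample at a
regular cadence; :func:`qc_monitor` applies the escalation rule: two
consecutive QC deviations beyond ±30% trigger a 1-point recalibration of
the slope, and a failure persisting immediately after that adjustment
triggers a fresh 5-point calibration.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

from .panel_io import (AcceptanceThresholds, CalibrationRecord, Measurement,
                       PanelEntry)

__all__ = [
    "QuantResult",
    "QCSeriesPoint",
    "QCAction",
    "quantify",
    "interpret",
    "one_point_recalibrate",
    "qc_monitor",
]

#: Censoring statuses, exhaustive and mutually exclusive.
STATUSES = ("value", "below_lloq", "above_uloq", "nd")

#: Interpretation bands against literature reference ranges.
BANDS = ("subtherapeutic", "therapeutic", "above_therapeutic", "toxic",
         "not_interpretable")


@dataclass(frozen=True)
class QuantResult:
    """A quantified concentration with censoring and interpretation."""

    analyte_name: str
    conc: Optional[float]
    status: str
    band: str
    used_slope: float
    used_intercept: float

    def __post_init__(self):
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")
        if self.band not in BANDS:
            raise ValueError(f"unknown band {self.band!r}")
        if (self.conc is not None) != (self.status == "value"):
            raise ValueError("conc must be present exactly when "
                             "status == 'value'")


@dataclass(frozen=True)
class QCSeriesPoint:
    """One QC-high monitoring observation."""

    timestamp: _dt.date
    analyte_name: str
    nominal: float
    calculated: float

    @property
    def deviation_pct(self) -> float:
        return 100.0 * (self.calculated - self.nominal) / self.nominal


@dataclass(frozen=True)
class QCAction:
    """A recalibration action fired by the QC monitor."""

    action: str  # none | one_point_recalibration | five_point_recalibration
    trigger_points: tuple[int, ...]

    def __post_init__(self):
        if self.action not in ("none", "one_point_recalibration",
                               "five_point_recalibration"):
            raise ValueError(f"unknown action {self.action!r}")


def quantify(m: Measurement, rec: CalibrationRecord,
             entry: Optional[PanelEntry] = None,
             sum_partner_conc: Optional[float] = None) -> QuantResult:
    """Quantify one measurement against a stored calibration record.

    The analyte/IS area ratio is converted with the record's working slope
    (mean of the 5-point slope and the 1-point history) and stored
    intercept.  Status:

    * ``nd`` — no analyte peak (area absent or zero);
    * ``below_lloq`` / ``above_uloq`` — computed concentration outside the
      calibrated range, not reported numerically;
    * ``value`` — concentration within [LLOQ, ULOQ].

    When a :class:`~toxscreen.panel_io.PanelEntry` is supplied, a
    quantifiable result is additionally banded against its
    therapeutic/toxic ranges via :func:`interpret`.
    """
    if rec.archived:
        raise ValueError(f"{rec.analyte_name}: calibration record archived")
    slope = rec.working_slope
    if slope <= 0:
        raise ValueError(f"{rec.analyte_name}: nonpositive working slope")
    ratio = m.ratio
    if ratio is None or m.analyte_area == 0:
        return QuantResult(m.analyte_name, None, "nd", "not_interpretable",
                           slope, rec.intercept)
    conc = (ratio - rec.intercept) / slope
    if conc < rec.lloq:
        return QuantResult(m.analyte_name, None, "below_lloq",
                           "not_interpretable", slope, rec.intercept)
    if conc > rec.uloq:
        return QuantResult(m.analyte_name, None, "above_uloq",
                           "not_interpretable", slope, rec.intercept)
    band = ("not_interpretable" if entry is None
            else interpret(conc, entry, sum_partner_conc))
    return QuantResult(m.analyte_name, conc, "value", band,
                       slope, rec.intercept)


def interpret(conc: float, entry: PanelEntry,
              sum_partner_conc: Optional[float] = None) -> str:
    """Band a concentration against literature therapeutic/toxic ranges.

    Bounds are inclusive on both ends of the therapeutic range, and the
    toxic threshold is inclusive ("toxic above" read as ≥).  Where ranges
    overlap (e.g. a toxic threshold inside the therapeutic range, as for
    carbamazepine) the toxic verdict wins — the safety-conservative
    reading.  For drug + active-metabolite pairs whose printed range refers
    to the sum, passing ``sum_partner_conc`` bands the summed concentration
    against that summed range; without a partner the single concentration
    is banded as-is (no imputation).
    """
    if not entry.has_interpretation_range:
        return "not_interpretable"
    total = conc
    if entry.range_is_sum and sum_partner_conc is not None:
        total = conc + sum_partner_conc
    if entry.toxic_above is not None and total >= entry.toxic_above:
        return "toxic"
    if entry.therapeutic_low is None and entry.therapeutic_high is None:
        return "not_interpretable"
    if entry.therapeutic_low is not None and total < entry.therapeutic_low:
        return "subtherapeutic"
    if entry.therapeutic_high is not None and total > entry.therapeutic_high:
        return "above_therapeutic"
    return "therapeutic"


def one_point_recalibrate(rec: CalibrationRecord,
                          triplicate_ratios: Sequence[float],
                          conc: float) -> CalibrationRecord:
    """Adjust a stored calibration from a triplicate 1-point calibrator.

    The freshly prepared 1-point calibrator (at the stored 1-point
    concentration, i.e. calibrator 3) yields an observed slope
    (mean ratio − intercept) / conc, which is appended to the record's
    slope history; quantification then uses the mean of the 5-point slope
    and all history entries.  The intercept is left unchanged.  Returns a
    new record; the input is not mutated.
    """
    if conc != rec.one_point_conc:
        raise ValueError(
            f"1-point calibrator at {conc} ng/mL does not match stored "
            f"1-point concentration {rec.one_point_conc} ng/mL")
    if len(triplicate_ratios) < 1 or any(r <= 0 for r in triplicate_ratios):
        raise ValueError("1-point ratios must be positive")
    mean_ratio = sum(triplicate_ratios) / len(triplicate_ratios)
    if mean_ratio <= rec.intercept:
        raise ValueError(
            "mean 1-point ratio does not exceed the intercept; "
            "observed slope would be nonpositive")
    observed = (mean_ratio - rec.intercept) / conc
    return dataclasses.replace(
        rec, one_point_slopes=[*rec.one_point_slopes, observed])


def qc_monitor(series: Sequence[QCSeriesPoint],
               thresholds: AcceptanceThresholds = AcceptanceThresholds(),
               ) -> list[QCAction]:
    """Apply the QC-drift escalation rule to a time-ordered QC series.

    A point *fails* when its absolute deviation from nominal exceeds the
    ±30% acceptance limit.  Two consecutive failures trigger a 1-point
    recalibration (fired at the second point); if the very next point
    still fails after that slope adjustment, a fresh 5-point calibration
    is triggered.  After any action, or a passing point, the failure
    episode resets.  Returns the fired actions in order, each with the
    indices of the points that triggered it.
    """
    if not series:
        return []
    if any(s.analyte_name != series[0].analyte_name for s in series):
        raise ValueError("QC series must cover a single analyte")
    times = [s.timestamp for s in series]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("QC series timestamps must be non-decreasing")
    limit = thresholds.qc_drift_pct
    actions: list[QCAction] = []
    consec_fail = 0           # consecutive failing points in this episode
    after_one_point = False   # next point decides escalation
    for i, s in enumerate(series):
        fails = abs(s.deviation_pct) > limit
        if after_one_point:
            after_one_point = False
            if fails:
                actions.append(QCAction("five_point_recalibration", (i,)))
                consec_fail = 0
                continue
        if fails:
            consec_fail += 1
            if consec_fail >= 2:
                actions.append(QCAction("one_point_recalibration",
                                        (i - 1, i)))
                consec_fail = 0
                after_one_point = True
        else:
            consec_fail = 0
    return actions
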