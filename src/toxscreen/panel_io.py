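"""Data model and CSV I/O for the analyte panel, the electronically stored
calibration, peak-area measurement tables and proficiency-test tables.

All tables are plain comma-delimited UTF-8 CSV with a mandatory header row
and period decimal separators; every concentration is in ng/mL.  The panel
describes one analyte per row: its five calibrator levels (calibrator 1 is
the LLOQ, calibrator 5 the ULOQ), QC low/high levels, the weighting label of
its linear calibration model, and literature therapeutic/toxic reference
ranges used for interpretation.  The calibration store holds, per analyte,
the slope and intercept of the stored 5-point curve plus the growing history
of 1-point recalibration slopes.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import math
import re
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

__all__ = [
    "WEIGHTING_LABELS",
    "canonical_weighting",
    "PanelEntry",
    "CalibrationRecord",
    "Measurement",
    "PTEntry",
    "AcceptanceThresholds",
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "load_reference_panel",
    "read_calibration_store",
    "write_calibration_store",
    "renew_calibration_store",
    "read_measurements",
    "write_measurements",
    "read_pt_table",
    "write_pt_table",
    "load_reference_pt_table",
]

#: Canonical weighting labels for the linear calibration model.
WEIGHTING_LABELS = ("equal", "1/x", "1/x2", "1/y", "1/y2")

_WEIGHTING_ALIASES = {
    "equal": "equal",
    "none": "equal",
    "1": "equal",
    "1/x": "1/x",
    "1/x2": "1/x2",
    "1/x^2": "1/x2",
    "1/x²": "1/x2",
    "1/y": "1/y",
    "1/y2": "1/y2",
    "1/y^2": "1/y2",
    "1/y²": "1/y2",
}


class PanelFormatError(ValueError):
    """Raised when a panel/store/measurement/PT CSV violates the format."""


def canonical_weighting(label: str) -> str:
    """Normalize a weighting label to one of :data:`WEIGHTING_LABELS`.

    Accepts the notation used in method documentation ("Equal", "1/x^2")
    as well as the canonical forms.
    """
    key = str(label).strip().lower()
    try:
        return _WEIGHTING_ALIASES[key]
    except KeyError:
        raise PanelFormatError(f"unknown weighting label: {label!r}") from None


def _opt(x) -> Optional[float]:
    """None for NaN/empty, float otherwise."""
    if x is None:
        return None
    if isinstance(x, str):
        x = x.strip()
        if not x or x in {"—", "-", "na", "NA"}:
            return None
        x = float(x)
    if isinstance(x, float) and math.isnan(x):
        return None
    return float(x)


@dataclass(frozen=True)
class PanelEntry:
    """One analyte's calibration design, quantification limits, weighting
    and therapeutic/toxic interpretation ranges.

    ``therapeutic_low``/``therapeutic_high``/``toxic_above`` may be absent
    (``None``) for metabolites without literature reference ranges.  When
    ``range_is_sum`` is true the printed range refers to the sum of the drug
    and its active metabolite (``sum_group`` names the pair).
    """

    analyte_name: str
    weighting_label: str
    cal_levels: tuple[float, float, float, float, float]
    qc_low: float
    qc_high: float
    therapeutic_low: Optional[float] = None
    therapeutic_high: Optional[float] = None
    toxic_above: Optional[float] = None
    range_is_sum: bool = False
    sum_group: Optional[str] = None
    dual_status: bool = False
    working_solution: Optional[int] = None
    retention_time_min: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "weighting_label",
                           canonical_weighting(self.weighting_label))
        levels = tuple(float(c) for c in self.cal_levels)
        if len(levels) != 5:
            raise PanelFormatError(
                f"{self.analyte_name}: expected 5 calibrator levels, "
                f"got {len(levels)}")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise PanelFormatError(
                f"{self.analyte_name}: calibrator levels must be strictly "
                f"increasing, got {levels}")
        object.__setattr__(self, "cal_levels", levels)
        if not (self.lloq <= self.qc_low < self.qc_high <= self.uloq):
            raise PanelFormatError(
                f"{self.analyte_name}: QC levels must satisfy "
                f"LLOQ <= QC low < QC high <= ULOQ "
                f"({self.lloq} <= {self.qc_low} < {self.qc_high} "
                f"<= {self.uloq})")
        if (self.therapeutic_low is not None
                and self.therapeutic_high is not None
                and self.therapeutic_low > self.therapeutic_high):
            raise PanelFormatError(
                f"{self.analyte_name}: inverted therapeutic range")
        if self.working_solution is not None and \
                self.working_solution not in (1, 2, 3):
            raise PanelFormatError(
                f"{self.analyte_name}: working solution must be 1-3")

    @property
    def lloq(self) -> float:
        """Lower limit of quantification == calibrator 1."""
        return self.cal_levels[0]

    @property
    def uloq(self) -> float:
        """Upper limit of quantification == calibrator 5."""
        return self.cal_levels[-1]

    @property
    def one_point_conc(self) -> float:
        """Concentration of the 1-point recalibrator == calibrator 3."""
        return self.cal_levels[2]

    @property
    def is_metabolite(self) -> bool:
        """True for active-metabolite entries (name carries '-M (')."""
        return "-M (" in self.analyte_name

    @property
    def has_interpretation_range(self) -> bool:
        return (self.therapeutic_low is not None
                or self.therapeutic_high is not None
                or self.toxic_above is not None)


@dataclass
class CalibrationRecord:
    """Electronically stored calibration for one analyte.

    Carries the 5-point slope/intercept plus the ordered history of slopes
    determined from 1-point recalibration runs.  The slope actually used for
    quantification (:attr:`working_slope`) is the arithmetic mean of the
    stored 5-point slope and all 1-point slopes.
    """

    analyte_name: str
    istd_name: str
    slope: float
    intercept: float
    lloq: float
    uloq: float
    unit: str = "ng/mL"
    one_point_conc: float = 0.0
    quant_mz: Optional[float] = None
    one_point_slopes: list[float] = field(default_factory=list)
    created_date: Optional[_dt.date] = None
    archived: bool = False

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"{self.analyte_name}: slope must be positive")
        if not self.lloq < self.uloq:
            raise ValueError(f"{self.analyte_name}: LLOQ must be < ULOQ")

    @property
    def working_slope(self) -> float:
        """Mean of the stored 5-point slope and the 1-point slope history."""
        slopes = [self.slope, *self.one_point_slopes]
        return sum(slopes) / len(slopes)


@dataclass(frozen=True)
class Measurement:
    """One peak-area observation for one analyte in one injection."""

    sample_id: str
    analyte_name: str
    analyte_area: Optional[float]  # None => not detected
    is_area: float
    nominal_conc: Optional[float] = None
    sample_role: str = "case"
    run_index: int = 0
    day_index: int = 0
    timestamp: Optional[_dt.datetime] = None

    _ROLES = frozenset({
        "calibrator", "qc_low", "qc_high", "blank", "case", "pt", "neat",
        "postextraction_spike", "single_solution", "mixture",
    })

    def __post_init__(self):
        if self.sample_role not in self._ROLES:
            raise ValueError(f"unknown sample role: {self.sample_role!r}")
        if self.sample_role != "blank" and self.is_area <= 0:
            raise ValueError(
                f"{self.sample_id}/{self.analyte_name}: IS area must be "
                f"positive for quantifiable samples")
        if self.sample_role in {"calibrator", "qc_low", "qc_high"} \
                and self.nominal_conc is None:
            raise ValueError(
                f"{self.sample_id}/{self.analyte_name}: nominal "
                f"concentration required for {self.sample_role} samples")
        if self.analyte_area is not None and self.analyte_area < 0:
            raise ValueError("analyte area must be nonnegative")

    @property
    def ratio(self) -> Optional[float]:
        """IS-normalized response (analyte area / IS area); None if nd."""
        if self.analyte_area is None or self.is_area <= 0:
            return None
        return self.analyte_area / self.is_area


@dataclass(frozen=True)
class PTEntry:
    """One proficiency-test result row.

    ``calculated`` is the numeric concentration or ``None`` when censored;
    censoring is carried in ``censored`` as '' (numeric), '<LLOQ' (detected
    but below the quantification range) or 'nd' (not detected).
    """

    analyte_name: str
    calculated: Optional[float]
    target: float
    accepted_low: float
    accepted_high: float
    censored: str = ""
    censor_limit: Optional[float] = None   # X of a "<X" token
    lloq: Optional[float] = None           # LLOQ printed with the PT row
    reference_comment: Optional[str] = None
    case_type: Optional[str] = None

    def __post_init__(self):
        if self.censored not in ("", "<LLOQ", "nd"):
            raise ValueError(f"bad censor token: {self.censored!r}")
        if (self.calculated is None) == (self.censored == ""):
            raise ValueError("calculated must be numeric XOR censored")
        if not self.accepted_low < self.accepted_high:
            raise PanelFormatError(
                f"{self.analyte_name}: inverted range "
                f"[{self.accepted_low}, {self.accepted_high}]")
        if not self.accepted_low <= self.target <= self.accepted_high:
            raise PanelFormatError(
                f"{self.analyte_name}: target {self.target} outside "
                f"accepted range")
        for v in (self.calculated, self.target, self.accepted_low):
            if v is not None and v < 0:
                raise PanelFormatError(
                    f"{self.analyte_name}: negative concentration")


@dataclass(frozen=True)
class AcceptanceThresholds:
    """All acceptance-criterion constants of the method in one place.

    Percentages follow the EMA bioanalytical guideline and the GTFCh
    recommendations for 24/7 emergency toxicology: calibrator
    back-calculation within ±15% (±20% at the LLOQ, at least 75% of levels
    passing), accuracy/precision and matrix effects within ±30%,
    co-elution ionization effects within ±25%, carry-over below 20% of the
    LLOQ response (5% for the IS), QC drift within ±30%, retention-time
    identification window ±0.4 min, Mandel-test alpha 0.05.
    """

    backcalc_pct: float = 15.0
    backcalc_lloq_pct: float = 20.0
    backcalc_pass_fraction: float = 0.75
    accuracy_pct: float = 30.0
    precision_cv_pct: float = 30.0
    matrix_pct: float = 30.0
    ionization_pct: float = 25.0
    carryover_analyte_pct: float = 20.0
    carryover_is_pct: float = 5.0
    qc_drift_pct: float = 30.0
    rt_window_min: float = 0.4
    alpha_mandel: float = 0.05

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if f.name == "alpha_mandel":
                if not 0 < v < 1:
                    raise ValueError("alpha must be in (0, 1)")
            elif f.name == "backcalc_pass_fraction":
                if not 0 < v <= 1:
                    raise ValueError("pass fraction must be in (0, 1]")
            elif f.name == "rt_window_min":
                if v <= 0:
                    raise ValueError("RT window must be positive")
            elif not 0 < v <= 100:
                raise ValueError(f"{f.name} must be in (0, 100]")


# ---------------------------------------------------------------------------
# panel CSV

_PANEL_REQUIRED = ["analyte", "weighting", "cal1", "cal2", "cal3", "cal4",
                   "cal5", "qc_low", "qc_high"]


def read_panel(path: Union[str, Path]) -> list[PanelEntry]:
    """Read an analyte-panel CSV into a list of :class:`PanelEntry`.

    Raises :class:`PanelFormatError` identifying the offending row and
    column on any parse failure, and on an empty table ("no analytes").
    """
    df = pd.read_csv(path, dtype={"analyte": str, "weighting": str,
                                  "sum_group": str})
    missing = [c for c in _PANEL_REQUIRED if c not in df.columns]
    if missing:
        raise PanelFormatError(f"missing mandatory column(s): {missing}")
    if df.empty:
        raise PanelFormatError("no analytes in panel file")
    entries = []
    for i, row in df.iterrows():
        try:
            ws = _opt(row.get("working_solution"))
            entries.append(PanelEntry(
                analyte_name=str(row["analyte"]).strip(),
                weighting_label=row["weighting"],
                cal_levels=tuple(float(row[f"cal{k}"]) for k in range(1, 6)),
                qc_low=float(row["qc_low"]),
                qc_high=float(row["qc_high"]),
                therapeutic_low=_opt(row.get("therapeutic_low")),
                therapeutic_high=_opt(row.get("therapeutic_high")),
                toxic_above=_opt(row.get("toxic_above")),
                range_is_sum=_parse_bool(row.get("range_is_sum", False)),
                sum_group=(str(row["sum_group"]).strip()
                           if isinstance(row.get("sum_group"), str)
                           and str(row["sum_group"]).strip() else None),
                dual_status=_parse_bool(row.get("dual_status", False)),
                working_solution=int(ws) if ws is not None else None,
                retention_time_min=_opt(row.get("rt_min")),
            ))
        except (PanelFormatError, ValueError, KeyError) as exc:
            raise PanelFormatError(
                f"panel row {i + 2} ({row.get('analyte', '?')}): {exc}"
            ) from exc
    names = [e.analyte_name for e in entries]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise PanelFormatError(f"duplicate analyte name(s): {dupes}")
    return entries


def _parse_bool(x) -> bool:
    if isinstance(x, bool):
        return x
    if isinstance(x, str):
        return x.strip().lower() in {"true", "1", "yes"}
    if isinstance(x, float) and math.isnan(x):
        return False
    return bool(x)


def write_panel(entries: Sequence[PanelEntry], path: Union[str, Path]) -> None:
    """Write panel entries back to CSV (inverse of :func:`read_panel`)."""
    rows = []
    for e in entries:
        rows.append({
            "analyte": e.analyte_name,
            "weighting": e.weighting_label,
            **{f"cal{k + 1}": c for k, c in enumerate(e.cal_levels)},
            "lloq": e.lloq, "uloq": e.uloq,
            "qc_low": e.qc_low, "qc_high": e.qc_high,
            "one_point_conc": e.one_point_conc,
            "therapeutic_low": e.therapeutic_low,
            "therapeutic_high": e.therapeutic_high,
            "toxic_above": e.toxic_above,
            "range_is_sum": e.range_is_sum,
            "sum_group": e.sum_group,
            "dual_status": e.dual_status,
            "working_solution": e.working_solution,
            "rt_min": e.retention_time_min,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_reference_panel() -> list[PanelEntry]:
    """The 69-analyte emergency-toxicology panel bundled with the package."""
    with resources.as_file(
            resources.files("toxscreen.data") / "panel.csv") as p:
        return read_panel(p)


# ---------------------------------------------------------------------------
# calibration-store CSV

_STORE_FIXED = ["analyte", "istd", "slope", "intercept", "lloq", "uloq",
                "unit", "cal_conc_1pt", "quant_mz"]


def write_calibration_store(records: Sequence[CalibrationRecord],
                            path: Union[str, Path]) -> None:
    """Write the electronically stored calibration to CSV.

    Column order mirrors the instrument's calibration-information file:
    analyte, ISTD, slope, intercept, LLOQ, ULOQ, unit, 1-point calibrator
    concentration, quantifier m/z, then one ``cal_slope_<k>`` column per
    1-point slope history entry.
    """
    if not records:
        raise ValueError("no calibration records to write")
    names = [r.analyte_name for r in records]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate analyte name(s) in store: {dupes}")
    n_hist = max(len(r.one_point_slopes) for r in records)
    rows = []
    for r in records:
        row = {
            "analyte": r.analyte_name, "istd": r.istd_name,
            "slope": repr(r.slope), "intercept": repr(r.intercept),
            "lloq": r.lloq, "uloq": r.uloq, "unit": r.unit,
            "cal_conc_1pt": r.one_point_conc,
            "quant_mz": r.quant_mz,
            "created_date": (r.created_date.isoformat()
                             if r.created_date else None),
            "archived": r.archived,
        }
        for k in range(n_hist):
            row[f"cal_slope_{k + 1}"] = (repr(r.one_point_slopes[k])
                                         if k < len(r.one_point_slopes)
                                         else None)
        rows.append(row)
    cols = (_STORE_FIXED[:8] + ["quant_mz"]
            + [f"cal_slope_{k + 1}" for k in range(n_hist)]
            + ["created_date", "archived"])
    # dict keys already include quant_mz once; dedupe preserving order
    cols = list(dict.fromkeys(cols))
    pd.DataFrame(rows).to_csv(path, index=False, columns=cols)


def read_calibration_store(path: Union[str, Path]) -> list[CalibrationRecord]:
    """Read a calibration-store CSV (inverse of
    :func:`write_calibration_store`)."""
    df = pd.read_csv(path, dtype={"analyte": str, "istd": str, "unit": str})
    slope_cols = sorted(
        (c for c in df.columns if re.fullmatch(r"cal_slope_\d+", c)),
        key=lambda c: int(c.rsplit("_", 1)[1]))
    records = []
    for _, row in df.iterrows():
        history = []
        for c in slope_cols:
            v = _opt(row[c])
            if v is None:
                break
            history.append(v)
        created = row.get("created_date")
        records.append(CalibrationRecord(
            analyte_name=row["analyte"], istd_name=row["istd"],
            slope=float(row["slope"]), intercept=float(row["intercept"]),
            lloq=float(row["lloq"]), uloq=float(row["uloq"]),
            unit=str(row["unit"]),
            one_point_conc=float(row["cal_conc_1pt"]),
            quant_mz=_opt(row.get("quant_mz")),
            one_point_slopes=history,
            created_date=(_dt.date.fromisoformat(created)
                          if isinstance(created, str) else None),
            archived=_parse_bool(row.get("archived", False)),
        ))
    return records


def renew_calibration_store(records: Sequence[CalibrationRecord],
                            path: Union[str, Path]) -> Optional[Path]:
    """Initiate a fresh calibration store, archiving any existing file.

    When a new 5-point calibration replaces the stored one, the older CSV is
    moved aside to ``<stem>.archive-<n>.csv`` (first free ``n``) and a new
    store with empty 1-point history is written.  Returns the archive path,
    or None when there was nothing to archive.
    """
    path = Path(path)
    archive = None
    if path.exists():
        n = 1
        while (archive := path.with_suffix(f".archive-{n}.csv")).exists():
            n += 1
        shutil.move(str(path), str(archive))
    write_calibration_store(records, path)
    return archive


# ---------------------------------------------------------------------------
# measurements CSV

def write_measurements(measurements: Sequence[Measurement],
                       path: Union[str, Path]) -> None:
    rows = [{
        "sample_id": m.sample_id, "analyte": m.analyte_name,
        "analyte_area": (repr(m.analyte_area)
                         if m.analyte_area is not None else None),
        "is_area": repr(m.is_area),
        "nominal_conc": m.nominal_conc, "sample_role": m.sample_role,
        "run_index": m.run_index, "day_index": m.day_index,
        "timestamp": m.timestamp.isoformat() if m.timestamp else None,
    } for m in measurements]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_measurements(path: Union[str, Path]) -> list[Measurement]:
    df = pd.read_csv(path, dtype={"sample_id": str, "analyte": str,
                                  "sample_role": str})
    out = []
    for i, row in df.iterrows():
        ts = row.get("timestamp")
        try:
            out.append(Measurement(
                sample_id=str(row["sample_id"]),
                analyte_name=str(row["analyte"]),
                analyte_area=_opt(row["analyte_area"]),
                is_area=float(row["is_area"]),
                nominal_conc=_opt(row.get("nominal_conc")),
                sample_role=str(row["sample_role"]),
                run_index=int(row.get("run_index", 0) or 0),
                day_index=int(row.get("day_index", 0) or 0),
                timestamp=(_dt.datetime.fromisoformat(ts)
                           if isinstance(ts, str) else None),
            ))
        except (ValueError, KeyError) as exc:
            raise PanelFormatError(
                f"measurements row {i + 2}: {exc}") from exc
    return out


# ---------------------------------------------------------------------------
# proficiency-test CSV

_RANGE_RE = re.compile(r"^\s*([0-9.]+)\s*[–\-]\s*([0-9.]+)\s*$")


def _parse_calculated(tok) -> tuple[Optional[float], str, Optional[float]]:
    """Split a 'calculated' cell into (value, censor token, censor limit)."""
    if isinstance(tok, (int, float)) and not (
            isinstance(tok, float) and math.isnan(tok)):
        return float(tok), "", None
    s = str(tok).strip()
    if s.lower() == "nd":
        return None, "nd", None
    if s.startswith("<"):
        return None, "<LLOQ", float(s[1:].strip())
    return float(s), "", None


def read_pt_table(path: Union[str, Path]) -> list[PTEntry]:
    """Read a proficiency-test CSV into :class:`PTEntry` rows.

    The ``calculated`` column holds a number, ``nd`` (not detected) or a
    censored token ``<X`` (detected but below the LLOQ X).  The accepted
    range is given either as ``accepted_low``/``accepted_high`` columns or
    as a single ``range`` column "low–high".
    """
    df = pd.read_csv(path, dtype={"analyte": str, "calculated": str,
                                  "comment": str, "case_type": str})
    if "analyte" not in df.columns or "calculated" not in df.columns \
            or "target" not in df.columns:
        raise PanelFormatError(
            "PT table needs columns: analyte, calculated, target, "
            "and a range")
    out = []
    for i, row in df.iterrows():
        try:
            if "range" in df.columns:
                m = _RANGE_RE.match(str(row["range"]))
                if not m:
                    raise PanelFormatError(
                        f"malformed range string: {row['range']!r}")
                lo, hi = float(m.group(1)), float(m.group(2))
            else:
                lo, hi = float(row["accepted_low"]), float(row["accepted_high"])
            value, censored, limit = _parse_calculated(row["calculated"])
            comment = row.get("comment")
            out.append(PTEntry(
                analyte_name=str(row["analyte"]).strip(),
                calculated=value, censored=censored, censor_limit=limit,
                lloq=_opt(row.get("lloq")),
                target=float(row["target"]),
                accepted_low=lo, accepted_high=hi,
                reference_comment=(str(comment).strip()
                                   if isinstance(comment, str) else None),
                case_type=(str(row["case_type"]).strip()
                           if isinstance(row.get("case_type"), str)
                           else None),
            ))
        except (PanelFormatError, ValueError) as exc:
            raise PanelFormatError(
                f"PT row {i + 2} ({row.get('analyte', '?')}): {exc}"
            ) from exc
    return out


def write_pt_table(entries: Sequence[PTEntry], path: Union[str, Path],
                   verdicts: Optional[Sequence] = None) -> None:
    """Write PT entries (optionally with verdicts) to CSV.

    A dedicated ``status`` column keeps the numeric column purely numeric;
    censored results render as ``nd`` / ``<X`` in ``calculated``.
    """
    rows = []
    for k, e in enumerate(entries):
        if e.censored == "nd":
            calc, status = "nd", "nd"
        elif e.censored == "<LLOQ":
            lim = e.censor_limit
            calc = f"<{lim:g}" if lim is not None else "<LLOQ"
            status = "below_lloq"
        else:
            calc, status = e.calculated, "value"
        row = {
            "case_type": e.case_type, "analyte": e.analyte_name,
            "calculated": calc, "status": status, "target": e.target,
            "accepted_low": e.accepted_low, "accepted_high": e.accepted_high,
            "comment": e.reference_comment,
        }
        if verdicts is not None:
            row["verdict"] = verdicts[k].verdict
            row["rationale"] = verdicts[k].rationale
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def load_reference_pt_table() -> list[PTEntry]:
    """The transcribed interlaboratory proficiency-test results bundled
    with the package (115 rows across six PT schemes)."""
    with resources.as_file(
            resources.files("toxscreen.data") / "proficiency_tests.csv") as p:
        return read_pt_table(p)
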