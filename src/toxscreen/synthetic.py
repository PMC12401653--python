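"""Seeded generator of synthetic peak-area measurement sets.

Emulates the statistical structure the quantification method assumes: a
linear IS-normalized response ratio = slope·conc + intercept with additive
Gaussian noise whose standard deviation has a constant and a
concentration-proportional component (proportional-dominant settings
reproduce the heteroscedasticity that justifies 1/x²-weighted
calibration), independently sampled internal-standard areas, per-donor
matrix-effect multipliers, and a slow multiplicative slope drift over time
emulating declining instrument performance.

All randomness flows through ``numpy.random.default_rng(seed)`` (PCG64),
so a given seed reproduces byte-identical measurement tables on any
platform.  Chromatographic peak shapes, spectra and retention-time drift
are out of scope.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .panel_io import CalibrationRecord, Measurement, PanelEntry
from .quantify import QCSeriesPoint, quantify

__all__ = ["ResponseModel", "generate_calibration_run",
           "generate_qc_timeseries", "generate_validation_batch"]


@dataclass(frozen=True)
class ResponseModel:
    """Parameters of the simulated LC-MS response for one analyte.

    ``noise_constant_sd`` and ``noise_proportional_sd`` combine into the
    ratio-scale noise sd(conc) = constant + proportional·conc.  IS areas
    are drawn lognormally with the given mean and CV; analyte areas are
    reconstructed as ratio × IS area.  ``matrix_factor_by_donor``
    multiplies post-extraction-spiked responses per donor;
    ``slope_drift_per_day`` shrinks the true slope multiplicatively, by
    that fraction per day.
    """

    slope: float = 1e-3
    intercept: float = 0.0
    noise_constant_sd: float = 0.0
    noise_proportional_sd: float = 0.0
    is_area_mean: float = 1e6
    is_area_cv: float = 0.05
    matrix_factor_by_donor: tuple[float, ...] = (1.0,) * 6
    carryover_fraction: float = 0.0
    slope_drift_per_day: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("slope must be positive")
        if self.noise_constant_sd < 0 or self.noise_proportional_sd < 0 \
                or self.is_area_cv < 0:
            raise ValueError("noise parameters must be nonnegative")
        if any(m <= 0 for m in self.matrix_factor_by_donor):
            raise ValueError("matrix multipliers must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def config_json(self) -> str:
        """The model parameters as JSON, for archiving next to outputs."""
        d = dataclasses.asdict(self)
        d["generator"] = "numpy.random.default_rng (PCG64)"
        return json.dumps(d, indent=2, sort_keys=True)

    def _noise_sd(self, conc: float) -> float:
        return self.noise_constant_sd + self.noise_proportional_sd * conc

    def _sample_is_area(self, rng: np.random.Generator) -> float:
        if self.is_area_cv == 0:
            return self.is_area_mean
        # lognormal parametrized by mean / CV keeps areas positive
        sigma2 = np.log1p(self.is_area_cv ** 2)
        mu = np.log(self.is_area_mean) - sigma2 / 2
        return float(rng.lognormal(mu, np.sqrt(sigma2)))

    def sample_ratio(self, conc: float, rng: np.random.Generator,
                     slope: Optional[float] = None) -> float:
        slope = self.slope if slope is None else slope
        ratio = slope * conc + self.intercept
        sd = self._noise_sd(conc)
        if sd > 0:
            ratio += rng.normal(0.0, sd)
        return ratio


def _measurement(model: ResponseModel, rng: np.random.Generator,
                 sample_id: str, analyte: str, conc: float, role: str,
                 run_index: int = 0, day_index: int = 0,
                 slope: Optional[float] = None,
                 response_multiplier: float = 1.0,
                 timestamp: Optional[_dt.datetime] = None) -> Measurement:
    ratio = model.sample_ratio(conc, rng, slope=slope) * response_multiplier
    is_area = model._sample_is_area(rng)
    return Measurement(sample_id=sample_id, analyte_name=analyte,
                       analyte_area=max(ratio, 0.0) * is_area,
                       is_area=is_area, nominal_conc=conc,
                       sample_role=role, run_index=run_index,
                       day_index=day_index, timestamp=timestamp)


def generate_calibration_run(model: ResponseModel,
                             levels: Sequence[float],
                             replicates: int = 1,
                             analyte: str = "Synthetic analyte",
                             ) -> list[Measurement]:
    """Simulate calibrator injections at the given levels.

    Returns ``replicates`` × ``len(levels)`` calibrator measurements with
    the model's linear response and noise, reproducible under the model
    seed.
    """
    if any(c <= 0 for c in levels):
        raise ValueError("calibrator levels must be positive")
    if list(levels) != sorted(levels):
        raise ValueError("calibrator levels must be ascending")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = model.rng()
    out = []
    for rep in range(replicates):
        for lvl, conc in enumerate(levels, start=1):
            out.append(_measurement(
                model, rng, sample_id=f"cal{lvl}_rep{rep + 1}",
                analyte=analyte, conc=float(conc), role="calibrator",
                run_index=rep))
    return out


def generate_qc_timeseries(model: ResponseModel, rec: CalibrationRecord,
                           nominal: float, n_points: int = 48,
                           cadence_days: int = 14,
                           start: Optional[_dt.date] = None,
                           ) -> list[QCSeriesPoint]:
    """Simulate the biweekly QC-high monitoring of a stored calibration.

    The true instrument slope decays multiplicatively by
    ``slope_drift_per_day`` per day while quantification keeps using the
    un-drifted stored record ``rec``, so the expected deviation at day t
    is (1 − drift)^t − 1 (for zero intercept): deviations grow
    deterministically in expectation and noise scatters around that trend.
    The default design, 48 points at a 14-day cadence, spans about two
    years of monitoring.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    start = start or _dt.date(2000, 1, 3)
    rng = model.rng()
    series = []
    for k in range(n_points):
        days = k * cadence_days
        true_slope = model.slope * (1.0 - model.slope_drift_per_day) ** days
        m = _measurement(model, rng, sample_id=f"qc_high_{k + 1}",
                         analyte=rec.analyte_name, conc=nominal,
                         role="qc_high", run_index=k, slope=true_slope)
        res = quantify(m, rec)
        if res.status == "value":
            calc = res.conc
        else:
            # monitoring tracks the raw calculated value even outside
            # the calibrated range
            calc = (m.ratio - rec.intercept) / rec.working_slope
        series.append(QCSeriesPoint(
            timestamp=start + _dt.timedelta(days=days),
            analyte_name=rec.analyte_name, nominal=nominal,
            calculated=calc))
    return series


def generate_validation_batch(model: ResponseModel, entry: PanelEntry,
                              reps: int = 5, days: int = 3,
                              donors: int = 6) -> dict[str, list[Measurement]]:
    """Simulate a full accuracy/precision + matrix-effect validation batch.

    Returns role-tagged measurement sets:

    * ``"neat"`` — ``donors`` replicate neat-solution samples per QC level;
    * ``"postextraction_spike"`` — the same design with the model's
      per-donor matrix multipliers applied to the response;
    * ``"qc"`` — ``reps`` replicates × ``days`` runs at LLOQ, QC low and
      QC high for the accuracy/precision statistics.
    """
    if reps < 5 or days < 3 or donors < 6:
        raise ValueError("validation design below the required minimums "
                         "(5 replicates, 3 days, 6 donors)")
    if len(model.matrix_factor_by_donor) < donors:
        raise ValueError("need a matrix multiplier per donor")
    rng = model.rng()
    batch: dict[str, list[Measurement]] = {
        "neat": [], "postextraction_spike": [], "qc": []}
    for level_name, conc in (("qc_low", entry.qc_low),
                             ("qc_high", entry.qc_high)):
        for d in range(donors):
            batch["neat"].append(_measurement(
                model, rng, sample_id=f"neat_{level_name}_{d + 1}",
                analyte=entry.analyte_name, conc=conc, role="neat"))
        for d in range(donors):
            batch["postextraction_spike"].append(_measurement(
                model, rng, sample_id=f"post_{level_name}_{d + 1}",
                analyte=entry.analyte_name, conc=conc,
                role="postextraction_spike",
                response_multiplier=model.matrix_factor_by_donor[d]))
    for level_name, conc in (("lloq", entry.lloq),
                             ("qc_low", entry.qc_low),
                             ("qc_high", entry.qc_high)):
        role = "qc_high" if level_name == "qc_high" else "qc_low"
        for day in range(days):
            for rep in range(reps):
                batch["qc"].append(_measurement(
                    model, rng,
                    sample_id=f"qc_{level_name}_d{day + 1}_r{rep + 1}",
                    analyte=entry.analyte_name, conc=conc, role=role,
                    run_index=day, day_index=day))
    return batch
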