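"""Instrument-reading quantification and analytical QC.

Flame AAS reports a ppm reading R for a digested aliquot.  With a batch
reagent blank B, dilution factor D (digests are brought to a 50 ml final
volume from a 1 g sample, so D defaults to 50 downstream) and sample mass
W in g, the tissue concentration is

    c [mg/kg] = max(0, R - B) * D / W

Blank-corrected readings below zero have no concentration meaning and are
clamped to 0 with a QC flag.  The module also covers calibration-line
fitting, spike-recovery percent, moisture-basis conversion, and
summarising concentration tables under an explicit below-detection-limit
(BDL) policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats

from .core import ConcentrationRecord, ConcentrationSummary, ValidationError

__all__ = [
    "InstrumentReading",
    "CalibrationFit",
    "RecoveryResult",
    "MoistureSpec",
    "concentration_from_reading",
    "fit_calibration",
    "recovery_percent",
    "dry_fresh_convert",
    "summarize",
    "CALIBRATION_R2_THRESHOLD",
    "STANDARD_SERIES",
    "STANDARD_SERIES_CD",
]

#: Working-standard series, mg/l (Cd uses a narrower range).
STANDARD_SERIES: tuple[float, ...] = (0.0, 0.1, 0.2, 0.5, 1.0, 2.0)
STANDARD_SERIES_CD: tuple[float, ...] = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5)

#: Minimum r-squared for a calibration line to count as usable.
CALIBRATION_R2_THRESHOLD = 0.995


@dataclass
class InstrumentReading:
    """One replicate AAS reading for a digested sample."""

    sample_id: str
    market: str
    body_part: str
    element: str
    replicate: int
    reading: float  # ppm, from the instrument
    dilution: float  # dimensionless
    weight: float  # g
    blank: float = 0.0  # ppm, batch reagent blank

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValidationError(f"{self.sample_id}: sample weight must be positive")
        if self.dilution <= 0:
            raise ValidationError(f"{self.sample_id}: dilution factor must be positive")
        if self.reading < 0 or self.blank < 0:
            raise ValidationError(f"{self.sample_id}: readings must be >= 0")


@dataclass
class CalibrationFit:
    element: str
    slope: float
    intercept: float
    r_squared: float
    standard_concs: tuple[float, ...]

    @property
    def usable(self) -> bool:
        return self.slope > 0 and self.r_squared >= CALIBRATION_R2_THRESHOLD


@dataclass
class RecoveryResult:
    element: str
    added: float  # mg/kg spiked
    measured_spiked: float
    measured_unspiked: float

    @property
    def recovery_pct(self) -> float:
        return recovery_percent(self.measured_spiked, self.measured_unspiked, self.added)


@dataclass
class MoistureSpec:
    """Water fraction of fresh tissue mass, in [0, 1)."""

    body_part: str
    moisture_fraction: float

    def __post_init__(self) -> None:
        if not (0 <= self.moisture_fraction < 1):
            raise ValidationError(
                f"moisture fraction must be in [0, 1), got {self.moisture_fraction}"
            )


def concentration_from_reading(reading: InstrumentReading) -> tuple[float, bool]:
    """Blank-corrected concentration in mg/kg and a clamp flag.

    The flag is true when the raw reading fell below the blank and the
    result was clamped to zero.
    """
    net = reading.reading - reading.blank
    clamped = net < 0
    conc = max(0.0, net) * reading.dilution / reading.weight
    return conc, clamped


def fit_calibration(
    element: str,
    standard_concs: Sequence[float],
    responses: Sequence[float],
) -> CalibrationFit:
    """Ordinary least-squares calibration line response = a*conc + b.

    Requires at least three strictly increasing standard concentrations.
    A fit with non-positive slope or r-squared below
    :data:`CALIBRATION_R2_THRESHOLD` is reported but flagged unusable.
    """
    concs = np.asarray(standard_concs, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if concs.size < 3:
        raise ValidationError("calibration needs at least 3 standards")
    if concs.size != resp.size:
        raise ValidationError("standards and responses differ in length")
    if not np.all(np.diff(concs) > 0):
        raise ValidationError("standard concentrations must be strictly increasing")
    fit = stats.linregress(concs, resp)
    r2 = fit.rvalue**2
    if math.isnan(r2):  # constant responses: zero variance in y
        r2 = 0.0
    return CalibrationFit(
        element=element,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(r2),
        standard_concs=tuple(concs.tolist()),
    )


def recovery_percent(measured_spiked: float, measured_unspiked: float, added: float) -> float:
    """Spike recovery, % = 100 * (spiked - unspiked) / added.  May exceed 100."""
    if added <= 0:
        raise ValidationError(f"spiked amount must be positive, got {added}")
    return 100.0 * (measured_spiked - measured_unspiked) / added


def dry_fresh_convert(
    conc: float,
    moisture: MoistureSpec,
    direction: Literal["dry_to_fresh", "fresh_to_dry"],
) -> float:
    """Convert between dry-weight and fresh-weight bases by mass balance.

    dry -> fresh multiplies by (1 - m), fresh -> dry divides; the two are
    exact inverses.
    """
    m = moisture.moisture_fraction
    if direction == "dry_to_fresh":
        return conc * (1.0 - m)
    if direction == "fresh_to_dry":
        return conc / (1.0 - m)
    raise ValidationError(f"unknown direction {direction!r}")


def summarize(
    records: Iterable[ConcentrationRecord],
    bdl_policy: Literal["zero", "omit"] = "zero",
) -> list[ConcentrationSummary]:
    """Per (body part, element) summaries under an explicit BDL policy.

    ``zero``: censored entries contribute 0 to the mean/SD and count in
    the denominator.  ``omit``: censored entries are dropped from both.
    Min/max always span detected values only.  A cell that is entirely
    censored under ``omit`` is returned with ``n_detected=0`` and NaN
    statistics rather than a silent zero.

    SD is the population-style sample SD (ddof=1) over the included
    values; with one included value it is 0.
    """
    if bdl_policy not in ("zero", "omit"):
        raise ValidationError(f"unknown BDL policy {bdl_policy!r}")
    groups: dict[tuple[str, str], list[ConcentrationRecord]] = {}
    for rec in records:
        groups.setdefault((rec.body_part, rec.element), []).append(rec)
    out: list[ConcentrationSummary] = []
    for (part, element), recs in groups.items():
        detected = np.array([r.mean_conc for r in recs if not r.bdl], dtype=float)
        n_total = len(recs)
        n_det = detected.size
        if bdl_policy == "zero":
            values = np.concatenate([detected, np.zeros(n_total - n_det)])
        else:
            values = detected
        if values.size:
            mean = float(values.mean())
            sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
        else:
            mean = float("nan")
            sd = float("nan")
        out.append(
            ConcentrationSummary(
                body_part=part,
                element=element,
                overall_mean=mean,
                overall_sd=sd,
                min_val=float(detected.min()) if n_det else float("nan"),
                max_val=float(detected.max()) if n_det else float("nan"),
                n_detected=n_det,
                n_total=n_total,
                bdl_policy=bdl_policy,
            )
        )
    return out
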