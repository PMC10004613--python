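"""Seeded generator for a full synthetic market-basket study.

Emulates the sampling design the analysis assumes: six markets, three
chickens per market, six edible body parts, six elements (108 part
samples per element), each digested in triplicate and read on a flame
AAS.  Chicken-level concentrations are lognormal — positive, right-skewed
values whose spread is comparable to their mean, as tissue residue data
typically are — with per-cell (body part, element) medians and geometric
SDs moment-matched to the packaged market-mean table.  On top of the
concentrations the generator produces instrument readings (inverse of the
quantification formula plus multiplicative reading noise and a reagent
blank), calibration series, detection-limit censoring, and paired
spiked/unspiked recovery samples.

Everything is driven by :class:`numpy.random.Generator` seeded from the
config, so a fixed seed reproduces the study exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core import (
    BODY_PARTS,
    ELEMENTS,
    ConcentrationRecord,
    ValidationError,
    load_defaults,
    load_market_survey,
)
from .quantify import (
    STANDARD_SERIES,
    STANDARD_SERIES_CD,
    InstrumentReading,
    RecoveryResult,
)

__all__ = [
    "SyntheticConfig",
    "fit_lognormal_params",
    "generate_concentrations",
    "censor_bdl",
    "emit_readings",
    "generate_calibration_responses",
    "generate_recovery_set",
    "simulate_study",
]

#: Spike recoveries (fraction re-measured) used as generator truth; these
#: are the package's default QC targets for the six elements.
DEFAULT_RECOVERY = {
    "Pb": 1.15,
    "Cd": 0.8036,
    "Cr": 1.0854,
    "Fe": 0.7667,
    "Cu": 0.8524,
    "Zn": 0.9223,
}

#: Tissue water fractions; muscle and liver from gravimetric moisture
#: estimates, the remaining parts a generic 0.70 placeholder.
DEFAULT_MOISTURE = {
    "muscle": 0.7278,
    "liver": 0.6974,
    "gizzard": 0.70,
    "heart": 0.70,
    "kidney": 0.70,
    "brain": 0.70,
}

_FALLBACK_GSD = 1.5  # for cells with <2 detected markets


def fit_lognormal_params(
    records: Iterable[ConcentrationRecord] | None = None,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Moment-match a lognormal per (body part, element) cell.

    Uses the detected market means of the packaged table (or any record
    list): with arithmetic mean m and SD s across markets, the lognormal
    with the same first two moments has sigma^2 = ln(1 + (s/m)^2) and
    median m / sqrt(1 + (s/m)^2).  Cells with fewer than two detected
    markets fall back to a geometric SD of 1.5.
    """
    if records is None:
        records = load_market_survey()
    groups: dict[tuple[str, str], list[float]] = {}
    for rec in records:
        if not rec.bdl:
            groups.setdefault((rec.body_part, rec.element), []).append(rec.mean_conc)
    params: dict[tuple[str, str], tuple[float, float]] = {}
    for key, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        m = float(arr.mean())
        s = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
        if m <= 0:
            raise ValidationError(f"cell {key}: non-positive mean {m}")
        if s <= 0:
            gsd = _FALLBACK_GSD
        else:
            sigma = math.sqrt(math.log1p((s / m) ** 2))
            gsd = math.exp(sigma)
        median = m / math.sqrt(1.0 + (s / m) ** 2) if s > 0 else m
        params[key] = (median, gsd)
    return params


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic study.

    Defaults reproduce the real design: 6 markets x 3 chickens x 6 body
    parts x 6 elements, triplicate 1 g digests brought to 50 ml (dilution
    50), 2% instrument reading CV, and a small reagent blank.
    """

    n_markets: int = 6
    n_chickens_per_market: int = 3
    body_parts: tuple[str, ...] = BODY_PARTS
    elements: tuple[str, ...] = ELEMENTS
    conc_params: Mapping[tuple[str, str], tuple[float, float]] = field(
        default_factory=fit_lognormal_params
    )
    detection_limits: Mapping[str, float] = field(
        default_factory=lambda: {s.symbol: s.detection_limit for s in load_defaults()[0]}
    )
    replicates: int = 3
    dilution: float = 50.0
    sample_weight_g: float = 1.0
    blank_level: float = 0.005  # ppm
    reading_noise_cv: float = 0.02
    recovery_true: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RECOVERY))
    moisture: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_MOISTURE))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markets <= 0 or self.n_chickens_per_market <= 0 or self.replicates <= 0:
            raise ValidationError("design sizes must be positive")
        if self.dilution <= 0 or self.sample_weight_g <= 0:
            raise ValidationError("dilution and sample weight must be positive")
        if self.reading_noise_cv < 0 or self.blank_level < 0:
            raise ValidationError("noise and blank levels must be >= 0")
        for key, (median, gsd) in self.conc_params.items():
            if median <= 0:
                raise ValidationError(f"cell {key}: median must be positive")
            if gsd < 1.0:
                raise ValidationError(f"cell {key}: geometric SD must be >= 1")
        for part, m in self.moisture.items():
            if not (0 <= m < 1):
                raise ValidationError(f"{part}: moisture fraction must be in [0, 1)")

    @property
    def markets(self) -> list[str]:
        return [f"market{i + 1}" for i in range(self.n_markets)]


def generate_concentrations(
    config: SyntheticConfig, seed: int | None = None
) -> list[ConcentrationRecord]:
    """Draw chicken-level concentrations, one record per chicken x part x element.

    Each draw is lognormal(ln median, ln gsd), independent across
    chickens and cells; the market label carries the chicken index as
    ``market{i}/c{j}`` ordering is preserved in the returned list.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[ConcentrationRecord] = []
    for market in config.markets:
        for chicken in range(config.n_chickens_per_market):
            for part in config.body_parts:
                for element in config.elements:
                    try:
                        median, gsd = config.conc_params[(part, element)]
                    except KeyError as err:
                        raise ValidationError(f"no distribution for cell {(part, element)}") from err
                    sigma = math.log(gsd)
                    conc = float(rng.lognormal(mean=math.log(median), sigma=sigma))
                    records.append(
                        ConcentrationRecord(
                            market=market,
                            body_part=part,
                            element=element,
                            mean_conc=conc,
                            n=1,
                            sd=None,
                            bdl=False,
                        )
                    )
    return records


def censor_bdl(
    records: Sequence[ConcentrationRecord],
    detection_limits: Mapping[str, float],
) -> tuple[list[ConcentrationRecord], float]:
    """Mask values below their element's detection limit.

    Returns the censored record list (new objects; originals untouched)
    and the overall censoring fraction.
    """
    out: list[ConcentrationRecord] = []
    n_censored = 0
    for rec in records:
        limit = detection_limits.get(rec.element, 0.0)
        if limit < 0:
            raise ValidationError(f"{rec.element}: detection limit must be >= 0")
        if not rec.bdl and rec.mean_conc < limit:
            out.append(
                ConcentrationRecord(
                    market=rec.market,
                    body_part=rec.body_part,
                    element=rec.element,
                    mean_conc=float("nan"),
                    sd=rec.sd,
                    n=rec.n,
                    bdl=True,
                )
            )
            n_censored += 1
        else:
            out.append(
                ConcentrationRecord(
                    market=rec.market,
                    body_part=rec.body_part,
                    element=rec.element,
                    mean_conc=rec.mean_conc,
                    sd=rec.sd,
                    n=rec.n,
                    bdl=rec.bdl,
                )
            )
    frac = n_censored / len(records) if records else 0.0
    return out, frac


def emit_readings(
    records: Sequence[ConcentrationRecord],
    config: SyntheticConfig,
    seed: int | None = None,
) -> list[InstrumentReading]:
    """Invert the quantification formula into noisy instrument readings.

    For a true concentration c the noise-free reading is
    ``c * W / D + blank``; multiplicative noise (CV =
    ``reading_noise_cv``) is applied to the whole reading so that blank
    subtraction and the zero clamp are both exercised downstream.
    Censored records are skipped (their aliquots produced no usable
    signal).
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 1)
    readings: list[InstrumentReading] = []
    for i, rec in enumerate(records):
        if rec.bdl:
            continue
        ideal = rec.mean_conc * config.sample_weight_g / config.dilution + config.blank_level
        for rep in range(1, config.replicates + 1):
            noise = rng.normal(0.0, config.reading_noise_cv) if config.reading_noise_cv else 0.0
            readings.append(
                InstrumentReading(
                    sample_id=f"S{i:04d}",
                    market=rec.market,
                    body_part=rec.body_part,
                    element=rec.element,
                    replicate=rep,
                    reading=max(0.0, ideal * (1.0 + noise)),
                    dilution=config.dilution,
                    weight=config.sample_weight_g,
                    blank=config.blank_level,
                )
            )
    return readings


def generate_calibration_responses(
    config: SyntheticConfig,
    element: str,
    sensitivity: float = 1.0,
    seed: int | None = None,
) -> tuple[tuple[float, ...], list[float]]:
    """Noisy linear responses over the working-standard series."""
    rng = np.random.default_rng((config.seed if seed is None else seed) + 2)
    concs = STANDARD_SERIES_CD if element == "Cd" else STANDARD_SERIES
    responses = [
        sensitivity * c * (1.0 + (rng.normal(0.0, config.reading_noise_cv) if c else 0.0))
        for c in concs
    ]
    return concs, responses


def generate_recovery_set(
    config: SyntheticConfig,
    seed: int | None = None,
    spike_levels: Sequence[float] = (0.5, 1.0, 2.0),
    base_conc: float = 1.0,
) -> list[RecoveryResult]:
    """Paired spiked/unspiked measurements, triplicate per spike level.

    The measured value of a sample with true concentration c is
    ``c * recovery_true * (1 + noise)``; noise-free, the recovery percent
    works out to exactly 100 x recovery_true.
    """
    rng = np.random.default_rng((config.seed if seed is None else seed) + 3)
    results: list[RecoveryResult] = []
    for element in config.elements:
        rec_true = config.recovery_true.get(element)
        if rec_true is None:
            raise ValidationError(f"no recovery_true configured for {element}")
        for added in spike_levels:
            if added <= 0:
                raise ValidationError("spike level must be positive")
            for _ in range(config.replicates):
                eps1 = rng.normal(0.0, config.reading_noise_cv) if config.reading_noise_cv else 0.0
                eps2 = rng.normal(0.0, config.reading_noise_cv) if config.reading_noise_cv else 0.0
                results.append(
                    RecoveryResult(
                        element=element,
                        added=added,
                        measured_spiked=(base_conc + added) * rec_true * (1.0 + eps1),
                        measured_unspiked=base_conc * rec_true * (1.0 + eps2),
                    )
                )
    return results


def simulate_study(config: SyntheticConfig, seed: int | None = None) -> dict[str, object]:
    """Full synthetic study: truth, censored records, readings, recovery.

    Returns a dict with keys ``truth`` (uncensored chicken-level
    records), ``records`` (after detection-limit censoring),
    ``censored_fraction``, ``readings`` and ``recovery``.
    """
    base = config.seed if seed is None else seed
    truth = generate_concentrations(config, seed=base)
    censored, frac = censor_bdl(truth, config.detection_limits)
    readings = emit_readings(censored, config, seed=base)
    recovery = generate_recovery_set(config, seed=base)
    return {
        "truth": truth,
        "records": censored,
        "censored_fraction": frac,
        "readings": readings,
        "recovery": recovery,
    }
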