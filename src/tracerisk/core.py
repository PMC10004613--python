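"""Domain types, default parameter tables, and tidy-CSV readers/writers.

The package works on a fixed vocabulary of six elements (Pb, Cd, Cr, Fe,
Cu, Zn) and six edible chicken body parts (muscle, liver, gizzard, heart,
kidney, brain).  Concentrations are carried internally in mg/kg fresh
weight; any dry-weight conversion is explicit at the boundary (see
:mod:`tracerisk.quantify`).

Regulatory maximum-allowable-concentration (MAC) limits are stored per
agency and per tissue class.  Agencies distinguish at most four tissue
classes — ``meat``, ``offal``, ``liver``, ``kidney`` — so body parts are
mapped onto classes: muscle is meat; liver and kidney use their own class
when the agency defines one and fall back to offal otherwise; gizzard,
heart and brain are offal.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "ELEMENTS",
    "BODY_PARTS",
    "MARKETS",
    "AGENCIES",
    "TISSUE_CLASSES",
    "SchemaError",
    "ValidationError",
    "ElementSpec",
    "ExposureScenario",
    "ConcentrationRecord",
    "ConcentrationSummary",
    "RiskResult",
    "AggregateRisk",
    "ComplianceFinding",
    "load_defaults",
    "element_table",
    "scenario_table",
    "load_market_survey",
    "read_concentrations",
    "write_concentrations",
    "write_risk_table",
    "apply_overrides",
    "tissue_class_for",
    "records_to_frame",
]

ELEMENTS: tuple[str, ...] = ("Pb", "Cd", "Cr", "Fe", "Cu", "Zn")
BODY_PARTS: tuple[str, ...] = ("muscle", "liver", "gizzard", "heart", "kidney", "brain")
MARKETS: tuple[str, ...] = (
    "Uttara",
    "Gabtoli",
    "Badda",
    "Karwan Bazar",
    "Mohammadpur",
    "Rayer Bazar",
)
TISSUE_CLASSES: tuple[str, ...] = ("meat", "offal", "liver", "kidney")
AGENCIES: tuple[str, ...] = (
    "FAO_WHO",
    "CODEX",
    "ANZFA",
    "EC",
    "FSSAI",
    "FSAI",
    "CN",
    "JECFA",
    "EIC",
    "EOS",
)


class SchemaError(ValueError):
    """A CSV file does not conform to the expected column schema."""


class ValidationError(ValueError):
    """A value violates a domain invariant (carries the offending row)."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ElementSpec:
    """Per-element toxicology and regulatory constants.

    Parameters
    ----------
    symbol:
        Chemical symbol, one of :data:`ELEMENTS`.
    rfd:
        Oral reference dose, mg per kg body weight per day.
    csfo:
        Oral cancer slope factor, (mg/kg/day)^-1, or ``None`` for elements
        with no published slope factor (Fe, Zn).
    detection_limit:
        Instrument detection limit, mg/kg fresh weight.
    mac:
        Mapping ``agency -> tissue class -> limit`` in mg/kg.  Missing
        entries mean the agency defines no limit.
    """

    symbol: str
    rfd: float
    csfo: float | None = None
    detection_limit: float = 0.0
    mac: Mapping[str, Mapping[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.rfd <= 0:
            raise ValidationError(f"{self.symbol}: RfD must be positive, got {self.rfd}")
        if self.csfo is not None and self.csfo <= 0:
            raise ValidationError(f"{self.symbol}: CSFo must be positive, got {self.csfo}")
        if self.detection_limit < 0:
            raise ValidationError(f"{self.symbol}: detection limit must be >= 0")
        for agency, limits in self.mac.items():
            for cls, lim in limits.items():
                if lim <= 0:
                    raise ValidationError(
                        f"{self.symbol}: MAC limit for {agency}/{cls} must be positive"
                    )

    def mac_limit(self, agency: str, body_part: str) -> tuple[str, float | None]:
        """Resolve the limit applying to ``body_part`` under ``agency``.

        Returns ``(tissue_class, limit)``; ``limit`` is ``None`` when the
        agency defines no limit for that class ("no limit defined").
        """
        limits = self.mac.get(agency, {})
        cls = tissue_class_for(body_part, limits)
        return cls, limits.get(cls)


@dataclass(frozen=True)
class ExposureScenario:
    """Population exposure parameters for deterministic intake estimates.

    ``dfc`` is the daily food consumption rate (equivalently the food
    ingestion rate FIR) in g/person/day; ``bw`` body weight in kg; ``ed``
    exposure duration in years; ``efr`` exposure frequency in days/year;
    ``at`` averaging time in days (defaults to ``efr * ed``, under which
    the intake equations simplify to EDI/RfD and EDI x CSFo forms).
    """

    label: str
    dfc: float
    bw: float
    ed: float
    efr: float = 365.0
    at: float | None = None

    def __post_init__(self) -> None:
        if self.at is None:
            object.__setattr__(self, "at", self.efr * self.ed)
        for name in ("dfc", "bw", "ed", "efr", "at"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"scenario {self.label!r}: {name} must be positive")


@dataclass
class ConcentrationRecord:
    """One market x body-part x element concentration observation.

    ``mean_conc`` is in mg/kg fresh weight.  When ``bdl`` is true the
    measurement fell below the detection limit and ``mean_conc`` is not a
    measured value (held as ``nan``; downstream policies decide how it
    contributes).
    """

    market: str
    body_part: str
    element: str
    mean_conc: float
    sd: float | None = None
    n: int | None = None
    bdl: bool = False

    def __post_init__(self) -> None:
        if self.body_part not in BODY_PARTS:
            raise ValidationError(f"unknown body part {self.body_part!r}")
        if self.element not in ELEMENTS:
            raise ValidationError(f"unknown element {self.element!r}")
        if self.bdl:
            self.mean_conc = float("nan")
        elif not (self.mean_conc >= 0):
            raise ValidationError(
                f"({self.market}, {self.body_part}, {self.element}): "
                f"concentration must be >= 0, got {self.mean_conc}"
            )
        if self.sd is not None and not math.isnan(self.sd) and self.sd < 0:
            raise ValidationError("sd must be >= 0")


@dataclass
class ConcentrationSummary:
    """Aggregate of one (body part, element) cell across markets/chickens."""

    body_part: str
    element: str
    overall_mean: float
    overall_sd: float
    min_val: float
    max_val: float
    n_detected: int
    n_total: int
    bdl_policy: str = "zero"


@dataclass
class RiskResult:
    """Deterministic exposure/risk indices for one scenario x element cell.

    ``edi`` in ug/kg BW/day; ``thq`` and ``tcr`` dimensionless.  ``tcr`` is
    ``None`` for elements without a slope factor (not applicable, distinct
    from zero risk).
    """

    scenario: str
    element: str
    edi: float
    thq: float
    market: str | None = None
    tcr: float | None = None
    bdl: bool = False


@dataclass
class AggregateRisk:
    """Roll-ups: TTHQ per food item, HI over items, total TCR per element."""

    scenario: str
    market: str | None = None
    tthq: float | None = None
    hi: float | None = None
    tcr_total: Mapping[str, float] = field(default_factory=dict)
    tcr_class: Mapping[str, str] = field(default_factory=dict)


@dataclass
class ComplianceFinding:
    """Outcome of screening one measurement against one agency limit."""

    element: str
    body_part: str
    agency: str
    tissue_class: str
    limit: float | None
    measured: float
    exceeds: bool
    ratio: float | None

    @property
    def no_limit(self) -> bool:
        return self.limit is None


# --------------------------------------------------------------------------
# default parameter tables
# --------------------------------------------------------------------------


def _all_classes(v: float) -> dict[str, float]:
    return {cls: v for cls in TISSUE_CLASSES}


def _meat_offal(meat: float, offal: float) -> dict[str, float]:
    # an "offal" limit covers liver and kidney unless the agency prints
    # a dedicated class for them
    return {"meat": meat, "offal": offal, "liver": offal, "kidney": offal}


_MAC: dict[str, dict[str, dict[str, float]]] = {
    "Pb": {
        "FAO_WHO": _meat_offal(0.1, 0.5),
        "CODEX": _meat_offal(0.1, 0.5),
        "ANZFA": _meat_offal(0.1, 0.5),
        "EC": {"meat": 0.1},
        "FSSAI": _meat_offal(0.1, 0.5),
        "FSAI": _meat_offal(0.1, 0.5),
        "CN": _all_classes(0.2),
        "JECFA": _all_classes(0.1),
        "EIC": _meat_offal(0.1, 0.5),
        "EOS": _meat_offal(0.1, 0.5),
    },
    "Cd": {
        "FAO_WHO": {"meat": 0.05, "liver": 0.5},
        "EC": {"meat": 0.05, "liver": 0.5},
        "FSAI": {"meat": 0.05, "liver": 0.5, "kidney": 1.0},
        "CN": {"meat": 0.1, "liver": 0.5},
        "JECFA": _all_classes(0.1),
        "EIC": {"meat": 0.05, "liver": 0.5, "kidney": 1.0},
        "EOS": {"meat": 0.05, "offal": 1.0, "liver": 1.0, "kidney": 1.0},
    },
    "Cr": {
        "FAO_WHO": _all_classes(1.0),
    },
    "Fe": {
        "FAO_WHO": _all_classes(180.0),
        "ANZFA": _all_classes(200.0),
        "EOS": _meat_offal(15.0, 20.0),
    },
    "Cu": {
        # the 0.4 mg/kg limit is screened against every tissue class
        "FAO_WHO": _all_classes(0.4),
        "JECFA": _all_classes(0.1),
        "EOS": _all_classes(15.0),
    },
    "Zn": {
        "FAO_WHO": _all_classes(150.0),
    },
}

_RFD = {"Pb": 0.0035, "Cd": 0.001, "Cr": 0.003, "Fe": 0.7, "Cu": 0.04, "Zn": 0.3}
_CSFO = {"Pb": 0.0085, "Cd": 0.38, "Cr": 0.5, "Cu": 1.5}

# Detection limits (mg/kg FW) are not published for this instrument setup;
# these are synthetic defaults chosen so that simulated studies censor Cd
# and Cr most often, matching the qualitative censoring pattern of the
# packaged concentration table.
_DETECTION_LIMIT = {
    "Pb": 0.05,
    "Cd": 0.01,
    "Cr": 0.25,
    "Fe": 0.5,
    "Cu": 0.02,
    "Zn": 0.5,
}


def load_defaults() -> tuple[list[ElementSpec], list[ExposureScenario]]:
    """Default element constants and adult/child exposure scenarios.

    RfDs (mg/kg BW/day): Pb 0.0035, Cd 0.001, Cr 0.003, Fe 0.7, Cu 0.04,
    Zn 0.3.  CSFo ((mg/kg/day)^-1): Pb 0.0085, Cd 0.38, Cr 0.5, Cu 1.5;
    Fe and Zn have none.  Adult: 17.4 g/day, 60 kg, 70 y; child: 8.3
    g/day, 27 kg, 14 y; exposure frequency 365 d/y and averaging time
    365 x ED days for both.
    """
    specs = [
        ElementSpec(
            symbol=el,
            rfd=_RFD[el],
            csfo=_CSFO.get(el),
            detection_limit=_DETECTION_LIMIT[el],
            mac=_MAC.get(el, {}),
        )
        for el in ELEMENTS
    ]
    scenarios = [
        ExposureScenario(label="adult", dfc=17.4, bw=60.0, ed=70.0),
        ExposureScenario(label="child", dfc=8.3, bw=27.0, ed=14.0),
    ]
    return specs, scenarios


def element_table(specs: Iterable[ElementSpec]) -> dict[str, ElementSpec]:
    """Index specs by symbol, rejecting duplicates."""
    table: dict[str, ElementSpec] = {}
    for spec in specs:
        if spec.symbol in table:
            raise ValidationError(f"duplicate element spec for {spec.symbol}")
        table[spec.symbol] = spec
    return table


def scenario_table(scenarios: Iterable[ExposureScenario]) -> dict[str, ExposureScenario]:
    table: dict[str, ExposureScenario] = {}
    for sc in scenarios:
        if sc.label in table:
            raise ValidationError(f"duplicate scenario {sc.label!r}")
        table[sc.label] = sc
    return table


def tissue_class_for(body_part: str, limits: Mapping[str, float] | None = None) -> str:
    """Map a body part onto the regulatory tissue class that applies.

    ``limits`` is the agency's class->limit map for one element; liver and
    kidney prefer their dedicated class when the agency defines one.
    """
    if body_part not in BODY_PARTS:
        raise ValidationError(f"unknown body part {body_part!r}")
    limits = limits or {}
    if body_part == "muscle":
        return "meat"
    if body_part == "liver" and "liver" in limits:
        return "liver"
    if body_part == "kidney" and "kidney" in limits:
        return "kidney"
    return "offal"


# --------------------------------------------------------------------------
# CSV I/O
# --------------------------------------------------------------------------

_CONC_COLUMNS = ("market", "body_part", "element", "mean_conc_mg_kg_fw", "sd_mg_kg", "n", "bdl")


def read_concentrations(path: str | Path) -> list[ConcentrationRecord]:
    """Read a tidy concentration CSV into validated records.

    Expected columns: ``market, body_part, element, mean_conc_mg_kg_fw,
    sd_mg_kg, n, bdl``.  Rows flagged ``bdl`` may leave the numeric
    columns empty.
    """
    df = pd.read_csv(path, dtype={"market": str, "body_part": str, "element": str})
    missing = [c for c in _CONC_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")
    records: list[ConcentrationRecord] = []
    for idx, row in df.iterrows():
        bdl = _parse_bool(row["bdl"])
        mean = float(row["mean_conc_mg_kg_fw"]) if not bdl else float("nan")
        if not bdl and not (mean >= 0):
            raise ValidationError(f"{path} row {idx}: negative or missing concentration {mean}")
        sd = row["sd_mg_kg"]
        n = row["n"]
        try:
            records.append(
                ConcentrationRecord(
                    market=row["market"],
                    body_part=row["body_part"],
                    element=row["element"],
                    mean_conc=mean,
                    sd=None if pd.isna(sd) else float(sd),
                    n=None if pd.isna(n) else int(n),
                    bdl=bdl,
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path} row {idx}: {err}") from err
    return records


def _parse_bool(value: object) -> bool:
    if isinstance(value, bool):
        return value
    if pd.isna(value):
        return False
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no", ""}:
        return False
    raise ValidationError(f"cannot parse boolean {value!r}")


def write_concentrations(records: Sequence[ConcentrationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def records_to_frame(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    """Tidy DataFrame view of concentration records (nan for BDL)."""
    return pd.DataFrame(
        {
            "market": [r.market for r in records],
            "body_part": [r.body_part for r in records],
            "element": [r.element for r in records],
            "mean_conc_mg_kg_fw": [r.mean_conc for r in records],
            "sd_mg_kg": [r.sd for r in records],
            "n": [r.n for r in records],
            "bdl": [r.bdl for r in records],
        }
    )


def load_market_survey() -> list[ConcentrationRecord]:
    """Packaged market-level concentration table (mg/kg fresh weight).

    Six markets x six body parts x six elements; BDL cells carry the flag
    only.  This is the dataset the worked examples and the regression
    tests run on.
    """
    with resources.as_file(resources.files("tracerisk.data") / "market_survey.csv") as p:
        return read_concentrations(p)


def _sig2(x: float) -> str:
    return f"{x:.1E}"


def write_risk_table(
    results: Sequence[RiskResult | AggregateRisk], path: str | Path
) -> pd.DataFrame:
    """Serialize risk results to CSV.

    Rounding happens only here: EDI/THQ/TTHQ/HI to 3 decimals, TCR to two
    significant figures in scientific notation.  Full precision is kept in
    the in-memory objects.
    """
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for r in results:
        if isinstance(r, RiskResult):
            rows.append(
                {
                    "scenario": r.scenario,
                    "market": r.market or "",
                    "element": r.element,
                    "kind": "cell",
                    "edi_ug_kg_day": round(r.edi, 3),
                    "thq": round(r.thq, 3),
                    "tcr": "" if r.tcr is None else _sig2(r.tcr),
                    "bdl": r.bdl,
                }
            )
        else:
            row = {
                "scenario": r.scenario,
                "market": r.market or "",
                "element": "",
                "kind": "aggregate",
                "edi_ug_kg_day": "",
                "thq": "" if r.tthq is None else round(r.tthq, 3),
                "tcr": "",
                "bdl": False,
            }
            rows.append(row)
            if r.hi is not None:
                rows.append({**row, "kind": "hazard_index", "thq": round(r.hi, 3)})
            for el, val in r.tcr_total.items():
                rows.append(
                    {
                        "scenario": r.scenario,
                        "market": r.market or "",
                        "element": el,
                        "kind": "tcr_total",
                        "edi_ug_kg_day": "",
                        "thq": "",
                        "tcr": _sig2(val),
                        "bdl": False,
                    }
                )
    frame = pd.DataFrame(rows)
    frame.to_csv(path, index=False)
    return frame


def apply_overrides(
    specs: Sequence[ElementSpec],
    scenarios: Sequence[ExposureScenario],
    path: str | Path,
) -> tuple[list[ElementSpec], list[ExposureScenario]]:
    """Override default parameters from a JSON or YAML file.

    Layout::

        elements:
          Pb: {rfd: 0.004, csfo: 0.009, detection_limit: 0.02}
        scenarios:
          adult: {dfc: 20.0, bw: 62.0}
    """
    text = Path(path).read_text()
    data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    data = data or {}
    el_over = data.get("elements", {})
    sc_over = data.get("scenarios", {})
    new_specs = []
    for spec in specs:
        over = el_over.get(spec.symbol, {})
        new_specs.append(
            ElementSpec(
                symbol=spec.symbol,
                rfd=over.get("rfd", spec.rfd),
                csfo=over.get("csfo", spec.csfo),
                detection_limit=over.get("detection_limit", spec.detection_limit),
                mac=over.get("mac", spec.mac),
            )
        )
    new_scenarios = []
    for sc in scenarios:
        over = sc_over.get(sc.label, {})
        new_scenarios.append(
            ExposureScenario(
                label=sc.label,
                dfc=over.get("dfc", sc.dfc),
                bw=over.get("bw", sc.bw),
                ed=over.get("ed", sc.ed),
                efr=over.get("efr", sc.efr),
                at=over.get("at", None),
            )
        )
    return new_specs, new_scenarios
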