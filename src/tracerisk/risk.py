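"""Deterministic dietary exposure and risk indices.

For a mean tissue concentration MC (mg/kg fresh weight), daily food
consumption DFC = FIR (g/person/day) and body weight BW (kg):

    EDI  = DFC * MC / BW                          [ug/kg BW/day]
    THQ  = (EFr*ED*FIR*MC) / (RfD*BW*AT) * 1e-3   [-]
    TTHQ = sum_elements THQ                       [-]  (one food item)
    HI   = sum_items TTHQ                         [-]
    TCR  = (EFr*ED*FIR*MC*CSFo) / (BW*AT) * 1e-3  [-]  (lifetime risk)

With the default averaging time AT = EFr*ED the quotients collapse to
THQ = EDI*1e-3/RfD and TCR = EDI*1e-3*CSFo (EDI in ug converted to mg).
THQ >= 1 flags a possible non-carcinogenic concern; lifetime cancer risk
is classed negligible below 1e-6, acceptable up to 1e-4, unacceptable
above.

The module also provides the vectorised market-table pipeline
(:func:`assess`) and the regulatory maximum-allowable-concentration
screen (:func:`check_compliance`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .core import (
    AGENCIES,
    AggregateRisk,
    ComplianceFinding,
    ConcentrationRecord,
    ConcentrationSummary,
    ElementSpec,
    ExposureScenario,
    RiskResult,
    ValidationError,
    element_table,
)

__all__ = [
    "edi",
    "thq",
    "tthq",
    "hazard_index",
    "tcr",
    "aggregate_tcr",
    "classify_tcr",
    "check_compliance",
    "compliance_screen",
    "assess",
    "AssessmentResult",
    "THQ_HAZARD_THRESHOLD",
    "TCR_NEGLIGIBLE",
    "TCR_UNACCEPTABLE",
]

THQ_HAZARD_THRESHOLD = 1.0
TCR_NEGLIGIBLE = 1e-6
TCR_UNACCEPTABLE = 1e-4


def edi(mc: float, scenario: ExposureScenario) -> float:
    """Estimated daily intake, ug/kg BW/day.

    ``mc`` in mg/kg FW; g/day times mg/kg yields ug/day, hence the
    ug-scale result without any explicit factor.
    """
    if mc < 0:
        raise ValidationError(f"concentration must be >= 0, got {mc}")
    return scenario.dfc * mc / scenario.bw


def thq(mc: float, scenario: ExposureScenario, spec: ElementSpec) -> float:
    """Target hazard quotient (dimensionless)."""
    if mc < 0:
        raise ValidationError(f"concentration must be >= 0, got {mc}")
    if spec.rfd <= 0:
        raise ValidationError(f"{spec.symbol}: RfD must be positive")
    num = scenario.efr * scenario.ed * scenario.dfc * mc
    den = spec.rfd * scenario.bw * scenario.at
    return num / den * 1e-3


def tthq(thqs: Iterable[float]) -> float:
    """Total THQ for one food item: plain sum over elements (BDL -> 0)."""
    return float(sum(thqs))


def hazard_index(tthqs: Iterable[float]) -> tuple[float, bool]:
    """Hazard index over food items and whether it crosses 1."""
    hi = float(sum(tthqs))
    return hi, hi > 1.0


def tcr(mc: float, scenario: ExposureScenario, spec: ElementSpec) -> float | None:
    """Target carcinogenic (lifetime) risk, or None when no slope factor.

    Elements without an oral cancer slope factor (Fe, Zn) get a
    not-applicable result — ``None`` — rather than a misleading zero.
    """
    if mc < 0:
        raise ValidationError(f"concentration must be >= 0, got {mc}")
    if spec.csfo is None:
        return None
    num = scenario.efr * scenario.ed * scenario.dfc * mc * spec.csfo
    den = scenario.bw * scenario.at
    return num / den * 1e-3


def aggregate_tcr(values: Sequence[float], mode: Literal["sum", "mean"] = "sum") -> float:
    """Aggregate per-market lifetime risks for one element.

    ``sum`` adds the per-market risks (the reproduction default);
    ``mean`` divides by the number of markets.  Censored markets should
    be passed as 0.
    """
    if len(values) == 0:
        raise ValidationError("cannot aggregate an empty TCR list")
    total = float(sum(values))
    if mode == "sum":
        return total
    if mode == "mean":
        return total / len(values)
    raise ValidationError(f"unknown aggregation mode {mode!r}")


def classify_tcr(value: float) -> str:
    """Band a lifetime risk: [0,1e-6) negligible, [1e-6,1e-4] acceptable,
    (1e-4, inf) unacceptable."""
    if value < 0:
        raise ValidationError(f"TCR must be >= 0, got {value}")
    if value < TCR_NEGLIGIBLE:
        return "negligible"
    if value > TCR_UNACCEPTABLE:
        return "unacceptable"
    return "acceptable"


# --------------------------------------------------------------------------
# vectorised pipeline over a market concentration table
# --------------------------------------------------------------------------


@dataclass
class AssessmentResult:
    """Everything :func:`assess` computes for one body part.

    ``cells``: per (scenario, market, element) indices; ``market_totals``:
    TTHQ per (scenario, market); ``element_means``: across-market mean
    indices per (scenario, element) with censored markets as 0;
    ``totals``: per scenario the HI over markets-as-items, aggregated TCR
    per element and its band.
    """

    cells: list[RiskResult]
    market_totals: list[AggregateRisk]
    element_means: list[RiskResult]
    totals: list[AggregateRisk]


def assess(
    records: Iterable[ConcentrationRecord],
    specs: Sequence[ElementSpec],
    scenarios: Sequence[ExposureScenario],
    body_part: str = "muscle",
    tcr_aggregation: Literal["sum", "mean"] = "sum",
) -> AssessmentResult:
    """Run EDI/THQ/TCR over every market x element cell of one body part.

    Censored (BDL) cells contribute 0 to sums and to across-market means
    (with the full market count in the denominator) and are flagged on
    their per-cell rows.
    """
    table = element_table(specs)
    recs = [r for r in records if r.body_part == body_part]
    if not recs:
        raise ValidationError(f"no records for body part {body_part!r}")
    markets = list(dict.fromkeys(r.market for r in recs))
    by_cell: dict[tuple[str, str], ConcentrationRecord] = {}
    for r in recs:
        key = (r.market, r.element)
        if key in by_cell:
            raise ValidationError(
                f"duplicate cell {key}: assess expects one record per market x element "
                "(aggregate chicken-level data with summarize first)"
            )
        by_cell[key] = r
    elements = list(dict.fromkeys(r.element for r in recs))

    cells: list[RiskResult] = []
    market_totals: list[AggregateRisk] = []
    element_means: list[RiskResult] = []
    totals: list[AggregateRisk] = []

    for sc in scenarios:
        per_market_tthq: dict[str, float] = {}
        per_element_tcrs: dict[str, list[float]] = {el: [] for el in elements}
        for market in markets:
            market_thqs: list[float] = []
            for el in elements:
                rec = by_cell.get((market, el))
                if rec is None:
                    continue
                spec = table[el]
                mc = 0.0 if rec.bdl else rec.mean_conc
                cell_edi = edi(mc, sc)
                cell_thq = thq(mc, sc, spec)
                cell_tcr = tcr(mc, sc, spec)
                cells.append(
                    RiskResult(
                        scenario=sc.label,
                        element=el,
                        market=market,
                        edi=cell_edi,
                        thq=cell_thq,
                        tcr=cell_tcr,
                        bdl=rec.bdl,
                    )
                )
                market_thqs.append(cell_thq)
                if cell_tcr is not None:
                    per_element_tcrs[el].append(cell_tcr)
            per_market_tthq[market] = tthq(market_thqs)
            market_totals.append(
                AggregateRisk(scenario=sc.label, market=market, tthq=per_market_tthq[market])
            )
        for el in elements:
            spec = table[el]
            mcs = [
                0.0 if by_cell[(m, el)].bdl else by_cell[(m, el)].mean_conc
                for m in markets
                if (m, el) in by_cell
            ]
            mean_mc = float(np.mean(mcs)) if mcs else 0.0
            element_means.append(
                RiskResult(
                    scenario=sc.label,
                    element=el,
                    market=None,
                    edi=edi(mean_mc, sc),
                    thq=thq(mean_mc, sc, spec),
                    tcr=tcr(mean_mc, sc, spec),
                )
            )
        hi, _ = hazard_index(per_market_tthq.values())
        tcr_total = {
            el: aggregate_tcr(vals, mode=tcr_aggregation)
            for el, vals in per_element_tcrs.items()
            if vals
        }
        totals.append(
            AggregateRisk(
                scenario=sc.label,
                market=None,
                tthq=None,
                hi=hi,
                tcr_total=tcr_total,
                tcr_class={el: classify_tcr(v) for el, v in tcr_total.items()},
            )
        )
    return AssessmentResult(
        cells=cells,
        market_totals=market_totals,
        element_means=element_means,
        totals=totals,
    )


# --------------------------------------------------------------------------
# regulatory screening
# --------------------------------------------------------------------------


def check_compliance(
    measurement: ConcentrationRecord | ConcentrationSummary,
    specs: Sequence[ElementSpec],
    agencies: Sequence[str] | None = None,
) -> list[ComplianceFinding]:
    """Screen one measurement against every applicable agency limit.

    Exceedance uses strict inequality (a value exactly at the limit is
    compliant).  Agencies with no limit for the element/tissue class
    yield a finding with ``limit=None`` ("no limit defined") so absence
    of regulation is visible, not silent.
    """
    table = element_table(specs)
    if isinstance(measurement, ConcentrationRecord):
        element, part = measurement.element, measurement.body_part
        measured = 0.0 if measurement.bdl else measurement.mean_conc
    else:
        element, part = measurement.element, measurement.body_part
        measured = measurement.overall_mean
    spec = table[element]
    findings = []
    for agency in agencies or AGENCIES:
        cls, limit = spec.mac_limit(agency, part)
        if limit is None:
            findings.append(
                ComplianceFinding(
                    element=element,
                    body_part=part,
                    agency=agency,
                    tissue_class=cls,
                    limit=None,
                    measured=measured,
                    exceeds=False,
                    ratio=None,
                )
            )
        else:
            findings.append(
                ComplianceFinding(
                    element=element,
                    body_part=part,
                    agency=agency,
                    tissue_class=cls,
                    limit=limit,
                    measured=measured,
                    exceeds=measured > limit,
                    ratio=measured / limit,
                )
            )
    return findings


def compliance_screen(
    measurements: Iterable[ConcentrationRecord | ConcentrationSummary],
    specs: Sequence[ElementSpec],
    agencies: Sequence[str] | None = None,
) -> list[ComplianceFinding]:
    """:func:`check_compliance` over many measurements, concatenated."""
    out: list[ComplianceFinding] = []
    for m in measurements:
        out.extend(check_compliance(m, specs, agencies))
    return out
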