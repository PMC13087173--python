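"""Human-health risk layer.

Risk quotients (RQ = C/ML), the cumulative risk index (RI = sum of RQs over
detected elements), exceedance percentages over regulatory limits,
estimated daily intake (EDI = C * IR / BW) across consumption-scenario x
consumer-profile grids, and reference-dose screening.

Note the EDI orientation: ingestion rate is supplied in g/day and converted
to kg/day internally, so EDI carries mg per kg body weight per day.  Liver
results are computed like any other tissue but flagged as non-edible
context in reports, since liver is not typically consumed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

from .data_model import (
    Authority,
    ConsumerProfile,
    ExposureScenario,
    ReferenceDose,
    ReferenceTables,
    RfdStatus,
    Tissue,
    TissueConcentration,
)
from .exceptions import ValidationError

__all__ = [
    "RiskBand",
    "RiskResult",
    "CumulativeRisk",
    "IntakeResult",
    "ExceedanceResult",
    "AssessmentReport",
    "rq",
    "ri",
    "exceedance_pct",
    "edi",
    "screen_rfd",
    "assess",
]

# Report rounding policy (internal computation is full precision).
RQ_DECIMALS = 2
EDI_ADULT_DECIMALS = 4
EDI_CHILD_DECIMALS = 3

RI_LOW_MAX = 150.0
RI_MODERATE_MAX = 300.0


class RiskBand(str, enum.Enum):
    LOW = "low"
    MODERATE = "moderate"
    ABOVE_MODERATE = "above_moderate"


@dataclass(frozen=True)
class RiskResult:
    element: str
    tissue: Tissue
    site: str
    rq: float
    ml_used: float
    authority: str
    non_edible: bool = False


@dataclass(frozen=True)
class CumulativeRisk:
    tissue: Tissue
    site: str
    ri: float
    components: tuple[RiskResult, ...]
    band: RiskBand
    non_edible: bool = False


@dataclass(frozen=True)
class IntakeResult:
    element: str
    scenario: str
    profile: str
    edi: float
    site: str = ""
    species: str = ""
    rfd: Optional[float] = None
    rfd_status: Optional[RfdStatus] = None
    hazard_ratio: Optional[float] = None
    exceeds_rfd: Optional[bool] = None


@dataclass(frozen=True)
class ExceedanceResult:
    element: str
    tissue: Tissue
    site: str
    authority: str
    ml: float
    excess_pct: float  # 100*(C-ML)/ML, canonical convention
    ratio_pct: float  # 100*C/ML, ratio convention


def rq(
    c: float,
    ml: float,
    *,
    element: str = "",
    tissue: Tissue | str = Tissue.MUSCLE,
    site: str = "",
    authority: str = "",
) -> RiskResult:
    """Risk quotient C/ML; RQ >= 1 flags potential adverse effects."""
    if ml <= 0:
        raise ValidationError(f"maximum limit must be strictly positive, got {ml}")
    if c < 0:
        raise ValidationError(f"concentration must be >= 0, got {c}")
    tissue = Tissue.parse(tissue)
    return RiskResult(
        element=element,
        tissue=tissue,
        site=site,
        rq=c / ml,
        ml_used=ml,
        authority=authority,
        non_edible=(tissue is Tissue.LIVER),
    )


def _band(total: float) -> RiskBand:
    if total < RI_LOW_MAX:
        return RiskBand.LOW
    if total <= RI_MODERATE_MAX:
        return RiskBand.MODERATE
    return RiskBand.ABOVE_MODERATE


def ri(components: Iterable[RiskResult | float]) -> CumulativeRisk:
    """Cumulative risk index: sum of component RQs (detected elements only).

    Accepts either :class:`RiskResult` objects or bare RQ values (the latter
    are wrapped).  Empty input yields RI = 0, band 'low'.
    """
    wrapped: list[RiskResult] = []
    for comp in components:
        if isinstance(comp, RiskResult):
            wrapped.append(comp)
        else:
            wrapped.append(rq(float(comp), 1.0))
    tissues = {c.tissue for c in wrapped}
    sites = {c.site for c in wrapped}
    tissue = tissues.pop() if len(tissues) == 1 else Tissue.MUSCLE
    site = sites.pop() if len(sites) == 1 else ""
    total = sum(c.rq for c in wrapped)
    return CumulativeRisk(
        tissue=tissue,
        site=site,
        ri=total,
        components=tuple(wrapped),
        band=_band(total),
        non_edible=(tissue is Tissue.LIVER),
    )


def exceedance_pct(c: float, ml: float) -> float:
    """Percent excess over the limit: 100*(C-ML)/ML; negative when C < ML.

    Related to the risk quotient by exceedance = 100*(RQ - 1) exactly.
    """
    if ml <= 0:
        raise ValidationError(f"maximum limit must be strictly positive, got {ml}")
    return 100.0 * (c - ml) / ml


def edi(
    c: float,
    scenario: ExposureScenario,
    profile: ConsumerProfile,
    *,
    element: str = "",
    site: str = "",
    species: str = "",
) -> IntakeResult:
    """Estimated daily intake, mg per kg body weight per day.

    EDI = C (mg/kg) * ingestion rate (g/day -> kg/day) / body weight (kg).
    The g/day -> kg/day conversion happens here, never at input time.
    """
    if c < 0:
        raise ValidationError(f"concentration must be >= 0, got {c}")
    if profile.body_weight <= 0:
        raise ValidationError("body weight must be strictly positive")
    value = c * (scenario.ingestion_rate / 1000.0) / profile.body_weight
    return IntakeResult(
        element=element,
        scenario=scenario.name,
        profile=profile.label,
        edi=value,
        site=site,
        species=species,
    )


def screen_rfd(r: IntakeResult, rfd_table: Sequence[ReferenceDose] | ReferenceTables) -> IntakeResult:
    """Complete an intake result with RfD, hazard ratio, and exceedance flag.

    hazard_ratio = EDI/RfD; exceeds only when strictly greater than 1.
    All three fields stay absent when no RfD is configured for the element.
    Revoked RfDs are used but keep their status for downstream warnings.
    """
    if isinstance(rfd_table, ReferenceTables):
        ref = rfd_table.rfd_for(r.element) if r.element else None
    else:
        ref = next((d for d in rfd_table if d.element == r.element), None)
    if ref is None:
        return r
    ratio = r.edi / ref.rfd
    return replace(
        r,
        rfd=ref.rfd,
        rfd_status=ref.status,
        hazard_ratio=ratio,
        exceeds_rfd=ratio > 1.0,
    )


@dataclass(frozen=True)
class AssessmentReport:
    """Full risk report: per-element RQs, per-group RIs, EDI grid, exceedances."""

    risk_results: tuple[RiskResult, ...]
    cumulative: tuple[CumulativeRisk, ...]
    intakes: tuple[IntakeResult, ...]
    exceedances: tuple[ExceedanceResult, ...]
    warnings: tuple[str, ...] = ()


def assess(
    rows: Sequence[TissueConcentration],
    tables: ReferenceTables,
    *,
    authority: Optional[Authority | str] = None,
    strictest: bool = False,
    elements: Optional[Iterable[str]] = None,
) -> AssessmentReport:
    """Run the full risk layer over a validated tissue-summary table.

    For every detected element with a configured ML: an RQ under the
    selected authority policy and exceedance percentages under every
    configured authority.  RIs per tissue x site sum the detected RQs.
    EDIs cover every detected muscle element over the scenario x profile
    grid, screened against RfDs.  Row order is deterministic:
    (element, tissue, site, scenario, profile) lexicographic.
    ``elements`` optionally restricts the whole report to a subset.
    """
    detected = [r for r in rows if r.detected and r.mean is not None]
    if elements is not None:
        wanted = {e for e in elements}
        detected = [r for r in detected if r.element in wanted]
    key = lambda r: (r.element, r.tissue.value, r.site)  # noqa: E731
    detected = sorted(detected, key=key)

    warnings: list[str] = []
    risk_results: list[RiskResult] = []
    exceedances: list[ExceedanceResult] = []
    for row in detected:
        lim = tables.ml_for(row.element, authority=authority, strictest=strictest)
        if lim is not None:
            risk_results.append(
                rq(
                    row.mean,
                    lim.ml,
                    element=row.element,
                    tissue=row.tissue,
                    site=row.site,
                    authority=lim.authority.value,
                )
            )
        for each in tables.limits_for(row.element):
            exceedances.append(
                ExceedanceResult(
                    element=row.element,
                    tissue=row.tissue,
                    site=row.site,
                    authority=each.authority.value,
                    ml=each.ml,
                    excess_pct=exceedance_pct(row.mean, each.ml),
                    ratio_pct=100.0 * row.mean / each.ml,
                )
            )

    cumulative: list[CumulativeRisk] = []
    groups = sorted({(r.tissue.value, r.site) for r in risk_results})
    for tissue_value, site in groups:
        comps = [r for r in risk_results if r.tissue.value == tissue_value and r.site == site]
        cum = ri(comps)
        cumulative.append(cum)
        if cum.non_edible:
            warnings.append(
                f"RI for {site}/{tissue_value} is a non-edible-tissue context"
            )

    intakes: list[IntakeResult] = []
    muscle_rows = [r for r in detected if r.tissue is Tissue.MUSCLE]
    for row in muscle_rows:
        for scenario in sorted(tables.scenarios, key=lambda s: s.name):
            for profile in sorted(tables.profiles, key=lambda p: p.label):
                result = edi(
                    row.mean,
                    scenario,
                    profile,
                    element=row.element,
                    site=row.site,
                    species=row.species,
                )
                result = screen_rfd(result, tables)
                if result.rfd_status is RfdStatus.REVOKED:
                    warnings.append(
                        f"RfD for {result.element} is revoked but still applied"
                    )
                intakes.append(result)
    intakes.sort(key=lambda r: (r.element, r.site, r.scenario, r.profile))

    return AssessmentReport(
        risk_results=tuple(risk_results),
        cumulative=tuple(cumulative),
        intakes=tuple(intakes),
        exceedances=tuple(exceedances),
        warnings=tuple(dict.fromkeys(warnings)),
    )
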