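"""Annual direct medical cost accrual per patient.

Components: drug acquisition (daily cost x horizon x the stratum's
medication possession ratio), stable-time outpatient care (a monthly
resource basket, prorated over stable days and scaled by a calibrated
``stable_care_scale``), relapse-event resource baskets, and adverse-event
resource baskets.  All quantities come from the resource-use matrix and all
prices from the unit-cost table; costs are linear in both.

The stable-care scale exists because the monthly stable basket priced at the
published unit costs exceeds the published annual totals by a wide margin;
the scale is a declared reconciliation device fitted against the published
olanzapine SOT total (see :func:`calibrate_stable_care_scale`), not an
inference about how those totals were derived.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Tuple

from .parameters import (
    AE_TYPES,
    CATEGORIES,
    EngineConfig,
    ModelParameters,
    ResourceUseMatrix,
    StrategyParams,
    UnitCostTable,
)
from .outcome_engine import annual_outcomes, occupancy

__all__ = [
    "CostBreakdown",
    "DAYS_PER_MONTH",
    "drug_cost",
    "event_cost",
    "ae_event_cost",
    "stable_care_cost",
    "expected_cost",
    "calibrate_stable_care_scale",
]

#: Month length used to convert stable days into months: 365 / 12.
DAYS_PER_MONTH = 365.0 / 12.0

#: Resource-use column charged per adverse-event occurrence.
_AE_COLUMNS = {"eps": "eps_per_event", "weight_gain": "weight_gain_per_event"}

#: The diabetes event has no usage column of its own; it consumes one unit
#: of ongoing medication (the "any other: medication" cost line).
DIABETES_RESOURCE = "other_medication"


@dataclass
class CostBreakdown:
    """Expected annual cost (MAD) split by component."""

    drug: float
    stable_care: float
    outpt_relapse: float
    hosp_relapse: float
    adverse_events: float

    @property
    def total(self) -> float:
        return (self.drug + self.stable_care + self.outpt_relapse
                + self.hosp_relapse + self.adverse_events)

    def as_dict(self) -> Dict[str, float]:
        return {
            "drug": self.drug,
            "stable_care": self.stable_care,
            "outpt_relapse": self.outpt_relapse,
            "hosp_relapse": self.hosp_relapse,
            "adverse_events": self.adverse_events,
            "total": self.total,
        }


def drug_cost(s: StrategyParams, category: str, cfg: EngineConfig) -> float:
    """Annual drug acquisition cost for one adherence stratum (MPR-prorated)."""
    mpr = s.adherence.mpr_by_category[category]
    return s.daily_drug_cost * cfg.horizon_days * mpr


def event_cost(column: str, ru: ResourceUseMatrix, uc: UnitCostTable) -> float:
    """Cost of one event (or one stable month) of the given usage column."""
    total = 0.0
    for res, q in ru.column(column).items():
        if q == 0.0:
            continue
        if res not in uc.cost_per_unit:
            raise KeyError(f"resource {res!r} has no unit cost")
        total += q * uc.cost_per_unit[res]
    return total


def ae_event_cost(ae: str, ru: ResourceUseMatrix, uc: UnitCostTable) -> float:
    """Cost of one occurrence of an adverse event."""
    if ae in _AE_COLUMNS:
        return event_cost(_AE_COLUMNS[ae], ru, uc)
    if ae == "diabetes":
        return uc.cost_per_unit.get(DIABETES_RESOURCE, 0.0)
    raise KeyError(f"unknown adverse event {ae!r}")


def stable_care_cost(stable_days: float, ru: ResourceUseMatrix,
                     uc: UnitCostTable, scale: float) -> float:
    """Outpatient maintenance cost over ``stable_days`` of stable time."""
    if stable_days < 0:
        raise ValueError("stable_days must be >= 0")
    monthly = event_cost("stable_per_month", ru, uc)
    return (stable_days / DAYS_PER_MONTH) * monthly * scale


def cost_by_cell(s: StrategyParams,
                 params: ModelParameters) -> Dict[Tuple[str, str], float]:
    """Non-AE cost per (adherence category, outcome) cell.

    Includes drug, stable care over the cell's occupancy, and the relapse
    event if any; adverse events are added separately (independent of the
    outcome).
    """
    cfg = params.config
    ru, uc = params.resource_use, params.unit_costs
    out: Dict[Tuple[str, str], float] = {}
    ev = {"stable": 0.0,
          "outpt": event_cost("outpt_relapse_per_event", ru, uc),
          "hosp": event_cost("hosp_relapse_per_event", ru, uc)}
    for cat in CATEGORIES:
        d = drug_cost(s, cat, cfg)
        for outcome in ("stable", "outpt", "hosp"):
            occ = occupancy(outcome, cfg)
            out[(cat, outcome)] = (
                d
                + stable_care_cost(occ.stable_days, ru, uc, cfg.stable_care_scale)
                + ev[outcome]
            )
    return out


def expected_cost(s: StrategyParams, params: ModelParameters) -> CostBreakdown:
    """Probability-weighted annual cost breakdown for a treatment arm."""
    cfg = params.config
    ru, uc = params.resource_use, params.unit_costs
    dist = annual_outcomes(s, cfg)
    shares = s.adherence.shares

    c_drug = sum(shares[cat] * drug_cost(s, cat, cfg) for cat in CATEGORIES)

    ev_outpt = event_cost("outpt_relapse_per_event", ru, uc)
    ev_hosp = event_cost("hosp_relapse_per_event", ru, uc)
    c_outpt = c_hosp = c_stable = 0.0
    for cat in CATEGORIES:
        p_stable, p_outpt, p_hosp = dist.per_stratum[cat]
        c_outpt += shares[cat] * p_outpt * ev_outpt
        c_hosp += shares[cat] * p_hosp * ev_hosp
        for outcome, p in (("stable", p_stable), ("outpt", p_outpt),
                           ("hosp", p_hosp)):
            occ = occupancy(outcome, cfg)
            c_stable += shares[cat] * p * stable_care_cost(
                occ.stable_days, ru, uc, cfg.stable_care_scale)

    c_ae = sum(s.ae_probs.get(ae, 0.0) * ae_event_cost(ae, ru, uc)
               for ae in AE_TYPES)

    return CostBreakdown(drug=c_drug, stable_care=c_stable,
                         outpt_relapse=c_outpt, hosp_relapse=c_hosp,
                         adverse_events=c_ae)


def calibrate_stable_care_scale(
    params: ModelParameters,
    target_total: float,
    strategy: str = "olanzapine_sot",
) -> Tuple[float, float]:
    """Fit the stable-care scale to a published annual total.

    The total cost is affine in the scale, so the fit is solved in closed
    form and clamped to the non-negative range.  Returns ``(scale,
    residual)`` where ``residual = modelled total at the fitted scale -
    target``; a non-zero residual means the target is unreachable with a
    valid (non-negative) scale and must be reported, not hidden.
    """
    s = params.strategy(strategy)
    base = params.copy()
    base.config.stable_care_scale = 0.0
    floor = expected_cost(base.strategy(strategy), base).total
    base.config.stable_care_scale = 1.0
    at_one = expected_cost(base.strategy(strategy), base).total
    slope = at_one - floor
    if slope <= 0:
        scale = 0.0
    else:
        scale = max(0.0, (target_total - floor) / slope)
    base.config.stable_care_scale = scale
    fitted_total = expected_cost(base.strategy(strategy), base).total
    return scale, fitted_total - target_total
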