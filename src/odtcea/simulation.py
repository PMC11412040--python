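"""Cohort evaluation: exact expected values and patient-level Monte Carlo.

``evaluate_expected`` composes the outcome engine and the costing module
into the exact probability-weighted cohort result; it is deterministic and
serves as the oracle.  ``simulate_microcohort`` draws individual patients
(adherence stratum, annual outcome, three adverse-event Bernoullis — a
fixed five variates per patient, so results do not depend on iteration
order) and reproduces the expected values up to Monte Carlo error; it
mirrors the published 1,000,000-patient simulation design.

Formulation groups (ODT + SOT) are aggregated by *summing* member costs and
QALYs — the published group totals are arithmetic sums of the two arm
totals — while outcome proportions are unweighted means over members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .parameters import AE_TYPES, CATEGORIES, ModelParameters, StrategyParams
from .outcome_engine import annual_outcomes, expected_qaly, qaly_by_cell
from .costing import ae_event_cost, cost_by_cell, expected_cost

__all__ = [
    "CohortResult",
    "evaluate_expected",
    "simulate_microcohort",
    "aggregate_group",
    "evaluate_name",
    "evaluate_all",
]


@dataclass
class CohortResult:
    """Per-strategy (or per-group) cohort summary."""

    strategy: str
    mean_cost: float
    mean_qaly: float
    p_stable: float
    p_outpt: float
    p_hosp: float
    ae_incidence: Dict[str, float] = field(default_factory=dict)
    se_cost: float = 0.0
    se_qaly: float = 0.0
    n: int = 0
    seed: Optional[int] = None


def evaluate_expected(s: StrategyParams, params: ModelParameters) -> CohortResult:
    """Exact expected-value evaluation of one treatment arm."""
    dist = annual_outcomes(s, params.config)
    cost = expected_cost(s, params)
    qaly = expected_qaly(s, params.utilities, params.config)
    return CohortResult(
        strategy=s.name,
        mean_cost=cost.total,
        mean_qaly=qaly,
        p_stable=dist.p_stable,
        p_outpt=dist.p_outpt,
        p_hosp=dist.p_hosp,
        ae_incidence=dict(s.ae_probs),
    )


def simulate_microcohort(s: StrategyParams, params: ModelParameters,
                         n: int, seed: int) -> CohortResult:
    """Patient-level Monte Carlo evaluation of one treatment arm.

    Reproducible given ``seed``; agrees with :func:`evaluate_expected`
    within Monte Carlo error.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dist = annual_outcomes(s, params.config)
    shares = s.adherence.shares

    u_cat = rng.random(n)
    u_out = rng.random(n)
    u_ae = {ae: rng.random(n) for ae in AE_TYPES}

    # stratum assignment from one uniform against the cumulative shares
    edges = np.cumsum([shares[c] for c in CATEGORIES])
    cat_idx = np.searchsorted(edges, u_cat, side="right")
    cat_idx = np.clip(cat_idx, 0, len(CATEGORIES) - 1)

    # outcome from one uniform against [0, p_hosp), [p_hosp, p_hosp + p_outpt)
    p_hosp_arr = np.array([dist.per_stratum[c][2] for c in CATEGORIES])
    p_outpt_arr = np.array([dist.per_stratum[c][1] for c in CATEGORIES])
    ph = p_hosp_arr[cat_idx]
    po = p_outpt_arr[cat_idx]
    outcome_idx = np.where(u_out < ph, 2, np.where(u_out < ph + po, 1, 0))
    # 0 = stable, 1 = outpt, 2 = hosp

    cells_cost = cost_by_cell(s, params)
    cells_qaly = qaly_by_cell(s, params.utilities, params.config)
    outcome_names = ("stable", "outpt", "hosp")
    cost_lut = np.array([[cells_cost[(c, o)] for o in outcome_names]
                         for c in CATEGORIES])
    qaly_lut = np.array([[cells_qaly[(c, o)] for o in outcome_names]
                         for c in CATEGORIES])

    cost = cost_lut[cat_idx, outcome_idx].astype(float)
    qaly = qaly_lut[cat_idx, outcome_idx].astype(float)

    ae_incidence: Dict[str, float] = {}
    for ae in AE_TYPES:
        hit = u_ae[ae] < s.ae_probs.get(ae, 0.0)
        cost = cost + hit * ae_event_cost(ae, params.resource_use,
                                          params.unit_costs)
        ae_incidence[ae] = float(hit.mean())

    ddof = 1 if n > 1 else 0
    return CohortResult(
        strategy=s.name,
        mean_cost=float(cost.mean()),
        mean_qaly=float(qaly.mean()),
        p_stable=float((outcome_idx == 0).mean()),
        p_outpt=float((outcome_idx == 1).mean()),
        p_hosp=float((outcome_idx == 2).mean()),
        ae_incidence=ae_incidence,
        se_cost=float(cost.std(ddof=ddof) / np.sqrt(n)),
        se_qaly=float(qaly.std(ddof=ddof) / np.sqrt(n)),
        n=n,
        seed=seed,
    )


def aggregate_group(members: Sequence[CohortResult],
                    name: Optional[str] = None) -> CohortResult:
    """Aggregate formulation arms into a group result.

    Costs and QALYs are summed over member arms (matching the published
    group totals, which double the per-patient scale); outcome proportions
    and adverse-event incidences are unweighted means.
    """
    members = list(members)
    if not members:
        raise ValueError("aggregate_group needs at least one member")
    k = len(members)
    ae: Dict[str, float] = {}
    for m in members:
        for a, v in m.ae_incidence.items():
            ae[a] = ae.get(a, 0.0) + v / k
    return CohortResult(
        strategy=name or "+".join(m.strategy for m in members),
        mean_cost=sum(m.mean_cost for m in members),
        mean_qaly=sum(m.mean_qaly for m in members),
        p_stable=sum(m.p_stable for m in members) / k,
        p_outpt=sum(m.p_outpt for m in members) / k,
        p_hosp=sum(m.p_hosp for m in members) / k,
        ae_incidence=ae,
        se_cost=float(np.sqrt(sum(m.se_cost ** 2 for m in members))),
        se_qaly=float(np.sqrt(sum(m.se_qaly ** 2 for m in members))),
        n=sum(m.n for m in members),
        seed=members[0].seed,
    )


def evaluate_name(name: str, params: ModelParameters) -> CohortResult:
    """Expected-value result for an arm name or a group name."""
    if name in params.group_definitions:
        members = [evaluate_expected(params.strategy(m), params)
                   for m in params.group_definitions[name]]
        return aggregate_group(members, name=name)
    return evaluate_expected(params.strategy(name), params)


def evaluate_all(params: ModelParameters,
                 include_groups: bool = True) -> List[CohortResult]:
    """Expected-value results for every arm (and optionally every group)."""
    out = [evaluate_expected(s, params) for s in params.strategies]
    if include_groups:
        for g in params.group_definitions:
            out.append(evaluate_name(g, params))
    return out
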