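"""Synthetic parameter sets with known ground truth.

Every pipeline stage can be exercised without the Moroccan reference
fixtures: the generator emits random, structurally valid parameter sets
whose dominance relations are known *by construction* (parameter orderings
imply cost/QALY orderings through the monotone engine), so the frontier and
ICER machinery can be verified end to end.  It also provides multiplicative
perturbations of the reference set for robustness tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np

from .parameters import (
    AE_TYPES,
    CATEGORIES,
    STATES,
    USAGE_COLUMNS,
    AdherenceDistribution,
    EngineConfig,
    ModelParameters,
    ResourceUseMatrix,
    StrategyParams,
    UnitCostTable,
    UtilityTable,
    morocco_2022_parameters,
    validate_parameters,
)

__all__ = ["SyntheticSpec", "GroundTruth", "generate_parameter_set",
           "perturb_reference_set"]


@dataclass
class SyntheticSpec:
    """Recipe for a synthetic parameter set.

    ``dominance_plan``:
      * ``one_dominant`` — strategy 0 has strictly lower relapse risk and a
        strictly cheaper drug than every other arm (shared adherence,
        utilities and adverse events), so it strictly dominates all others.
      * ``all_equal`` — all arms identical; every pairwise comparison is an
        equal-effect tie.
      * ``frontier_chain`` — arms ordered with strictly increasing cost and
        QALY (no strict dominance anywhere).
    ``effect_scale`` controls the separation between adjacent arms.
    """

    n_strategies: int = 4
    seed: int = 0
    dominance_plan: Optional[str] = "one_dominant"
    effect_scale: float = 0.2

    def __post_init__(self) -> None:
        if self.n_strategies < 2:
            raise ValueError("n_strategies must be >= 2")
        if self.effect_scale < 0:
            raise ValueError("effect_scale must be >= 0")


@dataclass
class GroundTruth:
    plan: Optional[str]
    dominant_strategy: Optional[str] = None
    qaly_order: Optional[List[str]] = None  # ascending


def _random_utilities(rng: np.random.Generator) -> UtilityTable:
    # Ordered both within a stratum (stable >= outpt >= hosp) and across
    # strata (compliant >= partial >= non) so higher adherence and fewer
    # relapses always mean more QALYs.
    grid = np.sort(rng.uniform(0.3, 0.95, size=9))[::-1].reshape(3, 3)
    u: Dict[Tuple[str, str], float] = {}
    for i, cat in enumerate(CATEGORIES):
        for j, state in enumerate(STATES):
            u[(cat, state)] = float(grid[j, i])
    # enforce both orderings explicitly
    for j, state in enumerate(STATES):
        row = sorted((u[(c, state)] for c in CATEGORIES), reverse=True)
        for c, v in zip(CATEGORIES, row):
            u[(c, state)] = v
    for cat in CATEGORIES:
        col = sorted((u[(cat, s)] for s in STATES), reverse=True)
        for s, v in zip(STATES, col):
            u[(cat, s)] = v
    return UtilityTable(u)


def _random_resources(rng: np.random.Generator) -> Tuple[ResourceUseMatrix,
                                                         UnitCostTable]:
    resources = ["hospital_day", "clinic_visit", "home_care_hour",
                 "counselling_hour", "other_medication"]
    quantity: Dict[Tuple[str, str], float] = {}
    cost: Dict[str, float] = {}
    for res in resources:
        cost[res] = float(rng.uniform(100, 2000))
        for col in USAGE_COLUMNS:
            if res == "hospital_day":
                q = rng.uniform(5, 15) if col == "hosp_relapse_per_event" else 0.0
            elif col == "stable_per_month":
                q = rng.uniform(0, 2)
            else:
                q = rng.uniform(0, 3)
            quantity[(res, col)] = float(q)
    return ResourceUseMatrix(quantity), UnitCostTable(cost)


def generate_parameter_set(spec: SyntheticSpec) -> Tuple[ModelParameters,
                                                         GroundTruth]:
    """Generate a random valid parameter set plus its ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_strategies
    utilities = _random_utilities(rng)
    resource_use, unit_costs = _random_resources(rng)
    config = EngineConfig(cycle_exponent_K=float(rng.uniform(1.0, 4.0)),
                          stable_care_scale=0.0, seed=spec.seed)

    shares = rng.dirichlet((4.0, 3.0, 3.0))
    adherence = AdherenceDistribution(*map(float, shares))

    def relapse_triples(level: float) -> Tuple[Dict[str, float], Dict[str, float]]:
        # relapse risk rises with the level and with non-adherence
        base = 0.02 + 0.10 * level
        ph = {c: float(base * (1.0 + 0.5 * i)) for i, c in enumerate(CATEGORIES)}
        po = {c: float(base * (1.0 + 0.4 * i)) for i, c in enumerate(CATEGORIES)}
        return ph, po

    ae = {a: float(rng.uniform(0.01, 0.3)) for a in AE_TYPES}
    sep = spec.effect_scale

    strategies: List[StrategyParams] = []
    plan = spec.dominance_plan
    if plan == "all_equal":
        level = float(rng.uniform(0.2, 0.8))
        drug = float(rng.uniform(5, 20))
        ph, po = relapse_triples(level)
        for i in range(n):
            strategies.append(StrategyParams(
                name=f"s{i}", formulation="SOT", daily_drug_cost=drug,
                adherence=adherence.copy(), p_relapse_hosp=dict(ph),
                p_relapse_outpt=dict(po), ae_probs=dict(ae)))
        truth = GroundTruth(plan=plan)
    elif plan == "frontier_chain":
        # arm i: lower relapse (more QALYs) but much higher drug cost
        for i in range(n):
            level = 0.8 - 0.6 * i / max(1, n - 1) * max(sep, 0.05)
            ph, po = relapse_triples(level)
            drug = 5.0 + 40.0 * i * max(sep, 0.05)
            strategies.append(StrategyParams(
                name=f"s{i}", formulation="SOT", daily_drug_cost=float(drug),
                adherence=adherence.copy(), p_relapse_hosp=ph,
                p_relapse_outpt=po, ae_probs=dict(ae)))
        truth = GroundTruth(plan=plan, qaly_order=[f"s{i}" for i in range(n)])
    elif plan == "one_dominant":
        levels = rng.uniform(0.4, 0.9, size=n)
        levels[0] = float(levels.min() * (1.0 - max(sep, 0.05)))
        drugs = rng.uniform(10, 20, size=n)
        drugs[0] = float(drugs.min() * (1.0 - max(sep, 0.05)))
        for i in range(n):
            ph, po = relapse_triples(float(levels[i]))
            strategies.append(StrategyParams(
                name=f"s{i}", formulation="SOT",
                daily_drug_cost=float(drugs[i]),
                adherence=adherence.copy(), p_relapse_hosp=ph,
                p_relapse_outpt=po, ae_probs=dict(ae)))
        truth = GroundTruth(plan=plan, dominant_strategy="s0")
    else:
        for i in range(n):
            ph, po = relapse_triples(float(rng.uniform(0.2, 0.9)))
            strategies.append(StrategyParams(
                name=f"s{i}", formulation="SOT",
                daily_drug_cost=float(rng.uniform(5, 25)),
                adherence=adherence.copy(), p_relapse_hosp=ph,
                p_relapse_outpt=po,
                ae_probs={a: float(rng.uniform(0.01, 0.3)) for a in AE_TYPES}))
        truth = GroundTruth(plan=None)

    params = ModelParameters(
        strategies=strategies,
        group_definitions={},
        utilities=utilities,
        resource_use=resource_use,
        unit_costs=unit_costs,
        config=config,
    )
    report = validate_parameters(params)
    assert report.ok, f"synthetic set invalid: {report.codes()}"
    return params, truth


def perturb_reference_set(magnitude: float, seed: int,
                          base: Optional[ModelParameters] = None
                          ) -> ModelParameters:
    """Multiplicative noise around the built-in reference set.

    Each probability, utility, cost and quantity is multiplied by a factor
    uniform on [1 - magnitude, 1 + magnitude]; adherence triples are
    renormalized, utilities re-sorted and probabilities clamped so every
    invariant holds.  ``magnitude = 0`` returns the base set unchanged.
    """
    if not (0.0 <= magnitude <= 0.5):
        raise ValueError("magnitude must be in [0, 0.5]")
    params = (base or morocco_2022_parameters()).copy()
    if magnitude == 0.0:
        return params
    rng = np.random.default_rng(seed)

    def jitter(x: float) -> float:
        return x * float(rng.uniform(1.0 - magnitude, 1.0 + magnitude))

    for s in params.strategies:
        a = s.adherence
        raw = np.array([jitter(a.p_compliant), jitter(a.p_partial),
                        jitter(a.p_non)])
        raw /= raw.sum()
        a.p_compliant, a.p_partial, a.p_non = map(float, raw)
        for cat in CATEGORIES:
            s.p_relapse_hosp[cat] = min(0.99, jitter(s.p_relapse_hosp[cat]))
            s.p_relapse_outpt[cat] = min(0.99, jitter(s.p_relapse_outpt[cat]))
            tot = s.p_relapse_hosp[cat] + s.p_relapse_outpt[cat]
            if tot >= 1.0:
                s.p_relapse_hosp[cat] *= 0.99 / tot
                s.p_relapse_outpt[cat] *= 0.99 / tot
        for ae in AE_TYPES:
            s.ae_probs[ae] = min(1.0, jitter(s.ae_probs[ae]))
        s.daily_drug_cost = jitter(s.daily_drug_cost)

    for cat in CATEGORIES:
        drawn = sorted((min(1.0, jitter(params.utilities.value(cat, st)))
                        for st in STATES), reverse=True)
        for st, v in zip(("stable", "relapse_outpt", "relapse_hosp"), drawn):
            params.utilities.u[(cat, st)] = v

    for key, q in list(params.resource_use.quantity.items()):
        res, col = key
        if res == "hospital_day" and col != "hosp_relapse_per_event":
            continue  # keep the structural zeros
        params.resource_use.quantity[key] = jitter(q)
    for res, c in list(params.unit_costs.cost_per_unit.items()):
        params.unit_costs.cost_per_unit[res] = jitter(c)

    report = validate_parameters(params)
    assert report.ok, f"perturbed set invalid: {report.codes()}"
    return params
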