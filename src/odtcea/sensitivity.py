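"""Sensitivity analysis: one-way sweeps (tornado), sequential-bifurcation
parameter screening, and probabilistic sensitivity analysis (PSA).

Parameters are addressed by dotted paths into the model parameter set, e.g.
``utilities.non.stable``, ``strategies.olanzapine_odt.daily_drug_cost``,
``strategies.risperidone_sot.p_relapse_hosp.partial`` or
``unit_costs.hospital_day``.  Setting an adherence share renormalizes the
other two shares proportionally so the triple keeps summing to one;
probabilities and utilities are clamped to [0, 1].

The PSA follows standard health-economics practice: beta distributions for
probabilities and utilities (method of moments, SE = a fraction of the
mean), gamma for costs, and a Dirichlet for the adherence triple preserving
the base means.  The cost-effectiveness acceptability curve (CEAC) reports,
for each willingness-to-pay value, the fraction of iterations in which each
strategy has the highest net monetary benefit (ties split equally).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .parameters import (
    AE_TYPES,
    CATEGORIES,
    STATES,
    ModelParameters,
    validate_parameters,
)
from .simulation import CohortResult, evaluate_name
from .cea import compare, nmb

__all__ = [
    "TornadoEntry",
    "PSAResult",
    "list_parameter_ids",
    "get_param",
    "set_param",
    "owsa",
    "screen_parameters",
    "psa_draw_parameters",
    "run_psa",
    "default_wtp_grid",
]


# ---------------------------------------------------------------------------
# Parameter paths
# ---------------------------------------------------------------------------

def list_parameter_ids(params: ModelParameters,
                       include_adherence: bool = True,
                       include_quantities: bool = False) -> List[str]:
    """Enumerate the scalar parameter paths subject to sensitivity analysis."""
    ids: List[str] = []
    for cat in CATEGORIES:
        for state in STATES:
            ids.append(f"utilities.{cat}.{state}")
    for s in params.strategies:
        if include_adherence:
            for share in ("p_compliant", "p_partial", "p_non"):
                ids.append(f"strategies.{s.name}.adherence.{share}")
        for cat in CATEGORIES:
            ids.append(f"strategies.{s.name}.p_relapse_hosp.{cat}")
            ids.append(f"strategies.{s.name}.p_relapse_outpt.{cat}")
        for ae in AE_TYPES:
            ids.append(f"strategies.{s.name}.ae_probs.{ae}")
        ids.append(f"strategies.{s.name}.daily_drug_cost")
    for res in params.unit_costs.cost_per_unit:
        ids.append(f"unit_costs.{res}")
    if include_quantities:
        for (res, col), q in params.resource_use.quantity.items():
            if q != 0:
                ids.append(f"resource_use.{res}.{col}")
    return ids


def get_param(params: ModelParameters, pid: str) -> float:
    parts = pid.split(".")
    if parts[0] == "utilities":
        return params.utilities.value(parts[1], parts[2])
    if parts[0] == "unit_costs":
        return params.unit_costs.cost_per_unit[parts[1]]
    if parts[0] == "resource_use":
        return params.resource_use.quantity[(parts[1], parts[2])]
    if parts[0] == "strategies":
        s = params.strategy(parts[1])
        if parts[2] == "daily_drug_cost":
            return s.daily_drug_cost
        if parts[2] == "adherence":
            return getattr(s.adherence, parts[3])
        if parts[2] == "p_relapse_hosp":
            return s.p_relapse_hosp[parts[3]]
        if parts[2] == "p_relapse_outpt":
            return s.p_relapse_outpt[parts[3]]
        if parts[2] == "ae_probs":
            return s.ae_probs[parts[3]]
    raise KeyError(f"cannot resolve parameter path {pid!r}")


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


def set_param(params: ModelParameters, pid: str, value: float) -> None:
    """Set a parameter in place, restoring structural invariants.

    Probabilities and utilities are clamped to [0, 1]; adherence shares are
    renormalized (the other two shares absorb the change proportionally).
    """
    parts = pid.split(".")
    if parts[0] == "utilities":
        params.utilities.u[(parts[1], parts[2])] = _clamp01(value)
        return
    if parts[0] == "unit_costs":
        params.unit_costs.cost_per_unit[parts[1]] = max(0.0, value)
        return
    if parts[0] == "resource_use":
        params.resource_use.quantity[(parts[1], parts[2])] = max(0.0, value)
        return
    if parts[0] == "strategies":
        s = params.strategy(parts[1])
        if parts[2] == "daily_drug_cost":
            s.daily_drug_cost = max(0.0, value)
            return
        if parts[2] == "adherence":
            value = _clamp01(value)
            a = s.adherence
            shares = {"p_compliant": a.p_compliant, "p_partial": a.p_partial,
                      "p_non": a.p_non}
            rest = [k for k in shares if k != parts[3]]
            rest_sum = sum(shares[k] for k in rest)
            remaining = 1.0 - value
            if rest_sum > 0:
                for k in rest:
                    shares[k] = shares[k] / rest_sum * remaining
            else:
                for k in rest:
                    shares[k] = remaining / len(rest)
            shares[parts[3]] = value
            a.p_compliant = shares["p_compliant"]
            a.p_partial = shares["p_partial"]
            a.p_non = shares["p_non"]
            return
        if parts[2] == "p_relapse_hosp":
            s.p_relapse_hosp[parts[3]] = _clamp01(value)
            return
        if parts[2] == "p_relapse_outpt":
            s.p_relapse_outpt[parts[3]] = _clamp01(value)
            return
        if parts[2] == "ae_probs":
            s.ae_probs[parts[3]] = _clamp01(value)
            return
    raise KeyError(f"cannot resolve parameter path {pid!r}")


def _perturbed(params: ModelParameters, pid: str, value: float) -> ModelParameters:
    out = params.copy()
    set_param(out, pid, value)
    return out


# ---------------------------------------------------------------------------
# One-way sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class TornadoEntry:
    parameter_id: str
    base_value: float
    low_value: float
    high_value: float
    icer_low: float
    icer_high: float

    @property
    def spread(self) -> float:
        return abs(self.icer_high - self.icer_low)


def _comparison_icer(params: ModelParameters,
                     comparison: Tuple[str, str]) -> float:
    a = evaluate_name(comparison[0], params)
    b = evaluate_name(comparison[1], params)
    c = compare(a, b)
    if c.icer is None:
        return math.nan
    return c.icer


def owsa(params: ModelParameters, comparison: Tuple[str, str],
         parameter_ids: Optional[Sequence[str]] = None,
         range_fraction: Optional[float] = None) -> List[TornadoEntry]:
    """One-way sweeps of each parameter; entries sorted by ICER spread.

    Each parameter is set to base x (1 - f) and base x (1 + f), clamped to
    validity, and the comparison's ICER is recomputed at both endpoints.
    """
    if range_fraction is None:
        range_fraction = params.config.owsa_range_fraction
    if parameter_ids is None:
        parameter_ids = list_parameter_ids(params)
    entries: List[TornadoEntry] = []
    for pid in parameter_ids:
        base = get_param(params, pid)
        low = base * (1.0 - range_fraction)
        high = base * (1.0 + range_fraction)
        icer_low = _comparison_icer(_perturbed(params, pid, low), comparison)
        icer_high = _comparison_icer(_perturbed(params, pid, high), comparison)
        entries.append(TornadoEntry(parameter_id=pid, base_value=base,
                                    low_value=low, high_value=high,
                                    icer_low=icer_low, icer_high=icer_high))
    entries.sort(key=lambda e: (-(e.spread if math.isfinite(e.spread) else 0.0),
                                e.parameter_id))
    return entries


# ---------------------------------------------------------------------------
# Sequential-bifurcation screening
# ---------------------------------------------------------------------------

def _cost_direction(pid: str) -> float:
    """Direction in which perturbing a parameter increases total cost.

    Relapse and adverse-event probabilities, prices and quantities all raise
    cost when raised; shifting adherence out of (into) the compliant or
    partial stratum raises (lowers) relapse risk, hence cost, under the
    monotone stratum ordering.  Utilities do not enter the cost side at all
    (their direction is immaterial).
    """
    if ".adherence.p_compliant" in pid or ".adherence.p_partial" in pid:
        return -1.0
    return 1.0


def screen_parameters(params: ModelParameters, comparison: Tuple[str, str],
                      threshold: float,
                      parameter_ids: Optional[Sequence[str]] = None,
                      range_fraction: Optional[float] = None
                      ) -> List[Tuple[str, float]]:
    """Group-screen parameters by their effect on total comparison cost.

    Sequential bifurcation: the parameter list is split into blocks; all
    parameters of a block are perturbed jointly (each in its
    cost-increasing direction by the given fraction) and the block is
    discarded when the joint effect on the combined total cost of the two
    compared strategies does not exceed ``threshold``.  Under the model's
    cost monotonicity the joint effect bounds every individual effect, so
    the surviving shortlist equals one-at-a-time screening at the same
    threshold.  Returns ``(parameter_id, individual effect)`` pairs sorted
    by effect, descending.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if range_fraction is None:
        range_fraction = params.config.owsa_range_fraction
    if parameter_ids is None:
        parameter_ids = list_parameter_ids(params)

    def metric(p: ModelParameters) -> float:
        return (evaluate_name(comparison[0], p).mean_cost
                + evaluate_name(comparison[1], p).mean_cost)

    base_metric = metric(params)

    def block_effect(block: Sequence[str]) -> float:
        p = params.copy()
        for pid in block:
            base = get_param(params, pid)
            set_param(p, pid, base * (1.0 + _cost_direction(pid) * range_fraction))
        return abs(metric(p) - base_metric)

    survivors: List[Tuple[str, float]] = []

    def recurse(block: List[str]) -> None:
        if not block:
            return
        eff = block_effect(block)
        if eff <= threshold:
            return
        if len(block) == 1:
            survivors.append((block[0], eff))
            return
        mid = len(block) // 2
        recurse(block[:mid])
        recurse(block[mid:])

    recurse(list(parameter_ids))
    survivors.sort(key=lambda t: (-t[1], t[0]))
    return survivors


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def _draw_beta(rng: np.random.Generator, mean: float, se: float) -> float:
    """Method-of-moments beta draw; degenerate cases return the mean."""
    if se <= 0 or mean <= 0.0 or mean >= 1.0:
        return mean
    max_var = mean * (1.0 - mean)
    var = min(se ** 2, 0.95 * max_var)  # clamp infeasible moments
    nu = max_var / var - 1.0
    a, b = mean * nu, (1.0 - mean) * nu
    return float(rng.beta(a, b))


def _draw_gamma(rng: np.random.Generator, mean: float, se: float) -> float:
    if se <= 0 or mean <= 0:
        return mean
    f2 = (se / mean) ** 2
    return float(rng.gamma(1.0 / f2, mean * f2))


def psa_draw_parameters(params: ModelParameters,
                        rng: np.random.Generator) -> ModelParameters:
    """Draw one probabilistic parameter set around the base values.

    Beta for relapse/adverse-event probabilities and utilities, gamma for
    drug and unit costs, Dirichlet for the adherence triple.  The drawn set
    satisfies every structural invariant (utility ordering is restored by
    sorting within each stratum; competing relapse risks are rescaled away
    from one if a draw lands there).
    """
    fp = params.config.psa_se_fraction_prob
    fc = params.config.psa_se_fraction_cost
    out = params.copy()

    # Formulations of the same molecule (arms sharing a group) are assumed
    # equal in efficacy and safety, so their relapse and adverse-event
    # probabilities are the *same* parameters: one draw per group, applied
    # to every member whose base value matches.
    shared_prob: Dict[Tuple[str, str, str, float], float] = {}
    arm_group: Dict[str, str] = {}
    for g, members in out.group_definitions.items():
        for m in members:
            arm_group[m] = g

    def correlated_beta(key: Tuple[str, str, str], mean: float) -> float:
        # one draw per (group, parameter, base value); members with a
        # differing base value get their own independent draw
        full = key + (mean,)
        if full not in shared_prob:
            shared_prob[full] = _draw_beta(rng, mean, fp * mean)
        return shared_prob[full]

    for s in out.strategies:
        a = s.adherence
        means = np.array([a.p_compliant, a.p_partial, a.p_non])
        if fp > 0 and (means > 0).all():
            m = means[0]
            conc = max(1.0, (1.0 - m) / (fp ** 2 * m) - 1.0)
            draw = rng.dirichlet(means * conc)
            a.p_compliant, a.p_partial, a.p_non = map(float, draw)
        g = arm_group.get(s.name, s.name)
        for cat in CATEGORIES:
            s.p_relapse_hosp[cat] = correlated_beta(
                (g, "ph", cat), s.p_relapse_hosp[cat])
            s.p_relapse_outpt[cat] = correlated_beta(
                (g, "po", cat), s.p_relapse_outpt[cat])
            tot = s.p_relapse_hosp[cat] + s.p_relapse_outpt[cat]
            if tot >= 1.0:
                s.p_relapse_hosp[cat] *= 0.99 / tot
                s.p_relapse_outpt[cat] *= 0.99 / tot
        for ae in AE_TYPES:
            s.ae_probs[ae] = correlated_beta((g, "ae_" + ae, ""),
                                             s.ae_probs[ae])
        s.daily_drug_cost = _draw_gamma(rng, s.daily_drug_cost,
                                        fc * s.daily_drug_cost)

    for cat in CATEGORIES:
        draws = sorted(
            (_draw_beta(rng, out.utilities.value(cat, st),
                        fp * out.utilities.value(cat, st)) for st in STATES),
            reverse=True,
        )
        for st, v in zip(("stable", "relapse_outpt", "relapse_hosp"), draws):
            out.utilities.u[(cat, st)] = v

    for res, c in out.unit_costs.cost_per_unit.items():
        out.unit_costs.cost_per_unit[res] = _draw_gamma(rng, c, fc * c)

    return out


def default_wtp_grid(params: ModelParameters, n: int = 101,
                     upper: float = 400_000.0) -> np.ndarray:
    """WTP grid from 0 to ``upper``, always containing the configured WTP."""
    grid = np.linspace(0.0, upper, n)
    wtp = params.config.wtp
    if wtp not in grid:
        grid = np.sort(np.append(grid, wtp))
    return grid


@dataclass
class PSAResult:
    """Probabilistic draws plus the acceptability curve."""

    draws: pd.DataFrame  # columns: iteration, strategy, cost, qaly
    ceac: pd.DataFrame  # columns: wtp, strategy, probability
    n_iterations: int
    seed: int

    def ceac_at(self, wtp: float) -> Dict[str, float]:
        """Acceptability probabilities at the WTP grid point nearest ``wtp``."""
        wtps = self.ceac["wtp"].unique()
        nearest = wtps[np.argmin(np.abs(wtps - wtp))]
        sub = self.ceac[self.ceac["wtp"] == nearest]
        return dict(zip(sub["strategy"], sub["probability"]))


def run_psa(params: ModelParameters, strategies: Sequence[str],
            n_iterations: Optional[int] = None, seed: Optional[int] = None,
            wtp_grid: Optional[np.ndarray] = None) -> PSAResult:
    """Second-order Monte Carlo over the compared strategies.

    Per iteration: draw a parameter set, evaluate every compared strategy
    (arm or group) with the expected-value engine, record (cost, QALY).
    The CEAC gives the frequency with which each strategy attains the
    maximum net monetary benefit on the WTP grid.
    """
    if n_iterations is None:
        n_iterations = params.config.psa_iterations
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    if seed is None:
        seed = params.config.seed
    if wtp_grid is None:
        wtp_grid = default_wtp_grid(params)
    strategies = list(strategies)
    rng = np.random.default_rng(seed)

    records = []
    costs = np.empty((n_iterations, len(strategies)))
    qalys = np.empty((n_iterations, len(strategies)))
    for it in range(n_iterations):
        drawn = psa_draw_parameters(params, rng)
        for j, name in enumerate(strategies):
            r = evaluate_name(name, drawn)
            costs[it, j] = r.mean_cost
            qalys[it, j] = r.mean_qaly
            records.append({"iteration": it, "strategy": name,
                            "cost": r.mean_cost, "qaly": r.mean_qaly})

    ceac_rows = []
    for wtp in wtp_grid:
        nmb_mat = qalys * wtp - costs  # (iterations, strategies)
        best = nmb_mat.max(axis=1, keepdims=True)
        winners = nmb_mat >= best - 1e-12  # ties split equally
        prob = (winners / winners.sum(axis=1, keepdims=True)).mean(axis=0)
        for j, name in enumerate(strategies):
            ceac_rows.append({"wtp": float(wtp), "strategy": name,
                              "probability": float(prob[j])})

    return PSAResult(draws=pd.DataFrame.from_records(records),
                     ceac=pd.DataFrame.from_records(ceac_rows),
                     n_iterations=n_iterations, seed=seed)
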