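"""Annual clinical outcomes and quality-adjusted life years.

Per adherence stratum the inputs give per-cycle probabilities of a relapse
requiring hospitalization (``ph``) and of one managed on an outpatient basis
(``po``).  Over the one-year horizon the engine assumes a constant hazard,
so the probability of never relapsing is ``(1 - ph - po) ** K`` where ``K``
is the number of effective cycles per year.  ``K`` is not an observable
quantity; it is calibrated once, by least squares, against the published
annual outcome table and then frozen in the engine configuration.  The
first relapse is absorbing for outcome classification, and the relapse mass
is split between the hospitalized and outpatient classes in the ratio
``ph : po`` of the stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, NamedTuple, Tuple

from scipy.optimize import minimize_scalar

from .parameters import (
    CATEGORIES,
    AdherenceDistribution,
    EngineConfig,
    ModelParameters,
    StrategyParams,
    UtilityTable,
)

__all__ = [
    "OutcomeDistribution",
    "Occupancy",
    "adherence_weighted",
    "stratum_outcomes",
    "annual_outcomes",
    "calibrate_cycle_exponent",
    "occupancy",
    "expected_qaly",
]

#: Outcome labels in triple order (stable, outpatient relapse, hospitalized).
OUTCOMES: Tuple[str, ...] = ("stable", "outpt", "hosp")


@dataclass
class OutcomeDistribution:
    """Annual outcome probabilities, per stratum and marginal.

    Each triple is ``(p_stable, p_outpt, p_hosp)`` and sums to one.
    """

    per_stratum: Dict[str, Tuple[float, float, float]]
    marginal: Tuple[float, float, float]

    @property
    def p_stable(self) -> float:
        return self.marginal[0]

    @property
    def p_outpt(self) -> float:
        return self.marginal[1]

    @property
    def p_hosp(self) -> float:
        return self.marginal[2]


class Occupancy(NamedTuple):
    """Days spent in each state over the horizon (sums to the horizon)."""

    stable_days: float
    outpt_days: float
    hosp_days: float


def adherence_weighted(values: Mapping[str, float],
                       adherence: AdherenceDistribution) -> float:
    """Average ``values`` over the adherence strata.

    Raises ``KeyError`` if the mapping does not cover every stratum.
    """
    shares = adherence.shares
    missing = [c for c in CATEGORIES if c not in values]
    if missing:
        raise KeyError(f"values missing adherence categories {missing}")
    return sum(shares[c] * values[c] for c in CATEGORIES)


def stratum_outcomes(ph: float, po: float, K: float) -> Tuple[float, float, float]:
    """Annual ``(p_stable, p_outpt, p_hosp)`` for one adherence stratum."""
    if ph + po >= 1.0:
        raise ValueError(f"per-cycle relapse probabilities sum to {ph + po} >= 1")
    p_stable = (1.0 - ph - po) ** K
    mass = 1.0 - p_stable
    if ph + po == 0.0:
        return (1.0, 0.0, 0.0)
    p_hosp = mass * (ph / (ph + po))  # fraction first: keeps outpt >= 0 at po=0
    return (p_stable, max(0.0, mass - p_hosp), p_hosp)


def annual_outcomes(s: StrategyParams, cfg: EngineConfig) -> OutcomeDistribution:
    """One-year outcome distribution for a treatment arm."""
    per: Dict[str, Tuple[float, float, float]] = {}
    for cat in CATEGORIES:
        per[cat] = stratum_outcomes(s.p_relapse_hosp[cat], s.p_relapse_outpt[cat],
                                    cfg.cycle_exponent_K)
    marginal = tuple(
        adherence_weighted({c: per[c][i] for c in CATEGORIES}, s.adherence)
        for i in range(3)
    )
    return OutcomeDistribution(per_stratum=per, marginal=marginal)  # type: ignore[arg-type]


def _marginal_for_name(name: str, params: ModelParameters,
                       K: float) -> Tuple[float, float, float]:
    """Marginal outcome triple for an arm or a group (mean over members)."""
    cfg = params.config.copy()
    cfg.cycle_exponent_K = K
    if name in params.group_definitions:
        members = params.group_definitions[name]
        triples = [annual_outcomes(params.strategy(m), cfg).marginal
                   for m in members]
        return tuple(sum(t[i] for t in triples) / len(triples) for i in range(3))  # type: ignore[return-value]
    return annual_outcomes(params.strategy(name), cfg).marginal


def calibrate_cycle_exponent(
    params: ModelParameters,
    targets: Mapping[str, Tuple[float, float, float]],
    bounds: Tuple[float, float] = (0.5, 12.0),
) -> float:
    """Least-squares fit of the cycle exponent ``K`` to annual outcome targets.

    ``targets`` maps an arm or group name to its published annual
    ``(stable%, hosp%, outpt%)`` percentages.  Returns the ``K`` minimizing
    the sum of squared differences between model marginal percentages and
    the targets over all named strategies and outcome classes.
    """
    if not targets:
        raise ValueError("calibration targets are empty")

    def sse(K: float) -> float:
        total = 0.0
        for name, (stable_pct, hosp_pct, outpt_pct) in targets.items():
            p_stable, p_outpt, p_hosp = _marginal_for_name(name, params, K)
            total += (100.0 * p_stable - stable_pct) ** 2
            total += (100.0 * p_hosp - hosp_pct) ** 2
            total += (100.0 * p_outpt - outpt_pct) ** 2
        return total

    res = minimize_scalar(sse, bounds=bounds, method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)


def occupancy(outcome: str, cfg: EngineConfig) -> Occupancy:
    """State occupancy (days) over the horizon for a given annual outcome.

    A hospitalized relapse occupies one inpatient episode
    (``hosp_episode_days``, anchored to the published 11.7-day length of
    stay); an outpatient relapse occupies ``outpt_episode_days``; the rest
    of the year is spent stable on the initial treatment.
    """
    h = cfg.horizon_days
    if outcome == "stable":
        return Occupancy(h, 0.0, 0.0)
    if outcome == "outpt":
        return Occupancy(h - cfg.outpt_episode_days, cfg.outpt_episode_days, 0.0)
    if outcome == "hosp":
        return Occupancy(h - cfg.hosp_episode_days, 0.0, cfg.hosp_episode_days)
    raise ValueError(f"unknown outcome {outcome!r}")


def qaly_by_cell(s: StrategyParams, u: UtilityTable,
                 cfg: EngineConfig) -> Dict[Tuple[str, str], float]:
    """QALYs accrued in each (adherence category, outcome) cell.

    Episode days carry the relapse-state utility of the stratum; the
    remainder of the year carries its stable-state utility.  Time is
    denominated in years of ``horizon_days`` length.
    """
    out: Dict[Tuple[str, str], float] = {}
    h = cfg.horizon_days
    for cat in CATEGORIES:
        us = u.value(cat, "stable")
        uo = u.value(cat, "relapse_outpt")
        uh = u.value(cat, "relapse_hosp")
        for outcome, urel in (("stable", us), ("outpt", uo), ("hosp", uh)):
            occ = occupancy(outcome, cfg)
            out[(cat, outcome)] = (occ.stable_days * us
                                   + occ.outpt_days * uo
                                   + occ.hosp_days * uh) / h
    return out


def expected_qaly(s: StrategyParams, u: UtilityTable, cfg: EngineConfig) -> float:
    """Expected QALYs over the one-year horizon for a treatment arm."""
    dist = annual_outcomes(s, cfg)
    cell = qaly_by_cell(s, u, cfg)
    total = 0.0
    shares = s.adherence.shares
    for cat in CATEGORIES:
        p_stable, p_outpt, p_hosp = dist.per_stratum[cat]
        total += shares[cat] * (p_stable * cell[(cat, "stable")]
                                + p_outpt * cell[(cat, "outpt")]
                                + p_hosp * cell[(cat, "hosp")])
    return total
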