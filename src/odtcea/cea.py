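"""Incremental cost-effectiveness mathematics.

ICERs (incremental cost per QALY gained), dominance classification, net
monetary benefit (NMB), and the cost-effectiveness frontier with strict and
extended dominance.  A negative ICER is ambiguous on its own; comparisons
therefore carry an explicit flag (``dominant`` when the intervention is
cheaper and more effective, ``dominated`` for the reverse,
``equal_effect`` when the QALY difference is zero and the decision reduces
to cost minimization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

from .simulation import CohortResult

__all__ = ["CEAComparison", "FrontierEntry", "icer", "compare", "nmb", "frontier"]


@dataclass
class CEAComparison:
    intervention: str
    comparator: str
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]  # undefined when delta_qaly == 0
    flag: Optional[str]  # "dominant" | "dominated" | "equal_effect" | None
    cost_effective_at_wtp: Optional[bool] = None
    wtp: Optional[float] = None


def nmb(cost: float, qaly: float, wtp: float) -> float:
    """Net monetary benefit at a willingness-to-pay threshold."""
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    return qaly * wtp - cost


def icer(cost_i: float, qaly_i: float, cost_c: float, qaly_c: float,
         intervention: str = "intervention", comparator: str = "comparator",
         wtp: Optional[float] = None) -> CEAComparison:
    """Incremental comparison of an intervention against a comparator."""
    d_cost = cost_i - cost_c
    d_qaly = qaly_i - qaly_c
    flag: Optional[str] = None
    ratio: Optional[float] = None
    if d_qaly == 0.0:
        flag = "equal_effect"
    else:
        ratio = d_cost / d_qaly
        if d_cost < 0 and d_qaly > 0:
            flag = "dominant"
        elif d_cost > 0 and d_qaly < 0:
            flag = "dominated"
    ce: Optional[bool] = None
    if wtp is not None:
        ce = nmb(cost_i, qaly_i, wtp) >= nmb(cost_c, qaly_c, wtp)
    return CEAComparison(intervention=intervention, comparator=comparator,
                         delta_cost=d_cost, delta_qaly=d_qaly, icer=ratio,
                         flag=flag, cost_effective_at_wtp=ce, wtp=wtp)


def compare(a: CohortResult, b: CohortResult,
            wtp: Optional[float] = None) -> CEAComparison:
    """ICER of cohort result ``a`` versus ``b``."""
    return icer(a.mean_cost, a.mean_qaly, b.mean_cost, b.mean_qaly,
                intervention=a.strategy, comparator=b.strategy, wtp=wtp)


@dataclass
class FrontierEntry:
    result: CohortResult
    dominated: bool = False
    extendedly_dominated: bool = False
    icer_vs_previous: Optional[float] = None  # along the frontier

    @property
    def on_frontier(self) -> bool:
        return not (self.dominated or self.extendedly_dominated)


def frontier(results: Sequence[CohortResult]) -> List[FrontierEntry]:
    """Cost-effectiveness frontier with dominance annotations.

    Strategies are sorted by cost (ties broken by QALY descending, then
    name).  A strategy is *dominated* if another is no more costly and no
    less effective (strictly better on one margin, or identical but earlier
    in the tie-break); it is *extendedly dominated* if it is skipped by the
    efficient frontier, i.e. the sequential ICER to it exceeds the ICER past
    it.  Sequential ICERs are reported along the surviving frontier.
    """
    results = list(results)
    if len(results) < 2:
        raise ValueError("frontier needs at least two strategies")
    names = [r.strategy for r in results]
    if len(set(names)) != len(names):
        raise ValueError("duplicate strategy names")

    order = sorted(results, key=lambda r: (r.mean_cost, -r.mean_qaly, r.strategy))
    entries = {r.strategy: FrontierEntry(result=r) for r in order}

    for i, r in enumerate(order):
        for j, other in enumerate(order):
            if other is r:
                continue
            better_cost = other.mean_cost <= r.mean_cost
            better_qaly = other.mean_qaly >= r.mean_qaly
            strictly = (other.mean_cost < r.mean_cost
                        or other.mean_qaly > r.mean_qaly)
            identical = (other.mean_cost == r.mean_cost
                         and other.mean_qaly == r.mean_qaly)
            if better_cost and better_qaly and (strictly or (identical and j < i)):
                entries[r.strategy].dominated = True
                break

    # extended dominance on the survivors: walk the cost-sorted chain and
    # drop points whose incoming ICER exceeds their outgoing ICER
    chain = [r for r in order if not entries[r.strategy].dominated]
    changed = True
    while changed:
        changed = False
        for k in range(1, len(chain) - 1):
            prev, cur, nxt = chain[k - 1], chain[k], chain[k + 1]
            dq_in = cur.mean_qaly - prev.mean_qaly
            dq_out = nxt.mean_qaly - cur.mean_qaly
            if dq_in <= 0 or dq_out <= 0:
                continue
            icer_in = (cur.mean_cost - prev.mean_cost) / dq_in
            icer_out = (nxt.mean_cost - cur.mean_cost) / dq_out
            if icer_in > icer_out:
                entries[cur.strategy].extendedly_dominated = True
                chain.pop(k)
                changed = True
                break

    for k in range(1, len(chain)):
        prev, cur = chain[k - 1], chain[k]
        dq = cur.mean_qaly - prev.mean_qaly
        entries[cur.strategy].icer_vs_previous = (
            (cur.mean_cost - prev.mean_cost) / dq if dq != 0 else None
        )

    return [entries[r.strategy] for r in order]
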