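"""Deterministic cost-effectiveness analytics.

Net monetary benefit (NMB) at threshold λ is QALYs·λ − costs; the strategy
with the highest NMB — equivalently the highest incremental NMB vs the
model comparator — is the most cost-effective at that threshold.  For the
ICER ladder, options are sorted by cost, strictly dominated options removed,
then extendedly dominated options (above the lower convex frontier in
(QALY, cost) space) removed iteratively; ICERs are reported only between
adjacent frontier members, where they are strictly increasing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

NONDOMINATED = "nondominated"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly_dominated"


def nmb(qalys: float, costs: float, lam: float) -> float:
    if lam <= 0:
        raise ValueError("threshold lambda must be > 0")
    return qalys * lam - costs


def dominance_filter(points: Sequence[tuple[float, float]]) -> list[bool]:
    """Strict dominance flags for (cost, qalys) points.

    A point is dominated if another is no worse on both axes and strictly
    better on at least one; exact ties dominate nothing (both retained).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2:
        return [False] * len(pts)
    out = []
    for i, (ci, qi) in enumerate(pts):
        dominated = False
        for j, (cj, qj) in enumerate(pts):
            if j != i and cj <= ci and qj >= qi and (cj < ci or qj > qi):
                dominated = True
                break
        out.append(dominated)
    return out


def extended_dominance_filter(
    points: Sequence[tuple[float, float]],
    dominated: Optional[Sequence[bool]] = None,
) -> tuple[list[str], list[int], list[Optional[float]]]:
    """Statuses, frontier member indices (by increasing cost) and ICERs.

    Iteratively removes points whose ICER against the previous frontier
    member exceeds the next one's (equivalently, points above the lower-left
    convex hull in (QALY, cost) space).  ICERs are attached to frontier
    members vs the previous member (None for the cheapest).
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    if dominated is None:
        dominated = dominance_filter(pts)
    statuses = [DOMINATED if d else NONDOMINATED for d in dominated]
    # candidates sorted by cost then QALYs (stable on exact ties)
    cand = sorted(
        (i for i in range(n) if not dominated[i]),
        key=lambda i: (pts[i][0], pts[i][1]),
    )
    changed = True
    while changed and len(cand) > 2:
        changed = False
        for pos in range(1, len(cand) - 1):
            i_prev, i, i_next = cand[pos - 1], cand[pos], cand[pos + 1]
            dq1 = pts[i][1] - pts[i_prev][1]
            dc1 = pts[i][0] - pts[i_prev][0]
            dq2 = pts[i_next][1] - pts[i][1]
            dc2 = pts[i_next][0] - pts[i][0]
            # ICER sequence must be non-decreasing along the frontier
            if dc1 * dq2 > dc2 * dq1 + 1e-12:
                statuses[i] = EXT_DOMINATED
                cand.pop(pos)
                changed = True
                break
    icers: list[Optional[float]] = [None] * n
    for pos in range(1, len(cand)):
        i_prev, i = cand[pos - 1], cand[pos]
        dq = pts[i][1] - pts[i_prev][1]
        dc = pts[i][0] - pts[i_prev][0]
        icers[i] = float(dc / dq) if dq != 0 else float("inf")
    return statuses, cand, icers


def rank_by_nmb(
    qalys: Sequence[float],
    costs: Sequence[float],
    lam: float,
    names: Optional[Sequence[str]] = None,
) -> list[int]:
    """Rank 1 = highest NMB; ties broken by lower cost then name."""
    n = len(qalys)
    names = list(names) if names is not None else [str(i) for i in range(n)]
    values = [nmb(q, c, lam) for q, c in zip(qalys, costs)]
    order = sorted(range(n), key=lambda i: (-values[i], costs[i], names[i]))
    ranks = [0] * n
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    return ranks


@dataclass
class CEResult:
    """Per-strategy deterministic cost-effectiveness table."""

    table: pd.DataFrame  # indexed by strategy slug
    lam: float
    comparator: str

    @property
    def best(self) -> str:
        return self.table.index[self.table["rank"] == 1][0]

    def frontier(self) -> pd.DataFrame:
        return self.table[self.table["icer"].notna() |
                          ((self.table["status"] == NONDOMINATED) &
                           (self.table["cost"] == self.table["cost"].min()))]


def evaluate_strategies(
    names: Sequence[str],
    qalys: Sequence[float],
    costs: Sequence[float],
    lam: float,
    comparator: str,
) -> CEResult:
    """Assemble NMB/INMB, dominance statuses, frontier ICERs and ranks."""
    if comparator not in names:
        raise KeyError(f"comparator {comparator!r} not among strategies")
    qalys = np.asarray(qalys, dtype=float)
    costs = np.asarray(costs, dtype=float)
    points = list(zip(costs, qalys))
    statuses, _, icers = extended_dominance_filter(points)
    nmbs = qalys * lam - costs
    comp_idx = list(names).index(comparator)
    ranks = rank_by_nmb(qalys, costs, lam, names)
    table = pd.DataFrame(
        {
            "qalys": qalys,
            "cost": costs,
            "inc_qalys": qalys - qalys[comp_idx],
            "inc_cost": costs - costs[comp_idx],
            "nmb": nmbs,
            "inmb": nmbs - nmbs[comp_idx],
            "status": statuses,
            "icer": icers,
            "rank": ranks,
        },
        index=pd.Index(names, name="strategy"),
    )
    return CEResult(table=table, lam=lam, comparator=comparator)
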