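"""The STAR efficiency frontier.

Each baseline intervention is drawn as a right triangle with cost on the
x-axis and PHB on the y-axis: a horizontal leg at the entry height, a
vertical leg at the exit cost, hypotenuse from (x0, y0) to (x1, y1).  Tall,
narrow triangles are more cost-effective than short, wide ones.  Ordering
triangles by PHB-per-cost slope, descending, and chaining them from the
origin produces a concave cumulative curve — the efficiency frontier.  The
goal of pathway redesign is to move this curve up and to the left.

Zero-cost interventions with positive benefit have INFINITE slope and sort
first; zero-benefit, zero-cost interventions have slope zero by convention.
The baseline frontier admits only non-negative costs — improvements with
negative *net* cost belong on the improvement scatter, not on the frontier.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._util import INFINITE
from .benefit import pathway_benefits
from .pathway import ICSDataset
from .valuation import ScoreSet, scoreset_from_dataset

__all__ = [
    "FrontierItem",
    "FrontierSegment",
    "ce_slope",
    "order_frontier",
    "cumulative_frontier",
    "baseline_frontier",
]


@dataclass(frozen=True)
class FrontierItem:
    intervention_id: str
    phb: float
    cost: float

    @property
    def slope(self) -> float:
        return ce_slope(self.phb, self.cost)


@dataclass(frozen=True)
class FrontierSegment:
    """One triangle on the cumulative frontier."""

    intervention_id: str
    phb: float
    cost: float
    slope: float
    x0: float
    y0: float
    x1: float
    y1: float

    @property
    def triangle(self) -> tuple[tuple[float, float], ...]:
        return ((self.x0, self.y0), (self.x1, self.y0), (self.x1, self.y1))


def ce_slope(phb: float, cost: float) -> float:
    """Cost-effectiveness slope: PHB per currency unit.

    ``phb / cost`` for positive cost; INFINITE for a vertical triangle
    (benefit at zero cost); 0.0 for the degenerate zero-benefit, zero-cost
    point.  Negative cost is a domain error on the baseline frontier.
    """
    if cost < 0:
        raise ValueError(f"baseline frontier cost must be non-negative, got {cost}")
    if phb < 0:
        raise ValueError(f"PHB must be non-negative, got {phb}")
    if cost == 0:
        return INFINITE if phb > 0 else 0.0
    return phb / cost


def _as_items(results: Iterable) -> list[FrontierItem]:
    items = []
    for r in results:
        if isinstance(r, FrontierItem):
            items.append(r)
        else:
            iid, phb, cost = r
            items.append(FrontierItem(intervention_id=iid, phb=phb, cost=cost))
    return items


def order_frontier(results: Iterable) -> list[FrontierItem]:
    """Sort interventions by cost-effectiveness, from high to low.

    Accepts ``FrontierItem`` objects or ``(id, phb, cost)`` tuples.  INFINITE
    slopes come first; ties are broken by larger PHB, then id ascending.
    This is the unique ordering (up to the declared tie rule) that makes the
    cumulative frontier concave.
    """
    items = _as_items(results)
    return sorted(items, key=lambda it: (-it.slope, -it.phb, it.intervention_id))


def cumulative_frontier(ordered: Sequence) -> list[FrontierSegment]:
    """Chain ordered triangles from the origin into the efficiency frontier.

    Input must already be sorted by non-increasing slope (the output of
    :func:`order_frontier`); anything else raises ``ValueError``.  Segment k
    starts where segment k-1 ends, and the final vertex is
    (total cost, total PHB).
    """
    items = _as_items(ordered)
    slopes = [it.slope for it in items]
    for a, b in zip(slopes, slopes[1:]):
        if b > a:
            raise ValueError(
                "input not ordered by non-increasing cost-effectiveness; "
                "call order_frontier first"
            )
    segments: list[FrontierSegment] = []
    x = y = 0.0
    for it in items:
        x1, y1 = x + it.cost, y + it.phb
        segments.append(
            FrontierSegment(
                intervention_id=it.intervention_id,
                phb=it.phb,
                cost=it.cost,
                slope=it.slope,
                x0=x,
                y0=y,
                x1=x1,
                y1=y1,
            )
        )
        x, y = x1, y1
    return segments


def baseline_frontier(
    dataset: ICSDataset, scores: ScoreSet | None = None
) -> list[FrontierSegment]:
    """Build the baseline frontier for a dataset.

    Scores default to the benefit scores stored on the dataset's
    intervention records.
    """
    if scores is None:
        scores = scoreset_from_dataset(dataset)
    benefits = {b.intervention_id: b.phb for b in pathway_benefits(dataset, scores)}
    items = [
        FrontierItem(intervention_id=r.id, phb=benefits[r.id], cost=r.annual_cost)
        for r in dataset.interventions
    ]
    return cumulative_frontier(order_frontier(items))
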