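"""Costing, ranking and stability analysis of pathway improvements.

For each candidate improvement scenario the allocation model computes:

* ``net_cost = implementation_cost - offset_savings`` (signed; negative
  means the change pays for itself through reduced resource use elsewhere
  in the pathway, e.g. avoided admissions);
* ``cost_ratio = offset_savings / implementation_cost`` — "saves £r for
  every £1 spent elsewhere in the pathway";
* ``cost_phb_ratio = net_cost / phb_gain`` — net cost per unit of
  population health benefit gained, the ranking key.  Scenarios are ranked
  ascending (most negative, i.e. most health per pound saved, first).

Ratios use the INFINITE/UNDEFINED conventions from :mod:`._util`; UNDEFINED
ratios rank after all defined ones.  Displayed ratios are rounded half away
from zero to two decimals; internal values are never rounded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import INFINITE, UNDEFINED, is_undefined
from .pathway import ICSDataset, ImprovementScenario

__all__ = [
    "RankedImprovement",
    "Recommendation",
    "net_cost",
    "cost_ratio",
    "cost_phb_ratio",
    "rank_improvements",
    "recommend",
    "rank_stability",
]


def net_cost(gross_cost: float, offset_savings: float) -> float:
    """Signed net annual cost; negative means a net saving."""
    if gross_cost < 0 or offset_savings < 0:
        raise ValueError("gross cost and offset savings must be non-negative")
    return gross_cost - offset_savings


def cost_ratio(gross_cost: float, offset_savings: float) -> float:
    """Savings returned per unit of gross implementation cost.

    INFINITE when savings accrue at zero cost; UNDEFINED for 0/0.
    """
    if gross_cost < 0 or offset_savings < 0:
        raise ValueError("gross cost and offset savings must be non-negative")
    if gross_cost == 0:
        return INFINITE if offset_savings > 0 else UNDEFINED
    return offset_savings / gross_cost


def cost_phb_ratio(net_cost: float, phb_gain: float) -> float:
    """Net cost per PHB unit gained; UNDEFINED when no benefit is generated."""
    if phb_gain < 0:
        raise ValueError(f"phb_gain must be non-negative, got {phb_gain}")
    if phb_gain == 0:
        return UNDEFINED
    return net_cost / phb_gain


@dataclass(frozen=True)
class RankedImprovement:
    """One scenario with its computed economics and rank (1 = best)."""

    improvement_id: str
    name: str
    scenario_label: str
    phb_gain: float
    gross_cost: float  # UNDEFINED when the decomposition is not known
    offset_savings: float  # likewise
    net_cost: float
    cost_ratio: float
    cost_phb_ratio: float
    rank: int
    recommended_flag: bool = False

    @property
    def key(self) -> tuple[str, str]:
        return (self.improvement_id, self.scenario_label)


def _sort_key(ratio: float, phb: float, iid: str, label: str):
    # UNDEFINED last; then ratio ascending; ties by larger PHB, then ids.
    return (1 if is_undefined(ratio) else 0, 0.0 if is_undefined(ratio) else ratio,
            -phb, iid, label)


def _evaluate(s: ImprovementScenario) -> tuple[float, float, float, float, float]:
    phb = s.effective_phb_gain
    net = s.effective_net_cost
    if s.implementation_cost is not None and s.offset_savings is not None:
        gross, savings = float(s.implementation_cost), float(s.offset_savings)
        cr = cost_ratio(gross, savings)
    elif s.implementation_cost is not None:
        gross, savings = float(s.implementation_cost), UNDEFINED
        cr = UNDEFINED
    else:
        gross, savings = UNDEFINED, UNDEFINED
        # fall back to the transcribed annotation when the decomposition
        # was never published
        cr = s.cost_ratio_printed if s.cost_ratio_printed is not None else UNDEFINED
    return phb, net, gross, savings, cr


def rank_improvements(
    scenarios: Iterable[ImprovementScenario],
) -> list[RankedImprovement]:
    """Rank scenarios ascending by cost/PHB ratio.

    The most negative ratio (greatest saving per unit of health gained) gets
    rank 1.  UNDEFINED ratios are placed last rather than erroring; ties are
    broken by larger PHB gain, then by (improvement_id, scenario_label).
    Ranks are exactly 1..n.
    """
    rows = []
    for s in scenarios:
        phb, net, gross, savings, cr = _evaluate(s)
        ratio = cost_phb_ratio(net, phb)
        rows.append((s, phb, net, gross, savings, cr, ratio))
    rows.sort(key=lambda r: _sort_key(r[6], r[1], r[0].improvement_id,
                                      r[0].scenario_label))
    return [
        RankedImprovement(
            improvement_id=s.improvement_id,
            name=s.name,
            scenario_label=s.scenario_label,
            phb_gain=phb,
            gross_cost=gross,
            offset_savings=savings,
            net_cost=net,
            cost_ratio=cr,
            cost_phb_ratio=ratio,
            rank=k,
            recommended_flag=s.recommended_flag,
        )
        for k, (s, phb, net, gross, savings, cr, ratio) in enumerate(rows, start=1)
    ]


@dataclass(frozen=True)
class Recommendation:
    selected: tuple[RankedImprovement, ...]
    cumulative_net_cost: float
    cumulative_phb_gain: float


def recommend(
    ranked: Sequence[RankedImprovement],
    budget_cap: Optional[float] = None,
    ratio_threshold: float = 1.0,
) -> Recommendation:
    """Greedy selection in rank order.

    Items are taken in rank order while (a) their cost/PHB ratio is defined
    and below ``ratio_threshold`` (currency per PHB unit) and (b) the running
    net cost stays within ``budget_cap`` (default: no cap).  Net-saving items
    relax the cap, so a zero cap still admits a rank-1 saver.  Selection
    stops at the first item that fails either test.
    """
    cap = math.inf if budget_cap is None else budget_cap
    selected: list[RankedImprovement] = []
    cum_cost = cum_phb = 0.0
    for item in ranked:
        if is_undefined(item.cost_phb_ratio) or item.cost_phb_ratio >= ratio_threshold:
            break
        if cum_cost + item.net_cost > cap:
            break
        selected.append(item)
        cum_cost += item.net_cost
        cum_phb += item.phb_gain
    return Recommendation(
        selected=tuple(selected),
        cumulative_net_cost=cum_cost,
        cumulative_phb_gain=cum_phb,
    )


def rank_stability(
    dataset: ICSDataset,
    delta: float,
    n_draws: int,
    seed: int,
    top_k: int = 3,
) -> pd.DataFrame:
    """Monte-Carlo rank stability under valuation noise.

    Each draw perturbs every scenario's valuation by u ~ Uniform(-delta,
    +delta) on the 0–100 benefit scale: scenarios carrying an explicit
    benefit score have the score shifted and clipped to [0, 100] before the
    PHB gain is recomputed; scenarios that only carry a PHB gain (the
    transcribed fixtures) are scaled by ``max(0, 1 + u/100)``, i.e. the same
    noise expressed relative to the 100-point benchmark.  Re-anchoring the
    benchmark is a uniform positive rescale of every PHB gain, which cannot
    change any rank, so it is not simulated.  Net costs are held fixed.

    Returns a DataFrame (one row per scenario, in point-estimate rank order)
    with columns ``improvement_id, scenario_label, point_rank, mean_rank,
    top_k_freq``.  Deterministic for a given seed; with ``delta=0`` every
    frequency is exactly 0 or 1.
    """
    if delta < 0:
        raise ValueError("delta must be non-negative")
    if n_draws < 1:
        raise ValueError("n_draws must be at least 1")
    scenarios = list(dataset.improvements)
    point = rank_improvements(scenarios)
    point_rank = {r.key: r.rank for r in point}
    n = len(scenarios)
    if n == 0:
        return pd.DataFrame(
            columns=["improvement_id", "scenario_label", "point_rank",
                     "mean_rank", "top_k_freq"]
        )

    scored = [
        s.benefit_score is not None
        and s.additional_treated is not None
        and s.nnt is not None
        for s in scenarios
    ]
    has_score = np.array(scored)
    score0 = np.array([s.benefit_score if ok else 0.0
                       for s, ok in zip(scenarios, scored)])
    per_point = np.array(
        [s.additional_treated / s.nnt if ok else 0.0
         for s, ok in zip(scenarios, scored)]
    )
    phb0 = np.array([s.effective_phb_gain for s in scenarios])
    net = np.array([s.effective_net_cost for s in scenarios])
    ids = [s.improvement_id for s in scenarios]
    labels = [s.scenario_label for s in scenarios]

    rng = np.random.default_rng(seed)
    rank_sum = np.zeros(n)
    topk_count = np.zeros(n)
    for _ in range(n_draws):
        u = rng.uniform(-delta, delta, size=n)
        phb = np.where(
            has_score,
            per_point * np.clip(score0 + u, 0.0, 100.0),
            phb0 * np.maximum(0.0, 1.0 + u / 100.0),
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(phb > 0, net / phb, np.nan)
        order = sorted(
            range(n), key=lambda i: _sort_key(float(ratio[i]), float(phb[i]),
                                              ids[i], labels[i])
        )
        ranks = np.empty(n, dtype=int)
        for pos, i in enumerate(order, start=1):
            ranks[i] = pos
        rank_sum += ranks
        topk_count += ranks <= top_k

    df = pd.DataFrame(
        {
            "improvement_id": ids,
            "scenario_label": labels,
            "point_rank": [point_rank[(i, l)] for i, l in zip(ids, labels)],
            "mean_rank": rank_sum / n_draws,
            "top_k_freq": topk_count / n_draws,
        }
    )
    df = df.sort_values("point_rank").reset_index(drop=True)
    df.attrs.update({"delta": delta, "n_draws": n_draws, "top_k": top_k,
                     "seed": seed})
    return df
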