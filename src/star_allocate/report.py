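"""Tabular exports and deterministic figure rendering.

``ranking.csv`` mirrors the published table layout (rank, improvement,
scenario, PHB gain, net cost, cost ratio, cost/PHB ratio, recommended);
ratio columns are display-rounded to two decimals, half away from zero,
while PHB and cost columns stay unrounded so a reloaded ranking re-ranks
identically.  Figures are written as SVG with hashing salted and the date
stripped so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd

from ._util import round_half_away
from .frontier import FrontierSegment
from .improvements import RankedImprovement

__all__ = [
    "ranking_table",
    "write_ranking_csv",
    "frontier_table",
    "write_frontier_csv",
    "render_frontier",
    "render_improvements_scatter",
]

log = logging.getLogger("star_allocate")

_SVG_STYLE = {"svg.hashsalt": "star-allocate", "svg.fonttype": "path"}


def ranking_table(ranked: Sequence[RankedImprovement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": [r.rank for r in ranked],
            "improvement_id": [r.improvement_id for r in ranked],
            "name": [r.name for r in ranked],
            "scenario_label": [r.scenario_label for r in ranked],
            "phb_gain": [r.phb_gain for r in ranked],
            "net_cost": [r.net_cost for r in ranked],
            "cost_ratio": [round_half_away(r.cost_ratio) for r in ranked],
            "cost_phb_ratio": [round_half_away(r.cost_phb_ratio) for r in ranked],
            "recommended": [r.recommended_flag for r in ranked],
        }
    )


def write_ranking_csv(ranked: Sequence[RankedImprovement], path) -> Path:
    path = Path(path)
    ranking_table(ranked).to_csv(path, index=False)
    return path


def frontier_table(segments: Sequence[FrontierSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": range(1, len(segments) + 1),
            "intervention_id": [s.intervention_id for s in segments],
            "cost": [s.cost for s in segments],
            "phb": [s.phb for s in segments],
            "slope": [s.slope for s in segments],
            "x0": [s.x0 for s in segments],
            "y0": [s.y0 for s in segments],
            "x1": [s.x1 for s in segments],
            "y1": [s.y1 for s in segments],
        }
    )


def write_frontier_csv(segments: Sequence[FrontierSegment], path) -> Path:
    path = Path(path)
    frontier_table(segments).to_csv(path, index=False)
    return path


def _save_svg(fig, path: Path) -> None:
    fig.savefig(path, format="svg", metadata={"Date": None})
    plt.close(fig)


def render_frontier(segments: Sequence[FrontierSegment], path,
                    currency_label: str = "currency") -> Path:
    """Draw the cumulative triangle frontier (cost on x, PHB on y)."""
    path = Path(path)
    if not segments:
        log.warning("rendering an empty frontier: axes only")
    with plt.rc_context(_SVG_STYLE):
        fig, ax = plt.subplots(figsize=(7, 5))
        for seg in segments:
            xs = [p[0] for p in seg.triangle] + [seg.x0]
            ys = [p[1] for p in seg.triangle] + [seg.y0]
            ax.fill(xs, ys, alpha=0.35, linewidth=0.5, edgecolor="black")
            ax.plot([seg.x0, seg.x1], [seg.y0, seg.y1], color="black", linewidth=1.2)
        ax.set_xlabel(f"Cumulative annual cost ({currency_label})")
        ax.set_ylabel("Cumulative population health benefit (PHB units)")
        ax.set_title("Efficiency frontier")
        _save_svg(fig, path)
    return path


def render_improvements_scatter(ranked: Sequence[RankedImprovement], path,
                                currency_label: str = "currency") -> Path:
    """Scatter of improvements: net annual cost (x) vs PHB gain (y).

    The favourable quadrant is to the upper left (net savings, more
    health); recommended items are drawn filled.
    """
    path = Path(path)
    with plt.rc_context(_SVG_STYLE):
        fig, ax = plt.subplots(figsize=(7, 5))
        for r in ranked:
            ax.scatter(
                r.net_cost,
                r.phb_gain,
                marker="o",
                facecolors="tab:blue" if r.recommended_flag else "none",
                edgecolors="tab:blue",
            )
            ax.annotate(str(r.rank), (r.net_cost, r.phb_gain),
                        textcoords="offset points", xytext=(4, 4), fontsize=7)
        ax.axvline(0.0, color="grey", linewidth=0.8)
        ax.set_xlabel(f"Net annual cost ({currency_label})")
        ax.set_ylabel("PHB gain (units)")
        ax.set_title("Modelled pathway improvements")
        _save_svg(fig, path)
    return path
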