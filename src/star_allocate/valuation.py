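"""Relative-benefit (VAS) score handling.

In a STAR decision conference, stakeholders rate each pathway intervention
on a 0–100 visual analogue scale: the option judged to deliver the greatest
individual health benefit anchors the scale at 100, and 0 corresponds to no
additional benefit over current care.  Consensus in the workshops is reached
by facilitated discussion; this module provides a deterministic,
reproducible stand-in (median or trimmed mean across a rater panel, rescaled
to a 100 maximum) used by the synthetic pipeline and sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScoreError",
    "ScoreSet",
    "PanelScores",
    "validate_scoreset",
    "consensus_scores",
    "load_panel_csv",
    "scoreset_from_dataset",
]


class ScoreError(ValueError):
    """A score set or panel violated the VAS protocol."""


@dataclass(frozen=True)
class ScoreSet:
    """Final per-intervention benefit scores anchored at a 100 benchmark."""

    scores: dict[str, float]
    benchmark_id: str = field(default="")

    def __post_init__(self):
        if not self.scores:
            raise ScoreError("empty score set")
        if not self.benchmark_id:
            # deterministic default: lexicographically smallest id scoring 100
            tops = sorted(i for i, s in self.scores.items() if s == 100)
            object.__setattr__(self, "benchmark_id", tops[0] if tops else "")

    def __getitem__(self, intervention_id: str) -> float:
        return self.scores[intervention_id]


@dataclass(frozen=True)
class PanelScores:
    """Raw rater x intervention VAS scores prior to consensus."""

    matrix: pd.DataFrame  # index: rater ids; columns: intervention ids

    @property
    def raters(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def interventions(self) -> list[str]:
        return list(self.matrix.columns)

    def validate(self) -> "PanelScores":
        if self.matrix.empty:
            raise ScoreError("empty panel")
        if self.matrix.isna().any().any():
            raise ScoreError("every rater must score every intervention")
        vals = self.matrix.to_numpy(dtype=float)
        if (vals < 0).any() or (vals > 100).any():
            raise ScoreError("panel scores must lie in [0, 100]")
        if not (vals == 100).any(axis=1).all():
            bad = [r for r, ok in zip(self.raters, (vals == 100).any(axis=1)) if not ok]
            raise ScoreError(f"rater(s) {bad} have no benchmark score of 100")
        return self


def validate_scoreset(s: ScoreSet) -> ScoreSet:
    """Check the anchoring invariants and return the score set unchanged.

    Raises :class:`ScoreError` if any score is outside [0, 100], if no
    intervention carries the benchmark score of 100, or if the declared
    benchmark is not (tied at) the maximum.
    """
    for iid, v in s.scores.items():
        if not (0 <= v <= 100):
            raise ScoreError(f"score for {iid!r} is {v}, outside [0, 100]")
    if max(s.scores.values()) != 100:
        raise ScoreError("missing benchmark: no intervention scored 100")
    if s.benchmark_id not in s.scores or s.scores[s.benchmark_id] != 100:
        raise ScoreError(f"benchmark {s.benchmark_id!r} does not score 100")
    return s


def consensus_scores(
    panel: PanelScores, rule: str = "median", trim: float = 0.1
) -> ScoreSet:
    """Aggregate a rater panel into a final score set.

    ``rule`` is ``"median"`` (default; robust to single outlying raters) or
    ``"trimmed_mean"`` (``trim`` fraction cut from each tail).  Aggregates
    are rescaled so the maximum is exactly 100; the benchmark on ties is the
    lexicographically smallest id.  The aggregation is invariant to rater
    order and monotone: rescaling never reorders interventions.
    """
    panel.validate()
    vals = panel.matrix.to_numpy(dtype=float)
    if rule == "median":
        agg = np.median(vals, axis=0)
    elif rule == "trimmed_mean":
        agg = stats.trim_mean(vals, proportiontocut=trim, axis=0)
    else:
        raise ValueError(f"unknown consensus rule {rule!r}")
    top = agg.max()
    if top <= 0:
        raise ScoreError("all aggregate scores are zero; cannot anchor at 100")
    scaled = agg * (100.0 / top)
    scaled[agg == top] = 100.0  # avoid 99.999... at the anchor
    scores = dict(zip(panel.interventions, (float(v) for v in scaled)))
    return validate_scoreset(ScoreSet(scores=scores))


def load_panel_csv(path) -> PanelScores:
    """Read a long-format ``panel.csv`` (rater_id, intervention_id, score)."""
    df = pd.read_csv(Path(path))
    required = {"rater_id", "intervention_id", "score"}
    if not required.issubset(df.columns):
        raise ScoreError(f"panel.csv must have columns {sorted(required)}")
    wide = df.pivot(index="rater_id", columns="intervention_id", values="score")
    return PanelScores(matrix=wide.sort_index())


def scoreset_from_dataset(dataset) -> ScoreSet:
    """Build a score set from the benefit scores stored on a dataset."""
    scores = {r.id: float(r.benefit_score) for r in dataset.interventions}
    return validate_scoreset(ScoreSet(scores=scores))
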