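"""Population health benefit (PHB) arithmetic.

PHB is the relative, unitless quantity at the heart of the STAR model:

    number benefiting = people treated per year / NNT
    PHB              = number benefiting x relative benefit score

It is explicitly *not* a QALY and is not comparable across datasets, because
each dataset's scores are anchored to its own benchmark intervention.  The
modelling horizon is one year (the budget-planning period); activity counts
are annual.  A simplifying assumption carried through the whole pipeline is
that each intervention's benefit is independent of the others, so pathway
totals are plain sums.  ``number_benefiting`` is kept as a real number —
flooring to whole people would introduce quantisation the published tables
do not show.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .pathway import ICSDataset
from .valuation import ScoreSet

__all__ = [
    "BenefitResult",
    "number_benefiting",
    "population_health_benefit",
    "pathway_benefits",
    "total_phb",
]


@dataclass(frozen=True)
class BenefitResult:
    intervention_id: str
    n_benefiting: float
    phb: float


def number_benefiting(n_treated: float, nnt: float) -> float:
    """People expected to benefit per year: ``n_treated / nnt``."""
    if n_treated < 0:
        raise ValueError(f"n_treated must be non-negative, got {n_treated}")
    if nnt < 1:
        raise ValueError(f"NNT must be >= 1, got {nnt}")
    return n_treated / nnt


def population_health_benefit(n_benefiting: float, benefit_score: float) -> float:
    """PHB units: number benefiting times the 0–100 relative benefit score."""
    if n_benefiting < 0:
        raise ValueError(f"n_benefiting must be non-negative, got {n_benefiting}")
    if benefit_score < 0:
        raise ValueError(f"benefit_score must be non-negative, got {benefit_score}")
    return n_benefiting * benefit_score


def pathway_benefits(dataset: ICSDataset, scores: ScoreSet) -> list[BenefitResult]:
    """Per-intervention PHB for the baseline pathway.

    Every intervention id must appear in ``scores`` (the valuation step's
    output); a missing score raises ``KeyError`` listing the absent ids.
    Each intervention is valued in isolation (independence assumption).
    """
    missing = [r.id for r in dataset.interventions if r.id not in scores.scores]
    if missing:
        raise KeyError(f"no benefit score for intervention id(s): {missing}")
    results = []
    for rec in dataset.interventions:
        nb = number_benefiting(rec.n_treated, rec.nnt)
        results.append(
            BenefitResult(
                intervention_id=rec.id,
                n_benefiting=nb,
                phb=population_health_benefit(nb, scores[rec.id]),
            )
        )
    return results


def total_phb(results: Iterable[BenefitResult]) -> float:
    """Total pathway PHB: the sum of per-intervention PHB."""
    return sum(r.phb for r in results)
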