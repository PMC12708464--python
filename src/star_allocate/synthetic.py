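"""Synthetic ICS datasets with planted ground truth, and packaged fixtures.

The generator emulates the *structure* of a real ICS COPD dataset — an
anchored 0–100 valuation with exactly one benchmark intervention, NNTs of a
few to a few tens, activity counts spanning hundreds to tens of thousands,
and annual costs spanning several orders of magnitude (hundreds to
millions, driven by log-normal unit costs) — without attempting any
epidemiological realism.  Every generated improvement scenario carries its
latent cost/PHB ratio in ``dataset.extras["latent_cost_phb_ratio"]`` so the
ranking pipeline can be checked against planted truth exactly.

The five packaged fixtures transcribe the published ranked improvement
tables from the STAR COPD pilot in five English integrated care systems;
their baseline intervention lists are empty because only the improvement
tables were published in machine-readable form.  ``population_copd`` in the
fixtures is an indicative round number used for context only.
"""

from __future__ import annotations

from importlib import resources
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .pathway import ICSDataset, ImprovementScenario, InterventionRecord, load_dataset

__all__ = ["GeneratorConfig", "generate_ics", "load_fixture", "FIXTURE_NAMES"]

FIXTURE_NAMES = (
    "birmingham_solihull",
    "coventry_place",
    "gloucestershire",
    "northamptonshire",
    "nottingham_nottinghamshire",
)

# names recycled across generated pathways; COPD-flavoured but arbitrary
_INTERVENTION_POOL = [
    ("smoking cessation (primary prevention)", "prevention"),
    ("smoking cessation (tertiary prevention)", "prevention"),
    ("pulmonary rehabilitation", "community"),
    ("spirometry diagnostic testing", "primary care"),
    ("primary care case management", "primary care"),
    ("primary care management of exacerbations", "primary care"),
    ("community respiratory team", "community"),
    ("virtual ward", "secondary care"),
    ("hospital admissions for AECOPD", "secondary care"),
    ("outpatient respiratory clinics", "secondary care"),
    ("home oxygen service", "community"),
    ("vaccination programme", "prevention"),
    ("psychological support", "community"),
    ("palliative and end-of-life care", "secondary care"),
    ("self-management app", "digital"),
    ("social prescribing", "community"),
]

_IMPROVEMENT_POOL = [
    "expand virtual ward",
    "targeted case finding",
    "increase PR uptake",
    "very brief advice for tobacco dependency",
    "group consultation yearly reviews",
    "digital self-management rollout",
    "post-exacerbation support",
    "community spirometry capacity",
    "social prescribing referral route",
    "awareness campaign",
    "school-based smoking prevention",
    "affordable warmth scheme",
]


class GeneratorConfig(BaseModel):
    """Knobs for :func:`generate_ics`; defaults mirror the study structure."""

    model_config = ConfigDict(frozen=True)

    n_interventions: int = Field(12, ge=1)
    n_improvements: int = Field(8, ge=0)
    population_copd: Optional[int] = Field(None, gt=0)
    nnt_range: tuple[float, float] = (2.0, 40.0)
    score_beta: tuple[float, float] = (2.0, 2.0)
    cost_scale: float = Field(200.0, gt=0, description="median unit cost")
    savings_probability: float = Field(0.5, ge=0, le=1)
    multi_scenario_probability: float = Field(0.3, ge=0, le=1)
    uptake_levels: tuple[float, ...] = (0.10, 0.25, 0.50)
    seed: int = 0

    @model_validator(mode="after")
    def _ranges(self) -> "GeneratorConfig":
        lo, hi = self.nnt_range
        if not (1 <= lo <= hi):
            raise ValueError(f"nnt_range must satisfy 1 <= low <= high, got {self.nnt_range}")
        if any(not (0 < u <= 1) for u in self.uptake_levels):
            raise ValueError("uptake levels must lie in (0, 1]")
        return self


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def generate_ics(config: GeneratorConfig) -> ICSDataset:
    """Generate a valid synthetic dataset; identical seeds give identical data."""
    rng = np.random.default_rng(config.seed)
    population = config.population_copd or int(rng.integers(20_000, 60_001))

    a, b = config.score_beta
    scores = 100.0 * rng.beta(a, b, size=config.n_interventions)
    scores[int(np.argmax(scores))] = 100.0  # the benchmark anchor

    interventions = []
    for i in range(config.n_interventions):
        name, segment = _INTERVENTION_POOL[i % len(_INTERVENTION_POOL)]
        if i >= len(_INTERVENTION_POOL):
            name = f"{name} ({i // len(_INTERVENTION_POOL) + 1})"
        n_treated = int(np.round(rng.lognormal(np.log(1500), 1.0)))
        unit_cost = rng.lognormal(np.log(config.cost_scale), 1.2)
        interventions.append(
            InterventionRecord(
                id=f"iv{i + 1:02d}",
                name=name,
                segment=segment,
                n_treated=n_treated,
                nnt=_log_uniform(rng, *config.nnt_range),
                benefit_score=float(scores[i]),
                annual_cost=round(unit_cost * max(n_treated, 1), 2),
            )
        )

    improvements: list[ImprovementScenario] = []
    latent: dict[str, float] = {}
    for j in range(config.n_improvements):
        imp_id = f"imp{j + 1:02d}"
        name = _IMPROVEMENT_POOL[j % len(_IMPROVEMENT_POOL)]
        base_treated = int(np.round(rng.lognormal(np.log(800), 1.0))) + 1
        nnt = _log_uniform(rng, *config.nnt_range)
        score = float(100.0 * rng.beta(a, b))
        unit_cost = rng.lognormal(np.log(config.cost_scale), 1.2)
        base_gross = unit_cost * base_treated
        if rng.uniform() < config.savings_probability:
            base_savings = base_gross * rng.lognormal(0.0, 0.8)
        else:
            base_savings = 0.0
        if rng.uniform() < config.multi_scenario_probability:
            scales = [(f"{round(u * 100)}% uptake", u) for u in config.uptake_levels]
        else:
            scales = [("base", 1.0)]
        for label, u in scales:
            add = max(1, int(np.round(base_treated * u)))
            gross = round(base_gross * u, 2)
            savings = round(base_savings * u, 2)
            improvements.append(
                ImprovementScenario(
                    improvement_id=imp_id,
                    name=name,
                    scenario_label=label,
                    additional_treated=add,
                    nnt=nnt,
                    benefit_score=score,
                    implementation_cost=gross,
                    offset_savings=savings,
                )
            )
            latent[f"{imp_id}::{label}"] = (gross - savings) / (add / nnt * score)

    return ICSDataset(
        name=f"synthetic_ics_seed{config.seed}",
        population_copd=population,
        currency_label="CUR",
        provenance="synthetic",
        interventions=interventions,
        improvements=improvements,
        extras={"latent_cost_phb_ratio": latent, "generator_seed": config.seed},
    )


def load_fixture(name: str) -> ICSDataset:
    """Load one of the five packaged ICS fixtures by name."""
    if name not in FIXTURE_NAMES:
        raise ValueError(
            f"unknown fixture {name!r}; valid names: {', '.join(FIXTURE_NAMES)}"
        )
    root = resources.files("star_allocate") / "fixtures" / name
    with resources.as_file(root) as path:
        return load_dataset(path, format="csv_bundle")
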