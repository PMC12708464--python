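import pytest
from hypothesis import HealthCheck, settings

from star_allocate import (
    GeneratorConfig,
    ICSDataset,
    ImprovementScenario,
    InterventionRecord,
    generate_ics,
)

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def tiny_dataset() -> ICSDataset:
    """Three baseline interventions and two hand-made improvement scenarios."""
    return ICSDataset(
        name="tiny",
        population_copd=25_000,
        provenance="user",
        interventions=[
            InterventionRecord(
                id="smoking", name="smoking cessation", segment="prevention",
                n_treated=500, nnt=10, benefit_score=100, annual_cost=50_000,
            ),
            InterventionRecord(
                id="pr", name="pulmonary rehabilitation", segment="community",
                n_treated=1000, nnt=8, benefit_score=40, annual_cost=400_000,
            ),
            InterventionRecord(
                id="admissions", name="hospital admissions", segment="secondary care",
                n_treated=2000, nnt=4, benefit_score=60, annual_cost=4_000_000,
            ),
        ],
        improvements=[
            ImprovementScenario(
                improvement_id="expand_pr", name="expand PR", scenario_label="base",
                additional_treated=200, nnt=8, benefit_score=40,
                implementation_cost=90_000, offset_savings=120_000,
            ),
            ImprovementScenario(
                improvement_id="app", name="self-management app", scenario_label="base",
                additional_treated=3000, nnt=20, benefit_score=25,
                implementation_cost=30_000, offset_savings=0,
            ),
        ],
    )


@pytest.fixture
def synthetic_dataset() -> ICSDataset:
    return generate_ics(GeneratorConfig(seed=11, n_interventions=8, n_improvements=6))
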