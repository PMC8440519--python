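import numpy as np
import pytest

from concord.cohort import CohortSpec, PlantedEffect, generate_cohort
from concord.contrast import ChangeCategory


def standard_effect_plan(magnitude: float = 0.8) -> tuple[PlantedEffect, ...]:
    """30 planted effects: 10 common-decrease, 10 common-increase, 5+5 unique."""
    cats = (
        [ChangeCategory.COMMON_DECREASE] * 10
        + [ChangeCategory.COMMON_INCREASE] * 10
        + [ChangeCategory.SZ_UNIQUE_DECREASE] * 5
        + [ChangeCategory.ASD_UNIQUE_DECREASE] * 5
    )
    return tuple(PlantedEffect(i, c, magnitude) for i, c in enumerate(cats))


@pytest.fixture(scope="session")
def multisite_spec() -> CohortSpec:
    """Four SZ-recruiting and two ASD-recruiting datasets, ASD effects halved."""
    return CohortSpec(
        n_per_group_per_dataset=150,
        n_datasets=6,
        n_features=200,
        dataset_kinds=("SZ", "SZ", "SZ", "SZ", "ASD", "ASD"),
        effect_plan=standard_effect_plan(0.8),
        asd_scale=0.5,
        site_shift_sd=0.4,
        age_slope_sd=0.2,
        gender_shift_sd=0.1,
        seed=7,
    )


@pytest.fixture(scope="session")
def multisite_cohort(multisite_spec):
    return generate_cohort(multisite_spec)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
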