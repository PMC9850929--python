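import math

import pytest

from openburn.types import HouseholdRecord


def make_household(hid="H1", persons=6, masses=(1.0, 1.0, 1.0, 1.0),
                   burn=True, **kwargs):
    return HouseholdRecord(
        household_id=hid, persons=persons,
        weekly_masses_kg=tuple(masses), burn_primary=burn, **kwargs,
    )


@pytest.fixture
def two_households():
    return [
        make_household("A", persons=4, masses=(2.0, 1.0, 1.0, 1.0), burn=True),
        make_household("B", persons=2, masses=(4.0, 1.0, 1.0, 1.0), burn=False),
    ]


@pytest.fixture
def default_cohort():
    """Medium synthetic cohort drawn from the default generator spec."""
    from openburn.synthetic_data import SurveyGenSpec, gen_households

    return gen_households(SurveyGenSpec(n_households=1000, seed=11))


@pytest.fixture
def missing_week_household():
    return make_household("M", persons=3, masses=(1.0, math.nan, 2.0, 1.0))
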