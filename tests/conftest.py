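import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pbi_ark import (
    Cohort,
    Respondent,
    ResponseValue,
    Sex,
    SimulationConfig,
    builtin_instrument,
    simulate_cohort,
)
from pbi_ark.instrument import MISSING, NOT_APPLICABLE

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_responses(spec):
    """Build a 19-long response vector from a compact spec.

    ``spec`` maps item id -> int level, "NA", or None; unmentioned items
    default to level 2.
    """
    out = []
    for item_id in range(1, 20):
        v = spec.get(item_id, 2)
        if v == "NA":
            out.append(NOT_APPLICABLE)
        elif v is None:
            out.append(MISSING)
        else:
            out.append(ResponseValue.ordinal(v))
    return tuple(out)


def make_respondent(rid="r1", age=9.0, sex=Sex.MALE, asthma=False,
                    pnq=None, pbq=None, convergent=None):
    return Respondent(
        id=rid,
        age_years=age,
        sex=sex,
        asthma=asthma,
        pnq=make_responses(pnq or {}),
        pbq=make_responses(pbq or {}),
        convergent=convergent or {},
    )


@pytest.fixture(scope="session")
def instrument():
    return builtin_instrument()


@pytest.fixture(scope="session")
def small_children_cohort():
    """Default-condition simulated children cohort, small enough for fast tests."""
    return simulate_cohort(SimulationConfig(n_children=300, n_adolescents=0, seed=11))


@pytest.fixture(scope="session")
def small_mixed_cohort():
    return simulate_cohort(SimulationConfig(n_children=150, n_adolescents=120, seed=23))


@pytest.fixture()
def cohort_factory(instrument):
    def build(respondents):
        return Cohort(instrument, tuple(respondents))

    return build
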