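import numpy as np
import pytest

from cogrisk.cohort import SimConfig, generate_cohort
from cogrisk.scoring import ScoreDefinition, ScoreItem


def toy_items_a():
    return (ScoreItem(name="smoking", kind="binary", points=2.0),
            ScoreItem(name="diabetes", kind="binary", points=1.5))


@pytest.fixture
def toy_definition():
    """Two binary risk items, weights 2.0 and 1.5 (theoretical max 3.5)."""
    return ScoreDefinition(name="toy", items=toy_items_a())


@pytest.fixture
def toy_definition_b():
    return ScoreDefinition(name="toy_b", items=(
        ScoreItem(name="smoking", kind="binary", points=1.0),
        ScoreItem(name="diabetes", kind="binary", points=4.0),
        ScoreItem(name="hypertension", kind="binary", points=0.5)))


def random_profiles(rng, n, item_names, missing_rate=0.2):
    """Random binary profiles with some missing entries."""
    profiles = []
    for _ in range(n):
        prof = {}
        for name in item_names:
            u = rng.random()
            if u < missing_rate:
                prof[name] = None
            else:
                prof[name] = float(rng.integers(0, 2))
        profiles.append(prof)
    return profiles


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-sized cohort under the default study conditions."""
    return generate_cohort(SimConfig(n_participants=1500, seed=424242))


@pytest.fixture
def clean_config():
    """No attrition, no missingness: every stage sees complete data."""
    return SimConfig(n_participants=500, seed=7, attrition_coefficients={},
                     item_missingness_rates={})
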