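"""Shared fixtures: small hand-built registries and rate tables."""

import pandas as pd
import pytest

from famsir.exposure import RateTable
from famsir.registry import RegistryConfig


def persons_frame(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "family_id", "role", "sex", "race_ethnicity", "birth_year"]
    )


def events_frame(rows):
    return pd.DataFrame(
        rows, columns=["person_id", "diagnosis_year", "iccc3_group", "subtype_label", "sequence"]
    )


@pytest.fixture
def config():
    return RegistryConfig()


@pytest.fixture
def toy_family():
    """One family: proband (dx 2000), healthy sibling, mother."""
    persons = persons_frame(
        [
            ("c1", "f1", "child", "male", "latino", 1990),
            ("c2", "f1", "child", "female", "latino", 1992),
            ("m1", "f1", "mother", "female", "latino", 1970),
        ]
    )
    events = events_frame([("c1", 2000, "I", "lymphoid", 1)])
    return persons, events


@pytest.fixture
def flat_rates():
    """Rate table constant at 1e-3 per person-year across all layers."""
    return RateTable.flat(
        1e-3,
        outcomes=("any", "hematologic", "solid") + tuple(
            g for g in "I II III IV V VI VII VIII IX X XI XII".split()
        ),
    )
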