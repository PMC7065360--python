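"""Shared fixtures: a seeded tomato-like experiment and its smoothed form.

Everything is generated programmatically; session scope keeps the heavier
smoothing work to one pass.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import setgrowth as sg

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")

ENDPOINTS = (18, 22, 27, 33, 39, 43, 51)


def make_ds(records, factors=(), block=None, traits=("PSA",)):
    """Small hand-built dataset from a list of dicts."""
    return sg.LongitudinalDataset(
        data=pd.DataFrame(records),
        subject="subject",
        time="DAP",
        block=block,
        factors=factors,
        traits=traits,
    )


@pytest.fixture
def simple_ds():
    """One subject, irregular grid, exact values for GR arithmetic."""
    rows = [
        {"subject": "c1", "DAP": 1, "PSA": 2.0},
        {"subject": "c1", "DAP": 2, "PSA": 4.0},
        {"subject": "c1", "DAP": 4, "PSA": 8.0},
    ]
    return make_ds(rows)


@pytest.fixture(scope="session")
def tomato():
    """Default synthetic tomato-like experiment plus ground truth."""
    ds, truth = sg.generate_experiment(sg.SimConfig(seed=42))
    return ds, truth


@pytest.fixture(scope="session")
def tomato_gr(tomato):
    ds, _ = tomato
    return sg.derive_continuous_gr(ds, "PSA")


@pytest.fixture(scope="session")
def smoothed_log6(tomato_gr):
    return sg.smooth_dataset(
        tomato_gr, "PSA", sg.SmoothingScheme(scale="log", df=6.0)
    )


@pytest.fixture(scope="session")
def trait_table(smoothed_log6):
    return sg.extract_traits(
        smoothed_log6, sg.IntervalSpec(ENDPOINTS), include_endpoint_gr=False
    )
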