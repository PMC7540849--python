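"""Shared fixtures: one simulated experiment at the published scale."""

import pytest

from pasturepheno.experiment_design import generate_design
from pasturepheno.mixed_model import ModelSpec, fit_trait
from pasturepheno.set_smoothing import aggregate_psa_table, smooth_table, traits_table
from pasturepheno.synthetic_data import default_params, simulate


@pytest.fixture(scope="session")
def design10():
    return generate_design(10, seed=101)


@pytest.fixture(scope="session")
def sim10(design10):
    return simulate(design10, default_params(), seed=202)


@pytest.fixture(scope="session")
def traits10(sim10):
    agg, _ = aggregate_psa_table(sim10.psa)
    return traits_table(smooth_table(agg))


@pytest.fixture(scope="session")
def ag_fit(design10, traits10):
    return fit_trait(design10.table, traits10, ModelSpec(response="AG", variance_model="full"))
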