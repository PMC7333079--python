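"""Shared fixtures: a reference model, a small synthetic cohort, fitted distributions."""

import numpy as np
import pytest

from gaitaug.cycles import table_to_cycles
from gaitaug.msk.params import Anthropometry, scale_model
from gaitaug.sampler import assemble_cycle_vector, fit_distribution
from gaitaug.synth import generate_dataset


@pytest.fixture(scope="session")
def model75():
    """Reference subject: 75 kg, 1.75 m."""
    return scale_model(Anthropometry(75.0, 1.75))


@pytest.fixture(scope="session")
def small_dataset():
    """Four subjects, three trials per band (72 cycles) - enough for every stage."""
    return generate_dataset(n_subjects=4, trials_per_band=3, seed=7)


@pytest.fixture(scope="session")
def small_cycles(small_dataset):
    return table_to_cycles(small_dataset)


@pytest.fixture(scope="session")
def walk_fit(small_cycles):
    """(distribution, model) fitted on subject S04's walking cycles."""
    cyc = [c for c in small_cycles if c.subject_id == "S04" and c.gait == "walk"]
    Z = np.stack([assemble_cycle_vector(c) for c in cyc])
    dist = fit_distribution(Z, "S04", "walk")
    model = scale_model(Anthropometry(cyc[0].bw, cyc[0].bh))
    return dist, model


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
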