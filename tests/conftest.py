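"""Shared fixtures: configurations, cohorts, and a reference twin."""

from __future__ import annotations

import numpy as np
import pytest

import patchtwin as pt
from patchtwin.config import default_config
from patchtwin.parameters import assemble_twin


@pytest.fixture(scope="session")
def config() -> dict:
    return default_config()


@pytest.fixture(scope="session")
def config_novar(config) -> dict:
    """Default configuration with inter-individual variability off."""
    cfg = {**config, "variability": {"sd_theta": 0.0}}
    return cfg


@pytest.fixture(scope="session")
def sample_cohort():
    return pt.generate_sample_cohort(seed=1, n=20)


@pytest.fixture(scope="session")
def small_population(sample_cohort):
    """Reduced-size Gibbs population for unit tests (full size is exercised
    by the acceptance suite)."""
    cfg = pt.GibbsConfig(n_burn=2_000, n_keep=400, seed=2)
    return pt.gibbs_sample_population(sample_cohort, cfg)


@pytest.fixture(scope="session")
def patient_one() -> pt.PatientProfile:
    """The 58-year-old male reference patient (74.2 kg, 1.73 m)."""
    return pt.PatientProfile(age=58, gender=1, weight=74.2, height=1.73)


@pytest.fixture(scope="session")
def twin_nominal(patient_one, config_novar):
    """Reference twin with every parameter at its deterministic value."""
    return assemble_twin(patient_one, config_novar, 0)


@pytest.fixture(scope="session")
def fast_numerics(config) -> dict:
    """Coarser grid for controller-logic tests where spatial accuracy is
    immaterial."""
    return {**config["numerics"], "n_cells_per_layer": [10, 6, 6, 10]}


@pytest.fixture(scope="session")
def twin_result(twin_nominal, config):
    """One full twin-assisted simulation of the reference patient."""
    policy = pt.TherapyPolicy(kind="twin_assisted", check_interval_h=8.0)
    return pt.run_simulation(twin_nominal, policy, config["numerics"])


@pytest.fixture(scope="session")
def conventional_result(twin_nominal, config):
    policy = pt.TherapyPolicy(kind="conventional")
    return pt.run_simulation(twin_nominal, policy, config["numerics"])
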