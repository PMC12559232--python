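"""Shared fixtures: calibrated presets and the default labeled dataset.

Calibration and dataset generation are expensive (minutes of ODE solves),
so they are computed once per session and shared by the unit, property
and acceptance tests.
"""

import pytest

from rosvgic.dataset import DatasetSpec, generate_dataset
from rosvgic.presets import get_preset
from rosvgic.simulator import calibrate_preset, run_open_loop
from rosvgic.stressors import standard_protocol


@pytest.fixture(scope="session")
def calibrated_hela():
    return calibrate_preset(get_preset("HELA"))


@pytest.fixture(scope="session")
def calibrated_gbm():
    return calibrate_preset(get_preset("GBM"))


@pytest.fixture(scope="session")
def calibrated_mda():
    return calibrate_preset(get_preset("MDA_MB_231"))


@pytest.fixture(scope="session")
def calibrated_mcf10a():
    return calibrate_preset(get_preset("MCF10A"))


@pytest.fixture(scope="session")
def calibrated_fibroblast():
    return calibrate_preset(get_preset("FIBROBLAST"))


@pytest.fixture(scope="session")
def hela_standard_run(calibrated_hela):
    return run_open_loop(calibrated_hela, standard_protocol(1.0))


@pytest.fixture(scope="session")
def default_dataset():
    """The benchmark dataset: 250 trajectories per class, CV 0.10, seed 42."""
    return generate_dataset(DatasetSpec(n_per_class=250, jitter_cv=0.10, seed=42))
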