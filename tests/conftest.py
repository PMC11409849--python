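import dataclasses

import numpy as np
import pytest

import synthlung as sl


@pytest.fixture(scope="session")
def default_series():
    """One full-size phantom with matched noiseless frames (seed 7)."""
    return sl.generate_series(sl.PhantomConfig(seed=7), keep_noiseless=True)


@pytest.fixture(scope="session")
def noiseless_series():
    return sl.generate_series(sl.PhantomConfig(seed=7, noise=False))


@pytest.fixture(scope="session")
def small_config():
    """Reduced temporal sampling for fast orchestration tests."""
    return sl.PhantomConfig(seed=3, time=sl.TimeGrid(n_frames=50, dt=0.192))


@pytest.fixture(scope="session")
def experiment_report():
    """The full repeated-phantom validation run (20 phantoms, REF)."""
    from synthlung.experiment import run_experiment

    return run_experiment(sl.ExperimentConfig(n_phantoms=20, base_seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def class_map():
    return sl.build_base_geometry(sl.GridSpec(), sl.LayoutConfig())


@pytest.fixture()
def seeded_map(class_map, rng):
    return sl.seed_defect_clusters(class_map, rng=rng)


def make_phantom_config(**kwargs) -> sl.PhantomConfig:
    base = sl.PhantomConfig()
    return dataclasses.replace(base, **kwargs)
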