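import numpy as np
import pytest

from astromorph import SimulationConfig, make_benchmark, simulate_sample


@pytest.fixture(scope="session")
def default_cfg() -> SimulationConfig:
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_sample(default_cfg):
    """One rendered sample of the default benchmark: (grid, labels, cells)."""
    return simulate_sample(default_cfg, 11)


@pytest.fixture(scope="session")
def benchmark_dir(tmp_path_factory, default_cfg):
    """The default 7-sample benchmark (5 train / 2 test), written to disk."""
    out = tmp_path_factory.mktemp("benchmark")
    make_benchmark(default_cfg, out, seed=7)
    return out


@pytest.fixture()
def tiny_cfg() -> SimulationConfig:
    """A small, fast configuration for smoke tests."""
    return SimulationConfig(
        n_slices=16,
        z_step_um=1.0,
        field_um=60.0,
        lateral_px=100,
        n_cells=2,
        min_separation_um=24.0,
        placement_margin_um=16.0,
        soma_radius_um=(4.0, 4.5),
        n_branches=4,
        branch_jitter=0,
        branch_length_um=(6.0, 9.0),
        bifurcation_prob=0.0,
        n_samples=2,
        n_train=1,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
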