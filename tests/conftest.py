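import numpy as np
import pytest

from nanocolloid import (
    Box,
    SimulationConfig,
    TwoYukawaPotential,
    YukawaTerm,
    run_mc,
)

SIGMA = 7.0  # nm, core + ligand shell contact distance


@pytest.fixture(scope="session")
def hard_sphere_frames():
    """Equilibrated hard-sphere frames at phi = 0.10 in a periodic cube."""
    n = 128
    phi = 0.10
    L = (n * (np.pi / 6.0) * SIGMA**3 / phi) ** (1.0 / 3.0)
    cfg = SimulationConfig(
        n_particles=n, box=Box.cube(L),
        potential=TwoYukawaPotential.hard_sphere(SIGMA),
        n_sweeps_equilibration=200, n_sweeps_production=400,
        sample_interval=20, max_displacement=2.0, seed=42)
    frames, stats = run_mc(cfg)
    return frames, stats, cfg


@pytest.fixture()
def attractive_potential():
    """Moderate short-range attraction + weak long-range repulsion."""
    return TwoYukawaPotential(SIGMA, YukawaTerm(2.0, 8.0), YukawaTerm(-0.5, 1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
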