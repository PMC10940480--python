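import numpy as np
import pytest

from fiberperm import (
    BundleLayout,
    FiberSpec,
    SolverSettings,
    build_preset,
    build_unit_cell,
)

D = 380.0
PITCH = 500.0


@pytest.fixture(scope="session")
def ortho_cell():
    return build_unit_cell(FiberSpec(D, 50), BundleLayout("orthogonal", PITCH))


@pytest.fixture(scope="session")
def angled_cell():
    return build_unit_cell(FiberSpec(D, 50), BundleLayout("angled", PITCH, 20.0))


@pytest.fixture(scope="session")
def coarse_ortho_grid(ortho_cell):
    """d/20 grid of the orthogonal reference cell (fast flow solves)."""
    from fiberperm import enforce_min_gap, voxelize

    return enforce_min_gap(voxelize(ortho_cell, D / 20), 1.0)


@pytest.fixture(scope="session")
def tight_settings():
    return SolverSettings(residual_tolerance=1e-7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)
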