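import numpy as np
import pytest

from simsentry import DGMSpec, default_specs
from simsentry.engine import RunPlan, run_study


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def mcar_spec():
    return default_specs()[0]


@pytest.fixture(scope="session")
def mar_spec():
    return default_specs()[1]


@pytest.fixture(scope="session")
def mnar_spec():
    return default_specs()[2]


@pytest.fixture(scope="session")
def smoke_study():
    """A 3-repetition run of all three mechanisms with stored data sets."""
    plan = RunPlan(n_sim=3, seed=7, store_datasets=True)
    return run_study(plan)


@pytest.fixture(scope="session")
def medium_study():
    """100 repetitions of the MCAR mechanism, all three methods."""
    plan = RunPlan(dgm_specs=[default_specs()[0]], n_sim=100, seed=11)
    return run_study(plan)


def grid_maximize(objective, n_params, half_width=10.0, n_points=13, n_zoom=10):
    """Brute-force maximization of an objective on a shrinking grid.

    Independent oracle for the likelihood-based fits: evaluates the
    objective on a full factorial grid, re-centres on the best point and
    shrinks, achieving ~1e-4 precision for up to 3 parameters.
    """
    centre = np.zeros(n_params)
    h = half_width
    best = None
    for _ in range(n_zoom):
        axes = [np.linspace(c - h, c + h, n_points) for c in centre]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.column_stack([m.ravel() for m in mesh])
        vals = np.array([objective(p) for p in pts])
        i = int(np.argmax(vals))
        centre, best = pts[i], vals[i]
        h *= 0.35
    return centre, best
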