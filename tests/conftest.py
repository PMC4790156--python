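import numpy as np
import pytest

from confcount.discretize import ConformerDefinition, DihedralTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)


@pytest.fixture
def random_traj(rng):
    """200 snapshots x 5 torsions of uniform random angles."""
    angles = rng.uniform(-180.0, 180.0, size=(200, 5))
    return DihedralTrajectory(angles, source="fixture:uniform")


@pytest.fixture
def injective_traj():
    """Every snapshot is its own conformer: torsions 1..6 enumerate all
    3**6 base-3 patterns (angles at arc centers), torsion 0 sweeps the circle
    as an order parameter.  The exact-ISWD limit by construction."""
    n = 3**6
    digits = np.array([[(k // 3**j) % 3 for j in range(6)] for k in range(n)])
    arc_centers = np.array([-120.0, 0.0, 120.0])
    angles = np.empty((n, 7))
    angles[:, 0] = -179.0 + 358.0 * np.arange(n) / (n - 1)
    angles[:, 1:] = arc_centers[digits]
    return DihedralTrajectory(angles, source="fixture:injective")


@pytest.fixture
def injective_conf_def():
    return ConformerDefinition("fine6", tuple(range(1, 7)))
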