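import numpy as np
import pytest

from carbonyl_nci.nci_classify import NCIThresholds, inventory_structure
from carbonyl_nci.synthetic_data import (
    BuildSpec,
    build_motif_fixture,
    build_peptide,
)


@pytest.fixture(scope="session")
def thresholds():
    return NCIThresholds()


@pytest.fixture(scope="session")
def helix20():
    return build_peptide(BuildSpec(template="alpha_helix", n_res=20))


@pytest.fixture(scope="session")
def helix20_inventory(helix20, thresholds):
    return inventory_structure(helix20, thresholds)


@pytest.fixture(scope="session")
def sheet8():
    """Two-strand ideal antiparallel sheet (the rigid fit is the slow part;
    build once per session)."""
    return build_peptide(BuildSpec(template="antiparallel_sheet", n_res=8))


@pytest.fixture(scope="session")
def solvated_extended():
    return build_peptide(
        BuildSpec(template="extended", n_res=8, solvation="exposed_carbonyls")
    )


@pytest.fixture(scope="session")
def motif_fixtures():
    return {
        name: build_motif_fixture(name)
        for name in ("M1", "M2_bifurcated", "M3_capping", "water_only", "undersatisfied")
    }


def random_rigid_motion(rng):
    """A uniformly random rotation matrix plus a random translation."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )
    t = rng.normal(scale=10.0, size=3)
    return R, t


def apply_rigid(structure, R, t):
    moved = structure.copy()
    for a in moved.all_atoms():
        a.xyz = R @ a.xyz + t
    return moved
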