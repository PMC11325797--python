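import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from switch_allostery import (
    ContactPlant,
    HBondPlant,
    Trajectory,
    TrajectorySpec,
    generate_trajectory,
    load_regions,
    toy_ligand_selection,
    toy_structure,
)


@pytest.fixture(scope="session")
def toy_top():
    return toy_structure()


@pytest.fixture(scope="session")
def regions():
    return load_regions()


@pytest.fixture(scope="session")
def ligand():
    return toy_ligand_selection()


@pytest.fixture(scope="session")
def planted_traj():
    """Shared 500-frame trajectory with one H-bond and one contact plant."""
    spec = TrajectorySpec(
        n_frames=500,
        fluctuation_sd=0.1,
        hbond_plants=[HBondPlant(205, 230, 0.8)],
        contact_plants=[ContactPlant(52, "a", 0.6)],
        seed=11,
    )
    return generate_trajectory(spec)


def static_trajectory(structure, n_frames=10):
    return Trajectory(structure, np.repeat(structure.coordinates[None], n_frames, axis=0))
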