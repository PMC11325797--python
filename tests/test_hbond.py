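"""Geometric H-bond detection, occupancy matrices, tiers, and comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from scipy.spatial.transform import Rotation

from oracles import hbond_counts
from switch_allostery import (
    HBondCriteria,
    HBondPlant,
    RegionDefinition,
    Trajectory,
    TrajectorySpec,
    compare_networks,
    detect_hbonds_frame,
    generate_trajectory,
    hbond_occupancy,
    persistence_tiers,
)
from switch_allostery.errors import (
    ComparisonError,
    ConfigError,
    NoHydrogensError,
)
from switch_allostery.structures import Structure

REGION_1 = RegionDefinition("donor_side", (1,))
REGION_2 = RegionDefinition("acceptor_side", (2,))


def _two_residue_system(ho_distance, angle_deg):
    """Residue 1: N-H donor; residue 2: lone O acceptor placed so that the
    H...O distance and N-H...O angle take the requested values."""
    n = np.array([0.0, 0.0, 0.0])
    h = np.array([0.0, 1.0, 0.0])
    theta = np.radians(180.0 - angle_deg)
    o = h + ho_distance * np.array([np.sin(theta), np.cos(theta), 0.0])
    return Structure(
        ["N", "H", "O"],
        ["N", "H", "O"],
        [1, 1, 2],
        ["GLY", "GLY", "GLY"],
        ["A", "A", "A"],
        np.array([n, h, o]),
    )


@pytest.mark.parametrize(
    "distance,angle,expected",
    [
        (2.0, 180.0, True),   # satisfies both cutoffs
        (2.5, 180.0, False),  # too long
        (2.0, 110.0, False),  # too bent
        (2.39, 121.0, True),  # just inside both
        (2.4, 150.0, False),  # boundary: strict < on distance
        (2.0, 119.9, False),  # just below the angle cutoff
    ],
)
def test_detection_against_constructed_geometry(distance, angle, expected):
    s = _two_residue_system(distance, angle)
    found = detect_hbonds_frame(s, s.coordinates, REGION_1, REGION_2)
    assert bool(found) is expected
    if expected:
        assert found == {(0, 1, 2)}


def test_detection_evaluates_both_directions():
    s = _two_residue_system(2.0, 180.0)
    # swap region roles: donor residue 1 still found via the (B, A) pass
    found = detect_hbonds_frame(s, s.coordinates, REGION_2, REGION_1)
    assert found == {(0, 1, 2)}


def test_no_hydrogens_is_an_explicit_error():
    s = Structure(["N", "O"], ["N", "O"], [1, 2], ["GLY", "GLY"], ["A", "A"],
                  np.array([[0.0, 0, 0], [2.0, 0, 0]]))
    with pytest.raises(NoHydrogensError):
        detect_hbonds_frame(s, s.coordinates, REGION_1, REGION_2)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(hst.integers(0, 2**16))
def test_detection_invariant_under_rigid_motion(seed):
    s = _two_residue_system(2.2, 150.0)
    rng = np.random.default_rng(seed)
    R = Rotation.from_euler("xyz", rng.uniform(-180, 180, 3), degrees=True)
    moved = s.coordinates @ R.as_matrix().T + rng.uniform(-50, 50, 3)
    assert detect_hbonds_frame(s, moved, REGION_1, REGION_2) == {(0, 1, 2)}


def test_occupancy_counts_planted_bond(planted_traj, regions):
    traj, ledger = planted_traj
    mat = hbond_occupancy(traj, regions["switch_I"], regions["switch_II"])
    planted = ledger["hbond_plants"][0]
    assert mat.occupancy(205, "N", 230, "O") == pytest.approx(planted["realized"])
    assert mat.residue_entries[(205, 230)] == pytest.approx(planted["realized"])
    assert mat.n_frames == traj.n_frames
    assert all(0.0 <= v <= 1.0 for v in mat.entries.values())


def test_occupancy_is_frame_weighted_mean_over_concatenation(regions):
    spec = TrajectorySpec(
        n_frames=200, hbond_plants=[HBondPlant(205, 230, 0.5)], seed=21
    )
    traj, _ = generate_trajectory(spec)
    a = Trajectory(traj.topology, traj.frames[:80])
    b = Trajectory(traj.topology, traj.frames[80:])
    full = hbond_occupancy(traj, regions["switch_I"], regions["switch_II"])
    part_a = hbond_occupancy(a, regions["switch_I"], regions["switch_II"])
    part_b = hbond_occupancy(b, regions["switch_I"], regions["switch_II"])
    for key, occ in full.entries.items():
        combined = (
            part_a.entries.get(key, 0.0) * 80 + part_b.entries.get(key, 0.0) * 120
        ) / 200
        assert occ == pytest.approx(combined, abs=1e-12)


def test_occupancy_matches_bruteforce_oracle(regions):
    spec = TrajectorySpec(
        n_frames=120,
        fluctuation_sd=0.6,
        hbond_plants=[HBondPlant(205, 230, 0.5), HBondPlant(227, 259, 0.7)],
        seed=33,
    )
    traj, _ = generate_trajectory(spec)
    for pair in (("switch_I", "switch_II"), ("switch_II", "switch_III")):
        a, b = regions[pair[0]], regions[pair[1]]
        mat = hbond_occupancy(traj, a, b)
        atom_counts, res_counts = hbond_counts(traj.topology, traj.frames, a, b)
        assert {k: round(v * traj.n_frames) for k, v in mat.entries.items()} == atom_counts
        assert {k: round(v * traj.n_frames) for k, v in mat.residue_entries.items()} == res_counts


@pytest.mark.parametrize(
    "occ,expected",
    [(0.6, 2), (0.5, 2), (0.75, 3), (0.3, 1), (1.0, 3)],
)
def test_persistence_tiers_inclusive_thresholds(occ, expected):
    mat = _matrix_with(occ)
    tiers = persistence_tiers(mat, (0.25, 0.5, 0.75))
    assert tiers[(1, "N", 2, "O")] == expected


def test_persistence_tiers_excludes_below_lowest():
    tiers = persistence_tiers(_matrix_with(0.2), (0.25, 0.5, 0.75))
    assert tiers == {}


def test_persistence_tiers_rejects_bad_thresholds():
    mat = _matrix_with(0.5)
    for bad in ((0.5, 0.25), (0.0, 0.5), (0.25, 0.25)):
        with pytest.raises(ConfigError):
            persistence_tiers(mat, bad)


def _matrix_with(occ, region_pair=("switch_I", "switch_II")):
    from switch_allostery.hbond import HBondOccupancyMatrix

    return HBondOccupancyMatrix(
        region_pair=region_pair,
        n_frames=100,
        criteria=HBondCriteria(),
        entries={(1, "N", 2, "O"): occ},
        residue_entries={(1, 2): occ},
    )


def test_compare_networks_classifies_gained_lost_shared():
    a = _matrix_with(0.9)
    b = _matrix_with(0.1)
    b.entries[(3, "N", 4, "O")] = 0.8
    b.residue_entries[(3, 4)] = 0.8
    comp = compare_networks(a, b, threshold=0.5)
    assert comp.lost == {(1, 2)}
    assert comp.gained == {(3, 4)}
    assert comp.shared == frozenset()


def test_compare_identical_matrices_is_empty_delta():
    a = _matrix_with(0.9)
    comp = compare_networks(a, a, threshold=0.5)
    assert comp.gained == comp.lost == frozenset()
    assert comp.shared == {(1, 2)}


def test_compare_networks_rejects_mismatched_regions():
    a = _matrix_with(0.9)
    b = _matrix_with(0.9, region_pair=("switch_II", "switch_III"))
    with pytest.raises(ComparisonError):
        compare_networks(a, b)


def test_criteria_validation():
    with pytest.raises(ConfigError):
        HBondCriteria(max_ha_distance=-1.0)
    with pytest.raises(ConfigError):
        HBondCriteria(min_dha_angle=200.0)
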