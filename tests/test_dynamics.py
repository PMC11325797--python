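"""RMSF and nonbonded interaction energies."""

import numpy as np
import pandas as pd
import pytest

from switch_allostery import (
    COULOMB_CONSTANT,
    NonbondedParams,
    RegionDefinition,
    Trajectory,
    compute_rmsf,
    nonbonded_energy,
    normalize_energies,
    toy_structure,
)
from switch_allostery.errors import (
    EmptyInputError,
    NormalizationError,
    ParameterizationError,
    UsageError,
)
from switch_allostery.structures import Structure


def _static(top, n=5):
    return Trajectory(top, np.repeat(top.coordinates[None], n, axis=0))


def test_rmsf_zero_for_static_trajectory(toy_top):
    prof = compute_rmsf(_static(toy_top))
    assert all(v == 0.0 for v in prof.per_residue.values())


def test_rmsf_single_frame_warns_and_is_zero(toy_top):
    with pytest.warns(UserWarning):
        prof = compute_rmsf(Trajectory(toy_top, toy_top.coordinates[None]))
    assert all(v == 0.0 for v in prof.per_residue.values())


def test_rmsf_two_frame_closed_form(toy_top):
    d = 0.7
    lo = toy_top.coordinates.copy()
    hi = toy_top.coordinates.copy()
    lo[:, 0] -= d
    hi[:, 0] += d
    prof = compute_rmsf(Trajectory(toy_top, np.stack([lo, hi])))
    for v in prof.per_residue.values():
        assert v == pytest.approx(d, abs=1e-12)


def test_rmsf_gaussian_analytic_expectation(toy_top):
    # E[RMSF] for iid Gaussian displacement of per-coordinate SD s is s*sqrt(3)
    rng = np.random.default_rng(5)
    s = 0.5
    frames = toy_top.coordinates[None] + rng.normal(
        scale=s, size=(4000, toy_top.n_atoms, 3)
    )
    prof = compute_rmsf(Trajectory(toy_top, frames))
    expected = s * np.sqrt(3.0)
    for v in prof.per_atom.values():
        assert abs(v - expected) / expected < 0.05


def test_rmsf_invariant_under_uniform_rigid_shift(toy_top):
    rng = np.random.default_rng(6)
    frames = toy_top.coordinates[None] + rng.normal(
        scale=0.3, size=(50, toy_top.n_atoms, 3)
    )
    base = compute_rmsf(Trajectory(toy_top, frames))
    shifted = compute_rmsf(Trajectory(toy_top, frames + np.array([5.0, -3.0, 2.0])))
    for r in base.per_residue:
        assert shifted.per_residue[r] == pytest.approx(base.per_residue[r], abs=1e-9)


def test_rmsf_empty_selection_errors(toy_top):
    with pytest.raises(EmptyInputError):
        compute_rmsf(_static(toy_top), atom_names=["XX"])


# ---------------------------------------------------------------------------
# nonbonded energies
# ---------------------------------------------------------------------------

def _point_charge_system(r, q1=1.0, q2=1.0, sigma=0.0, eps=0.0):
    s = Structure(
        ["Q1", "Q2"], ["X", "X"], [1, 2], ["ION", "ION"], ["A", "A"],
        np.array([[0.0, 0, 0], [r, 0, 0]]),
    )
    params = NonbondedParams(pd.DataFrame({
        "residue_name": ["ION", "ION"],
        "atom_name": ["Q1", "Q2"],
        "charge": [q1, q2],
        "sigma": [sigma, sigma],
        "epsilon": [eps, eps],
    }))
    return s, params


def test_coulomb_closed_form_unit_charges_at_10A():
    s, params = _point_charge_system(10.0)
    traj = Trajectory(s, s.coordinates[None])
    e = nonbonded_energy(
        traj, RegionDefinition("a", (1,)), RegionDefinition("b", (2,)), params
    )
    assert e == pytest.approx(COULOMB_CONSTANT / 10.0, abs=1e-6)
    assert e == pytest.approx(33.20636, abs=1e-4)


def test_zero_charges_zero_epsilon_gives_zero():
    s, params = _point_charge_system(5.0, q1=0.0, q2=0.0)
    traj = Trajectory(s, s.coordinates[None])
    e = nonbonded_energy(
        traj, RegionDefinition("a", (1,)), RegionDefinition("b", (2,)), params
    )
    assert e == 0.0


def test_lj_vanishes_at_sigma():
    s, params = _point_charge_system(3.4, q1=0.0, q2=0.0, sigma=3.4, eps=0.2)
    traj = Trajectory(s, s.coordinates[None])
    e = nonbonded_energy(
        traj, RegionDefinition("a", (1,)), RegionDefinition("b", (2,)), params
    )
    assert e == pytest.approx(0.0, abs=1e-10)


def test_energy_symmetric_and_additive_over_frames(toy_top, regions):
    rng = np.random.default_rng(7)
    frames = toy_top.coordinates[None] + rng.normal(
        scale=0.2, size=(40, toy_top.n_atoms, 3)
    )
    traj = Trajectory(toy_top, frames)
    params = NonbondedParams.bundled_minimal()
    a, b = regions["switch_I"], regions["switch_II"]
    e_ab = nonbonded_energy(traj, a, b, params)
    e_ba = nonbonded_energy(traj, b, a, params)
    assert e_ab == pytest.approx(e_ba, rel=1e-12)
    first = nonbonded_energy(Trajectory(toy_top, frames[:15]), a, b, params)
    second = nonbonded_energy(Trajectory(toy_top, frames[15:]), a, b, params)
    assert e_ab == pytest.approx((first * 15 + second * 25) / 40, rel=1e-12)


def test_energy_decays_at_long_range():
    # two charge-neutral dipolar groups: interaction ~ 1/r^3 at long range
    coords = np.array([
        [0.0, 0.0, 0.0], [0.0, 1.0, 0.0],       # group 1: +q, -q
        [3.0, 0.0, 0.0], [3.0, 1.0, 0.0],       # group 2: +q, -q
    ])
    s = Structure(
        ["P", "M", "P", "M"], ["X"] * 4, [1, 1, 2, 2],
        ["DIP"] * 4, ["A"] * 4, coords,
    )
    params = NonbondedParams(pd.DataFrame({
        "residue_name": ["DIP", "DIP"], "atom_name": ["P", "M"],
        "charge": [0.4, -0.4], "sigma": [3.2, 3.2], "epsilon": [0.1, 0.1],
    }))
    ga, gb = RegionDefinition("a", (1,)), RegionDefinition("b", (2,))
    near = nonbonded_energy(Trajectory(s, coords[None]), ga, gb, params)
    far_coords = coords.copy()
    far_coords[2:, 0] += 97.0
    far = nonbonded_energy(Trajectory(s, far_coords[None]), ga, gb, params)
    assert abs(far) < 1e-3 * abs(near)


def test_missing_parameters_listed(toy_top, regions):
    params = NonbondedParams(pd.DataFrame({
        "residue_name": ["*"], "atom_name": ["N"],
        "charge": [-0.5], "sigma": [3.25], "epsilon": [0.17],
    }))
    with pytest.raises(ParameterizationError) as err:
        nonbonded_energy(
            _static(toy_top), regions["switch_I"], regions["switch_II"], params
        )
    assert ("SER", "CA") in err.value.missing


def test_overlapping_groups_rejected(toy_top):
    params = NonbondedParams.bundled_minimal()
    with pytest.raises(UsageError):
        nonbonded_energy(
            _static(toy_top),
            RegionDefinition("a", (205, 227)),
            RegionDefinition("b", (227,)),
            params,
        )


def test_normalize_energies_reference_maps_to_one():
    table = pd.DataFrame({
        "system": ["WT", "WT", "VAR", "VAR"],
        "region_pair": ["I|II", "II|III", "I|II", "II|III"],
        "energy": [-40.0, -10.0, -20.0, -5.0],
    })
    out = normalize_energies(table, "WT")
    by = {(r.system, r.region_pair): r.normalized for r in out.itertuples()}
    assert by[("WT", "I|II")] == 1.0
    assert by[("WT", "II|III")] == 1.0
    assert by[("VAR", "I|II")] == 0.5
    assert by[("VAR", "II|III")] == 0.5


def test_normalize_energies_zero_reference_errors():
    table = pd.DataFrame({
        "system": ["WT", "VAR"], "region_pair": ["I|II", "I|II"],
        "energy": [1e-12, -5.0],
    })
    with pytest.raises(NormalizationError):
        normalize_energies(table, "WT")
    with pytest.raises(NormalizationError):
        normalize_energies(table, "MISSING")
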