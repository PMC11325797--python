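"""Per-residue RMSF and group-wise nonbonded interaction energies.

RMSF follows the standard definition: per atom, the root-mean-square deviation
from that atom's trajectory-mean position; per residue, the unweighted mean
over its backbone atoms (N, CA, C, O). The trajectory should be superposed on
the analysis selection first so rigid-body motion does not inflate the result.

Nonbonded energies are bare pairwise sums over inter-group atom pairs of a
Coulomb term k_e·q_i·q_j/r (k_e = 332.0636 kcal·Å/mol/e²) and a 12-6
Lennard-Jones term, averaged over frames. No cutoff or solvent screening is
applied: group sizes are small and the downstream quantity of interest is the
ratio to a reference system, not the absolute energy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    ConfigError,
    EmptyInputError,
    NormalizationError,
    ParameterizationError,
    UsageError,
)
from .structures import BACKBONE_ATOM_NAMES, RegionDefinition, Structure, Trajectory

COULOMB_CONSTANT = 332.0636  # kcal * A / (mol * e^2)


@dataclass
class RMSFProfile:
    per_residue: dict
    per_atom: dict
    atom_names: tuple
    n_frames: int

    def as_series(self) -> pd.Series:
        return pd.Series(self.per_residue, name="rmsf_A").sort_index()


def compute_rmsf(
    traj: Trajectory,
    atom_names: Sequence[str] = BACKBONE_ATOM_NAMES,
    residue_numbers: Sequence[int] | None = None,
) -> RMSFProfile:
    """Backbone RMSF per residue: deviation from the trajectory-mean position."""
    top = traj.topology
    sel = top.select(residue_numbers=residue_numbers, atom_names=atom_names)
    if sel.size == 0:
        raise EmptyInputError("RMSF selection resolves to no atoms")
    if traj.n_frames == 1:
        warnings.warn("single-frame trajectory: RMSF is identically zero")
    coords = traj.frames[:, sel]                     # (F, S, 3)
    # deviations computed relative to frame 0 so a static trajectory yields
    # exactly zero (no rounding from averaging large absolute coordinates)
    delta = coords - coords[0]
    dev = delta - delta.mean(axis=0, keepdims=True)
    per_atom_rmsf = np.sqrt(np.mean(np.sum(dev * dev, axis=2), axis=0))
    per_atom = {int(i): float(v) for i, v in zip(sel, per_atom_rmsf)}
    per_res: dict = {}
    for i, v in zip(sel, per_atom_rmsf):
        per_res.setdefault(int(top.residue_numbers[i]), []).append(float(v))
    return RMSFProfile(
        per_residue={r: float(np.mean(vs)) for r, vs in per_res.items()},
        per_atom=per_atom,
        atom_names=tuple(atom_names),
        n_frames=traj.n_frames,
    )


class NonbondedParams:
    """Per-atom partial charges (e) and Lennard-Jones sigma (Å) / epsilon
    (kcal/mol), looked up by (residue_name, atom_name) with a ``*`` residue
    wildcard fallback.

    The bundled minimal table covers the toy backbone and nucleotide atoms used
    by the synthetic generator; it is a plausible, internally consistent set
    for exercising the energy machinery, not a validated force field.
    """

    def __init__(self, table: pd.DataFrame, combining_rule: str = "geometric"):
        required = {"residue_name", "atom_name", "charge", "sigma", "epsilon"}
        missing = required - set(table.columns)
        if missing:
            raise ConfigError(f"parameter table missing columns: {sorted(missing)}")
        if (table["epsilon"] < 0).any():
            raise ConfigError("epsilon must be >= 0")
        bad = table[(table["epsilon"] > 0) & (table["sigma"] <= 0)]
        if len(bad):
            raise ConfigError("sigma must be > 0 for LJ-active atoms")
        if combining_rule not in ("geometric", "lorentz-berthelot"):
            raise ConfigError(f"unknown combining rule: {combining_rule!r}")
        self.table = table
        self.combining_rule = combining_rule
        self._index = {
            (str(r), str(a)): (float(q), float(s), float(e))
            for r, a, q, s, e in zip(
                table["residue_name"], table["atom_name"],
                table["charge"], table["sigma"], table["epsilon"],
            )
        }

    @classmethod
    def from_csv(cls, path, combining_rule: str = "geometric") -> "NonbondedParams":
        return cls(pd.read_csv(path, comment="#"), combining_rule)

    @classmethod
    def bundled_minimal(cls, combining_rule: str = "geometric") -> "NonbondedParams":
        from importlib.resources import files
        import io

        text = files("switch_allostery.data").joinpath("minimal_nonbonded.csv").read_text()
        return cls(pd.read_csv(io.StringIO(text), comment="#"), combining_rule)

    def lookup(self, structure: Structure, indices: np.ndarray):
        """(charge, sigma, epsilon) arrays for the given atoms."""
        q = np.empty(len(indices))
        s = np.empty(len(indices))
        e = np.empty(len(indices))
        missing = []
        for k, i in enumerate(indices):
            key = (str(structure.residue_names[i]), str(structure.atom_names[i]))
            row = self._index.get(key) or self._index.get(("*", key[1]))
            if row is None:
                missing.append(key)
            else:
                q[k], s[k], e[k] = row
        if missing:
            raise ParameterizationError(sorted(set(missing)))
        return q, s, e


def _pair_energy_frames(coords_a, coords_b, qa, qb, sa, sb, ea, eb, rule):
    """Per-frame inter-group energy (kcal/mol); coords are (F, n, 3)."""
    diff = coords_a[:, :, None, :] - coords_b[:, None, :, :]
    r = np.linalg.norm(diff, axis=3)                  # (F, na, nb)
    coulomb = COULOMB_CONSTANT * (qa[:, None] * qb[None, :]) / r
    eps = np.sqrt(ea[:, None] * eb[None, :])
    if rule == "geometric":
        sig = np.sqrt(sa[:, None] * sb[None, :])
    else:  # lorentz-berthelot
        sig = 0.5 * (sa[:, None] + sb[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        sr6 = np.where(eps > 0, (sig / r) ** 6, 0.0)
    lj = 4.0 * eps * (sr6 * sr6 - sr6)
    return (coulomb + lj).sum(axis=(1, 2))


def nonbonded_energy(
    traj: Trajectory,
    group_a: RegionDefinition,
    group_b: RegionDefinition,
    params: NonbondedParams,
) -> float:
    """Frame-averaged inter-group nonbonded energy (kcal/mol).

    Groups must be disjoint; all their atoms must be parameterized.
    """
    top = traj.topology
    if set(group_a.residue_numbers) & set(group_b.residue_numbers):
        raise UsageError(
            f"groups {group_a.name!r} and {group_b.name!r} share residues"
        )
    ia = group_a.atom_indices(top)
    ib = group_b.atom_indices(top)
    qa, sa, ea = params.lookup(top, ia)
    qb, sb, eb = params.lookup(top, ib)
    per_frame = _pair_energy_frames(
        traj.frames[:, ia], traj.frames[:, ib],
        qa, qb, sa, sb, ea, eb, params.combining_rule,
    )
    return float(per_frame.mean())


def normalize_energies(
    table: pd.DataFrame,
    reference: str,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Divide each (system, region_pair) energy by the reference system's
    energy for the same region pair. Columns: system, region_pair, energy."""
    required = {"system", "region_pair", "energy"}
    if not required <= set(table.columns):
        raise ConfigError(f"energy table needs columns {sorted(required)}")
    ref_rows = table[table["system"] == reference]
    if ref_rows.empty:
        raise NormalizationError(f"reference system {reference!r} not in table")
    ref = dict(zip(ref_rows["region_pair"], ref_rows["energy"]))
    normalized = []
    for _, row in table.iterrows():
        e_ref = ref.get(row["region_pair"])
        if e_ref is None:
            raise NormalizationError(
                f"reference lacks region pair {row['region_pair']!r}"
            )
        if abs(e_ref) < tol:
            raise NormalizationError(
                f"reference energy ~0 for region pair {row['region_pair']!r}"
            )
        normalized.append(row["energy"] / e_ref)
    out = table.copy()
    out["normalized"] = normalized
    return out
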