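"""Structures, trajectories, region/ligand selections, and superposition.

Coordinates are stored in Angstrom throughout (mdtraj's nm are converted on
ingest), residues keep their author (PDB) numbering, and HETATM ligand atoms
are retained so nucleotide protons stay selectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from .errors import (
    ConfigError,
    DegenerateSuperpositionError,
    EmptyInputError,
    FormatError,
    TopologyError,
)

BACKBONE_ATOM_NAMES = ("N", "CA", "C", "O")

#: Covalent bond cutoff used to attach a hydrogen to its heavy-atom parent.
_H_PARENT_CUTOFF = 1.3


@dataclass
class Structure:
    """A static structure: per-atom annotation plus one coordinate set (A)."""

    atom_names: np.ndarray
    elements: np.ndarray
    residue_numbers: np.ndarray
    residue_names: np.ndarray
    chains: np.ndarray
    coordinates: np.ndarray

    def __post_init__(self):
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.residue_numbers = np.asarray(self.residue_numbers, dtype=np.int64)
        self.residue_names = np.asarray(self.residue_names, dtype=object)
        self.chains = np.asarray(self.chains, dtype=object)
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.n_atoms == 0:
            raise EmptyInputError("structure contains no atoms")
        if self.coordinates.shape != (self.n_atoms, 3):
            raise TopologyError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{self.n_atoms} atoms"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise FormatError("structure coordinates contain non-finite values")
        self._h_parents = None

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def hydrogen_mask(self) -> np.ndarray:
        return np.asarray([e == "H" for e in self.elements], dtype=bool)

    def select(
        self,
        residue_numbers: Iterable[int] | None = None,
        atom_names: Iterable[str] | None = None,
        residue_name: str | None = None,
        elements: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Return atom indices matching all given filters (AND semantics)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if residue_numbers is not None:
            wanted = set(int(r) for r in residue_numbers)
            mask &= np.asarray([int(r) in wanted for r in self.residue_numbers])
        if atom_names is not None:
            names = set(atom_names)
            mask &= np.asarray([a in names for a in self.atom_names])
        if residue_name is not None:
            mask &= np.asarray([r == residue_name for r in self.residue_names])
        if elements is not None:
            els = set(elements)
            mask &= np.asarray([e in els for e in self.elements])
        return np.flatnonzero(mask)

    def hydrogen_parents(self) -> np.ndarray:
        """Heavy-atom parent index per atom (-1 for heavies and orphan H).

        Parents are assigned once from the reference coordinates: the nearest
        heavy atom within 1.3 A.  This works for any topology whose reference
        geometry has chemically sensible bond lengths and avoids relying on
        residue templates that toy systems would not match.
        """
        if self._h_parents is None:
            parents = np.full(self.n_atoms, -1, dtype=np.int64)
            hmask = self.hydrogen_mask
            heavy = np.flatnonzero(~hmask)
            if heavy.size and hmask.any():
                hxyz = self.coordinates[hmask]
                d = np.linalg.norm(
                    hxyz[:, None, :] - self.coordinates[heavy][None, :, :], axis=2
                )
                nearest = np.argmin(d, axis=1)
                ok = d[np.arange(len(nearest)), nearest] < _H_PARENT_CUTOFF
                idx = np.flatnonzero(hmask)
                parents[idx[ok]] = heavy[nearest[ok]]
            self._h_parents = parents
        return self._h_parents

    def copy(self) -> "Structure":
        return Structure(
            self.atom_names.copy(),
            self.elements.copy(),
            self.residue_numbers.copy(),
            self.residue_names.copy(),
            self.chains.copy(),
            self.coordinates.copy(),
        )


@dataclass
class Trajectory:
    """Frames bound to a topology. ``frames`` is (n_frames, n_atoms, 3) in A."""

    topology: Structure
    frames: np.ndarray
    frame_interval_ps: float | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise TopologyError("frames must have shape (n_frames, n_atoms, 3)")
        if self.n_frames < 1:
            raise EmptyInputError("trajectory has no frames")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise TopologyError(
                f"trajectory has {self.frames.shape[1]} atoms but topology "
                f"has {self.topology.n_atoms}"
            )
        if not np.all(np.isfinite(self.frames)):
            raise FormatError("trajectory coordinates contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.frames.shape[1]


@dataclass(frozen=True)
class RegionDefinition:
    """A named, ordered set of author residue numbers (e.g. a switch region)."""

    name: str
    residue_numbers: tuple

    def __post_init__(self):
        numbers = tuple(int(r) for r in self.residue_numbers)
        if not numbers:
            raise ConfigError(f"region {self.name!r} is empty")
        object.__setattr__(self, "residue_numbers", numbers)

    @classmethod
    def from_range(cls, name: str, lo: int, hi: int) -> "RegionDefinition":
        if hi < lo:
            raise ConfigError(f"region {name!r}: range [{lo}, {hi}] is inverted")
        return cls(name, tuple(range(lo, hi + 1)))

    def atom_indices(
        self, structure: Structure, atom_names: Iterable[str] | None = None
    ) -> np.ndarray:
        idx = structure.select(
            residue_numbers=self.residue_numbers, atom_names=atom_names
        )
        if idx.size == 0:
            raise TopologyError(
                f"region {self.name!r} resolves to no atoms in this topology"
            )
        return idx


@dataclass(frozen=True)
class LigandSelection:
    """Ligand residue plus the monitored-proton label map ('a'..'d')."""

    residue_name: str
    monitored_protons: Mapping[str, tuple]

    def __post_init__(self):
        protons = {
            str(k): tuple(str(a) for a in (v if isinstance(v, (list, tuple)) else [v]))
            for k, v in self.monitored_protons.items()
        }
        if not protons:
            raise ConfigError("ligand selection declares no monitored protons")
        object.__setattr__(self, "monitored_protons", protons)

    def resolve(self, structure: Structure) -> dict:
        """Map each label to the atom index of every declared proton."""
        resolved = {}
        for label, names in self.monitored_protons.items():
            idx = []
            for name in names:
                sel = structure.select(
                    residue_name=self.residue_name, atom_names=[name]
                )
                sel = [i for i in sel if structure.elements[i] == "H"]
                if not sel:
                    raise TopologyError(
                        f"proton {label!r}: atom {name!r} not found as a hydrogen "
                        f"of residue {self.residue_name!r}"
                    )
                idx.extend(sel)
            resolved[label] = tuple(idx)
        return resolved

    def equivalent_labels(self) -> tuple:
        """Labels declared as groups of equivalent protons (>=2 atoms)."""
        return tuple(
            k for k, v in self.monitored_protons.items() if len(v) > 1
        )


# ---------------------------------------------------------------------------
# IO via mdtraj
# ---------------------------------------------------------------------------

def _from_mdtraj(mdtop, xyz_nm) -> Structure:
    atoms = list(mdtop.atoms)
    return Structure(
        atom_names=[a.name for a in atoms],
        elements=[(a.element.symbol if a.element is not None else "X") for a in atoms],
        residue_numbers=[a.residue.resSeq for a in atoms],
        residue_names=[a.residue.name for a in atoms],
        chains=[str(a.residue.chain.chain_id or a.residue.chain.index) for a in atoms],
        coordinates=np.asarray(xyz_nm, dtype=np.float64) * 10.0,
    )


def _to_mdtraj_topology(structure: Structure):
    import mdtraj as md
    from mdtraj.core import element as md_element

    top = md.Topology()
    chain = None
    residue = None
    last = (None, None, None)
    for i in range(structure.n_atoms):
        key_chain = structure.chains[i]
        key_res = (key_chain, int(structure.residue_numbers[i]),
                   structure.residue_names[i])
        if chain is None or key_chain != last[0]:
            chain = top.add_chain()
        if residue is None or key_res != (last[0], last[1], last[2]):
            residue = top.add_residue(
                structure.residue_names[i], chain,
                resSeq=int(structure.residue_numbers[i]),
            )
        last = key_res
        try:
            el = md_element.get_by_symbol(structure.elements[i])
        except KeyError:
            el = md_element.virtual
        top.add_atom(structure.atom_names[i], el, residue)
    return top


def _to_mdtraj(traj: Trajectory):
    import mdtraj as md

    return md.Trajectory(
        xyz=traj.frames / 10.0, topology=_to_mdtraj_topology(traj.topology)
    )


def read_structure(path) -> Structure:
    """Read a PDB file, keeping author numbering and HETATM ligand atoms."""
    import mdtraj as md

    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        traj = md.load(str(path), standard_names=False)
    except Exception as exc:  # mdtraj raises a zoo of exception types
        raise FormatError(f"could not parse {path} as PDB: {exc}") from exc
    if traj.n_atoms == 0:
        raise EmptyInputError(f"{path} contains no atoms")
    return _from_mdtraj(traj.topology, traj.xyz[0])


def read_trajectory(
    topology: Structure, paths: Sequence, frame_interval_ps: float | None = None
) -> Trajectory:
    """Read and concatenate DCD/XTC files (file order preserved)."""
    import mdtraj as md

    if isinstance(paths, (str, Path)):
        paths = [paths]
    mdtop = _to_mdtraj_topology(topology)
    chunks = []
    for p in paths:
        p = Path(p)
        if not p.exists():
            raise FormatError(f"no such file: {p}")
        try:
            t = md.load(str(p), top=mdtop)
        except Exception as exc:
            msg = str(exc)
            if "atom" in msg.lower() or "shape" in msg.lower():
                raise TopologyError(
                    f"{p}: atom count does not match topology ({msg})"
                ) from exc
            raise FormatError(f"could not read trajectory {p}: {exc}") from exc
        if t.n_atoms != topology.n_atoms:
            raise TopologyError(
                f"{p}: trajectory has {t.n_atoms} atoms, topology has "
                f"{topology.n_atoms}"
            )
        chunks.append(np.asarray(t.xyz, dtype=np.float64) * 10.0)
    if not chunks:
        raise EmptyInputError("no trajectory files given")
    return Trajectory(topology, np.concatenate(chunks, axis=0),
                      frame_interval_ps=frame_interval_ps)


def write_structure(structure: Structure, path) -> None:
    import mdtraj as md

    md.Trajectory(
        xyz=structure.coordinates[None] / 10.0,
        topology=_to_mdtraj_topology(structure),
    ).save_pdb(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write frames to DCD or XTC (chosen by extension)."""
    path = Path(path)
    mdt = _to_mdtraj(traj)
    if path.suffix.lower() == ".dcd":
        mdt.save_dcd(str(path))
    elif path.suffix.lower() == ".xtc":
        mdt.save_xtc(str(path))
    else:
        raise ConfigError(f"unsupported trajectory extension: {path.suffix}")


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_rotation(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Optimal rotation R (row-vector convention) mapping centered P onto
    centered Q: argmin_R || (P - Pc) R - (Q - Qc) ||."""
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    H = Pc.T @ Qc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def _check_superposable(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateSuperpositionError(
            f"selection has {coords.shape[0]} atoms; >=3 required"
        )
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] < 1e-8:
        raise DegenerateSuperpositionError("selection atoms are collinear")


def superpose(
    traj: Trajectory,
    selection: np.ndarray,
    max_iter: int = 5,
    tol: float = 1e-6,
) -> Trajectory:
    """Least-squares superpose every frame onto the iteratively refined mean
    structure of ``selection`` (Kabsch). Returns a new Trajectory."""
    selection = np.asarray(selection, dtype=np.int64)
    if selection.size == 0:
        raise DegenerateSuperpositionError("empty superposition selection")
    _check_superposable(traj.frames[0, selection])

    frames = traj.frames.copy()
    ref = traj.frames[0, selection].copy()
    ref -= ref.mean(axis=0)
    for _ in range(max_iter):
        for f in range(frames.shape[0]):
            sel = frames[f, selection]
            R = kabsch_rotation(sel, ref)
            frames[f] = (frames[f] - sel.mean(axis=0)) @ R
        new_ref = frames[:, selection].mean(axis=0)
        new_ref -= new_ref.mean(axis=0)
        shift = float(np.max(np.abs(new_ref - ref)))
        ref = new_ref
        if shift < tol:
            break
    return Trajectory(traj.topology, frames, traj.frame_interval_ps)


# ---------------------------------------------------------------------------
# Region configuration
# ---------------------------------------------------------------------------

def _regions_from_mapping(mapping: Mapping) -> dict:
    regions = {}
    for name, value in mapping.items():
        if (
            isinstance(value, (list, tuple))
            and len(value) == 2
            and all(isinstance(v, int) for v in value)
        ):
            regions[name] = RegionDefinition.from_range(name, value[0], value[1])
        elif isinstance(value, (list, tuple)):
            regions[name] = RegionDefinition(name, tuple(value))
        else:
            raise ConfigError(
                f"region {name!r}: expected [lo, hi] or an explicit residue list"
            )
    return regions


def load_regions(source=None) -> dict:
    """Load switch-region definitions from YAML (``regions: {name: [lo, hi]}``).

    With no argument the packaged defaults are returned: switch_I 197-207,
    switch_II 219-236, switch_III 254-270 (author numbering of the Gα_S short
    isoform, chosen so every commonly discussed switch residue — R201, S205,
    G226, Q227, R228, E230, R258, E259, R265, E268 — falls in its region).
    """
    if source is None:
        from importlib.resources import files

        text = files("switch_allostery.data").joinpath("default_regions.yaml").read_text()
        data = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        data = {"regions": dict(source)}
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    if not isinstance(data, Mapping) or "regions" not in data:
        raise ConfigError("region YAML must contain a top-level 'regions' mapping")
    return _regions_from_mapping(data["regions"])


def load_ligand_selection(source=None) -> LigandSelection:
    """Load the ligand/proton map from YAML; defaults to GDP with
    a=H8, b=H1', c=H2', d=(H5', H5'')."""
    if source is None:
        from importlib.resources import files

        text = files("switch_allostery.data").joinpath("default_protons.yaml").read_text()
        data = yaml.safe_load(text)
    elif isinstance(source, Mapping):
        data = dict(source)
    else:
        with open(source) as fh:
            data = yaml.safe_load(fh)
    try:
        return LigandSelection(data["ligand"], data["protons"])
    except KeyError as exc:
        raise ConfigError(f"ligand YAML missing key: {exc}") from exc
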