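"""Nucleotide-proton / protein-residue contact profiling.

For each monitored nucleotide proton the analysis asks, frame by frame, which
protein residues have a proton within a cutoff radius of it (proximity
occupancy) and which residue is nearest (closest-residue frequency). Distances
are proton-to-proton because saturation transfer is proton-mediated; the
default radius is 6.0 Å. Labels declared as equivalent protons (e.g. the two
H5'/H5'' sugar protons sharing one resonance) are reported as the arithmetic
average of the individual protons' profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AggregationError,
    DomainError,
    EmptyInputError,
    NoHydrogensError,
    UsageError,
)
from .structures import LigandSelection, Structure, Trajectory

DEFAULT_CONTACT_RADIUS = 6.0  # Angstrom, proton-to-proton


@dataclass(frozen=True)
class ContactStats:
    proximity_occupancy: float
    closest_frequency: float


def _protein_proton_index(structure: Structure, ligand_resname: str):
    """(atom_indices, residue_numbers) of all non-ligand hydrogens."""
    hmask = structure.hydrogen_mask
    keep = np.flatnonzero(
        hmask & np.asarray([r != ligand_resname for r in structure.residue_names])
    )
    if keep.size == 0:
        raise NoHydrogensError("topology has no protein hydrogens")
    return keep, structure.residue_numbers[keep]


def proton_contacts_frame(
    structure: Structure,
    coords: np.ndarray,
    ligand: LigandSelection,
    radius: float = DEFAULT_CONTACT_RADIUS,
) -> dict:
    """Per proton atom: residues within ``radius`` and the closest residue.

    Returns {label: {atom_name: (set_of_residues_in_radius, closest_or_None)}}.
    The per-residue distance is to that residue's nearest proton; the closest
    residue is the argmin, ties broken toward the lower residue number.
    """
    if radius <= 0:
        raise DomainError("radius must be positive")
    h_idx, h_res = _protein_proton_index(structure, ligand.residue_name)
    resolved = ligand.resolve(structure)
    residues = np.unique(h_res)
    out = {}
    for label, atoms in resolved.items():
        out[label] = {}
        for a in atoms:
            d = np.linalg.norm(coords[h_idx] - coords[a], axis=1)
            # min distance per residue
            per_res = {
                int(r): float(d[h_res == r].min()) for r in residues
            }
            within = {r for r, dist in per_res.items() if dist < radius}
            closest = None
            if within:
                best = min((per_res[r], r) for r in within)
                closest = best[1]
            out[label][str(structure.atom_names[a])] = (within, closest)
    return out


@dataclass
class ProtonContactProfile:
    """Contact statistics per proton label (equivalent protons averaged)."""

    radius: float
    n_frames: int
    per_proton: dict                      # label -> {residue: ContactStats}
    per_atom: dict                        # (label, atom_name) -> {residue: ContactStats}
    union_occupancy: dict                 # residue -> fraction of frames near >=1 proton

    def labels(self):
        return tuple(self.per_proton.keys())


def average_equivalent_protons(
    profile: ProtonContactProfile, ligand: LigandSelection, label: str
) -> dict:
    """Arithmetic average of the per-atom entries of an equivalent-proton pair.

    Only labels declared with >=2 atoms in the ligand selection qualify.
    """
    if label not in ligand.equivalent_labels():
        raise UsageError(f"proton {label!r} is not declared as equivalent protons")
    atom_entries = [
        stats for (lab, _), stats in profile.per_atom.items() if lab == label
    ]
    residues = sorted({r for entry in atom_entries for r in entry})
    merged = {}
    n = len(atom_entries)
    for r in residues:
        occ = sum(e.get(r, ContactStats(0.0, 0.0)).proximity_occupancy
                  for e in atom_entries) / n
        clo = sum(e.get(r, ContactStats(0.0, 0.0)).closest_frequency
                  for e in atom_entries) / n
        merged[r] = ContactStats(occ, clo)
    return merged


def contact_occupancy(
    traj: Trajectory,
    ligand: LigandSelection,
    radius: float = DEFAULT_CONTACT_RADIUS,
) -> ProtonContactProfile:
    """Proximity occupancy and closest-residue frequency over a trajectory.

    Frames in which no residue lies within the radius contribute to no
    residue's closest frequency, so frequencies may sum to < 1.
    """
    if traj.n_frames < 1:
        raise EmptyInputError("empty trajectory")
    top = traj.topology
    # counting containers keyed by (label, atom_name)
    in_radius_counts: dict = {}
    closest_counts: dict = {}
    union_counts: dict = {}
    atom_keys = []
    resolved = ligand.resolve(top)
    for label, atoms in resolved.items():
        for a in atoms:
            atom_keys.append((label, str(top.atom_names[a])))

    for f in range(traj.n_frames):
        frame_result = proton_contacts_frame(top, traj.frames[f], ligand, radius)
        union_res = set()
        for label, by_atom in frame_result.items():
            for atom_name, (within, closest) in by_atom.items():
                key = (label, atom_name)
                for r in within:
                    in_radius_counts.setdefault(key, {}).setdefault(r, 0)
                    in_radius_counts[key][r] += 1
                if closest is not None:
                    closest_counts.setdefault(key, {}).setdefault(closest, 0)
                    closest_counts[key][closest] += 1
                union_res.update(within)
        for r in union_res:
            union_counts[r] = union_counts.get(r, 0) + 1

    n = traj.n_frames
    per_atom = {}
    for key in atom_keys:
        residues = set(in_radius_counts.get(key, {})) | set(closest_counts.get(key, {}))
        per_atom[key] = {
            r: ContactStats(
                in_radius_counts.get(key, {}).get(r, 0) / n,
                closest_counts.get(key, {}).get(r, 0) / n,
            )
            for r in residues
        }

    profile = ProtonContactProfile(
        radius=radius,
        n_frames=n,
        per_proton={},
        per_atom=per_atom,
        union_occupancy={r: c / n for r, c in union_counts.items()},
    )
    for label, atoms in resolved.items():
        if len(atoms) > 1:
            profile.per_proton[label] = average_equivalent_protons(
                profile, ligand, label
            )
        else:
            key = (label, str(top.atom_names[atoms[0]]))
            profile.per_proton[label] = dict(per_atom[key])
    return profile


def aggregate_contacts(profiles) -> pd.DataFrame:
    """Mean ± SEM (in %) of proximity occupancy across systems.

    ``profiles`` is a sequence of (system_label, ProtonContactProfile). A
    residue absent from a system's profile counts as occupancy 0 there. SEM is
    the sample SD divided by sqrt(n_systems).
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise AggregationError("need >=2 systems for a SEM")
    label_sets = [tuple(sorted(p.per_proton)) for _, p in profiles]
    if len(set(label_sets)) != 1:
        raise AggregationError(f"proton labels differ across systems: {label_sets}")
    systems = [s for s, _ in profiles]
    rows = []
    for proton in label_sets[0]:
        residues = sorted(
            {r for _, p in profiles for r in p.per_proton[proton]}
        )
        for r in residues:
            vals = np.asarray(
                [
                    p.per_proton[proton].get(r, ContactStats(0.0, 0.0)).proximity_occupancy
                    for _, p in profiles
                ]
            )
            rows.append(
                {
                    "proton": proton,
                    "residue": r,
                    "mean_pct": float(vals.mean() * 100.0),
                    "sem_pct": float(vals.std(ddof=1) / np.sqrt(len(vals)) * 100.0),
                    "n_systems": len(vals),
                }
            )
    out = pd.DataFrame(rows, columns=["proton", "residue", "mean_pct", "sem_pct", "n_systems"])
    out.attrs["systems"] = systems
    return out
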