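"""Geometric hydrogen-bond detection and inter-region occupancy matrices.

A hydrogen bond is declared between a donor heavy atom D (N or O carrying the
hydrogen H) and an acceptor heavy atom A (any N or O) when the H···A distance
is below a cutoff and the D–H···A angle (measured at H) exceeds a cutoff.
Defaults are the common trajectory-analysis criteria: H···A < 2.4 Å and
D–H···A > 120°. Occupancy is the fraction of frames in which a given
(D, H, A) pair satisfies both criteria; both directions between two regions
(A-donates-to-B and B-donates-to-A) are always evaluated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ComparisonError, ConfigError, EmptyInputError, NoHydrogensError
from .structures import RegionDefinition, Structure, Trajectory

#: Elements that may act as H-bond donors (when protonated) or acceptors.
POLAR_ELEMENTS = frozenset({"N", "O"})

#: Default persistence tiers mirroring a three-intensity occupancy map.
DEFAULT_TIERS = (0.25, 0.50, 0.75)


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric cutoffs: H···A distance (Å) and D–H···A angle (degrees)."""

    max_ha_distance: float = 2.4
    min_dha_angle: float = 120.0

    def __post_init__(self):
        if not self.max_ha_distance > 0:
            raise ConfigError("max_ha_distance must be positive")
        if not 0 < self.min_dha_angle <= 180:
            raise ConfigError("min_dha_angle must lie in (0, 180]")


def polar_hydrogens(structure: Structure) -> tuple[np.ndarray, np.ndarray]:
    """(donor_heavy_idx, hydrogen_idx) for every H bonded to N or O.

    Raises NoHydrogensError if the topology has no hydrogens at all, because a
    silent empty result would masquerade as "no hydrogen bonds".
    """
    hmask = structure.hydrogen_mask
    if not hmask.any():
        raise NoHydrogensError(
            "topology contains no hydrogens; H-bond analysis is undefined"
        )
    parents = structure.hydrogen_parents()
    h_idx = np.flatnonzero(hmask)
    keep = [
        (parents[h], h)
        for h in h_idx
        if parents[h] >= 0 and structure.elements[parents[h]] in POLAR_ELEMENTS
    ]
    if not keep:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    d, h = zip(*keep)
    return np.asarray(d, dtype=np.int64), np.asarray(h, dtype=np.int64)


def acceptor_atoms(structure: Structure) -> np.ndarray:
    """Indices of all N/O atoms (backbone and sidechain)."""
    return np.flatnonzero(
        np.asarray([e in POLAR_ELEMENTS for e in structure.elements])
    )


def _directional_hbonds(coords, donors, hydrogens, acceptors, criteria):
    """Triplets (D, H, A) passing both cutoffs, donors→acceptors direction."""
    if len(hydrogens) == 0 or len(acceptors) == 0:
        return []
    H = coords[hydrogens]
    A = coords[acceptors]
    diff = H[:, None, :] - A[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    # a hydrogen's own parent can appear in the acceptor list; mask it out
    same = donors[:, None] == acceptors[None, :]
    cand = (dist < criteria.max_ha_distance) & ~same
    out = []
    if not cand.any():
        return out
    D = coords[donors]
    for i, j in zip(*np.nonzero(cand)):
        hd = D[i] - H[i]
        ha = A[j] - H[i]
        denom = np.linalg.norm(hd) * np.linalg.norm(ha)
        if denom == 0:
            continue
        cosang = np.clip(np.dot(hd, ha) / denom, -1.0, 1.0)
        angle = np.degrees(np.arccos(cosang))
        if angle > criteria.min_dha_angle:
            out.append((int(donors[i]), int(hydrogens[i]), int(acceptors[j])))
    return out


def detect_hbonds_frame(
    structure: Structure,
    coords: np.ndarray,
    region_a: RegionDefinition,
    region_b: RegionDefinition,
    criteria: HBondCriteria = HBondCriteria(),
) -> set:
    """Hydrogen bonds between two regions in one frame.

    Returns a set of atom-index triplets (donor, hydrogen, acceptor); both
    donation directions are evaluated.
    """
    donors_all, hyd_all = polar_hydrogens(structure)
    acceptors_all = acceptor_atoms(structure)
    res = structure.residue_numbers
    out = set()
    for don_region, acc_region in ((region_a, region_b), (region_b, region_a)):
        dres = set(don_region.residue_numbers)
        ares = set(acc_region.residue_numbers)
        dsel = np.asarray(
            [r in dres for r in res[donors_all]], dtype=bool
        ) if len(donors_all) else np.empty(0, dtype=bool)
        asel = np.asarray([r in ares for r in res[acceptors_all]], dtype=bool)
        out.update(
            _directional_hbonds(
                coords,
                donors_all[dsel],
                hyd_all[dsel],
                acceptors_all[asel],
                criteria,
            )
        )
    return out


@dataclass
class HBondOccupancyMatrix:
    """Occupancy per donor/acceptor pair between two named regions.

    ``entries`` is keyed by (donor_residue, donor_atom, acceptor_residue,
    acceptor_atom); ``residue_entries`` aggregates to residue pairs (a pair of
    residues counts as bonded in a frame if *any* atom-level pair passes).
    """

    region_pair: tuple
    n_frames: int
    criteria: HBondCriteria
    entries: dict = field(default_factory=dict)
    residue_entries: dict = field(default_factory=dict)

    def occupancy(self, donor_residue, donor_atom, acceptor_residue, acceptor_atom):
        return self.entries.get(
            (donor_residue, donor_atom, acceptor_residue, acceptor_atom), 0.0
        )

    def to_records(self):
        """List of dicts suitable for CSV/JSON export."""
        return [
            {
                "donor_residue": k[0],
                "donor_atom": k[1],
                "acceptor_residue": k[2],
                "acceptor_atom": k[3],
                "occupancy": v,
            }
            for k, v in sorted(self.entries.items())
        ]


def hbond_occupancy(
    traj: Trajectory,
    region_a: RegionDefinition,
    region_b: RegionDefinition,
    criteria: HBondCriteria = HBondCriteria(),
) -> HBondOccupancyMatrix:
    """Occupancy matrix over the whole trajectory; never-detected pairs are
    omitted rather than reported as zero."""
    if traj.n_frames < 1:
        raise EmptyInputError("empty trajectory")
    top = traj.topology
    atom_counts: dict = {}
    res_counts: dict = {}
    for f in range(traj.n_frames):
        triplets = detect_hbonds_frame(top, traj.frames[f], region_a, region_b, criteria)
        res_pairs = set()
        for d, h, a in triplets:
            key = (
                int(top.residue_numbers[d]),
                str(top.atom_names[d]),
                int(top.residue_numbers[a]),
                str(top.atom_names[a]),
            )
            atom_counts[key] = atom_counts.get(key, 0) + 1
            res_pairs.add((key[0], key[2]))
        for rp in res_pairs:
            res_counts[rp] = res_counts.get(rp, 0) + 1
    n = traj.n_frames
    return HBondOccupancyMatrix(
        region_pair=(region_a.name, region_b.name),
        n_frames=n,
        criteria=criteria,
        entries={k: c / n for k, c in atom_counts.items()},
        residue_entries={k: c / n for k, c in res_counts.items()},
    )


def persistence_tiers(
    matrix: HBondOccupancyMatrix,
    thresholds: Sequence[float] = DEFAULT_TIERS,
    level: str = "atom",
) -> dict:
    """Tier index per pair: the number of thresholds met (inclusive ≥).

    Pairs below the lowest threshold are excluded. Thresholds must be strictly
    increasing within (0, 1].
    """
    thresholds = tuple(float(t) for t in thresholds)
    if not thresholds or any(
        b <= a for a, b in zip(thresholds, thresholds[1:])
    ) or not all(0 < t <= 1 for t in thresholds):
        raise ConfigError(
            f"thresholds must be strictly increasing in (0, 1]: {thresholds}"
        )
    source = matrix.entries if level == "atom" else matrix.residue_entries
    tiers = {}
    for key, occ in source.items():
        tier = sum(occ >= t for t in thresholds)
        if tier > 0:
            tiers[key] = tier
    return tiers


@dataclass(frozen=True)
class NetworkComparison:
    """Pairs present (occupancy ≥ threshold) in one matrix but not the other."""

    gained: frozenset
    lost: frozenset
    shared: frozenset
    threshold: float


def compare_networks(
    mat_a: HBondOccupancyMatrix,
    mat_b: HBondOccupancyMatrix,
    threshold: float = 0.5,
    level: str = "residue",
) -> NetworkComparison:
    """Classify pairs as gained in B, lost in B, or shared, at ≥ threshold.

    Matrices must describe the same region pair and use identical criteria.
    """
    if mat_a.region_pair != mat_b.region_pair:
        raise ComparisonError(
            f"region pairs differ: {mat_a.region_pair} vs {mat_b.region_pair}"
        )
    if mat_a.criteria != mat_b.criteria:
        raise ComparisonError("matrices were computed with different criteria")
    src_a = mat_a.entries if level == "atom" else mat_a.residue_entries
    src_b = mat_b.entries if level == "atom" else mat_b.residue_entries
    present_a = {k for k, v in src_a.items() if v >= threshold}
    present_b = {k for k, v in src_b.items() if v >= threshold}
    return NetworkComparison(
        gained=frozenset(present_b - present_a),
        lost=frozenset(present_a - present_b),
        shared=frozenset(present_a & present_b),
        threshold=threshold,
    )
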