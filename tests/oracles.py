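"""Independent brute-force oracles.

Pure-Python, per-frame, all-pairs implementations of the geometric analyses,
written against the definitions only (no shared code with the package's
vectorized paths). Deliberately naive O(N^2) loops on small fixtures.
"""

import math


def _dist(p, q):
    return math.sqrt(
        (p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 + (p[2] - q[2]) ** 2
    )


def _angle_deg(center, a, b):
    v1 = (a[0] - center[0], a[1] - center[1], a[2] - center[2])
    v2 = (b[0] - center[0], b[1] - center[1], b[2] - center[2])
    dot = v1[0] * v2[0] + v1[1] * v2[1] + v1[2] * v2[2]
    n1 = math.sqrt(v1[0] ** 2 + v1[1] ** 2 + v1[2] ** 2)
    n2 = math.sqrt(v2[0] ** 2 + v2[1] ** 2 + v2[2] ** 2)
    if n1 == 0 or n2 == 0:
        return 0.0
    c = max(-1.0, min(1.0, dot / (n1 * n2)))
    return math.degrees(math.acos(c))


def polar_pairs(structure):
    """(donor_heavy, hydrogen) pairs: H whose nearest heavy atom (within
    1.3 A) is N or O."""
    coords = structure.coordinates
    heavies = [i for i in range(structure.n_atoms) if structure.elements[i] != "H"]
    pairs = []
    for h in range(structure.n_atoms):
        if structure.elements[h] != "H":
            continue
        best, best_d = None, None
        for j in heavies:
            d = _dist(coords[h], coords[j])
            if best_d is None or d < best_d:
                best, best_d = j, d
        if best is not None and best_d < 1.3 and structure.elements[best] in ("N", "O"):
            pairs.append((best, h))
    return pairs


def hbond_counts(structure, frames, region_a, region_b,
                 max_ha=2.4, min_angle=120.0):
    """Frame counts per (donor_res, donor_atom, acceptor_res, acceptor_atom)
    and per (donor_res, acceptor_res), both donation directions."""
    donors = polar_pairs(structure)
    acceptors = [
        i for i in range(structure.n_atoms)
        if structure.elements[i] in ("N", "O")
    ]
    res = structure.residue_numbers
    set_a = set(region_a.residue_numbers)
    set_b = set(region_b.residue_numbers)
    atom_counts, res_counts = {}, {}
    for frame in frames:
        res_pairs = set()
        for dres, ares in ((set_a, set_b), (set_b, set_a)):
            for d, h in donors:
                if int(res[d]) not in dres:
                    continue
                for a in acceptors:
                    if int(res[a]) not in ares or a == d:
                        continue
                    if _dist(frame[h], frame[a]) >= max_ha:
                        continue
                    if _angle_deg(frame[h], frame[d], frame[a]) <= min_angle:
                        continue
                    key = (
                        int(res[d]), str(structure.atom_names[d]),
                        int(res[a]), str(structure.atom_names[a]),
                    )
                    atom_counts[key] = atom_counts.get(key, 0) + 1
                    res_pairs.add((key[0], key[2]))
        for rp in res_pairs:
            res_counts[rp] = res_counts.get(rp, 0) + 1
    return atom_counts, res_counts


def contact_counts(structure, frames, ligand_resname, proton_atoms, radius=6.0):
    """Per ligand proton atom index: frame counts of in-radius residues and
    of being the closest residue (ties to the lower residue number)."""
    protein_h = [
        i for i in range(structure.n_atoms)
        if structure.elements[i] == "H"
        and structure.residue_names[i] != ligand_resname
    ]
    res = structure.residue_numbers
    residues = sorted({int(res[i]) for i in protein_h})
    in_counts = {a: {} for a in proton_atoms}
    closest_counts = {a: {} for a in proton_atoms}
    for frame in frames:
        for a in proton_atoms:
            per_res = {}
            for i in protein_h:
                d = _dist(frame[a], frame[i])
                r = int(res[i])
                if r not in per_res or d < per_res[r]:
                    per_res[r] = d
            within = [r for r in residues if per_res[r] < radius]
            for r in within:
                in_counts[a][r] = in_counts[a].get(r, 0) + 1
            if within:
                best = min((per_res[r], r) for r in within)[1]
                closest_counts[a][best] = closest_counts[a].get(best, 0) + 1
    return in_counts, closest_counts
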