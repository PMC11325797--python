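"""Per-residue backbone RMSF and inter-region nonbonded energies.

Generates a trajectory whose switch-II residues fluctuate three times more
than the rest, superposes it, and prints the per-residue RMSF profile; then
computes the switch-I/switch-II nonbonded interaction energy with the bundled
minimal parameter set and normalizes it against a second system.
"""

import pandas as pd

from switch_allostery import (
    NonbondedParams,
    TrajectorySpec,
    compute_rmsf,
    generate_trajectory,
    load_regions,
    nonbonded_energy,
    normalize_energies,
    superpose,
    toy_structure,
)

top = toy_structure()
sd = {int(r): 0.2 for r in set(top.residue_numbers)}
for r in (227, 228, 230):      # switch II fluctuates more
    sd[r] = 0.6

traj, _ = generate_trajectory(
    TrajectorySpec(n_frames=3000, fluctuation_sd=sd, seed=2), topology=top
)
backbone = top.select(atom_names=["N", "CA", "C", "O"])
profile = compute_rmsf(superpose(traj, backbone))

print("residue  RMSF (A)")
for residue, value in sorted(profile.per_residue.items()):
    marker = "  <- switch II" if residue in (227, 228, 230) else ""
    print(f"  {residue:5d}  {value:.3f}{marker}")
# Expect ~0.35 A (= 0.2 * sqrt(3)) baseline and ~1.0 A for switch II.

regions = load_regions()
params = NonbondedParams.bundled_minimal()
e1 = nonbonded_energy(traj, regions["switch_I"], regions["switch_II"], params)

traj2, _ = generate_trajectory(
    TrajectorySpec(n_frames=3000, fluctuation_sd=0.2, seed=3), topology=top
)
e2 = nonbonded_energy(traj2, regions["switch_I"], regions["switch_II"], params)

table = pd.DataFrame({
    "system": ["reference", "variant"],
    "region_pair": ["I|II", "I|II"],
    "energy": [e1, e2],
})
print(normalize_energies(table, "reference"))
# 'normalized' is the energy ratio to the reference system (reference = 1.0);
# with no planted contacts the absolute energies are tiny long-range sums.
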