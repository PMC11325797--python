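"""Hydrogen-bond occupancy between switch regions.

Builds a synthetic trajectory with a switch-I/switch-II hydrogen bond planted
at 80% occupancy, detects it geometrically (H...A < 2.4 A, D-H...A > 120 deg),
and prints the occupancy matrix with persistence tiers.
"""

from switch_allostery import (
    HBondPlant,
    TrajectorySpec,
    generate_trajectory,
    hbond_occupancy,
    load_regions,
    persistence_tiers,
)

spec = TrajectorySpec(
    n_frames=2000,
    hbond_plants=[HBondPlant(donor_residue=205, acceptor_residue=230, occupancy=0.8)],
    seed=1,
)
traj, ledger = generate_trajectory(spec)
regions = load_regions()

matrix = hbond_occupancy(traj, regions["switch_I"], regions["switch_II"])
tiers = persistence_tiers(matrix, (0.25, 0.50, 0.75))

print(f"frames analysed: {matrix.n_frames}")
for record in matrix.to_records():
    key = (record["donor_residue"], record["donor_atom"],
           record["acceptor_residue"], record["acceptor_atom"])
    print(
        f"  {record['donor_residue']}:{record['donor_atom']} -> "
        f"{record['acceptor_residue']}:{record['acceptor_atom']}  "
        f"occupancy {record['occupancy']:.3f}  tier {tiers.get(key, 0)}"
    )
planted = ledger["hbond_plants"][0]
print(f"ground truth (counted in the generator): {planted['realized']:.3f}")
# The detected occupancy equals the counted ground truth exactly; the tier
# says how many of the 25/50/75% persistence thresholds the bond clears.
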