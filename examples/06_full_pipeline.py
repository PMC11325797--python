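"""End-to-end run: two systems, all stages, and a reference comparison.

Configures a WT-like reference and a variant that (i) melts 9 C lower,
(ii) loses a switch-II/switch-III hydrogen bond, and (iii) shifts its proton-b
fingerprint from 90% to 160% of the reference proton. Runs the pipeline and
prints the comparison table a user would inspect.
"""

import json

from switch_allostery import compare_systems, run_pipeline

config = {
    "seed": 11,
    "reference": "WT:GTP",
    "systems": {
        "WT:GTP": {
            "trajectory": {"synthetic": {
                "n_frames": 1000, "seed_offset": 0,
                "hbond_plants": [
                    {"donor_residue": 228, "acceptor_residue": 259,
                     "occupancy": 0.9},
                ],
            }},
            "melt": {"synthetic": {"v50": 71.0, "slope": 2.0,
                                   "noise_sd": 0.01, "seed_offset": 1}},
            "stdaf": {"peaks": [
                {"proton": "a", "I0": 1.0, "Idiff": 0.020, "SNR": 20},
                {"proton": "b", "I0": 1.0, "Idiff": 0.018, "SNR": 18},
            ], "ligand_conc": 2000, "protein_conc": 40},
        },
        "R228C:GTP": {
            "trajectory": {"synthetic": {"n_frames": 1000, "seed_offset": 10}},
            "melt": {"synthetic": {"v50": 62.0, "slope": 2.0,
                                   "noise_sd": 0.01, "seed_offset": 11}},
            "stdaf": {"peaks": [
                {"proton": "a", "I0": 1.0, "Idiff": 0.020, "SNR": 20},
                {"proton": "b", "I0": 1.0, "Idiff": 0.032, "SNR": 18},
            ], "ligand_conc": 2000, "protein_conc": 40},
        },
    },
}

report = run_pipeline(config)
comparison = compare_systems(report, reference="WT:GTP")
variant = comparison["systems"]["R228C:GTP"]

print(f"delta-Tm vs WT: {variant['delta_tm']['delta']:.2f} "
      f"+/- {variant['delta_tm']['sd']:.2f} C")
print("lost switch-II/III H-bonds:",
      variant["hbonds"]["switch_II|switch_III"]["lost"])
print("fingerprint shifts:")
print(json.dumps(variant["fingerprint"], indent=2))
# A destabilized variant shows a negative delta-Tm, the planted bond in the
# 'lost' list, and the proton-b bin moving from weak-moderate to strong.
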