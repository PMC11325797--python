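# Default switch-region residue ranges for the Galpha_S short isoform,
# author (PDB) numbering, inclusive. Override with your own YAML if your
# construct or numbering differs.
regions:
  switch_I: [197, 207]
  switch_II: [219, 236]
  switch_III: [254, 270]
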