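# Monitored nucleotide protons for GDP, labelled a-d as in STD-NMR spectra:
# a = guanine H8, b = ribose H1', c = ribose H2', d = the two equivalent
# H5'/H5'' protons (reported as their arithmetic average).
# Atom names follow PDB ligand nomenclature; this map is configuration, not
# ground truth - adjust it to your ligand's naming.
ligand: GDP
protons:
  a: [H8]
  b: ["H1'"]
  c: ["H2'"]
  d: ["H5'", "H5''"]
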