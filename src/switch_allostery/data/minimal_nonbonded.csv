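# Minimal nonbonded parameter set (charge in e, sigma in Angstrom, epsilon in
# kcal/mol) for the toy backbone and nucleotide atoms used by the synthetic
# generator. Internally consistent but NOT an authoritative force field:
# supply your own table for real systems.
residue_name,atom_name,charge,sigma,epsilon
*,N,-0.50,3.25,0.170
*,H,0.30,0.00,0.000
*,CA,0.14,3.50,0.066
*,HA,0.06,2.50,0.030
*,C,0.50,3.75,0.105
*,O,-0.50,2.96,0.210
GDP,C8,0.20,3.55,0.070
GDP,H8,0.10,2.42,0.030
GDP,C1',0.20,3.50,0.066
GDP,H1',0.10,2.50,0.030
GDP,C2',0.14,3.50,0.066
GDP,H2',0.06,2.50,0.030
GDP,C5',0.14,3.50,0.066
GDP,H5',0.06,2.50,0.030
GDP,H5'',0.06,2.50,0.030
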