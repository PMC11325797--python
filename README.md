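# switch-allostery

Integrative biophysical analysis of G-protein α-subunit (Gα) variants:
quantify how single point mutations reshape the allosteric network linking
the nucleotide-binding pocket to the three "switch" regions. The package
bundles the trajectory-, NMR-, and stability-side analyses that such studies
combine, plus a synthetic-data generator with planted ground truth so every
estimator is testable without proprietary raw data.

It is a library first (`import switch_allostery`), with narrative scripts in
`examples/` and a thin `switch-allostery` CLI for pipeline runs.

## What it computes

**Trajectory metrics** (for MD trajectories in DCD/XTC bound to a PDB
topology, author residue numbering preserved):

- *Hydrogen-bond occupancy matrices* between switch regions. A bond is
  declared geometrically per frame when the H···acceptor distance is < 2.4 Å
  and the donor–H···acceptor angle is > 120°; occupancy is the fraction of
  frames the pair passes. Matrices come at atom and residue granularity, with
  persistence tiers (default thresholds 25/50/75%) and gained/lost/shared
  comparisons between systems.
- *Per-residue backbone RMSF*: for each atom,
  `RMSF = sqrt(mean_t |x(t) − ⟨x⟩|²)` after Kabsch superposition onto the
  iterated mean structure; residues average their N, CA, C, O atoms.
- *Nonbonded interaction energies* between residue groups: bare pairwise
  Coulomb (`k_e q_i q_j / r`, `k_e = 332.0636 kcal·Å/mol/e²`) plus 12-6
  Lennard-Jones sums, frame-averaged and normalized to a reference system.
- *Nucleotide-proton contact profiles*: for each monitored ligand proton
  ("a"–"d"), the fraction of simulation time each protein residue has a
  proton within 6 Å (proximity occupancy) and how often it is the nearest
  residue (closest frequency), with cross-system mean ± SEM aggregation and
  arithmetic averaging of equivalent protons (the H5′/H5′′ pair).

**STD-NMR quantification**: difference spectra, trapezoidal peak
integration, amplification factors

    A_STD = (I0 − Isat)/I0 × [L]/[P],        σ = A_STD / SNR_diff

normalization to a reference proton (errors combined in quadrature on
relative terms), and interaction bins (≤50% weak, 50–100% weak-moderate,
100–150% moderate, >150% strong). FID processing (exponential apodization,
zero-fill, FFT, polynomial baseline) is included for array data.

**Stability and kinetics fits** (trust-region least squares, analytic
Jacobians, deterministic initialization):

    Y = Bottom + (Top − Bottom)/(1 + exp((V50 − X)/Slope))   (thermal melt; V50 = Tm)
    Y = Y0 + (Plateau − Y0)(1 − e^(−k·x))                    (one-phase association)

with replicate Tm aggregation (mean ± SD), ΔTm between nucleotide states,
and standard errors from the fit covariance.

**Synthetic data**: toy trajectories with hydrogen bonds and contacts
planted by a two-state telegraph process at a target occupancy, paired
on/off-resonance spectra with known saturation attenuations, and melt/
kinetics curves with replicate noise. Every generator is seed-deterministic
and returns a ledger of *counted* ground truth with 99% recovery intervals.

## Worked example

`examples/05_melt_and_kinetics.py` fits triplicate melts for a GTP-like and
a GDP-like state with a planted 9 °C stability gap, then an exchange trace
sampled every 12 s for 200 min:

```text
Tm (GTP-like): 70.99 +/- 0.04 C  (n=3)
Tm (GDP-like): 61.98 +/- 0.07 C  (n=3)
delta-Tm: 9.01 +/- 0.08 C
exchange kinetics: k = 0.0200 +/- 0.0001 min^-1 (true 0.02), plateau 180.0
```

The ΔTm recovers the planted GTP-state stabilization within replicate
scatter, and the exchange rate constant is recovered in reciprocal minutes.
`examples/06_full_pipeline.py` runs two systems end to end and prints the
comparison a user would read:

```text
delta-Tm vs WT: -8.98 +/- 0.05 C
lost switch-II/III H-bonds: ['228->259']
```

together with the per-proton fingerprint (proton *b* shifting from 90% /
weak-moderate to 160% / strong). The other examples cover the H-bond
matrices, RMSF/energies, pocket contacts, and the STD quantification path.

CLI equivalents: `switch-allostery run -c config.yaml`, plus `hbonds`,
`rmsf`, `energy`, `contacts`, `stdaf`, `melt-fit`, `kinetics-fit`, `synth`
and `compare` subcommands.

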