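# Methods

This note records the models implemented, the defaults and why they were
chosen, what the synthetic generators do and do not emulate, and the
numerical decisions a maintainer would want to know.

## Hydrogen-bond detection and occupancy

A hydrogen bond between a donor heavy atom D (N or O carrying a hydrogen H)
and an acceptor heavy atom A (any N or O, backbone or sidechain) is declared
in a frame when both geometric criteria hold:

- H···A distance < `max_ha_distance` (default 2.4 Å), and
- D–H···A angle, measured at H, > `min_dha_angle` (default 120°).

The distance is H-to-acceptor, not donor-to-acceptor: the tighter 2.4 Å
cutoff only makes sense for the hydrogen–acceptor separation (a D···A cutoff
would be ~3.5 Å). No angular criterion is applied at the acceptor; this is
the simplest two-parameter geometric definition and the common default in
trajectory analysis. Both cutoffs are configurable.

Donor hydrogens are identified structurally rather than from residue
templates: each hydrogen is attached to its nearest heavy atom within
1.3 Å (using the topology's reference coordinates), and qualifies as polar
when that parent is N or O. This works for arbitrary topologies, including
the toy systems used in testing; it assumes the reference geometry has
chemically sensible bond lengths. A topology with no hydrogens at all raises
an explicit error instead of returning an empty (and misleading) matrix.

Occupancy is the fraction of frames a (D, H, A) triplet passes; both
donation directions between two regions are always evaluated. Matrices are
kept at two granularities, because published inter-switch matrices are
ambiguous between them: atom-level (per D/A atom pair) and residue-level,
where a residue pair counts as bonded in a frame if *any* of its atom pairs
passes (note this is not the max over atom-level occupancies). Persistence
tiers map occupancies to the number of thresholds met — default (0.25,
0.50, 0.75), inclusive `≥` comparisons so boundary values are deterministic
— and network comparisons classify residue pairs as gained/lost/shared at a
single threshold (default 0.5).

## RMSF

Per atom, `RMSF = sqrt(mean_t |x(t) − ⟨x⟩|²)`; per residue, the unweighted
mean over its backbone atoms (N, CA, C, O). For an isotropic Gaussian
fluctuation of per-coordinate SD s this equals `s·sqrt(3)` — the analytic
check used in validation. Trajectories should be superposed first;
superposition uses the Kabsch algorithm against an iteratively refined mean
structure (max 5 iterations, 1e-6 Å convergence — 2 iterations typically
suffice), which is deterministic and standard. Deviations are accumulated
relative to frame 0 before centering so that a strictly static trajectory
yields exactly zero rather than ~1e-16 Å of rounding noise. Hydrogen-bond
and contact geometry are superposition-invariant, so those analyses run on
raw frames.

## Nonbonded interaction energies

Inter-group energy per frame is the bare double sum over atom pairs of
`k_e q_i q_j / r_ij` (k_e = 332.0636 kcal·Å/mol/e²) plus
`4ε_ij[(σ_ij/r)¹² − (σ_ij/r)⁶]`, with geometric-mean combining rules for
both σ and ε by default (Lorentz–Berthelot optional). No distance cutoff,
no solvent screening, no reaction-field correction: groups here are tens of
atoms, exact summation is cheap, and the quantity of scientific interest is
the *ratio* to a reference system, which is far less sensitive to these
choices than absolute energies. The bundled parameter table covers only the
toy atoms and is internally consistent but deliberately minimal — it is not
a validated force field, and real analyses should supply their own table
(CSV: residue_name, atom_name, charge, sigma, epsilon; `*` residue
wildcard). Normalization divides each (system, region-pair) energy by the
reference system's energy for the same pair and refuses references within
1e-9 kcal/mol of zero.

## Nucleotide-proton contacts

Distances are ligand-proton to protein-proton (per residue, the nearest
proton), default radius 6.0 Å. The proton–proton convention was chosen
because saturation transfer is proton-mediated; a heavy-atom convention is
a configuration change away. Per proton and residue the profile reports
proximity occupancy (fraction of frames within the radius) and closest
frequency (fraction of frames as the argmin residue; ties break toward the
lower residue number; frames with nothing in radius credit no residue, so
frequencies can sum below 1). Labels declared as equivalent protons — the
H5′/H5′′ pair sharing one resonance — are reported as the arithmetic
average of the individual protons' profiles. A union-over-protons occupancy
per residue is also emitted. Cross-system aggregation reports mean ± SEM in
percent, counting a residue absent from a system as zero occupancy there.

## STD-NMR quantification

The amplification factor of a ligand signal is
`A_STD = (Idiff / I0) × [L]/[P]`, where I0 is the signal's integral in the
off-resonance (reference) spectrum and Idiff its integral in the difference
spectrum. Prose definitions of "Isat" are often ambiguous between the
on-resonance integral and the difference integral; this package defines the
quantification from the difference integral `Idiff = I0 − Ion` and exposes
both integrals so either convention is recoverable. The associated error is
`σ = A_STD / SNR_diff` with `SNR = max|signal| / (2 × RMS noise)` — the
spectrometer "sino" convention; the divisor is configurable. Because of the
factor 2, σ behaves as an approximately 2-standard-deviation error for the
integral under the default synthetic-spectrum geometry (see below), which
is why ±σ intervals show ~95% empirical coverage in the validation study.

Normalized fingerprints express each proton as a percentage of a reference
proton (chosen as one whose environment is invariant across systems);
relative errors combine in quadrature. Interaction bins: ≤50% weak,
50–100% weak-moderate, 100–150% moderate, >150% strong. The published bin
edges omit exactly 50% and 100%; 50 closes downward and 100 upward (the
reference proton itself sits at 100%), making binning a total function on
[0, ∞).

The primary input path is an instrument-agnostic pre-integrated peak table
(CSV: proton, I0, Idiff, SNR); vendor raw formats are out of scope. For
array data, `process_fid` applies exponential apodization `exp(−π·LB·t)`,
zero-fill, FFT, and optional polynomial (degree ≤ 2) baseline correction on
declared signal-free regions.

## Curve fits

Thermal melts use the Boltzmann sigmoid
`Y = Bottom + (Top−Bottom)/(1 + exp((V50−X)/Slope))` with V50 the melting
temperature Tm (°C) and Slope the transition width (°C). As printed this
curve rises with temperature while a folded-fraction melt falls, so in the
fixed-normalization path (Top = 1, Bottom = 0 held) the model is fit to
(1 − folded fraction) and V50/Slope are reported unchanged in the
equation's own parameterization. Raw-signal curves can be normalized to
folded fraction via an unconstrained pre-fit whose plateaus map to 1
(pre-transition) and 0 (post-transition); the default analysis path is
normalize-then-fix. Exchange kinetics use the one-phase association
`Y = Y0 + (Plateau−Y0)(1 − e^(−k·x))` with k in reciprocal input time
units.

Both fits use scipy's trust-region least squares with analytic Jacobians
and deterministic initialization (V50 from the half-range crossing, Slope =
temperature range/10; k from a log-linear fit of the gap to the plateau
estimate), so results are bit-reproducible without a GUI fitter. Standard
errors come from the Gauss–Newton covariance `(JᵀJ)⁻¹s²`. Guard rails: a
curve whose signal range is within 5× its first-difference noise estimate
raises a no-transition error; a fitted V50 outside the measured temperature
range is a fit failure; a non-positive fitted k is a no-association error;
a fitted 1/k exceeding a third of the observation window sets an
identifiability warning. Replicate Tm aggregation (mean, sample SD) refuses
non-converged members; ΔTm combines SDs in quadrature. Replicates default
to the customary triplicate.

## Synthetic data

The generators emulate the *statistical structure* of the real inputs, not
their physics — no force field, no solvent, no relaxation model. They exist
to give every estimator a ground truth.

**Trajectories.** A miniature topology (13 sparse Gα-like residues — switch
and pocket positions with backbone-only atoms — plus a GDP-like ligand with
the four monitored protons) is perturbed with iid Gaussian displacements of
configurable per-residue SD (default 0.1 Å; residues are spaced 14 Å apart
so nothing interacts unless planted). Hydrogen bonds and contacts are
planted by a two-state telegraph process — dwell times are geometric with
lag-1 autocorrelation `exp(−1/ℓ)`, default correlation length ℓ = 20 frames
— chosen over iid coin flips so occupancy estimates face realistic
autocorrelation. On-frames rigidly translate the moved residue so the
planted geometry is exact (H···O = 2.0 Å at 180°, or the residue's amide
proton at 3 Å from the target ligand proton); the residue template was
designed with the carbonyl O as the −y extremity and the amide H as the +y
extremity so a planted bond is unique and clash-free. The ledger records
the *counted* realized occupancy, re-measured from the emitted coordinates
with inline naive geometry independent of the analysis modules, plus a 99%
recovery interval that inflates the binomial variance by the AR(1) factor
`(1+λ)/(1−λ)`. Known limitation: with fluctuation SDs ≳0.5 Å the planted
contact margins shrink (the toy spacing guarantees a ~3 Å buffer).

**Spectra.** Lorentzian peaks at the four proton shifts (defaults: 800 MHz,
4 Hz linewidth, 8192 points over 14 ppm, ±0.015 ppm integration windows,
unit reference integrals, attenuations α of a few percent, additive
Gaussian noise of SD 0.05 in peak-height units ≈ SNR 20 in the difference
spectrum, L/P = 50). On-resonance integrals are exactly `(1−α)·I0`; an
optional broad protein background appears in both spectra, partially
saturated, and its residual equals the returned control spectrum, so
control subtraction cancels it exactly. The digitization/linewidth defaults
were fixed by an a priori error-propagation argument: with the 2×RMS SNR
convention, `σ = A_STD/SNR` equals ≈2× the true SD of the integral-derived
A_STD when `2πΓ/sqrt(WΔ) ≈ 2` (Γ the half-width, W the window width, Δ the
point spacing), which these defaults satisfy — hence the ~95% coverage of
±σ intervals. What passing does *not* show: real spectra have phase errors,
baseline roll, overlapping multiplets, and t1 noise that the generator does
not model.

**Curves.** Exact model evaluation plus iid Gaussian noise, replicate-wise
independent. Default schedules follow common practice: melts every 1 °C
from 25–89 °C (65 points), kinetics every 12 s for 200 min (1001 points).

All generators draw from a single `numpy` Generator per invocation; the
seed is mandatory and recorded in the ledger, and identical specs and seeds
reproduce outputs bit for bit.

## Pipeline

A run is configured in YAML: per system (variant × nucleotide label), any
of trajectory (files or a synthetic spec), melt, kinetics, and STD peak
inputs. Stages are independent; missing inputs yield explicit skip records
and a failing stage is recorded without halting the rest. Reports are plain
JSON with provenance (config hash, seed, package version) and no
timestamps, so reruns are byte-identical. Mechanistic classification of
variants (gain- vs loss-of-function narratives) is deliberately not
automated: the report juxtaposes ΔTm, H-bond gains/losses, energy ratios,
and fingerprint bin shifts, and leaves interpretation to the analyst.

## Validation problem sizes

The validation suite and `scripts/acceptance.py` use: 20 random 500-frame
fixtures for oracle equivalence; 5000 frames for planted-occupancy recovery
at 0.10/0.50/0.75/0.95; 10,000 frames for the RMSF analytic check; 200
simulated spectra for coverage; 500 melt curves and 300 kinetics traces for
the parameter-recovery studies; 400-frame systems end to end. These sizes
make the statistical tolerances meaningful while keeping a full run in the
single-digit seconds.

## Known limitations

- The H-bond parent assignment trusts reference-geometry bond lengths; a
  distorted input structure could mis-assign hydrogens.
- Energies are bare two-group sums with a minimal bundled parameter set;
  absolute values are not comparable to engine outputs, only ratios are
  meaningful.
- The contact analysis is a structural proxy; no spin-diffusion or
  relaxation modelling (no CORCEMA-style back-prediction) is attempted.
- No Kd estimation from STD build-ups, no van 't Hoff thermodynamics, no
  two-state model testing.
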