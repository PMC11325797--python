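"""Synthetic inputs with planted ground truth.

No raw trajectories, spectra, or melt data accompany the study this package
supports, so every estimator is exercised against generated inputs whose true
values are known by construction:

* toy trajectories on a miniature Gα-like topology, with per-residue Gaussian
  fluctuations and hydrogen-bond/contact events planted by a two-state
  telegraph process whose stationary occupancy equals the requested target;
* paired off/on-resonance STD spectra with per-proton attenuation factors;
* Boltzmann melt curves and one-phase association traces with replicate noise.

Each generator returns its artifact together with a *ledger*: the counted
(not nominal) realized ground truth, plus the statistical interval inside
which a correct estimator must land. Generators are seed-deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import SpecError
from .fits import boltzmann_model, one_phase_model
from .stdnmr import Spectrum1D
from .structures import LigandSelection, Structure, Trajectory

# ---------------------------------------------------------------------------
# Toy topology
# ---------------------------------------------------------------------------

#: Residues of the toy system: a sparse subset of switch-region and
#: binding-pocket residues, placed far apart so that no interactions exist
#: unless planted.
_TOY_RESIDUES = (
    (50, "GLU"), (52, "GLY"), (173, "ASP"), (201, "ARG"), (205, "SER"),
    (227, "GLN"), (228, "ARG"), (230, "GLU"), (258, "ARG"), (259, "GLU"),
    (265, "ARG"), (268, "GLU"), (293, "LYS"),
)

# Local backbone template (A): one polar N-H donor, one carbonyl O acceptor,
# one apolar HA proton. The amide H points along +y and the carbonyl O is the
# -y extremity, so translating an acceptor residue until its O sits 2 A above
# a donor's H plants exactly one clash-free, linear H-bond (closest
# non-planted cross-residue atom pair is then ~3 A apart).
_RESIDUE_TEMPLATE = (
    ("C", "C", (0.00, -0.60, 0.00)),
    ("O", "O", (0.00, -1.83, 0.00)),
    ("CA", "C", (1.30, 0.15, 0.00)),
    ("HA", "H", (1.95, -0.35, 0.85)),
    ("N", "N", (1.45, 1.58, 0.00)),
    ("H", "H", (1.45, 2.59, 0.00)),
)

_LIGAND_ATOMS = (
    ("C8", "C", (0.00, 0.00, 0.00)),
    ("H8", "H", (1.08, 0.00, 0.00)),
    ("C1'", "C", (0.00, 4.00, 0.00)),
    ("H1'", "H", (1.05, 4.30, 0.00)),
    ("C2'", "C", (0.00, 8.00, 0.00)),
    ("H2'", "H", (1.05, 8.30, 0.00)),
    ("C5'", "C", (0.00, 12.00, 0.00)),
    ("H5'", "H", (1.00, 12.40, 0.00)),
    ("H5''", "H", (-0.60, 12.60, 0.60)),
)

_RESIDUE_SPACING = 14.0   # A between toy residues: no accidental interactions
_LIGAND_OFFSET = (40.0, 0.0, 80.0)


def toy_structure() -> Structure:
    """Miniature two-component system: 13 sparse protein residues plus a
    GDP-like ligand, small enough for brute-force O(N^2) oracles."""
    names, elements, resnums, resnames, chains, coords = [], [], [], [], [], []
    for k, (num, rname) in enumerate(_TOY_RESIDUES):
        origin = np.array([0.0, 0.0, _RESIDUE_SPACING * k])
        for aname, el, local in _RESIDUE_TEMPLATE:
            names.append(aname)
            elements.append(el)
            resnums.append(num)
            resnames.append(rname)
            chains.append("A")
            coords.append(origin + np.asarray(local))
    origin = np.asarray(_LIGAND_OFFSET)
    for aname, el, local in _LIGAND_ATOMS:
        names.append(aname)
        elements.append(el)
        resnums.append(400)
        resnames.append("GDP")
        chains.append("A")
        coords.append(origin + np.asarray(local))
    return Structure(names, elements, resnums, resnames, chains, np.asarray(coords))


def toy_ligand_selection() -> LigandSelection:
    return LigandSelection(
        "GDP", {"a": ["H8"], "b": ["H1'"], "c": ["H2'"], "d": ["H5'", "H5''"]}
    )


# ---------------------------------------------------------------------------
# Trajectory generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HBondPlant:
    """Plant a donor(N-H) -> acceptor(O) hydrogen bond between two residues.

    The acceptor residue is rigidly translated so its carbonyl O sits exactly
    2.0 A from the donor H along the N-H axis (angle 180 deg) whenever the
    telegraph process is 'on'.
    """

    donor_residue: int
    acceptor_residue: int
    occupancy: float
    corr_frames: float = 20.0


@dataclass(frozen=True)
class ContactPlant:
    """Plant a protein residue within ``distance`` of a monitored ligand
    proton (the label's first atom) on 'on' frames."""

    residue: int
    proton: str
    occupancy: float
    corr_frames: float = 20.0
    distance: float = 3.0


@dataclass
class TrajectorySpec:
    n_frames: int = 1000
    fluctuation_sd: float | dict = 0.1
    hbond_plants: tuple = ()
    contact_plants: tuple = ()
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise SpecError("a seed is mandatory for synthetic trajectories")
        if self.n_frames < 10:
            raise SpecError("n_frames must be >= 10")
        self.hbond_plants = tuple(self.hbond_plants)
        self.contact_plants = tuple(self.contact_plants)
        for p in (*self.hbond_plants, *self.contact_plants):
            if not 0.0 <= p.occupancy <= 1.0:
                raise SpecError(f"plant occupancy {p.occupancy} outside [0, 1]")
        moved = [p.acceptor_residue for p in self.hbond_plants]
        moved += [p.residue for p in self.contact_plants]
        if len(moved) != len(set(moved)):
            raise SpecError(
                "conflicting plants: a residue may be moved by at most one plant"
            )


def _telegraph(rng: np.random.Generator, n: int, p: float, corr: float) -> np.ndarray:
    """Two-state stationary Markov chain with P(on) = p and lag-1
    autocorrelation exp(-1/corr)."""
    if p <= 0.0:
        return np.zeros(n, dtype=bool)
    if p >= 1.0:
        return np.ones(n, dtype=bool)
    lam = math.exp(-1.0 / corr)
    total = 1.0 - lam                 # a + b
    b = p * total                     # off -> on
    a = total - b                     # on -> off
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < p
    u = rng.random(n - 1)
    for i in range(1, n):
        states[i] = (u[i - 1] >= a) if states[i - 1] else (u[i - 1] < b)
    return states


def _occupancy_interval(p: float, n: int, corr: float, z: float = 2.576):
    """99% interval for a counted occupancy of a telegraph plant, inflating
    the binomial variance by the AR(1) autocorrelation factor (1+r)/(1-r)."""
    lam = math.exp(-1.0 / corr)
    var = p * (1.0 - p) / n * (1.0 + lam) / (1.0 - lam)
    half = z * math.sqrt(var)
    return max(0.0, p - half), min(1.0, p + half)


def generate_trajectory(spec: TrajectorySpec, topology: Structure | None = None):
    """Generate a toy trajectory plus its ground-truth ledger.

    Frames are the reference coordinates plus iid Gaussian displacements of
    the stated per-residue SD; plants then override the moved residue's
    position on 'on' frames. The ledger records, for every plant, the target
    occupancy, the *counted* realized occupancy (re-measured from the emitted
    coordinates with inline naive geometry, independent of the analysis
    modules), and the 99% recovery interval.
    """
    top = topology if topology is not None else toy_structure()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_frames
    base = top.coordinates

    if isinstance(spec.fluctuation_sd, dict):
        sd = np.zeros(top.n_atoms)
        for i in range(top.n_atoms):
            sd[i] = spec.fluctuation_sd.get(int(top.residue_numbers[i]), 0.0)
    else:
        sd = np.full(top.n_atoms, float(spec.fluctuation_sd))
    frames = base[None, :, :] + rng.normal(size=(n, top.n_atoms, 3)) * sd[None, :, None]

    ledger: dict = {
        "seed": spec.seed,
        "n_frames": n,
        "fluctuation_sd": (
            spec.fluctuation_sd
            if not isinstance(spec.fluctuation_sd, dict)
            else dict(spec.fluctuation_sd)
        ),
        "hbond_plants": [],
        "contact_plants": [],
    }

    def atom(resnum, name):
        idx = top.select(residue_numbers=[resnum], atom_names=[name])
        if idx.size != 1:
            raise SpecError(f"residue {resnum} lacks a unique atom {name!r}")
        return int(idx[0])

    for plant in spec.hbond_plants:
        states = _telegraph(rng, n, plant.occupancy, plant.corr_frames)
        h = atom(plant.donor_residue, "H")
        dn = atom(plant.donor_residue, "N")
        o = atom(plant.acceptor_residue, "O")
        acc_atoms = top.select(residue_numbers=[plant.acceptor_residue])
        on = np.flatnonzero(states)
        for f in on:
            u = frames[f, h] - frames[f, dn]
            u /= np.linalg.norm(u)
            target = frames[f, h] + 2.0 * u
            frames[f, acc_atoms] += target - frames[f, o]
        # counted realized occupancy: naive geometric re-measurement
        hv = frames[:, h]
        dv = frames[:, dn]
        ov = frames[:, o]
        dist = np.linalg.norm(ov - hv, axis=1)
        v1 = dv - hv
        v2 = ov - hv
        cosang = np.einsum("ij,ij->i", v1, v2) / (
            np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
        )
        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        realized = float(np.mean((dist < 2.4) & (ang > 120.0)))
        lo, hi = _occupancy_interval(plant.occupancy, n, plant.corr_frames)
        ledger["hbond_plants"].append(
            {
                "donor_residue": plant.donor_residue,
                "acceptor_residue": plant.acceptor_residue,
                "donor_atom": "N",
                "acceptor_atom": "O",
                "target": plant.occupancy,
                "realized": realized,
                "n_on": int(states.sum()),
                "corr_frames": plant.corr_frames,
                "interval99": [lo, hi],
            }
        )

    lig = toy_ligand_selection()
    resolved = lig.resolve(top) if any(
        r == "GDP" for r in top.residue_names
    ) else {}
    for plant in spec.contact_plants:
        if plant.proton not in resolved:
            raise SpecError(f"unknown ligand proton label {plant.proton!r}")
        states = _telegraph(rng, n, plant.occupancy, plant.corr_frames)
        p0 = resolved[plant.proton][0]
        hres = atom(plant.residue, "H")
        res_atoms = top.select(residue_numbers=[plant.residue])
        direction = base[hres] - base[p0]
        direction /= np.linalg.norm(direction)
        on = np.flatnonzero(states)
        for f in on:
            target = frames[f, p0] + plant.distance * direction
            frames[f, res_atoms] += target - frames[f, hres]
        # counted per-atom occupancy: nearest residue proton within 6 A
        res_h = [
            i for i in res_atoms if top.elements[i] == "H"
        ]
        per_atom = {}
        for label_atom in resolved[plant.proton]:
            dmin = np.min(
                np.linalg.norm(
                    frames[:, res_h] - frames[:, label_atom][:, None, :], axis=2
                ),
                axis=1,
            )
            per_atom[str(top.atom_names[label_atom])] = float(np.mean(dmin < 6.0))
        lo, hi = _occupancy_interval(plant.occupancy, n, plant.corr_frames)
        ledger["contact_plants"].append(
            {
                "residue": plant.residue,
                "proton": plant.proton,
                "target": plant.occupancy,
                "realized": float(np.mean(list(per_atom.values()))),
                "per_atom": per_atom,
                "n_on": int(states.sum()),
                "corr_frames": plant.corr_frames,
                "interval99": [lo, hi],
            }
        )

    return Trajectory(top, frames), ledger


# ---------------------------------------------------------------------------
# STD spectra generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtonPeak:
    label: str
    shift_ppm: float
    attenuation: float            # alpha in [0, 1): Ion = (1 - alpha) * Ioff
    integral: float = 1.0
    linewidth_hz: float = 4.0


@dataclass
class SpectraSpec:
    """Paired off/on-resonance spectra with known per-proton attenuation.

    Defaults model a 800 MHz 1D proton spectrum digitized to 8192 points over
    14 ppm with 4 Hz Lorentzian lines; integration windows of +/-0.015 ppm are
    recorded in the ledger. With the 2x-RMS SNR convention these choices make
    sigma = A_STD/SNR an approximately 2-sigma error (see docs/methods.md).
    """

    protons: tuple = (
        ProtonPeak("a", 8.10, 0.020),
        ProtonPeak("b", 5.90, 0.030),
        ProtonPeak("c", 4.60, 0.025),
        ProtonPeak("d", 4.20, 0.015),
    )
    noise_sd: float = 0.05
    background: bool = False
    background_saturation: float = 0.3
    n_points: int = 8192
    ppm_min: float = -2.0
    ppm_max: float = 12.0
    spectrometer_mhz: float = 800.0
    window_halfwidth_ppm: float = 0.015
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise SpecError("a seed is mandatory for synthetic spectra")
        self.protons = tuple(self.protons)
        shifts = [p.shift_ppm for p in self.protons]
        if len(set(shifts)) != len(shifts):
            raise SpecError("proton chemical shifts must be distinct")
        for p in self.protons:
            if not 0.0 <= p.attenuation < 1.0:
                raise SpecError(f"attenuation {p.attenuation} outside [0, 1)")


def _lorentzian(x, x0, area, hwhm):
    return area * (hwhm / np.pi) / ((x - x0) ** 2 + hwhm**2)


def generate_std_spectra(spec: SpectraSpec):
    """(off, on, background) spectra plus a ledger of true attenuations.

    On-resonance peak integrals equal (1 - alpha) x the off-resonance
    integrals; a broad protein background, when enabled, appears in both and
    is partially saturated, so its residual shows up in the difference exactly
    as the returned background (control) spectrum.
    """
    rng = np.random.default_rng(spec.seed)
    ppm = np.linspace(spec.ppm_max, spec.ppm_min, spec.n_points)  # descending
    off = np.zeros_like(ppm)
    on = np.zeros_like(ppm)
    warnings = []
    windows = {}
    for p in spec.protons:
        hwhm_ppm = (p.linewidth_hz / 2.0) / spec.spectrometer_mhz
        peak = _lorentzian(ppm, p.shift_ppm, p.integral, hwhm_ppm)
        off += peak
        on += (1.0 - p.attenuation) * peak
        windows[p.label] = (
            p.shift_ppm - spec.window_halfwidth_ppm,
            p.shift_ppm + spec.window_halfwidth_ppm,
        )
    for p1 in spec.protons:
        for p2 in spec.protons:
            if p1.label < p2.label and abs(p1.shift_ppm - p2.shift_ppm) < 2 * spec.window_halfwidth_ppm:
                warnings.append(
                    f"windows of protons {p1.label!r} and {p2.label!r} overlap"
                )
    bg_diff = np.zeros_like(ppm)
    if spec.background:
        bg = 0.5 * np.exp(-0.5 * ((ppm - 1.0) / 1.0) ** 2)
        off = off + bg
        on = on + (1.0 - spec.background_saturation) * bg
        bg_diff = spec.background_saturation * bg
    noise = spec.noise_sd
    off_spec = Spectrum1D(ppm, off + rng.normal(size=ppm.shape) * noise,
                          {"role": "off", "seed": spec.seed})
    on_spec = Spectrum1D(ppm, on + rng.normal(size=ppm.shape) * noise,
                         {"role": "on", "seed": spec.seed})
    bg_spec = Spectrum1D(ppm, bg_diff + (rng.normal(size=ppm.shape) * noise
                                         if noise > 0 else 0.0),
                         {"role": "background", "seed": spec.seed})
    ledger = {
        "seed": spec.seed,
        "noise_sd": noise,
        "protons": {
            p.label: {
                "shift_ppm": p.shift_ppm,
                "attenuation": p.attenuation,
                "integral": p.integral,
                "window": list(windows[p.label]),
            }
            for p in spec.protons
        },
        "noise_window": [9.5, 11.5],
        "warnings": warnings,
    }
    return off_spec, on_spec, bg_spec, ledger


# ---------------------------------------------------------------------------
# Curve generator
# ---------------------------------------------------------------------------

@dataclass
class CurveSpec:
    """Melt curves (folded fraction vs deg C) or association traces.

    Default schedules follow common experimental practice: melts sampled every
    1 deg C from 25 to 89 deg C, kinetics every 12 s (0.2 min) for 200 min.
    """

    model: str = "boltzmann"
    params: dict = field(default_factory=dict)
    x: np.ndarray | None = None
    noise_sd: float = 0.0
    replicates: int = 3
    seed: int | None = None

    def __post_init__(self):
        if self.seed is None:
            raise SpecError("a seed is mandatory for synthetic curves")
        if self.model not in ("boltzmann", "one_phase"):
            raise SpecError(f"unknown curve model {self.model!r}")
        if self.replicates < 1:
            raise SpecError("replicate count must be >= 1")
        if self.x is None:
            if self.model == "boltzmann":
                self.x = np.arange(25.0, 90.0, 1.0)      # 65 points
            else:
                self.x = np.arange(0.0, 200.0 + 1e-9, 0.2)  # 12 s steps, 1001 pts
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.model == "boltzmann" and np.any(self.x < -273.15):
            raise SpecError("temperatures below absolute zero")
        if self.model == "one_phase" and np.any(self.x < 0):
            raise SpecError("negative times outside the association model domain")


def generate_curves(spec: CurveSpec):
    """Replicate curves (x, y) plus a ledger of the true parameters.

    Boltzmann curves are emitted as *folded fraction*, which falls with
    temperature: f(X) = 1 - [Bottom + (Top-Bottom)/(1 + exp((V50-X)/Slope))].
    """
    rng = np.random.default_rng(spec.seed)
    if spec.model == "boltzmann":
        p = {"v50": 62.0, "slope": 2.0, "top": 1.0, "bottom": 0.0, **spec.params}
        clean = 1.0 - boltzmann_model(spec.x, p["bottom"], p["top"], p["v50"], p["slope"])
    else:
        p = {"y0": 100.0, "plateau": 180.0, "k": 0.02, **spec.params}
        clean = one_phase_model(spec.x, p["y0"], p["plateau"], p["k"])
    curves = []
    for _ in range(spec.replicates):
        y = clean + rng.normal(size=spec.x.shape) * spec.noise_sd
        curves.append((spec.x.copy(), y))
    ledger = {
        "seed": spec.seed,
        "model": spec.model,
        "params": p,
        "noise_sd": spec.noise_sd,
        "replicates": spec.replicates,
        "n_points": int(len(spec.x)),
    }
    return curves, ledger
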