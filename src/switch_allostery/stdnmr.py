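"""STD-NMR quantification: difference spectra, integration, amplification
factors with error propagation, reference normalization, and interaction bins.

The amplification factor of a ligand signal is

    A_STD = (I0 - Isat) / I0 * [L] / [P]

where I0 is the signal's integral in the reference (off-resonance) spectrum,
(I0 - Isat) is its integral in the difference spectrum, and [L]/[P] is the
molar excess of ligand over protein. The associated error is
sigma = A_STD / SNRdiff, with SNRdiff the signal-to-noise of the signal in the
difference spectrum (peak over 2x RMS noise, the common spectrometer "sino"
convention). Fingerprints are expressed as percentages of a reference proton
and mapped to four interaction bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlignmentError,
    ConfigError,
    DegenerateNoiseError,
    DomainError,
    NormalizationError,
    WindowError,
)

#: Interaction bins for normalized fingerprints (percent of reference proton).
BIN_WEAK = "weak"
BIN_WEAK_MODERATE = "weak-moderate"
BIN_MODERATE = "moderate"
BIN_STRONG = "strong"


@dataclass
class Spectrum1D:
    """1D spectrum on a strictly monotone (conventionally descending) ppm axis."""

    ppm: np.ndarray
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ppm = np.asarray(self.ppm, dtype=np.float64)
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.ppm.shape != self.intensity.shape or self.ppm.ndim != 1:
            raise ConfigError("ppm axis and intensity must be equal-length 1D arrays")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ConfigError("ppm axis must be strictly monotone")

    @property
    def n_points(self) -> int:
        return len(self.ppm)


def difference_spectrum(
    off: Spectrum1D, on: Spectrum1D, background: Spectrum1D | None = None
) -> Spectrum1D:
    """off - on (minus an optional background); axes must agree to 1e-9 ppm."""
    for other, name in ((on, "on"), (background, "background")):
        if other is None:
            continue
        if other.n_points != off.n_points or np.max(np.abs(other.ppm - off.ppm)) > 1e-9:
            raise AlignmentError(
                f"{name}-resonance axis differs from off-resonance axis; "
                "no silent interpolation is performed"
            )
    diff = off.intensity - on.intensity
    if background is not None:
        diff = diff - background.intensity
    return Spectrum1D(off.ppm.copy(), diff, dict(off.metadata))


def _window_mask(spec: Spectrum1D, window) -> np.ndarray:
    lo, hi = sorted(float(w) for w in window)
    mask = (spec.ppm >= lo) & (spec.ppm <= hi)
    return mask


def integrate_peak(spec: Spectrum1D, window) -> float:
    """Sign-preserving trapezoidal integral (intensity x ppm) over a window."""
    mask = _window_mask(spec, window)
    if mask.sum() < 2:
        raise WindowError(f"window {tuple(window)} overlaps <2 points of the axis")
    x = spec.ppm[mask]
    y = spec.intensity[mask]
    order = np.argsort(x)
    return float(np.trapezoid(y[order], x[order]))


def compute_std_af(i0: float, idiff: float, ligand_conc: float, protein_conc: float) -> float:
    """A_STD = (Idiff / I0) * ([L] / [P]); concentrations in matching units."""
    if i0 <= 0:
        raise DomainError("reference integral I0 must be positive")
    if protein_conc <= 0 or ligand_conc < 0:
        raise DomainError("concentrations must be positive")
    return (idiff / i0) * (ligand_conc / protein_conc)


def compute_af_error(astd: float, snr_diff: float) -> float:
    """sigma = A_STD / SNRdiff."""
    if snr_diff <= 0:
        raise DomainError("SNRdiff must be positive")
    return astd / snr_diff


def bin_interaction(normalized_pct: float) -> str:
    """Map a normalized fingerprint percentage to an interaction bin.

    <=50 -> weak; (50, 100) -> weak-moderate; [100, 150] -> moderate;
    >150 -> strong. The published bins omit exactly 50% and 100%; 50 is closed
    downward and 100 upward (the reference proton itself sits at 100).
    """
    if normalized_pct < 0:
        raise DomainError("normalized percentage cannot be negative")
    if normalized_pct <= 50:
        return BIN_WEAK
    if normalized_pct < 100:
        return BIN_WEAK_MODERATE
    if normalized_pct <= 150:
        return BIN_MODERATE
    return BIN_STRONG


@dataclass(frozen=True)
class STDAFResult:
    proton: str
    astd: float
    sigma: float
    normalized_pct: float
    normalized_sigma_pct: float
    bin: str
    ligand_conc: float
    protein_conc: float


def normalize_af(
    afs: Mapping[str, float],
    sigmas: Mapping[str, float],
    reference: str,
    ligand_conc: float = float("nan"),
    protein_conc: float = float("nan"),
) -> dict:
    """Express amplification factors as percent of a reference proton.

    Relative errors combine in quadrature:
    (sig_norm/norm)^2 = (sig/astd)^2 + (sig_ref/astd_ref)^2. The reference
    proton is reported at exactly 100% carrying its own relative error.
    """
    if reference not in afs:
        raise NormalizationError(f"reference proton {reference!r} missing")
    ref = afs[reference]
    if ref <= 0:
        raise NormalizationError("reference A_STD must be positive")
    ref_rel = sigmas[reference] / ref if ref else 0.0
    out = {}
    for proton, astd in afs.items():
        pct = 100.0 * astd / ref
        rel = (sigmas[proton] / astd) if astd else 0.0
        if proton == reference:
            sig_pct = 100.0 * ref_rel
        else:
            sig_pct = pct * float(np.hypot(rel, ref_rel))
        out[proton] = STDAFResult(
            proton=proton,
            astd=float(astd),
            sigma=float(sigmas[proton]),
            normalized_pct=float(pct),
            normalized_sigma_pct=float(abs(sig_pct)),
            bin=bin_interaction(pct),
            ligand_conc=float(ligand_conc),
            protein_conc=float(protein_conc),
        )
    return out


def estimate_snr(
    spec: Spectrum1D,
    signal_window,
    noise_window,
    noise_divisor: float = 2.0,
) -> float:
    """SNR = max |intensity| in signal window / (divisor x RMS of the
    mean-removed noise window). Windows must not overlap."""
    s_lo, s_hi = sorted(float(w) for w in signal_window)
    n_lo, n_hi = sorted(float(w) for w in noise_window)
    if max(s_lo, n_lo) < min(s_hi, n_hi):
        raise WindowError("signal and noise windows overlap")
    smask = _window_mask(spec, signal_window)
    nmask = _window_mask(spec, noise_window)
    if not smask.any() or nmask.sum() < 2:
        raise WindowError("signal or noise window does not overlap the axis")
    noise = spec.intensity[nmask]
    rms = float(np.sqrt(np.mean((noise - noise.mean()) ** 2)))
    if rms == 0:
        raise DegenerateNoiseError("noise window has zero variance")
    return float(np.max(np.abs(spec.intensity[smask])) / (noise_divisor * rms))


def process_fid(
    fid: np.ndarray,
    line_broadening_hz: float,
    zero_fill: int,
    spectral_width_hz: float,
    spectrometer_freq_mhz: float,
    carrier_ppm: float = 0.0,
    baseline_regions: Sequence | None = None,
    baseline_degree: int = 2,
) -> Spectrum1D:
    """Exponential apodization, zero-fill, FFT, and polynomial baseline.

    The FID is multiplied by exp(-pi * LB * t), zero-filled to ``zero_fill``
    complex points, Fourier transformed, and (optionally) baseline-corrected
    by a polynomial of degree <= 2 fitted on declared signal-free ppm regions.
    Returns a Spectrum1D on a descending ppm axis (real part).
    """
    fid = np.asarray(fid, dtype=np.complex128)
    if fid.ndim != 1 or len(fid) < 2:
        raise ConfigError("FID must be a 1D array of length >= 2")
    if zero_fill < len(fid):
        raise ConfigError(
            f"zero_fill ({zero_fill}) smaller than FID length ({len(fid)})"
        )
    if baseline_degree > 2:
        raise ConfigError("baseline polynomial degree is capped at 2")
    dwell = 1.0 / spectral_width_hz
    t = np.arange(len(fid)) * dwell
    apodized = fid * np.exp(-np.pi * line_broadening_hz * t)
    spec = np.fft.fftshift(np.fft.fft(apodized, n=int(zero_fill)))
    freq_hz = np.fft.fftshift(np.fft.fftfreq(int(zero_fill), d=dwell))
    ppm = carrier_ppm + freq_hz / spectrometer_freq_mhz
    # descending ppm convention
    order = np.argsort(ppm)[::-1]
    ppm = ppm[order]
    real = spec.real[order]
    if baseline_regions:
        mask = np.zeros(len(ppm), dtype=bool)
        for lo, hi in (sorted(map(float, w)) for w in baseline_regions):
            mask |= (ppm >= lo) & (ppm <= hi)
        if mask.sum() > baseline_degree:
            coeff = np.polynomial.polynomial.polyfit(
                ppm[mask], real[mask], baseline_degree
            )
            real = real - np.polynomial.polynomial.polyval(ppm, coeff)
    return Spectrum1D(
        ppm,
        real,
        {
            "line_broadening_hz": line_broadening_hz,
            "zero_fill": int(zero_fill),
            "spectral_width_hz": spectral_width_hz,
            "spectrometer_freq_mhz": spectrometer_freq_mhz,
        },
    )


def analyze_peak_table(
    table: pd.DataFrame,
    ligand_conc: float,
    protein_conc: float,
    reference: str,
) -> dict:
    """Full AF analysis from a pre-integrated peak table.

    Expected columns: proton, I0, Idiff, SNR (integration windows, if present,
    are carried through untouched). Returns {proton: STDAFResult}.
    """
    required = {"proton", "I0", "Idiff", "SNR"}
    if not required <= set(table.columns):
        raise ConfigError(f"peak table needs columns {sorted(required)}")
    afs, sigmas = {}, {}
    for _, row in table.iterrows():
        astd = compute_std_af(row["I0"], row["Idiff"], ligand_conc, protein_conc)
        afs[str(row["proton"])] = astd
        sigmas[str(row["proton"])] = compute_af_error(astd, row["SNR"])
    return normalize_af(afs, sigmas, reference, ligand_conc, protein_conc)
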