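"""STD-NMR spectral processing and amplification-factor quantification."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from switch_allostery import (
    Spectrum1D,
    bin_interaction,
    compute_af_error,
    compute_std_af,
    difference_spectrum,
    estimate_snr,
    integrate_peak,
    normalize_af,
    process_fid,
)
from switch_allostery.errors import (
    AlignmentError,
    ConfigError,
    DegenerateNoiseError,
    DomainError,
    NormalizationError,
    WindowError,
)


def _axis(n=2000, lo=-1.0, hi=11.0):
    return np.linspace(hi, lo, n)  # descending


def test_difference_of_identical_spectra_is_zero():
    x = _axis()
    off = Spectrum1D(x, np.sin(x))
    on = Spectrum1D(x.copy(), np.sin(x))
    assert np.all(difference_spectrum(off, on).intensity == 0.0)


def test_difference_recovers_planted_delta_and_background():
    x = _axis()
    peak = np.exp(-0.5 * ((x - 5.0) / 0.01) ** 2)
    bg = 0.3 * np.exp(-0.5 * ((x - 1.0) / 1.0) ** 2)
    on = Spectrum1D(x, peak + bg)
    off = Spectrum1D(x, peak + 0.25 * peak + bg + 0.1 * bg)
    d = difference_spectrum(off, on, Spectrum1D(x, 0.1 * bg))
    np.testing.assert_allclose(d.intensity, 0.25 * peak, atol=1e-12)


def test_difference_rejects_mismatched_axes():
    off = Spectrum1D(_axis(), np.zeros(2000))
    on = Spectrum1D(_axis() + 1e-6, np.zeros(2000))
    with pytest.raises(AlignmentError):
        difference_spectrum(off, on)


def test_integrate_rectangle_area():
    x = _axis(12001, -1.0, 11.0)
    y = np.where(np.abs(x - 5.0) <= 0.05, 1.0, 0.0)
    area = integrate_peak(Spectrum1D(x, y), (4.95, 5.05))
    assert area == pytest.approx(0.1, rel=1e-3)


def test_integrate_lorentzian_captures_unit_area():
    hwhm = 0.004
    x = _axis(60001, 0.0, 10.0)
    y = (hwhm / np.pi) / ((x - 5.0) ** 2 + hwhm**2)
    # window spanning +/-50 half-widths holds ~98.7% of a unit Lorentzian
    area = integrate_peak(Spectrum1D(x, y), (5.0 - 50 * hwhm, 5.0 + 50 * hwhm))
    assert 0.98 <= area <= 1.0


def test_integrate_outside_data_is_window_error():
    with pytest.raises(WindowError):
        integrate_peak(Spectrum1D(_axis(), np.zeros(2000)), (100.0, 101.0))


@pytest.mark.parametrize(
    "i0,idiff,lp,expected",
    [
        (1.0, 0.02, 50.0, 1.0),   # the canonical 2 mM / 40 uM setup
        (1.0, 0.0, 50.0, 0.0),
        (2.0, 0.2, 50.0, 5.0),
    ],
)
def test_amplification_factor_closed_form(i0, idiff, lp, expected):
    assert compute_std_af(i0, idiff, lp * 40.0, 40.0) == pytest.approx(expected)


def test_amplification_factor_domain_errors():
    with pytest.raises(DomainError):
        compute_std_af(0.0, 0.1, 2000.0, 40.0)
    with pytest.raises(DomainError):
        compute_std_af(1.0, 0.1, 2000.0, 0.0)


def test_af_error_formula():
    assert compute_af_error(1.0, 20.0) == pytest.approx(0.05)
    assert compute_af_error(5.0, 10.0) == pytest.approx(0.5)
    assert compute_af_error(1.0, 1e9) == pytest.approx(0.0, abs=1e-8)
    with pytest.raises(DomainError):
        compute_af_error(1.0, 0.0)


def test_normalize_af_reference_and_quadrature():
    afs = {"a": 2.0, "b": 3.0}
    sigmas = {"a": 2.0 * 0.04, "b": 3.0 * 0.03}
    out = normalize_af(afs, sigmas, "a")
    assert out["a"].normalized_pct == pytest.approx(100.0)
    assert out["b"].normalized_pct == pytest.approx(150.0)
    # 3-4-5: relative errors 3% and 4% combine to 5%
    assert out["b"].normalized_sigma_pct / out["b"].normalized_pct == pytest.approx(0.05)
    # zero errors propagate to zero
    out2 = normalize_af({"a": 1.0, "b": 1.5}, {"a": 0.0, "b": 0.0}, "a")
    assert out2["b"].normalized_pct == pytest.approx(150.0)
    assert out2["b"].normalized_sigma_pct == 0.0


def test_normalize_af_bad_reference():
    with pytest.raises(NormalizationError):
        normalize_af({"a": 0.0}, {"a": 0.0}, "a")
    with pytest.raises(NormalizationError):
        normalize_af({"b": 1.0}, {"b": 0.1}, "a")


@pytest.mark.parametrize(
    "pct,expected",
    [
        (45.0, "weak"), (50.0, "weak"), (50.1, "weak-moderate"),
        (99.9, "weak-moderate"), (100.0, "moderate"), (120.0, "moderate"),
        (150.0, "moderate"), (150.1, "strong"), (160.0, "strong"), (0.0, "weak"),
    ],
)
def test_interaction_bins(pct, expected):
    assert bin_interaction(pct) == expected


@settings(max_examples=50, deadline=None, derandomize=True)
@given(hst.floats(0.0, 1e6, allow_nan=False))
def test_binning_total_on_nonnegative_axis(pct):
    assert bin_interaction(pct) in {"weak", "weak-moderate", "moderate", "strong"}


def test_bin_rejects_negative():
    with pytest.raises(DomainError):
        bin_interaction(-1.0)


def test_estimate_snr_by_formula():
    x = _axis(4000, -1.0, 11.0)
    y = np.zeros_like(x)
    y[np.argmin(np.abs(x - 5.0))] = 1.0
    rng = np.random.default_rng(0)
    noise_mask = (x > 8.0) & (x < 10.0)
    noise = rng.normal(scale=0.025, size=noise_mask.sum())
    y[noise_mask] = noise
    snr = estimate_snr(Spectrum1D(x, y), (4.9, 5.1), (8.0, 10.0))
    rms = np.sqrt(np.mean((noise - noise.mean()) ** 2))
    assert snr == pytest.approx(1.0 / (2 * rms))


def test_estimate_snr_degenerate_and_overlap():
    x = _axis(1000)
    flat = Spectrum1D(x, np.ones_like(x))
    with pytest.raises(DegenerateNoiseError):
        estimate_snr(flat, (4.0, 5.0), (8.0, 10.0))
    with pytest.raises(WindowError):
        estimate_snr(flat, (4.0, 9.0), (8.0, 10.0))


def test_process_fid_peak_position_and_linewidth():
    sw, n, mhz = 8000.0, 4096, 800.0
    t = np.arange(n) / sw
    fid = np.exp(1j * 2 * np.pi * 800.0 * t) * np.exp(-np.pi * 2.0 * t)
    spec = process_fid(fid, line_broadening_hz=3.0, zero_fill=65536,
                       spectral_width_hz=sw, spectrometer_freq_mhz=mhz,
                       carrier_ppm=5.0)
    peak_ppm = spec.ppm[np.argmax(spec.intensity)]
    assert peak_ppm == pytest.approx(5.0 + 800.0 / mhz, abs=1e-3)
    half = spec.intensity.max() / 2
    above = spec.ppm[spec.intensity > half]
    fwhm_hz = (above.max() - above.min()) * mhz
    # natural width 2 Hz + 3 Hz broadening ~ 5 Hz Lorentzian
    assert fwhm_hz == pytest.approx(5.0, abs=0.6)


def test_process_fid_zero_input_and_bad_zero_fill():
    fid = np.zeros(64, dtype=complex)
    spec = process_fid(fid, 3.0, 128, 8000.0, 800.0)
    assert np.all(spec.intensity == 0.0)
    with pytest.raises(ConfigError):
        process_fid(fid, 3.0, 32, 8000.0, 800.0)


def test_process_fid_baseline_correction_removes_offset():
    sw, n = 8000.0, 1024
    t = np.arange(n) / sw
    fid = np.exp(1j * 2 * np.pi * 400.0 * t) * np.exp(-np.pi * 5.0 * t)
    fid[0] += 50.0  # constant offset across the spectrum
    spec = process_fid(fid, 0.0, 1024, sw, 800.0, carrier_ppm=5.0,
                       baseline_regions=[(0.5, 4.0), (6.5, 9.5)])
    raw = process_fid(fid, 0.0, 1024, sw, 800.0, carrier_ppm=5.0)
    mask = (spec.ppm > 7.0) & (spec.ppm < 9.0)
    # offset suppressed by >100x in the signal-free region
    assert np.abs(spec.intensity[mask].mean()) < 1e-2 * np.abs(
        raw.intensity[mask].mean()
    )
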