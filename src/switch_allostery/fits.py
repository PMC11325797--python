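"""Thermal-unfolding (Boltzmann sigmoidal) and exchange-kinetics
(one-phase association) curve fitting.

Thermal melts are fit to the Boltzmann sigmoid

    Y(X) = Bottom + (Top - Bottom) / (1 + exp((V50 - X) / Slope))

where V50 is the midpoint temperature (the melting temperature Tm, deg C) and
Slope (deg C) sets the transition width. As printed, this curve *rises* with
temperature; a folded-fraction melt falls, so with ``fix_normalization`` the
model is fit to (1 - folded fraction) with Top = 1 and Bottom = 0 held fixed,
and V50/Slope are reported in the equation's own parameterization.

Exchange kinetics are fit to the one-phase association

    Y(x) = Y0 + (Plateau - Y0) * (1 - exp(-k * x))

with k the rate constant in reciprocal x-axis time units.

Both fits use trust-region least squares with analytic Jacobians and
deterministic data-driven initialization, so results are reproducible without
a GUI fitter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AggregationError,
    ConfigError,
    FitFailureError,
    NoAssociationError,
    NormalizationError,
    NoTransitionError,
)


def boltzmann_model(x, bottom, top, v50, slope):
    return bottom + (top - bottom) / (1.0 + np.exp((v50 - x) / slope))


def one_phase_model(x, y0, plateau, k):
    return y0 + (plateau - y0) * (1.0 - np.exp(-k * x))


def _noise_estimate(y: np.ndarray) -> float:
    """Local noise level from first differences (robust to slow trends)."""
    return float(np.std(np.diff(y)) / np.sqrt(2.0)) if len(y) > 2 else 0.0


def _standard_errors(jac: np.ndarray, residuals: np.ndarray) -> np.ndarray:
    dof = max(len(residuals) - jac.shape[1], 1)
    s2 = float(residuals @ residuals) / dof
    try:
        cov = np.linalg.inv(jac.T @ jac) * s2
        return np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    except np.linalg.LinAlgError:
        return np.full(jac.shape[1], np.nan)


@dataclass
class MeltCurve:
    """Temperature scan: strictly increasing temperatures (deg C) and >=8
    points, in either raw ellipticity or folded-fraction units."""

    temperature: np.ndarray
    signal: np.ndarray
    replicate: int | str | None = None

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=np.float64)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.temperature.shape != self.signal.shape:
            raise ConfigError("temperature and signal lengths differ")
        if len(self.temperature) < 8:
            raise ConfigError("melt curve needs >= 8 points spanning the transition")
        if not np.all(np.diff(self.temperature) > 0):
            raise ConfigError("temperatures must be strictly increasing")


@dataclass
class MeltFitResult:
    v50: float
    slope: float
    top: float
    bottom: float
    v50_se: float
    slope_se: float
    converged: bool
    fixed_normalization: bool

    @property
    def tm(self) -> float:
        return self.v50


@dataclass
class KineticsFit:
    y0: float
    plateau: float
    k: float
    y0_se: float
    plateau_se: float
    k_se: float
    converged: bool
    identifiability_warning: bool = False


def fit_boltzmann(curve: MeltCurve, fix_normalization: bool = True) -> MeltFitResult:
    """Fit the Boltzmann sigmoid to a melt curve.

    With ``fix_normalization`` the signal must be folded fraction (1 -> 0);
    Top/Bottom are pinned at 1/0 and the model is fit to the unfolded fraction
    (1 - signal). Otherwise all four parameters float and the signal may be in
    any units and either orientation.
    """
    x = curve.temperature
    noise = _noise_estimate(curve.signal)
    span = float(np.ptp(curve.signal))
    if span <= max(5.0 * noise, 1e-12):
        raise NoTransitionError(
            f"signal range {span:.3g} is within noise ({noise:.3g}); "
            "no unfolding transition to fit"
        )
    y = 1.0 - curve.signal if fix_normalization else curve.signal

    # deterministic initialization: midpoint crossing and a tenth-range slope
    lo, hi = float(y[0]), float(y[-1])
    half = 0.5 * (lo + hi)
    crossing = np.argmin(np.abs(y - half))
    v50_0 = float(x[crossing])
    slope_0 = float(np.ptp(x)) / 10.0
    sign = 1.0 if hi >= lo else -1.0

    if fix_normalization:
        def residual(p):
            return boltzmann_model(x, 0.0, 1.0, p[0], p[1]) - y

        def jacobian(p):
            v50, slope = p
            e = np.exp((v50 - x) / slope)
            denom = (1.0 + e) ** 2
            dv50 = -e / (slope * denom)
            dslope = e * (v50 - x) / (slope**2 * denom)
            return np.column_stack([dv50, dslope])

        p0 = [v50_0, slope_0]
    else:
        def residual(p):
            return boltzmann_model(x, p[0], p[1], p[2], p[3]) - y

        def jacobian(p):
            bottom, top, v50, slope = p
            e = np.exp((v50 - x) / slope)
            f = 1.0 / (1.0 + e)
            denom = (1.0 + e) ** 2
            dbottom = 1.0 - f
            dtop = f
            dv50 = -(top - bottom) * e / (slope * denom)
            dslope = (top - bottom) * e * (v50 - x) / (slope**2 * denom)
            return np.column_stack([dbottom, dtop, dv50, dslope])

        p0 = [lo, hi, v50_0, sign * slope_0]

    result = least_squares(residual, p0, jac=jacobian, method="trf", x_scale="jac")
    if not result.success:
        raise FitFailureError(
            "Boltzmann fit did not converge", {"status": result.status}
        )
    if fix_normalization:
        v50, slope = result.x
        bottom, top = 0.0, 1.0
        ses = _standard_errors(result.jac, result.fun)
        v50_se, slope_se = ses
    else:
        bottom, top, v50, slope = result.x
        ses = _standard_errors(result.jac, result.fun)
        v50_se, slope_se = ses[2], ses[3]
    if not (x[0] <= v50 <= x[-1]):
        raise FitFailureError(
            f"fitted V50 = {v50:.2f} lies outside the measured range "
            f"[{x[0]:.1f}, {x[-1]:.1f}]",
            {"v50": float(v50)},
        )
    return MeltFitResult(
        v50=float(v50),
        slope=float(slope),
        top=float(top),
        bottom=float(bottom),
        v50_se=float(v50_se),
        slope_se=float(slope_se),
        converged=True,
        fixed_normalization=fix_normalization,
    )


def normalize_to_folded_fraction(curve: MeltCurve) -> MeltCurve:
    """Map a raw melt curve to folded fraction via an unconstrained pre-fit.

    The pre-transition plateau (low temperature) maps to 1 and the
    post-transition plateau to 0.
    """
    fit = fit_boltzmann(curve, fix_normalization=False)
    pre = boltzmann_model(curve.temperature[0], fit.bottom, fit.top, fit.v50, fit.slope)
    post = boltzmann_model(curve.temperature[-1], fit.bottom, fit.top, fit.v50, fit.slope)
    noise = _noise_estimate(curve.signal)
    if abs(pre - post) <= max(5.0 * noise, 1e-12):
        raise NormalizationError("pre- and post-transition plateaus indistinguishable")
    folded = (curve.signal - post) / (pre - post)
    return MeltCurve(curve.temperature.copy(), folded, curve.replicate)


@dataclass
class AggregatedTm:
    mean: float
    sd: float
    n: int
    values: tuple


def aggregate_tm(fits) -> AggregatedTm:
    """Arithmetic mean and sample SD of replicate V50 values (all must have
    converged; the customary replicate count is three)."""
    fits = list(fits)
    if len(fits) < 2:
        raise AggregationError("need >= 2 replicates to aggregate")
    bad = [i for i, f in enumerate(fits) if not f.converged]
    if bad:
        raise AggregationError(f"non-converged replicates at positions {bad}")
    values = np.asarray([f.v50 for f in fits])
    return AggregatedTm(
        mean=float(values.mean()),
        sd=float(values.std(ddof=1)),
        n=len(values),
        values=tuple(float(v) for v in values),
    )


@dataclass
class DeltaTm:
    delta: float
    sd: float


def delta_tm(state_a: AggregatedTm, state_b: AggregatedTm) -> DeltaTm:
    """Tm difference (a - b) with SDs combined in quadrature."""
    return DeltaTm(
        delta=float(state_a.mean - state_b.mean),
        sd=float(np.hypot(state_a.sd, state_b.sd)),
    )


def fit_one_phase(time: np.ndarray, signal: np.ndarray) -> KineticsFit:
    """Fit a one-phase association trace; k is in reciprocal input time units.

    Warns (flag on the result) when the fitted 1/k exceeds a third of the
    observation window, i.e. when the plateau is poorly identified.
    """
    x = np.asarray(time, dtype=np.float64)
    y = np.asarray(signal, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigError("time and signal must be equal-length 1D arrays")
    if len(x) < 20:
        raise ConfigError("one-phase fit needs >= 20 points")
    if np.any(x < 0):
        raise ConfigError("negative times are not in the model's domain")

    y0_0 = float(y[0])
    tail = max(len(y) // 10, 3)
    plateau_0 = float(y[-tail:].mean())
    # log-linear slope of the approach to the plateau estimate
    gap = (plateau_0 - y) if plateau_0 >= y0_0 else (y - plateau_0)
    pos = gap > max(abs(plateau_0 - y0_0), 1e-12) * 1e-3
    if pos.sum() >= 2:
        coeff = np.polyfit(x[pos], np.log(gap[pos]), 1)
        k0 = max(-float(coeff[0]), 1e-9)
    else:
        k0 = 1.0 / max(float(x[-1]), 1e-9)

    def residual(p):
        return one_phase_model(x, p[0], p[1], p[2]) - y

    def jacobian(p):
        y0, plateau, k = p
        e = np.exp(-k * x)
        return np.column_stack([e, 1.0 - e, (plateau - y0) * x * e])

    result = least_squares(
        residual, [y0_0, plateau_0, k0], jac=jacobian, method="trf", x_scale="jac"
    )
    if not result.success:
        raise FitFailureError("one-phase fit did not converge",
                              {"status": result.status})
    y0, plateau, k = result.x
    if k <= 0:
        raise NoAssociationError(f"fitted rate constant k = {k:.3g} is not positive")
    ses = _standard_errors(result.jac, result.fun)
    window = float(x[-1] - x[0])
    slow = (1.0 / k) > window / 3.0
    if slow:
        warnings.warn(
            "fitted 1/k exceeds a third of the observation window; "
            "plateau and rate are weakly identified"
        )
    return KineticsFit(
        y0=float(y0),
        plateau=float(plateau),
        k=float(k),
        y0_se=float(ses[0]),
        plateau_se=float(ses[1]),
        k_se=float(ses[2]),
        converged=True,
        identifiability_warning=bool(slow),
    )
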