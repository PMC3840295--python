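"""Extraction of relaxation rate constants from intensity-decay tables.

Spin-lock (or inversion-recovery style) decays are fitted with a
two-parameter mono-exponential I(t) = A exp(-R t); errors come from Monte
Carlo resampling of the intensities within their sigmas.  Peak-volume errors
follow the box-sum rule sqrt(n_points) * 3 * noise_sd.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.optimize import curve_fit

from .constants import FieldContext
from .relaxation import SpinLockGeometry, r1rho_to_r2

DEFAULT_N_MC = 2000


def volume_error(n_points: int, noise_sd: float) -> float:
    """Error of a peak volume summed over ``n_points`` spectral points."""
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    return math.sqrt(n_points) * 3.0 * noise_sd


@dataclass
class DecaySeries:
    """Intensity vs spin-lock duration for one residue."""

    durations: np.ndarray
    intensities: np.ndarray
    sigma: np.ndarray

    def __post_init__(self):
        self.durations = np.asarray(self.durations, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.durations) < 3:
            raise ValueError("a decay series needs at least 3 points")
        if not np.all(np.diff(self.durations) > 0):
            raise ValueError("durations must be strictly increasing")
        if not np.all(self.sigma > 0):
            raise ValueError("sigmas must be positive")


@dataclass
class RateEstimate:
    """Fitted rate with Monte-Carlo error; ``flags`` lists QC problems."""

    value: float
    sigma: float
    kind: str = "R1rho"
    field: FieldContext | None = None
    flags: list = dc_field(default_factory=list)
    mc_samples: np.ndarray | None = None


def _monoexp(t, amp, rate):
    return amp * np.exp(-rate * t)


def _fit_once(t, y, sigma):
    # log-linear start values; fall back to crude guesses for flat/negative data
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(t[pos], np.log(y[pos]), 1)
        p0 = (math.exp(intercept), max(-slope, 0.0))
    else:
        p0 = (y[0] if y[0] != 0 else 1.0, 1.0 / (t[-1] - t[0]))
    popt, pcov = curve_fit(_monoexp, t, y, p0=p0, sigma=sigma,
                           absolute_sigma=True, maxfev=10000)
    return popt, pcov


def fit_decay(series: DecaySeries, n_mc: int = DEFAULT_N_MC,
              seed: int | None = 0, kind: str = "R1rho",
              fieldctx: FieldContext | None = None) -> RateEstimate:
    """Mono-exponential least-squares fit with Monte-Carlo error estimate."""
    t, y, s = series.durations, series.intensities, series.sigma
    flags = []
    try:
        popt, pcov = _fit_once(t, y, s)
    except RuntimeError:
        flags.append("not_converged")
        popt, pcov = (np.array([y[0], 0.0]), np.full((2, 2), np.nan))
    rate = popt[1]
    if rate < 0:
        flags.append("negative_rate")
    rng = np.random.default_rng(seed)
    samples = np.empty(n_mc)
    n_fail = 0
    for i in range(n_mc):
        y_mc = y + rng.normal(0.0, s)
        try:
            p_mc, _ = _fit_once(t, y_mc, s)
            samples[i] = p_mc[1]
        except RuntimeError:
            samples[i] = np.nan
            n_fail += 1
    if n_fail:
        flags.append(f"mc_failures:{n_fail}")
    sig = float(np.nanstd(samples))
    if sig == 0.0:
        sig = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else 1e-12
        sig = max(sig, 1e-12)
    return RateEstimate(value=float(rate), sigma=sig, kind=kind,
                        field=fieldctx, flags=flags, mc_samples=samples)


def extract_r2(series: DecaySeries, r1: RateEstimate, geom: SpinLockGeometry,
               n_mc: int = DEFAULT_N_MC, seed: int | None = 0,
               fieldctx: FieldContext | None = None) -> RateEstimate:
    """Fit an R1rho decay and convert to R2 via the tilt-angle correction,
    propagating both the decay-fit and the R1 uncertainty by Monte Carlo."""
    r1rho = fit_decay(series, n_mc=n_mc, seed=seed, kind="R1rho", fieldctx=fieldctx)
    r2_central, flagged = r1rho_to_r2(r1rho.value, r1.value, geom)
    rng = np.random.default_rng(None if seed is None else seed + 1)
    r1_draws = r1.value + rng.normal(0.0, r1.sigma, size=len(r1rho.mc_samples))
    th = math.radians(geom.theta_deg)
    r2_draws = (r1rho.mc_samples - r1_draws * math.cos(th) ** 2) / math.sin(th) ** 2
    flags = list(r1rho.flags)
    if flagged:
        flags.append("low_tilt_angle")
    return RateEstimate(value=float(r2_central), sigma=float(np.nanstd(r2_draws)),
                        kind="R2", field=fieldctx or r1rho.field, flags=flags,
                        mc_samples=r2_draws)
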