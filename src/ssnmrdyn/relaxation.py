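"""Model-free spectral densities and Redfield relaxation rates for amide 15N.

The motional model is either simple model-free (SMF: one order parameter S^2
and one correlation time tau) or extended model-free (EMF: fast and slow
motions with S_f^2, tau_f and S_s^2, tau_s; total order parameter
S_f^2 * S_s^2).  Spectral densities use the normalisation

    J(w) = (1 - S^2) * tau / (1 + w^2 tau^2)

without the isotropic-tumbling 2/5 prefactor (there is no overall tumbling in
the solid); the rate prefactors below absorb that convention.

Rates implemented (d, c from :class:`~ssnmrdyn.constants.InteractionConstants`):

    R2  = (1/20) d^2 [4J(0) + J(wH-wN) + 3J(wN) + 6J(wH) + 6J(wH+wN)]
          + (1/15) c^2 J(wN) + (4/45) c^2 J(0)
    R1  = (1/10) d^2 [J(wH-wN) + 3J(wN) + 6J(wH+wN)] + (2/15) c^2 J(wN)
    eta = (1/15) d c P2(cos beta) [4J(0) + 3J(wN)]

eta is the transverse 1H-15N dipole / 15N CSA cross-correlated rate; beta is
the angle between the N-H bond and the CSA symmetry axis (default 0).  All
model parameters may be numpy arrays, in which case the rates broadcast.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .constants import CONSTANTS, FieldContext, InteractionConstants
from .dataset import Observation, ResidueDataset


def _validate_unit_interval(x, name):
    if not np.all((np.asarray(x) >= 0) & (np.asarray(x) <= 1)):
        raise ValueError(f"{name} must lie in [0, 1]")


def _validate_positive(x, name):
    if not np.all(np.asarray(x) > 0):
        raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class MotionModelSMF:
    """Single-motion model: order parameter S2 and correlation time tau (s)."""

    S2: float
    tau: float

    def __post_init__(self):
        _validate_unit_interval(self.S2, "S2")
        _validate_positive(self.tau, "tau")

    @property
    def s2_total(self):
        return self.S2


@dataclass(frozen=True)
class MotionModelEMF:
    """Two-motion model; total order parameter is Sf2 * Ss2."""

    Sf2: float
    Ss2: float
    tauf: float
    taus: float

    def __post_init__(self):
        _validate_unit_interval(self.Sf2, "Sf2")
        _validate_unit_interval(self.Ss2, "Ss2")
        _validate_positive(self.tauf, "tauf")
        _validate_positive(self.taus, "taus")
        if not np.all(np.asarray(self.tauf) <= np.asarray(self.taus)):
            raise ValueError("tauf must not exceed taus")

    @property
    def s2_total(self):
        return self.Sf2 * self.Ss2


MotionModel = MotionModelSMF | MotionModelEMF


def spectral_density_smf(model: MotionModelSMF, omega):
    """J(w) for the simple model-free form; even in omega, units s/rad."""
    return _jw_smf(model.S2, model.tau, omega)


def _jw_smf(S2, tau, omega):
    return (1.0 - S2) * tau / (1.0 + (omega * tau) ** 2)


def spectral_density_emf(model: MotionModelEMF, omega):
    """J(w) for the extended model-free form: two Lorentzians weighted by
    (1 - Sf2) and Sf2 (1 - Ss2), with tau_f and tau_s in the respective terms."""
    return _jw_emf(model.Sf2, model.Ss2, model.tauf, model.taus, omega)


def _jw_emf(Sf2, Ss2, tauf, taus, omega):
    fast = (1.0 - Sf2) * tauf / (1.0 + (omega * tauf) ** 2)
    slow = Sf2 * (1.0 - Ss2) * taus / (1.0 + (omega * taus) ** 2)
    return fast + slow


def spectral_density(model: MotionModel, omega):
    if isinstance(model, MotionModelSMF):
        return spectral_density_smf(model, omega)
    return spectral_density_emf(model, omega)


def rate_R1(model: MotionModel, fieldctx: FieldContext,
            k: InteractionConstants | None = None):
    """Longitudinal 15N relaxation rate (s^-1)."""
    k = k or InteractionConstants.for_field(fieldctx)
    # the printed rate expressions assume unsigned Larmor frequencies:
    # |wH| - |wN| is the zero-quantum and |wH| + |wN| the double-quantum term
    wh, wn = abs(fieldctx.omega_h), abs(fieldctx.omega_n)
    J = lambda w: spectral_density(model, w)
    return (0.1 * k.d**2 * (J(wh - wn) + 3 * J(wn) + 6 * J(wh + wn))
            + (2.0 / 15.0) * k.c**2 * J(wn))


def rate_R2(model: MotionModel, fieldctx: FieldContext,
            k: InteractionConstants | None = None):
    """Transverse 15N relaxation rate (s^-1), pure stochastic (Redfield) part."""
    k = k or InteractionConstants.for_field(fieldctx)
    wh, wn = abs(fieldctx.omega_h), abs(fieldctx.omega_n)
    J = lambda w: spectral_density(model, w)
    return ((1.0 / 20.0) * k.d**2 * (4 * J(0.0) + J(wh - wn) + 3 * J(wn)
                                     + 6 * J(wh) + 6 * J(wh + wn))
            + (1.0 / 15.0) * k.c**2 * J(wn) + (4.0 / 45.0) * k.c**2 * J(0.0))


def rate_eta(model: MotionModel, fieldctx: FieldContext,
             k: InteractionConstants | None = None, beta_deg: float = 0.0):
    """Transverse dipole-CSA cross-correlated relaxation rate (s^-1).

    The sign follows sign(d*c); for 15N both d and c are negative, so eta is
    positive in this convention.
    """
    if not 0.0 <= beta_deg <= 90.0:
        raise ValueError("beta must be in [0, 90] degrees")
    k = k or InteractionConstants.for_field(fieldctx)
    wn = abs(fieldctx.omega_n)
    p2 = 0.5 * (3.0 * math.cos(math.radians(beta_deg)) ** 2 - 1.0)
    J = lambda w: spectral_density(model, w)
    return (1.0 / 15.0) * k.d * k.c * p2 * (4 * J(0.0) + 3 * J(wn))


@dataclass(frozen=True)
class SpinLockGeometry:
    """Spin-lock geometry: offset and rf field in Hz; tilt angle in degrees."""

    offset_hz: float
    nu1_hz: float

    def __post_init__(self):
        if self.nu1_hz <= 0:
            raise ValueError("spin-lock field strength must be positive")

    @property
    def theta_deg(self) -> float:
        return math.degrees(math.atan2(self.nu1_hz, self.offset_hz))

    @classmethod
    def from_theta(cls, theta_deg: float, nu1_hz: float = 15000.0) -> "SpinLockGeometry":
        if not 0.0 < theta_deg <= 90.0:
            raise ValueError("theta must be in (0, 90] degrees")
        offset = nu1_hz / math.tan(math.radians(theta_deg)) if theta_deg < 90.0 else 0.0
        return cls(offset_hz=offset, nu1_hz=nu1_hz)


#: tilt angles below this are flagged: the 1/sin^2(theta) factor amplifies errors
THETA_FLOOR_DEG = 60.0


def r1rho_to_r2(r1rho, r1, geom: SpinLockGeometry,
                theta_floor_deg: float = THETA_FLOOR_DEG):
    """Off-resonance correction R2 = [R1rho - R1 cos^2(theta)] / sin^2(theta).

    Returns ``(r2, flagged)`` where ``flagged`` is True when the tilt angle is
    below ``theta_floor_deg`` and the conversion is unreliable.
    """
    theta = geom.theta_deg
    if not 0.0 < theta <= 90.0:
        raise ValueError("tilt angle must be in (0, 90] degrees")
    if np.any(np.asarray(r1rho) < 0):
        raise ValueError("R1rho must be non-negative")
    th = math.radians(theta)
    r2 = (r1rho - r1 * math.cos(th) ** 2) / math.sin(th) ** 2
    flagged = theta < theta_floor_deg
    if flagged:
        warnings.warn(f"tilt angle {theta:.1f} deg below {theta_floor_deg} deg; "
                      "R1rho->R2 conversion unreliable", stacklevel=2)
    return r2, flagged


def back_calculate(model: MotionModel, requests, residue: str = "synthetic",
                   k_overrides: dict | None = None) -> ResidueDataset:
    """Back-calculate noiseless observables for ``(kind, FieldContext)`` requests.

    S2dip requests (field entry ignored / None) return the model's total order
    parameter, which is time-scale independent.  Sigmas are set to 1 and are
    meant to be overwritten by the caller's noise model.
    """
    k_overrides = k_overrides or {}
    obs = []
    for kind, fieldctx in requests:
        if kind == "S2dip":
            obs.append(Observation("S2dip", None, float(model.s2_total), 1.0))
            continue
        k = InteractionConstants.for_field(fieldctx, **k_overrides)
        if kind == "R1":
            val = rate_R1(model, fieldctx, k)
        elif kind == "R2":
            val = rate_R2(model, fieldctx, k)
        elif kind == "eta":
            val = rate_eta(model, fieldctx, k)
        else:
            raise ValueError(f"unknown observable kind {kind!r}")
        obs.append(Observation(kind, fieldctx, float(val), 1.0))
    return ResidueDataset(residue, obs)
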