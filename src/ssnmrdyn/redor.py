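"""Numerical REDOR simulation and dipolar-coupling fitting for 2-3 spin systems.

The recoupling element follows the time-shifted REDOR scheme: two 1H pi
pulses per rotor period, nominally at tau_r/2 and tau_r, displaced by
``time_shift`` (towards the centre of the period: tau_r/2 + ts and
tau_r - ts), with a single central 15N pi pulse at half the total recoupling
time.  Shifting the pulses scales down the net recoupled dipolar interaction
(the omega_r harmonic by cos(omega_r ts), while admixing a 2 omega_r
component; both vanish at ts = tau_r/4), which slows the dephasing
oscillation so that it can be sampled on the rotor-synchronised grid.  The
reference experiment S0 omits
the 1H pulses; the dephasing observable is dS/S0 = 1 - S/S0 after powder
averaging.

Propagation is piecewise-constant: the rotor-modulated Hamiltonian (dipolar
couplings, CSAs, offsets, plus rf during pulses) is averaged exactly over
each time slice and exponentiated blockwise (analytic 1x1/2x2 blocks, batched
eigendecomposition for larger blocks), vectorised over the powder
orientations.  Slice boundaries always coincide with pulse edges.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .constants import CONSTANTS, Constants
from .powder import (MAGIC_ANGLE, beta_gamma_quadrature, csa_components,
                     rotate_components, wigner_d2, zcw_orientations)

XY8_PHASES_DEG = (0.0, 90.0, 0.0, 90.0, 90.0, 0.0, 90.0, 0.0)

DEFAULT_N_ORIENT = 144
DEFAULT_N_GAMMA = 16
DEFAULT_SLICES_PER_ROTOR = 100


def pair_anisotropy_from_distance(isotopes, r_angstrom: float,
                                  constants: Constants = CONSTANTS) -> float:
    """Dipolar tensor anisotropy (Hz) from an internuclear distance.

    The anisotropy is twice the dipolar coupling constant,
    2 * (mu0/4pi) gamma_i gamma_j hbar / (2 pi r^3); absolute value reported.
    """
    iso1, iso2 = isotopes
    b = constants.dipolar_b(iso1, iso2, r_angstrom)
    return abs(2.0 * b / (2.0 * math.pi))


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class CsaTensor:
    aniso_hz: float
    asymmetry: float = 0.0
    euler_deg: tuple = (0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SpinSite:
    isotope: str                     # "1H" | "15N"
    offset_hz: float = 0.0
    csa: CsaTensor | None = None

    def __post_init__(self):
        if self.isotope not in ("1H", "15N"):
            raise ValueError("isotope must be '1H' or '15N'")
        if not math.isfinite(self.offset_hz):
            raise ValueError("offset must be finite")


@dataclass(frozen=True)
class DipolarPair:
    i: int
    j: int
    aniso_hz: float                  # tensor anisotropy = 2 b / 2pi
    euler_deg: tuple = (0.0, 0.0, 0.0)

    @classmethod
    def from_distance(cls, i, j, isotopes, r_angstrom, euler_deg=(0.0, 0.0, 0.0),
                      constants: Constants = CONSTANTS) -> "DipolarPair":
        return cls(i, j, pair_anisotropy_from_distance(isotopes, r_angstrom,
                                                       constants), euler_deg)


@dataclass
class SpinSystem:
    sites: list
    pairs: list = field(default_factory=list)

    def __post_init__(self):
        iso = [s.isotope for s in self.sites]
        if iso.count("15N") != 1:
            raise ValueError("a spin system needs exactly one 15N site")
        if not 1 <= iso.count("1H") <= 2:
            raise ValueError("a spin system needs one or two 1H sites")
        for p in self.pairs:
            if p.i == p.j or not (0 <= p.i < len(self.sites)) \
                    or not (0 <= p.j < len(self.sites)):
                raise ValueError("invalid pair indices")

    @property
    def n_index(self) -> int:
        return [s.isotope for s in self.sites].index("15N")

    @property
    def h_indices(self) -> list:
        return [i for i, s in enumerate(self.sites) if s.isotope == "1H"]

    def nh_pair(self) -> "DipolarPair":
        """The N-H pair with the largest anisotropy (the bonded amide pair)."""
        n = self.n_index
        cands = [p for p in self.pairs if n in (p.i, p.j)]
        if not cands:
            raise ValueError("no N-H dipolar pair in the system")
        return max(cands, key=lambda p: abs(p.aniso_hz))


def two_spin_nh(aniso_hz: float | None = None,
                constants: Constants = CONSTANTS) -> SpinSystem:
    """Bare 15N-1H pair along z; the default anisotropy is the effective
    (motionally pre-averaged) 20.4 kHz value rather than the ~22.95 kHz a
    1.02 A bond distance would give."""
    if aniso_hz is None:
        aniso_hz = constants.rigid_NH_anisotropy_hz
    sites = [SpinSite("15N"), SpinSite("1H")]
    return SpinSystem(sites, [DipolarPair(0, 1, aniso_hz)])


def three_spin_hhn(constants: Constants = CONSTANTS) -> SpinSystem:
    """H-H-N benchmark system: amide N-H (20.4 kHz) plus a remote proton at
    2.6 A from H1 and 4.1 A from N, with CSA tensors and offsets on all spins."""
    d_hh = pair_anisotropy_from_distance(("1H", "1H"), 2.6, constants)
    d_nh2 = pair_anisotropy_from_distance(("1H", "15N"), 4.1, constants)
    sites = [
        SpinSite("15N", offset_hz=100.0, csa=CsaTensor(0.0, 0.0, (0.0, 20.0, 0.0))),
        SpinSite("1H", offset_hz=600.0, csa=CsaTensor(1200.0, 0.0, (0.0, 29.0, 0.0))),
        SpinSite("1H", offset_hz=1200.0, csa=CsaTensor(900.0, 0.0, (0.0, -30.0, 0.0))),
    ]
    pairs = [
        DipolarPair(0, 1, constants.rigid_NH_anisotropy_hz, (0.0, 0.0, 0.0)),
        DipolarPair(0, 2, d_nh2, (0.0, 70.0, 0.0)),
        DipolarPair(1, 2, d_hh, (0.0, 22.0, 0.0)),
    ]
    return SpinSystem(sites, pairs)


@dataclass(frozen=True)
class RedorExperiment:
    mas_hz: float = 37037.0
    n_rotor_periods: tuple = (0, 2, 4, 6, 8, 10, 12, 14, 16)
    h_pulse: tuple = (5e-6, 100e3)     # (duration s, rf field Hz)
    n_pulse: tuple = (10e-6, 50e3)
    time_shift: float = 0.0
    phase_scheme: str = "xy8_mirror"   # or "xy8_continuous"

    def __post_init__(self):
        if self.mas_hz <= 0:
            raise ValueError("MAS frequency must be positive")
        tr = 1.0 / self.mas_hz
        for dur, _ in (self.h_pulse, self.n_pulse):
            if dur < 0 or dur >= tr / 2:
                raise ValueError("pulse durations must be in [0, rotor period/2)")
        if not 0.0 <= self.time_shift <= tr / 4:
            raise ValueError("time_shift must lie in [0, rotor period/4]")
        if any(n % 2 or n < 0 for n in self.n_rotor_periods):
            raise ValueError("n_rotor_periods must be non-negative even integers")
        if self.phase_scheme not in ("xy8_mirror", "xy8_continuous"):
            raise ValueError("unknown phase scheme")

    @property
    def rotor_period(self) -> float:
        return 1.0 / self.mas_hz

    def times(self) -> np.ndarray:
        return np.asarray(self.n_rotor_periods) * self.rotor_period


@dataclass
class RfProfile:
    """Discretised rf-field distribution across the sample coil."""

    grid_hz: np.ndarray
    weights: np.ndarray
    threshold: float = 0.0

    def __post_init__(self):
        self.grid_hz = np.asarray(self.grid_hz, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float).copy()
        if len(self.grid_hz) == 0:
            raise ValueError("empty rf profile")
        if not np.all(np.diff(self.grid_hz) > 0):
            raise ValueError("rf grid must be strictly increasing")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        self.weights[self.weights < self.threshold] = 0.0
        total = self.weights.sum()
        if total <= 0:
            raise ValueError("all weights removed by threshold")
        self.weights /= total

    @classmethod
    def delta(cls, rf_hz: float) -> "RfProfile":
        return cls(np.array([rf_hz]), np.array([1.0]))

    @classmethod
    def from_file(cls, path, threshold: float = 0.0) -> "RfProfile":
        arr = np.loadtxt(path)
        return cls(arr[:, 0], arr[:, 1], threshold=threshold)

    @classmethod
    def synthetic_solenoid(cls, center_hz: float = 100e3, sigma_low_hz: float = 4e3,
                           sigma_high_hz: float = 1.5e3, step_hz: float = 1e3,
                           span_low_hz: float = 12e3, span_high_hz: float = 5e3,
                           threshold: float = 0.02) -> "RfProfile":
        """Synthetic stand-in for a measured nutation profile: an asymmetric
        two-sided Gaussian with the broader tail towards low rf fields, as
        typically observed for solenoid coils.  Not a measured distribution."""
        grid = np.arange(center_hz - span_low_hz, center_hz + span_high_hz + 1.0,
                         step_hz)
        sig = np.where(grid < center_hz, sigma_low_hz, sigma_high_hz)
        w = np.exp(-0.5 * ((grid - center_hz) / sig) ** 2)
        return cls(grid, w, threshold=threshold)

    def shifted(self, delta_hz: float) -> "RfProfile":
        return RfProfile(self.grid_hz + delta_hz, self.weights.copy())

    def scaled_width(self, factor: float) -> "RfProfile":
        center = np.average(self.grid_hz, weights=self.weights)
        return RfProfile(center + factor * (self.grid_hz - center),
                         self.weights.copy())


@dataclass
class DephasingCurve:
    times: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.times < 0) or not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be non-negative and increasing")
        if self.times[0] == 0.0 and abs(self.values[0]) > 1e-9:
            raise ValueError("dS/S0 must vanish at t = 0")


# ---------------------------------------------------------------------------
# spin operators and Hamiltonian assembly

def _single_spin_ops(n_spins: int):
    sx = np.array([[0, 0.5], [0.5, 0]], dtype=complex)
    sy = np.array([[0, -0.5j], [0.5j, 0]], dtype=complex)
    sz = np.array([[0.5, 0], [0, -0.5]], dtype=complex)
    eye = np.eye(2, dtype=complex)
    ops = []
    for i in range(n_spins):
        mats = []
        for s in (sx, sy, sz):
            m = np.array([[1.0 + 0j]])
            for k in range(n_spins):
                m = np.kron(m, s if k == i else eye)
            mats.append(m)
        ops.append(tuple(mats))
    return ops


def _interaction_list(system: SpinSystem, ops):
    """(a_pas, euler_rad, coupling operator) for every anisotropic interaction."""
    inter = []
    iso = [s.isotope for s in system.sites]
    for p in system.pairs:
        b = math.pi * p.aniso_hz                      # rad/s coupling constant
        op = 2.0 * ops[p.i][2] @ ops[p.j][2]
        if iso[p.i] == iso[p.j]:                      # homonuclear: keep flip-flop
            op = op + ops[p.i][2] @ ops[p.j][2] \
                 - (ops[p.i][0] @ ops[p.j][0] + ops[p.i][1] @ ops[p.j][1]
                    + ops[p.i][2] @ ops[p.j][2])
        inter.append((csa_components(b, 0.0), np.radians(p.euler_deg), op))
    for i, site in enumerate(system.sites):
        if site.csa is not None and site.csa.aniso_hz != 0.0:
            zeta = 2.0 * math.pi * site.csa.aniso_hz
            inter.append((csa_components(zeta, site.csa.asymmetry),
                          np.radians(site.csa.euler_deg), ops[i][2]))
    return inter


def _rotor_components(inter, alpha, beta, gamma):
    """Per interaction: rotor-frame components A_m weighted by d^2_{m0}(theta_m)."""
    dm = wigner_d2(MAGIC_ANGLE)
    d10, d20 = dm[3, 2], dm[4, 2]
    comps = []
    for a_pas, euler, _ in inter:
        a_cr = rotate_components(a_pas, *euler)       # PAS -> crystal (fixed)
        a_rot = rotate_components(a_cr, alpha, beta, gamma)   # crystal -> rotor
        comps.append((a_rot[..., 3] * d10, a_rot[..., 4] * d20))
    return comps


def _blocks_from_mask(mask: np.ndarray):
    dim = mask.shape[0]
    seen = np.zeros(dim, dtype=bool)
    blocks = []
    for start in range(dim):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(mask[i])[0]:
                if not seen[j]:
                    seen[j] = True
                    stack.append(j)
        blocks.append(np.array(sorted(comp)))
    return blocks


def _apply_blocks(U, H, blocks, dt):
    """U <- expm(-i H dt) @ U, exploiting the block structure of H."""
    for idx in blocks:
        if len(idx) == 1:
            i = idx[0]
            U[:, i, :] *= np.exp(-1j * H[:, i, i].real * dt)[:, None]
        elif len(idx) == 2:
            i, j = idx
            a, b = H[:, i, i].real, H[:, j, j].real
            c = H[:, i, j]
            m, dl = (a + b) / 2.0, (a - b) / 2.0
            r = np.sqrt(dl**2 + np.abs(c) ** 2)
            phi = r * dt
            sinc = np.where(r > 1e-300, np.sin(phi) / np.where(r > 1e-300, r, 1.0), dt)
            ph = np.exp(-1j * m * dt)
            u00 = ph * (np.cos(phi) - 1j * dl * sinc)
            u11 = ph * (np.cos(phi) + 1j * dl * sinc)
            u01 = ph * (-1j * c * sinc)
            u10 = ph * (-1j * np.conj(c) * sinc)
            ri, rj = U[:, i, :].copy(), U[:, j, :]
            U[:, i, :] = u00[:, None] * ri + u01[:, None] * rj
            U[:, j, :] = u10[:, None] * ri + u11[:, None] * rj
        else:
            sub = H[np.ix_(np.arange(H.shape[0]), idx, idx)]
            w, v = np.linalg.eigh(sub)
            e = np.exp(-1j * w * dt)
            ub = (v * e[:, None, :]) @ np.conj(np.swapaxes(v, 1, 2))
            U[:, idx, :] = ub @ U[:, idx, :]


# ---------------------------------------------------------------------------
# pulse schedule

def _pulse_schedule(exp: RedorExperiment, n_periods: int, with_h_pulses: bool):
    """Ordered list of (t_center, channel) pulse marks for one recoupling block."""
    tr = exp.rotor_period
    T = n_periods * tr
    ts = exp.time_shift
    marks = []
    for j in range(1, 2 * n_periods):
        if j == n_periods:
            marks.append((T / 2.0, "N"))
        elif with_h_pulses:
            pos = j * tr / 2.0 + (ts if j % 2 else -ts)
            marks.append((pos, "H"))
    return marks, T


def _h_phases(n_h: int, scheme: str):
    pat = np.radians(XY8_PHASES_DEG)
    if scheme == "xy8_continuous":
        return [pat[i % 8] for i in range(n_h)]
    # mirror: increment in the first half, decrement in the second
    n1 = (n_h + 1) // 2
    first = [pat[i % 8] for i in range(n1)]
    second = [pat[(n1 - 1 - k) % 8] for k in range(n_h - n1)]
    return first + second


def _events(exp: RedorExperiment, n_periods: int, with_h_pulses: bool,
            h_rf_hz: float | None = None, n_rf_hz: float | None = None):
    """Contiguous (t0, t1, pulse) intervals; pulse = None or (channel, phase, w1)."""
    marks, T = _pulse_schedule(exp, n_periods, with_h_pulses)
    hd, hrf = exp.h_pulse
    nd, nrf = exp.n_pulse
    hrf = h_rf_hz if h_rf_hz is not None else hrf
    nrf = n_rf_hz if n_rf_hz is not None else nrf
    h_marks = [m for m in marks if m[1] == "H"]
    phases = _h_phases(len(h_marks), exp.phase_scheme)
    pulses = []
    pi = 0
    for center, ch in marks:
        if ch == "H":
            dur, w1, phase = hd, 2 * math.pi * hrf, phases[pi]
            pi += 1
        else:
            dur, w1, phase = nd, 2 * math.pi * nrf, 0.0
        t0, t1 = center - dur / 2.0, center + dur / 2.0
        if t0 < 0 or t1 > T:
            raise ValueError("pulse extends outside the recoupling block")
        pulses.append((t0, t1, (ch, phase, w1, dur == 0.0, center)))
    pulses.sort(key=lambda e: e[0])
    for (a0, a1, _), (b0, b1, _) in zip(pulses, pulses[1:]):
        if b0 < a1 - 1e-15:
            raise ValueError("pulses overlap; reduce durations or time shift")
    events, t = [], 0.0
    for t0, t1, p in pulses:
        if t0 > t + 1e-15:
            events.append((t, t0, None))
        events.append((t0, t1, p))
        t = t1
    if t < T - 1e-15:
        events.append((t, T, None))
    return events, T


# ---------------------------------------------------------------------------
# propagation

class _Engine:
    """Shared per-system setup for repeated REDOR propagations."""

    def __init__(self, system: SpinSystem, orientations=None):
        self.system = system
        n = len(system.sites)
        self.dim = 2 ** n
        self.ops = _single_spin_ops(n)
        self.inter = _interaction_list(system, self.ops)
        if orientations is None:
            orientations = zcw_orientations(DEFAULT_N_ORIENT, DEFAULT_N_GAMMA)
        elif isinstance(orientations, int):
            orientations = zcw_orientations(orientations, DEFAULT_N_GAMMA)
        self.alpha, self.beta, self.gamma, self.pw = orientations
        self.nb = len(self.alpha)
        self.comps = _rotor_components(self.inter, self.alpha, self.beta,
                                       self.gamma)
        self.op_stack = np.stack([op.real for *_, op in self.inter]) \
            if self.inter else np.zeros((0, self.dim, self.dim))
        self.static_diag = np.zeros(self.dim)
        for i, site in enumerate(system.sites):
            self.static_diag += 2 * math.pi * site.offset_hz \
                * np.diag(self.ops[i][2]).real
        ni = system.n_index
        self.detect = self.ops[ni][0].real          # Nx
        self.detect_norm = float(np.trace(self.detect @ self.detect).real)
        self.fx = {"H": sum(self.ops[i][0] for i in system.h_indices),
                   "N": self.ops[ni][0]}
        self.fy = {"H": sum(self.ops[i][1] for i in system.h_indices),
                   "N": self.ops[ni][1]}
        self._block_cache = {}

    def _blocks(self, kind: str):
        if kind not in self._block_cache:
            mask = np.abs(self.op_stack).sum(axis=0) > 1e-12 if len(self.op_stack) \
                else np.zeros((self.dim, self.dim), dtype=bool)
            mask = np.asarray(mask, dtype=bool)
            mask |= np.eye(self.dim, dtype=bool)
            if kind != "free":
                mask |= np.abs(self.fx[kind]) + np.abs(self.fy[kind]) > 1e-12
            self._block_cache[kind] = _blocks_from_mask(mask)
        return self._block_cache[kind]

    def _coeffs(self, t0: float, t1: float, mas_hz: float) -> np.ndarray:
        """Slice-averaged interaction frequencies, shape (n_inter, batch)."""
        wr = 2 * math.pi * mas_hz
        dt = t1 - t0
        e1 = (np.exp(-1j * wr * t0) - np.exp(-1j * wr * t1)) / (1j * wr * dt)
        e2 = (np.exp(-2j * wr * t0) - np.exp(-2j * wr * t1)) / (2j * wr * dt)
        rows = [2.0 * (a1 * e1).real + 2.0 * (a2 * e2).real
                for a1, a2 in self.comps]
        return np.stack(rows) if rows else np.zeros((0, self.nb))

    def _slice_H(self, t0, t1, mas_hz, pulse):
        W = self._coeffs(t0, t1, mas_hz)
        H = np.einsum("kb,kij->bij", W, self.op_stack).astype(complex) \
            if len(W) else np.zeros((self.nb, self.dim, self.dim), dtype=complex)
        H += np.diag(self.static_diag)
        if pulse is not None:
            ch, phase, w1, _, _ = pulse
            H += w1 * (math.cos(phase) * self.fx[ch] + math.sin(phase) * self.fy[ch])
        return H

    def propagate(self, exp: RedorExperiment, n_periods: int, with_h_pulses: bool,
                  slices_per_rotor: int = DEFAULT_SLICES_PER_ROTOR,
                  h_rf_hz=None, n_rf_hz=None, reduce: bool = True):
        """<Nx> after ``n_periods`` rotor periods of recoupling; powder-averaged
        unless ``reduce`` is False (then one value per batch orientation)."""
        if n_periods == 0:
            return 1.0 if reduce else np.ones(self.nb)
        events, T = _events(exp, n_periods, with_h_pulses, h_rf_hz, n_rf_hz)
        tr = exp.rotor_period
        dt_free = tr / slices_per_rotor
        dt_pulse = dt_free / 2.0                     # finer slicing inside pulses
        U = np.broadcast_to(np.eye(self.dim, dtype=complex),
                            (self.nb, self.dim, self.dim)).copy()
        free_blocks = self._blocks("free")
        free_diagonal = all(len(b) == 1 for b in free_blocks)
        for t0, t1, pulse in events:
            if pulse is not None and pulse[3]:       # ideal delta pulse
                ch, phase, _, _, _ = pulse
                gen = math.pi * (math.cos(phase) * self.fx[ch]
                                 + math.sin(phase) * self.fy[ch])
                w, v = np.linalg.eigh(gen)
                up = (v * np.exp(-1j * w)) @ v.conj().T
                U = up @ U
                continue
            if pulse is None:
                blocks = free_blocks
                if free_diagonal:
                    # diagonal H commutes at all times: one exact step
                    H = self._slice_H(t0, t1, exp.mas_hz, None)
                    _apply_blocks(U, H, blocks, t1 - t0)
                    continue
                dt = dt_free
                kind = None
            else:
                blocks = self._blocks(pulse[0])
                dt = dt_pulse
            n_slices = max(1, math.ceil((t1 - t0) / dt - 1e-9))
            edges = np.linspace(t0, t1, n_slices + 1)
            for a, b in zip(edges[:-1], edges[1:]):
                H = self._slice_H(a, b, exp.mas_hz, pulse)
                _apply_blocks(U, H, blocks, b - a)
        M = U @ self.detect @ np.conj(np.swapaxes(U, 1, 2))
        s = np.einsum("bij,ji->b", M, self.detect).real / self.detect_norm
        if not reduce:
            return s
        return float(np.sum(self.pw * s))

    def curve(self, exp: RedorExperiment,
              slices_per_rotor: int = DEFAULT_SLICES_PER_ROTOR,
              h_rf_hz=None, n_rf_hz=None, s0_cache: dict | None = None) -> np.ndarray:
        """dS/S0 on the experiment grid; S0 runs may be shared via ``s0_cache``
        (valid across 1H rf settings, which the reference does not see)."""
        values = []
        for npd in exp.n_rotor_periods:
            if npd == 0:
                values.append(0.0)
                continue
            s = self.propagate(exp, npd, True, slices_per_rotor, h_rf_hz, n_rf_hz)
            key = (npd, n_rf_hz, slices_per_rotor)
            if s0_cache is not None and key in s0_cache:
                s0 = s0_cache[key]
            else:
                s0 = self.propagate(exp, npd, False, slices_per_rotor,
                                    h_rf_hz, n_rf_hz)
                if s0_cache is not None:
                    s0_cache[key] = s0
            values.append(1.0 - s / s0)
        return np.asarray(values)


def simulate_redor(system: SpinSystem, exp: RedorExperiment, orientations=None,
                   slices_per_rotor: int = DEFAULT_SLICES_PER_ROTOR,
                   h_rf_hz: float | None = None,
                   n_rf_hz: float | None = None) -> DephasingCurve:
    """Powder-averaged REDOR dephasing curve dS/S0 on the experiment's grid."""
    eng = _Engine(system, orientations)
    values = eng.curve(exp, slices_per_rotor, h_rf_hz, n_rf_hz)
    meta = {"orientations": eng.nb, "slices_per_rotor": slices_per_rotor,
            "h_rf_hz": h_rf_hz, "n_rf_hz": n_rf_hz}
    return DephasingCurve(exp.times(), values, meta=meta)


def ideal_redor_curve(anisotropy_hz, times, mas_hz: float,
                      time_shift: float = 0.0, n_beta: int = 64,
                      n_gamma: int = 64) -> DephasingCurve | np.ndarray:
    """Closed-form ideal (delta-pulse, two-spin) REDOR dephasing.

    The toggling-frame dipolar phase is integrated analytically between pulse
    marks and powder-averaged on a Gauss-Legendre beta x uniform gamma grid.
    For an array of anisotropies, the (n_aniso, n_times) value matrix is
    returned instead of a curve (the phase is linear in the coupling, so all
    couplings share one orientation integral).
    """
    times = np.asarray(times, dtype=float)
    tr = 1.0 / mas_hz
    wr = 2 * math.pi * mas_hz
    _, beta, gamma, wts = beta_gamma_quadrature(n_beta, n_gamma)
    d2 = wigner_d2(np.asarray(beta))
    dm = wigner_d2(MAGIC_ANGLE)
    # unit-coupling rotor components: b * d2_{0m}(beta) e^{-im gamma} * d2_{m0}(theta_m)
    c1 = d2[:, 2, 3] * np.exp(-1j * gamma) * dm[3, 2]
    c2 = d2[:, 2, 4] * np.exp(-2j * gamma) * dm[4, 2]

    aniso = np.atleast_1d(np.asarray(anisotropy_hz, dtype=float))
    scalar_in = np.isscalar(anisotropy_hz) or np.ndim(anisotropy_hz) == 0
    values = np.zeros((len(aniso), len(times)))
    for it, T in enumerate(times):
        if T <= 0:
            continue
        n_periods = int(round(T / tr))
        if n_periods % 2 or abs(n_periods * tr - T) > 1e-9 * tr:
            raise ValueError("times must be even multiples of the rotor period")
        marks = [j * tr / 2.0 + (0.0 if j == n_periods
                                 else (time_shift if j % 2 else -time_shift))
                 for j in range(1, 2 * n_periods)]
        edges = np.concatenate([[0.0], np.sort(marks), [T]])
        signs = (-1.0) ** np.arange(len(edges) - 1)
        phi_unit = np.zeros(len(beta))
        for s, a, b in zip(signs, edges[:-1], edges[1:]):
            i1 = (np.exp(-1j * wr * a) - np.exp(-1j * wr * b)) / (1j * wr)
            i2 = (np.exp(-2j * wr * a) - np.exp(-2j * wr * b)) / (2j * wr)
            phi_unit += s * 2.0 * ((c1 * i1).real + (c2 * i2).real)
        phases = np.outer(math.pi * aniso, phi_unit)       # b = pi * anisotropy
        values[:, it] = 1.0 - np.cos(phases) @ wts
    if scalar_in:
        return DephasingCurve(times, values[0], meta={"kind": "ideal"})
    return values


def average_over_rf(system: SpinSystem, exp: RedorExperiment, profile: RfProfile,
                    orientations=None,
                    slices_per_rotor: int = DEFAULT_SLICES_PER_ROTOR) -> DephasingCurve:
    """rf-inhomogeneity average: weighted sum of simulations over the 1H rf grid."""
    eng = _Engine(system, orientations)
    s0_cache: dict = {}
    total = None
    for rf, w in zip(profile.grid_hz, profile.weights):
        if w == 0.0:
            continue
        vals = eng.curve(exp, slices_per_rotor, h_rf_hz=rf, s0_cache=s0_cache)
        total = w * vals if total is None else total + w * vals
    if total is None:
        raise ValueError("rf profile has no weight")
    return DephasingCurve(exp.times(), total,
                          meta={"profile_fields": int((profile.weights > 0).sum())})


def _simulated_library_matrix(exp: RedorExperiment, delta_grid, orientations,
                              slices_per_rotor: int) -> np.ndarray:
    """Finite-pulse two-spin reference curves for every coupling in one batch.

    The coupling enters the rotor-frame components linearly, so a single
    engine propagates all (orientation, coupling) combinations together; a
    bare N-H pair has no alpha dependence, so a beta/gamma quadrature set is
    used by default.
    """
    if orientations is None:
        orientations = beta_gamma_quadrature(16, 16)
    elif isinstance(orientations, int):
        orientations = zcw_orientations(orientations, DEFAULT_N_GAMMA)
    a, b, g, w = orientations
    nd, no = len(delta_grid), len(a)
    tiled = (np.tile(a, nd), np.tile(b, nd), np.tile(g, nd),
             np.tile(w, nd) / nd)
    eng = _Engine(two_spin_nh(1.0), orientations=tiled)
    scale = np.repeat(np.asarray(delta_grid, dtype=float), no)
    eng.comps = [(a1 * scale, a2 * scale) for a1, a2 in eng.comps]
    matrix = np.zeros((nd, len(exp.n_rotor_periods)))
    for it, npd in enumerate(exp.n_rotor_periods):
        if npd == 0:
            continue
        s = eng.propagate(exp, npd, True, slices_per_rotor,
                          reduce=False).reshape(nd, no) @ w
        s0 = eng.propagate(exp, npd, False, slices_per_rotor,
                           reduce=False).reshape(nd, no) @ w
        matrix[:, it] = 1.0 - s / s0
    return matrix


# ---------------------------------------------------------------------------
# coupling fits

@dataclass
class RedorFit:
    delta_hz: float
    sigma_hz: float
    flags: list
    chi2: float


class RedorLibrary:
    """Grid of reference two-spin dephasing curves for single-parameter fits.

    ``style='ideal'`` uses the closed-form delta-pulse curves (the default
    reference, as for fits of experimental data); ``style='simulated'`` builds
    the library from finite-pulse two-spin propagations at nominal calibration.
    """

    def __init__(self, times, mas_hz: float, time_shift: float = 0.0,
                 delta_grid=None, style: str = "ideal",
                 exp: RedorExperiment | None = None, orientations=None,
                 slices_per_rotor: int = DEFAULT_SLICES_PER_ROTOR,
                 n_beta: int = 64, n_gamma: int = 64):
        self.times = np.asarray(times, dtype=float)
        self.delta_grid = (np.arange(0.0, 26000.0 + 1, 50.0) if delta_grid is None
                           else np.asarray(delta_grid, dtype=float))
        self.style = style
        if style == "ideal":
            self.matrix = ideal_redor_curve(self.delta_grid, self.times, mas_hz,
                                            time_shift, n_beta, n_gamma)
        elif style == "simulated":
            if exp is None:
                raise ValueError("style='simulated' needs a RedorExperiment")
            self.matrix = _simulated_library_matrix(exp, self.delta_grid,
                                                    orientations,
                                                    slices_per_rotor)
        else:
            raise ValueError("style must be 'ideal' or 'simulated'")

    @classmethod
    def for_experiment(cls, exp: RedorExperiment, **kw) -> "RedorLibrary":
        return cls(exp.times(), exp.mas_hz, exp.time_shift, exp=exp, **kw)

    @property
    def grid_step(self) -> float:
        return float(np.median(np.diff(self.delta_grid)))

    def fit(self, curve: DephasingCurve, n_mc: int = 0,
            seed: int | None = 0) -> RedorFit:
        """Chi-square grid search with parabolic refinement; MC errors from
        resampling the curve within its per-point sigmas."""
        y = np.interp(curve.times, self.times, np.arange(len(self.times)))
        if not np.allclose(y, np.round(y)):
            raise ValueError("curve times do not match the library grid")
        idx = np.round(y).astype(int)
        lib = self.matrix[:, idx]
        sig = curve.sigma if curve.sigma is not None else np.ones(len(curve.times))
        w = 1.0 / sig**2
        chi = ((lib - curve.values) ** 2 * w).sum(axis=1)
        i = int(np.argmin(chi))
        flags = []
        if i in (0, len(self.delta_grid) - 1):
            flags.append("grid_edge")
            delta = float(self.delta_grid[i])
        else:
            delta = _parabolic_min(self.delta_grid[i - 1:i + 2], chi[i - 1:i + 2])
        sigma = float("nan")
        if n_mc > 0:
            if curve.sigma is None or len(curve.times) < 3:
                raise ValueError("MC errors need >=3 points with sigmas")
            rng = np.random.default_rng(seed)
            draws = curve.values[None, :] + rng.normal(
                size=(n_mc, len(curve.values))) * sig[None, :]
            # chi2(d, draw) up to a draw-constant: q - 2 L W y
            q = (lib**2 * w).sum(axis=1)
            scores = q[:, None] - 2.0 * (lib * w) @ draws.T
            best = np.argmin(scores, axis=0)
            sigma = float(np.std(self.delta_grid[best]))
        return RedorFit(delta_hz=delta, sigma_hz=sigma, flags=flags,
                        chi2=float(chi[i]))


def _parabolic_min(x3, y3) -> float:
    x0, x1, x2 = x3
    y0, y1, y2 = y3
    denom = (y0 - 2 * y1 + y2)
    if denom <= 0:
        return float(x1)
    shift = 0.5 * (y0 - y2) / denom
    return float(x1 + shift * (x1 - x0))


def fit_dipolar_coupling(curve: DephasingCurve, library: RedorLibrary,
                         n_mc: int = 2000, seed: int | None = 0) -> RedorFit:
    """Single-parameter dipolar-coupling fit against a reference library."""
    return library.fit(curve, n_mc=n_mc, seed=seed)


def correction_factor(system: SpinSystem, exp: RedorExperiment,
                      profile: RfProfile, library: RedorLibrary | None = None,
                      orientations=None,
                      slices_per_rotor: int = DEFAULT_SLICES_PER_ROTOR) -> float:
    """Fractional upscaling of fitted couplings due to rf inhomogeneity.

    Simulates the rf-averaged dephasing, fits it against a finite-pulse
    two-spin reference library at nominal calibration (the "standard
    simulation" an experimental curve would be fitted with), and returns
    input/fitted - 1; the factor is applied a posteriori to experimental fits.
    """
    delta_in = abs(system.nh_pair().aniso_hz)
    if library is None:
        grid = np.arange(0.75 * delta_in, 1.15 * delta_in, 50.0)
        library = RedorLibrary.for_experiment(exp, style="simulated",
                                              delta_grid=grid,
                                              slices_per_rotor=slices_per_rotor)
    curve = average_over_rf(system, exp, profile, orientations, slices_per_rotor)
    fit = library.fit(curve, n_mc=0)
    if "grid_edge" in fit.flags:
        raise RuntimeError("coupling fit hit the grid edge")
    return delta_in / fit.delta_hz - 1.0


def locate_scan_maximum(scan: pd.DataFrame):
    """Parabolic estimate of the apparent-coupling maximum of an rf scan.

    Returns (rf_hz, delta_hz, interior) where ``interior`` is False when the
    discrete argmax sits on the scan edge.
    """
    rf = scan["rf_hz"].to_numpy(dtype=float)
    d = scan["delta_fit_hz"].to_numpy(dtype=float)
    i = int(np.argmax(d))
    if i in (0, len(d) - 1):
        return float(rf[i]), float(d[i]), False
    denom = d[i - 1] - 2 * d[i] + d[i + 1]
    if denom >= 0:
        return float(rf[i]), float(d[i]), True
    shift = 0.5 * (d[i - 1] - d[i + 1]) / denom
    rf_max = rf[i] + shift * (rf[i] - rf[i - 1])
    d_max = d[i] - 0.25 * (d[i - 1] - d[i + 1]) * shift
    return float(rf_max), float(d_max), True


def _scan(system, exp, rf_values, channel: str, library, orientations,
          slices_per_rotor, profile: RfProfile | None = None) -> pd.DataFrame:
    if library is None:
        library = RedorLibrary(exp.times(), exp.mas_hz, exp.time_shift)
    eng = _Engine(system, orientations)
    s0_cache: dict = {}
    rows = []
    for rf in rf_values:
        if profile is not None and channel == "H":
            nominal = np.average(profile.grid_hz, weights=profile.weights)
            prof = profile.shifted(rf - nominal)
            vals = None
            for f, w in zip(prof.grid_hz, prof.weights):
                if w == 0.0:
                    continue
                v = eng.curve(exp, slices_per_rotor, h_rf_hz=f,
                              s0_cache=s0_cache)
                vals = w * v if vals is None else vals + w * v
        else:
            kw = {"h_rf_hz": rf} if channel == "H" else {"n_rf_hz": rf}
            vals = eng.curve(exp, slices_per_rotor, s0_cache=s0_cache, **kw)
        curve = DephasingCurve(exp.times(), vals)
        fit = library.fit(curve, n_mc=0)
        flags = list(fit.flags)
        if np.max(curve.values) < 0.1:
            flags.append("weak_dephasing")
        rows.append({"rf_hz": rf, "delta_fit_hz": fit.delta_hz,
                     "flags": ";".join(flags)})
    return pd.DataFrame(rows)


def scan_h_rf(system: SpinSystem, exp: RedorExperiment, rf_values,
              library: RedorLibrary | None = None, orientations=None,
              slices_per_rotor: int = DEFAULT_SLICES_PER_ROTOR,
              profile: RfProfile | None = None) -> pd.DataFrame:
    """Apparent dipolar coupling vs 1H rf field (optionally with an rf
    distribution whose centre of mass is moved along the scan)."""
    return _scan(system, exp, rf_values, "H", library, orientations,
                 slices_per_rotor, profile)


def scan_n_rf(system: SpinSystem, exp: RedorExperiment, rf_values,
              library: RedorLibrary | None = None, orientations=None,
              slices_per_rotor: int = DEFAULT_SLICES_PER_ROTOR) -> pd.DataFrame:
    """Apparent dipolar coupling vs 15N rf field of the central pi pulse."""
    return _scan(system, exp, rf_values, "N", library, orientations,
                 slices_per_rotor)
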