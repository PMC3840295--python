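"""Powder orientation sets and Wigner rotation utilities for MAS simulations."""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

MAGIC_ANGLE = math.acos(1.0 / math.sqrt(3.0))


@lru_cache(maxsize=None)
def _jy_spin2() -> tuple:
    """Spin-2 angular momentum matrix Jy (basis m = -2..2)."""
    m = np.arange(-2, 3)
    jp = np.zeros((5, 5))
    for i, mm in enumerate(m[:-1]):
        jp[i + 1, i] = math.sqrt(2 * 3 - mm * (mm + 1))
    jm = jp.T
    jy = (jp - jm) / 2j
    w, v = np.linalg.eigh(jy)
    return w, v


def wigner_d2(beta) -> np.ndarray:
    """Reduced Wigner matrix d^2_{m'm}(beta), indices m', m in -2..2.

    Built from the spin-2 Jy generator, d^2(beta) = exp(-i beta Jy); exact for
    scalar or array beta (extra axes appended in front).
    """
    w, v = _jy_spin2()
    beta = np.asarray(beta, dtype=float)
    phases = np.exp(-1j * beta[..., None] * w)
    d = np.einsum("ik,...k,jk->...ij", v, phases, v.conj())
    return d.real if np.allclose(d.imag, 0, atol=1e-12) else d


def wigner_D2(alpha, beta, gamma) -> np.ndarray:
    """Full Wigner matrix D^2_{m'm}(alpha, beta, gamma) (zyz convention)."""
    m = np.arange(-2, 3)
    d = wigner_d2(beta)
    ea = np.exp(-1j * np.multiply.outer(np.asarray(alpha), m))
    eg = np.exp(-1j * np.multiply.outer(np.asarray(gamma), m))
    return ea[..., :, None] * d * eg[..., None, :]


def rotate_components(a_pas: np.ndarray, alpha, beta, gamma) -> np.ndarray:
    """Rotate rank-2 spherical components: A_m = sum_m' a_m' D^2_{m'm}(omega)."""
    D = wigner_D2(alpha, beta, gamma)
    return np.einsum("k,...km->...m", np.asarray(a_pas, dtype=complex), D)


def csa_components(zeta: float, eta: float) -> np.ndarray:
    """PAS spherical components (m = -2..2) of a traceless symmetric tensor
    with anisotropy ``zeta`` (rad/s) and asymmetry ``eta``, normalised so that
    the m = 0 lab-frame frequency is zeta * P2(cos beta) for eta = 0."""
    a = np.zeros(5, dtype=complex)
    a[2] = zeta
    a[0] = a[4] = -zeta * eta / math.sqrt(6.0)
    return a


def zcw_orientations(n: int, n_gamma: int = 8):
    """Quasi-uniform powder set: ``n`` (alpha, beta) pairs on the Fibonacci
    (golden-spiral) sphere crossed with ``n_gamma`` evenly spaced gamma angles.

    Returns (alpha, beta, gamma, weights) flattened arrays; weights sum to 1.
    """
    j = np.arange(n)
    golden = (1 + math.sqrt(5)) / 2
    alpha = (2 * np.pi * j / golden) % (2 * np.pi)
    beta = np.arccos(1 - 2 * (j + 0.5) / n)
    gamma = 2 * np.pi * (np.arange(n_gamma) + 0.5) / n_gamma
    a = np.repeat(alpha, n_gamma)
    b = np.repeat(beta, n_gamma)
    g = np.tile(gamma, n)
    w = np.full(n * n_gamma, 1.0 / (n * n_gamma))
    return a, b, g, w


def beta_gamma_quadrature(n_beta: int = 64, n_gamma: int = 64):
    """Gauss-Legendre beta x uniform gamma set for single-tensor problems."""
    x, wx = np.polynomial.legendre.leggauss(n_beta)
    beta = np.arccos(x)
    gamma = 2 * np.pi * (np.arange(n_gamma) + 0.5) / n_gamma
    b = np.repeat(beta, n_gamma)
    g = np.tile(gamma, n_beta)
    w = np.repeat(wx / (2.0 * n_gamma), n_gamma)
    return np.zeros_like(b), b, g, w
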