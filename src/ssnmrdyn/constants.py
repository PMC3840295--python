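"""Physical constants and field/interaction bookkeeping.

All angular frequencies are kept in rad/s internally.  Static fields may be
specified either as the 1H Larmor frequency in MHz (500, 600, 850, ...) or as
B0 in tesla (11.74, 14.09, 19.96, ...); both are converted at construction
time.

The gyromagnetic ratios are pinned to the conventional NMR tabulation
(gamma_H = 2.67519e8, gamma_15N = -2.7116e7 rad s^-1 T^-1), which reproduces
the dipolar tensor anisotropies used throughout (e.g. 13,668 Hz for a 2.6 A
1H-1H pair) to the nearest Hz.  They can be overridden through a JSON table
of the same shape as the packaged ``data/constants.json``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path


def _default_table() -> dict:
    with resources.files("ssnmrdyn.data").joinpath("constants.json").open() as fh:
        return json.load(fh)


@dataclass(frozen=True)
class Constants:
    """Pinned physical constants; one instance is shared by default."""

    hbar: float
    mu0_over_4pi: float
    gamma: dict
    rNH_angstrom: float
    delta_sigma_ppm: float
    rigid_NH_anisotropy_hz: float

    @classmethod
    def load(cls, path: str | Path | None = None) -> "Constants":
        table = _default_table()
        if path is not None:
            with open(path) as fh:
                table.update(json.load(fh))
        return cls(**table)

    def gamma_of(self, isotope: str) -> float:
        try:
            return self.gamma[isotope]
        except KeyError:
            raise ValueError(f"unknown isotope {isotope!r}") from None

    def dipolar_b(self, iso1: str, iso2: str, r_angstrom: float) -> float:
        """Dipolar coupling constant b = (mu0/4pi) gamma_i gamma_j hbar / r^3 in rad/s.

        Signed by the product of the gyromagnetic ratios.
        """
        if r_angstrom <= 0:
            raise ValueError("internuclear distance must be positive")
        r = r_angstrom * 1e-10
        return self.mu0_over_4pi * self.gamma_of(iso1) * self.gamma_of(iso2) * self.hbar / r**3


CONSTANTS = Constants.load()


@dataclass(frozen=True)
class FieldContext:
    """Static magnetic field and the two Larmor angular frequencies.

    ``omega_n`` is signed by the gyromagnetic-ratio convention (negative for
    15N); spectral densities are even, so only rate expressions that combine
    frequencies care about the sign.
    """

    b0: float
    omega_h: float
    omega_n: float

    def __post_init__(self):
        if self.b0 <= 0:
            raise ValueError("B0 must be positive")

    @classmethod
    def from_tesla(cls, b0: float, constants: Constants = CONSTANTS) -> "FieldContext":
        return cls(b0=b0, omega_h=constants.gamma_of("1H") * b0,
                   omega_n=constants.gamma_of("15N") * b0)

    @classmethod
    def from_proton_mhz(cls, mhz: float, constants: Constants = CONSTANTS) -> "FieldContext":
        b0 = 2 * math.pi * mhz * 1e6 / constants.gamma_of("1H")
        return cls.from_tesla(b0, constants)

    @property
    def proton_mhz(self) -> float:
        return self.omega_h / (2 * math.pi * 1e6)


def field_from_value(value: float, unit: str, constants: Constants = CONSTANTS) -> FieldContext:
    """Build a FieldContext from a (value, unit) pair as found in input tables."""
    unit = unit.strip()
    if unit in ("T", "tesla"):
        return FieldContext.from_tesla(value, constants)
    if unit in ("MHz", "mhz"):
        return FieldContext.from_proton_mhz(value, constants)
    raise ValueError(f"unknown field unit {unit!r} (use 'T' or 'MHz')")


@dataclass(frozen=True)
class InteractionConstants:
    """Dipolar and CSA interaction constants entering the Redfield rates.

    ``d`` is (mu0/4pi) gamma_H gamma_N hbar / rNH^3 (rad/s, signed) and
    ``c = omega_N * delta_sigma * 1e-6`` for an axially symmetric 15N CSA.
    """

    rNH_angstrom: float
    delta_sigma_ppm: float
    d: float
    c: float

    @classmethod
    def for_field(cls, fieldctx: FieldContext,
                  rNH_angstrom: float | None = None,
                  delta_sigma_ppm: float | None = None,
                  constants: Constants = CONSTANTS) -> "InteractionConstants":
        r = constants.rNH_angstrom if rNH_angstrom is None else rNH_angstrom
        ds = constants.delta_sigma_ppm if delta_sigma_ppm is None else delta_sigma_ppm
        d = constants.dipolar_b("1H", "15N", r)
        c = fieldctx.omega_n * ds * 1e-6
        return cls(rNH_angstrom=r, delta_sigma_ppm=ds, d=d, c=c)
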