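"""Ubiquitin-like synthetic datasets for end-to-end pipeline testing.

A 76-residue template with a ubiquitin-like secondary-structure string
(beta1-beta2-alpha1-beta3-beta4-3_10-beta5 topology) carries per-class priors
over two-time-scale (EMF) motion: loops draw lower slow-motion order
parameters and longer slow correlation times than secondary structure,
mirroring the qualitative pattern seen experimentally.  From a drawn truth
table the generator emits, in the exact text formats the pipeline reads:

* a per-residue observation table (R1 at three fields, eta at two, R2 at one,
  and the dipolar order parameter) with Gaussian noise at the stated sigmas;
* R1rho intensity-decay tables on the 10-point 5-250 ms spin-lock grid;
* rotor-synchronised REDOR dephasing curves at 37.037 kHz MAS, scaled by each
  residue's total order parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import CONSTANTS, FieldContext
from .dataset import Observation, ResidueDataset
from .redor import ideal_redor_curve
from .relaxation import (MotionModelEMF, SpinLockGeometry, back_calculate,
                         rate_R1, rate_R2)
from .robustness import DEFAULT_NOISE, FIELDS

#: ubiquitin-like secondary structure, one letter per residue
#: (E = strand, H = helix/3_10, L = loop)
UBIQUITIN_SS = (
    "L" + "E" * 6            # beta1: 2-7
    + "L" * 3 + "E" * 7      # beta2: 11-17
    + "L" * 5 + "H" * 12     # alpha1: 23-34
    + "L" * 5 + "E" * 6      # beta3: 40-45
    + "L" * 2 + "E" * 3      # beta4: 48-50
    + "L" * 6 + "H" * 3      # 3_10: 57-59
    + "L" * 6 + "E" * 6      # beta5: 66-71
    + "L" * 5                # C-terminal tail: 72-76
)
assert len(UBIQUITIN_SS) == 76


@dataclass(frozen=True)
class MotionPrior:
    """Uniform ranges for the EMF parameters of one secondary-structure class
    (order parameters linear-uniform, correlation times log-uniform)."""

    sf2: tuple
    ss2: tuple
    tauf: tuple      # seconds
    taus: tuple      # seconds

    def draw(self, rng: np.random.Generator) -> MotionModelEMF:
        lo, hi = self.tauf
        tauf = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        lo, hi = self.taus
        taus = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        return MotionModelEMF(Sf2=rng.uniform(*self.sf2),
                              Ss2=rng.uniform(*self.ss2),
                              tauf=tauf, taus=max(tauf, taus))


DEFAULT_PRIORS = {
    # secondary structure: high, narrow order parameters, slow motion weak
    "E": MotionPrior(sf2=(0.86, 0.94), ss2=(0.96, 1.0),
                     tauf=(2e-11, 1e-10), taus=(2e-8, 1e-7)),
    "H": MotionPrior(sf2=(0.85, 0.93), ss2=(0.95, 1.0),
                     tauf=(2e-11, 1e-10), taus=(2e-8, 1e-7)),
    # loops: lower order parameters and longer slow correlation times
    "L": MotionPrior(sf2=(0.72, 0.88), ss2=(0.86, 0.97),
                     tauf=(3e-11, 1.5e-10), taus=(5e-8, 8e-7)),
}


@dataclass
class ProteinTemplate:
    n_residues: int = 76
    labels: str = UBIQUITIN_SS
    priors: dict = field(default_factory=lambda: dict(DEFAULT_PRIORS))

    def __post_init__(self):
        if len(self.labels) != self.n_residues:
            raise ValueError("labels must cover all residues")
        missing = set(self.labels) - set(self.priors)
        if missing:
            raise ValueError(f"no motion prior for classes {sorted(missing)}")


@dataclass
class NoiseModel:
    """Per-kind observation sigmas plus decay / dephasing noise levels."""

    sigmas: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    decay_sigma_frac: float = 0.01      # of the initial intensity
    redor_sigma: float = 0.02           # absolute on dS/S0
    scale: float = 1.0

    def __post_init__(self):
        if any(v <= 0 for v in self.sigmas.values()):
            raise ValueError("sigmas must be positive")

    def sigma(self, kind: str) -> float:
        return self.sigmas[kind] * self.scale


def draw_protein(template: ProteinTemplate | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Per-residue EMF truth table, deterministic for a given seed."""
    template = template or ProteinTemplate()
    rng = np.random.default_rng(seed)
    rows = []
    for i, label in enumerate(template.labels, start=1):
        m = template.priors[label].draw(rng)
        rows.append({"residue": i, "ss": label, "Sf2": m.Sf2, "Ss2": m.Ss2,
                     "tauf": m.tauf, "taus": m.taus,
                     "s2_total": m.Sf2 * m.Ss2})
    return pd.DataFrame(rows)


#: the full experimental observable set: up to 7 data points per residue
SEVEN_OBSERVABLE_SET = [
    ("R1", FIELDS[11.74]), ("R1", FIELDS[14.09]), ("R1", FIELDS[19.96]),
    ("eta", FIELDS[14.09]), ("eta", FIELDS[19.96]),
    ("R2", FIELDS[14.09]),
    ("S2dip", None),
]

#: spin-lock duration grid: 5 to 250 ms, 10 points
DECAY_GRID_S = np.linspace(0.005, 0.250, 10)

#: REDOR sampling: even rotor periods at 37.037 kHz MAS
REDOR_MAS_HZ = 37037.0
REDOR_PERIODS = (0, 2, 4, 6, 8, 10, 12, 14, 16)
REDOR_TIME_SHIFT = 3e-6


def _truth_model(row) -> MotionModelEMF:
    return MotionModelEMF(Sf2=row.Sf2, Ss2=row.Ss2, tauf=row.tauf, taus=row.taus)


def emit_dataset(truths: pd.DataFrame, observables=None,
                 noise: NoiseModel | None = None, seed: int = 0,
                 missing_fraction: float = 0.0,
                 spinlock_nu1_hz: float = 15000.0,
                 theta_range_deg: tuple = (85.0, 90.0)) -> dict:
    """Synthesise observation, decay, and REDOR tables from a truth table.

    Returns a dict with keys ``observations`` (long-format DataFrame),
    ``decays`` (per-residue intensity tables), ``redor`` (dephasing curves)
    and ``geometry`` (per-residue spin-lock tilt angles).  Setting
    ``missing_fraction`` masks random observations to emulate resonance
    overlap.
    """
    observables = observables or SEVEN_OBSERVABLE_SET
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed)
    obs_rows, decay_rows, redor_rows, geom_rows = [], [], [], []
    rigid = CONSTANTS.rigid_NH_anisotropy_hz
    redor_times = np.asarray(REDOR_PERIODS) / REDOR_MAS_HZ

    for row in truths.itertuples():
        model = _truth_model(row)
        ds = back_calculate(model, observables, residue=str(row.residue))
        for o in ds.observations:
            if missing_fraction > 0 and rng.uniform() < missing_fraction:
                continue
            sig = noise.sigma(o.kind)
            obs_rows.append({
                "residue_id": row.residue, "kind": o.kind,
                "field": "" if o.field is None else round(o.field.b0, 4),
                "field_unit": "" if o.field is None else "T",
                "value": o.value + rng.normal(0.0, sig), "sigma": sig,
            })
        # R1rho decay from R2/R1 and a residue-specific tilt angle
        theta = rng.uniform(*theta_range_deg)
        geom = SpinLockGeometry.from_theta(theta, spinlock_nu1_hz)
        f14 = FIELDS[14.09]
        r1 = float(rate_R1(model, f14))
        r2 = float(rate_R2(model, f14))
        th = math.radians(theta)
        r1rho = r2 * math.sin(th) ** 2 + r1 * math.cos(th) ** 2
        amp = 100.0
        sig_i = noise.decay_sigma_frac * amp * noise.scale
        for t in DECAY_GRID_S:
            decay_rows.append({
                "residue_id": row.residue, "duration_s": t,
                "intensity": amp * math.exp(-r1rho * t) + rng.normal(0.0, sig_i),
                "sigma": sig_i,
            })
        geom_rows.append({"residue_id": row.residue, "theta_deg": theta,
                          "offset_hz": geom.offset_hz,
                          "nu1_hz": spinlock_nu1_hz})
        # REDOR curve from the motionally scaled coupling
        delta_eff = math.sqrt(row.s2_total) * rigid
        curve = ideal_redor_curve(delta_eff, redor_times, REDOR_MAS_HZ,
                                  REDOR_TIME_SHIFT)
        for t, v in zip(curve.times, curve.values):
            noisy = v if t == 0.0 else v + rng.normal(0.0, noise.redor_sigma)
            redor_rows.append({"residue_id": row.residue, "time_s": t,
                               "dS_over_S0": noisy,
                               "sigma": noise.redor_sigma})
    return {
        "observations": pd.DataFrame(obs_rows),
        "decays": pd.DataFrame(decay_rows),
        "redor": pd.DataFrame(redor_rows),
        "geometry": pd.DataFrame(geom_rows),
        "truths": truths,
    }
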