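"""In-silico robustness studies: which observable sets constrain which motions.

These studies back-calculate noiseless observables from an assumed motion
model, optionally perturb them within realistic error margins, fit them with
the model-free machinery, and summarise how well the generating parameters
are recovered.  They reproduce three standard findings:

* relaxation rates alone leave picosecond motion (and hence the order
  parameter) poorly determined; adding the dipolar order parameter fixes it;
* fitting a one-motion (SMF) model to genuine two-time-scale motion returns a
  correlation time that snaps to either the fast or the slow process,
  depending on the slow-motion amplitude and time scale;
* relaxation-only SMF fits systematically overestimate the order parameter,
  worst when the underlying motion is predominantly fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import FieldContext
from .dataset import Observation, ResidueDataset
from .modelfree import FitConfig, fit_residue
from .relaxation import MotionModelEMF, MotionModelSMF, back_calculate

#: typical per-observable error margins (s^-1 for rates; absolute for S2dip)
DEFAULT_NOISE = {"R1": 0.009, "R2": 0.46, "eta": 1.57, "S2dip": 0.018}

FIELDS = {
    11.74: FieldContext.from_tesla(11.74),
    14.09: FieldContext.from_tesla(14.09),
    19.96: FieldContext.from_tesla(19.96),
}

#: six relaxation rates used in the multi-field recovery studies
SIX_RATE_SET = [
    ("R1", FIELDS[11.74]), ("R1", FIELDS[14.09]), ("R1", FIELDS[19.96]),
    ("R2", FIELDS[14.09]),
    ("eta", FIELDS[14.09]), ("eta", FIELDS[19.96]),
]

#: single-field observable set (one B0, R1 + R2)
SINGLE_FIELD_SET = [("R1", FIELDS[14.09]), ("R2", FIELDS[14.09])]


@dataclass
class Scenario:
    """One recovery experiment: truth, observables, noise, and fit settings."""

    truth: object
    observables: list
    noise: dict = field(default_factory=lambda: dict(DEFAULT_NOISE))
    n_mc: int = 2000
    fit: FitConfig | None = None
    name: str = ""

    def __post_init__(self):
        if not self.observables:
            raise ValueError("observable set must be non-empty")
        if any(v < 0 for v in self.noise.values()):
            raise ValueError("noise sigmas must be non-negative")


@dataclass
class RecoverySummary:
    name: str
    truth: dict
    params: dict           # central-fit parameters
    median: dict           # MC medians
    spread: dict           # MC standard deviations
    chi2: float
    flags: list
    mc_params: dict | None = None


def dataset_from_truth(truth, observables, noise, residue: str = "synthetic",
                       rng: np.random.Generator | None = None) -> ResidueDataset:
    """Back-calculate observables and tag them with the noise sigmas; values
    are perturbed only when an ``rng`` is supplied."""
    ds = back_calculate(truth, observables, residue=residue)
    out = []
    for o in ds.observations:
        sigma = noise.get(o.kind, 0.0)
        if sigma <= 0:
            sigma = max(abs(o.value) * 1e-6, 1e-12)   # effectively noiseless
        value = o.value + rng.normal(0.0, sigma) if rng is not None else o.value
        out.append(Observation(o.kind, o.field, value, sigma))
    return ResidueDataset(residue, out)


def run_scenario(scenario: Scenario, seed: int = 0) -> RecoverySummary:
    """Central fit of the noiseless back-calculated data plus Monte-Carlo
    refits of data resampled within the error margins."""
    cfg = scenario.fit or FitConfig()
    cfg.n_mc = scenario.n_mc
    cfg.seed = seed
    data = dataset_from_truth(scenario.truth, scenario.observables,
                              scenario.noise, residue=scenario.name or "scenario")
    fr = fit_residue(data, cfg)
    truth = {k: getattr(scenario.truth, k)
             for k in ("S2", "tau", "Sf2", "Ss2", "tauf", "taus")
             if hasattr(scenario.truth, k)}
    median = {k: float(np.median(v)) for k, v in (fr.mc_params or {}).items()}
    spread = {k: float(np.std(v)) for k, v in (fr.mc_params or {}).items()}
    return RecoverySummary(name=scenario.name, truth=truth, params=fr.params,
                           median=median, spread=spread, chi2=fr.chi2,
                           flags=fr.flags, mc_params=fr.mc_params)


def _emf_from_fraction(s_tot2: float, slow_fraction: float, tauf: float,
                       taus: float) -> MotionModelEMF:
    """EMF model with fixed total order parameter and a given share
    (1 - Ss2) / (1 - S_tot2) of the motional amplitude in the slow process."""
    ss2 = 1.0 - slow_fraction * (1.0 - s_tot2)
    sf2 = s_tot2 / ss2
    return MotionModelEMF(Sf2=sf2, Ss2=ss2, tauf=tauf, taus=taus)


def emf_truth_smf_fit_grid(taus_grid, slow_fraction_grid, tauf: float = 2e-12,
                           s_tot2: float = 0.8, observables=None,
                           noise: dict | None = None) -> pd.DataFrame:
    """Fitted SMF correlation time when the true motion has two time scales.

    For every (tau_s, slow-fraction) node, single-field relaxation rates plus
    the dipolar order parameter are back-calculated from the EMF truth and
    fitted with an SMF model whose total order parameter is pinned to the
    dipolar value.  The resulting map depends on tau_f but not on the total
    motional amplitude.
    """
    observables = observables or (SINGLE_FIELD_SET + [("S2dip", None)])
    noise = noise or DEFAULT_NOISE
    cfg = FitConfig(model="SMF", s2_mode="fixed_to_dipolar", n_mc=0)
    rows = []
    for taus in np.atleast_1d(taus_grid):
        for frac in np.atleast_1d(slow_fraction_grid):
            truth = _emf_from_fraction(s_tot2, frac, tauf, taus)
            data = dataset_from_truth(truth, observables, noise)
            fr = fit_residue(data, cfg)
            rows.append({"taus": float(taus), "slow_fraction": float(frac),
                         "tau_fit": fr.params["tau"], "s2_fit": fr.params["S2"],
                         "chi2": fr.chi2})
    return pd.DataFrame(rows)


def scenario_smf_recovery(tau: float, with_dipolar: bool, s2: float = 0.82,
                          n_mc: int = 2000) -> Scenario:
    """Single-motion recovery scenario: R1, R2, eta at 14.09 T, optionally
    plus the dipolar order parameter."""
    obs = [("R1", FIELDS[14.09]), ("R2", FIELDS[14.09]), ("eta", FIELDS[14.09])]
    mode = "free"
    if with_dipolar:
        obs = obs + [("S2dip", None)]
        mode = "weighted"
    cfg = FitConfig(model="SMF", s2_mode=mode, min_data=3, n_mc=n_mc)
    tag = "dip" if with_dipolar else "relax_only"
    return Scenario(truth=MotionModelSMF(S2=s2, tau=tau), observables=obs,
                    fit=cfg, n_mc=n_mc, name=f"smf_{tau:.1e}_{tag}")


def scenario_emf_recovery(slow_fraction: float = 0.5, s_tot2: float = 0.72,
                          tauf: float = 1e-10, taus: float = 5e-8,
                          relaxation_only: bool = False,
                          n_mc: int = 2000) -> Scenario:
    """Two-motion recovery: six rates (three fields) plus, unless
    ``relaxation_only``, the dipolar order parameter pinning the total S2."""
    truth = _emf_from_fraction(s_tot2, slow_fraction, tauf, taus)
    if relaxation_only:
        obs, mode = list(SIX_RATE_SET), "free"
    else:
        obs, mode = SIX_RATE_SET + [("S2dip", None)], "fixed_to_dipolar"
    cfg = FitConfig(model="EMF", s2_mode=mode, min_data=4, n_mc=n_mc)
    return Scenario(truth=truth, observables=obs, fit=cfg, n_mc=n_mc,
                    name=f"emf_{'relax' if relaxation_only else 'dip'}")


def run_preset(name: str, seed: int = 0, n_mc: int = 2000):
    """Named study presets; grid studies return tables, scenario presets a
    RecoverySummary."""
    presets = {
        "ps-relax": lambda: run_scenario(scenario_smf_recovery(3.2e-11, False,
                                                               n_mc=n_mc), seed),
        "ps-dip": lambda: run_scenario(scenario_smf_recovery(3.2e-11, True,
                                                             n_mc=n_mc), seed),
        "ns-relax": lambda: run_scenario(scenario_smf_recovery(3.2e-8, False,
                                                               n_mc=n_mc), seed),
        "ns-dip": lambda: run_scenario(scenario_smf_recovery(3.2e-8, True,
                                                             n_mc=n_mc), seed),
        "overestimation": lambda: smf_overestimation_study(
            0.72, np.round(np.arange(0.72, 1.0 + 1e-9, 0.02), 4)),
        "smf-on-emf": lambda: emf_truth_smf_fit_grid(
            np.logspace(-8.5, -6, 11), np.linspace(0.02, 0.98, 13)),
    }
    if name not in presets:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(presets)}")
    return presets[name]()


def classify_time_scale(tau: float, fieldctx: FieldContext) -> str:
    """'fast' or 'slow' relative to the R1 maximum at |omega_N| tau = 1."""
    return "fast" if tau < 1.0 / abs(fieldctx.omega_n) else "slow"


def smf_overestimation_study(s_tot2: float, sf2_grid, tauf: float = 1e-10,
                             taus: float = 5e-8, observables=None,
                             noise: dict | None = None,
                             include_dipolar: bool = False) -> pd.DataFrame:
    """Relaxation-only SMF order parameters fitted to EMF truths of fixed total
    amplitude; optionally with the dipolar order parameter pinning S2."""
    observables = observables or SIX_RATE_SET
    noise = noise or DEFAULT_NOISE
    if include_dipolar:
        observables = list(observables) + [("S2dip", None)]
        cfg = FitConfig(model="SMF", s2_mode="fixed_to_dipolar", n_mc=0)
    else:
        cfg = FitConfig(model="SMF", s2_mode="free", n_mc=0)
    rows = []
    for sf2 in np.atleast_1d(sf2_grid):
        if sf2 < s_tot2 - 1e-12:
            raise ValueError("Sf2 below the total order parameter is impossible")
        ss2 = min(1.0, s_tot2 / sf2)
        truth = MotionModelEMF(Sf2=float(sf2), Ss2=ss2, tauf=tauf, taus=taus)
        data = dataset_from_truth(truth, observables, noise)
        fr = fit_residue(data, cfg)
        rows.append({"Sf2_true": float(sf2), "Ss2_true": ss2,
                     "s2_total_true": s_tot2, "s2_fit": fr.params["S2"],
                     "tau_fit": fr.params["tau"], "chi2": fr.chi2})
    return pd.DataFrame(rows)
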