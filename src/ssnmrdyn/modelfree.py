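"""Joint model-free fitting of 15N relaxation rates and dipolar order parameters.

The target function is the (optionally weighted) chi-square

    chi2 = sum_i w_i (X_i,calc - X_i,exp)^2 / sigma_i^2

minimised by an exhaustive grid search followed by Nelder-Mead refinement.
Pinning the total order parameter to the dipolar-coupling value is implemented
by a strong weight (default w = 1000) on the S2dip term rather than by hard
substitution, which keeps a single minimisation code path.  Parameter errors
come from Monte-Carlo resampling of all observations within their sigmas;
model selection uses the F-ratio

    F = ((chi2_SMF - chi2_EMF) / chi2_EMF) / ((DF_SMF - DF_EMF) / DF_EMF)

with p from the F distribution with (DF_SMF - DF_EMF, DF_EMF) degrees of
freedom, and the Akaike criterion AIC = chi2 + 2 k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import f as f_dist

from .constants import FieldContext, InteractionConstants
from .dataset import Observation, ResidueDataset
from .relaxation import (MotionModelEMF, MotionModelSMF, rate_R1, rate_R2,
                         rate_eta)

TAU_BOUNDS = (1e-13, 1e-5)
#: cap on the fast correlation time / floor on the slow one; breaks the
#: label-swap degeneracy between the two EMF motions
TAUF_MAX = 5e-9
TAUS_MIN = 1e-9


class InsufficientDataError(ValueError):
    """Raised when a residue has fewer observations than the minimum-data rule."""


@dataclass
class FitConfig:
    model: str = "SMF"                 # "SMF" | "EMF"
    s2_mode: str = "weighted"          # "free" | "weighted" | "fixed_to_dipolar"
    dipolar_weight: float = 1000.0
    fixed_tauf: float | None = None
    min_data: int | None = None        # None -> 3 with dipolar data, 4 without
    n_mc: int = 2000
    seed: int = 0
    refine: bool = True
    # grids
    s2_grid: np.ndarray = dc_field(default=None)
    tau_grid: np.ndarray = dc_field(default=None)
    sf2_grid: np.ndarray = dc_field(default=None)
    ss2_grid: np.ndarray = dc_field(default=None)
    tauf_grid: np.ndarray = dc_field(default=None)
    taus_grid: np.ndarray = dc_field(default=None)
    mc_grid_stride: int = 2            # grid coarsening for the MC resampling fits

    def __post_init__(self):
        if self.model not in ("SMF", "EMF"):
            raise ValueError("model must be 'SMF' or 'EMF'")
        if self.s2_mode not in ("free", "weighted", "fixed_to_dipolar"):
            raise ValueError("unknown s2_mode")
        if self.s2_grid is None:
            self.s2_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.005), 6)
        if self.tau_grid is None:
            self.tau_grid = np.logspace(-13, -5, 160)
        if self.sf2_grid is None:
            self.sf2_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 6)
        if self.ss2_grid is None:
            self.ss2_grid = np.round(np.arange(0.0, 1.0 + 1e-9, 0.02), 6)
        if self.tauf_grid is None:
            self.tauf_grid = np.logspace(-13, np.log10(TAUF_MAX), 24)
        if self.taus_grid is None:
            self.taus_grid = np.logspace(np.log10(TAUS_MIN), -5, 28)

    @property
    def n_free(self) -> int:
        if self.model == "SMF":
            return 2
        return 3 if self.fixed_tauf is not None else 4


@dataclass
class FitResult:
    residue: str
    model: str
    params: dict
    errors: dict
    chi2: float
    dof: int
    flags: list
    n_obs: int
    mc_params: dict | None = None

    @property
    def s2_total(self) -> float:
        if self.model == "SMF":
            return self.params["S2"]
        return self.params["Sf2"] * self.params["Ss2"]

    @property
    def motion_model(self):
        if self.model == "SMF":
            return MotionModelSMF(self.params["S2"], self.params["tau"])
        return MotionModelEMF(self.params["Sf2"], self.params["Ss2"],
                              self.params["tauf"], self.params["taus"])


# ---------------------------------------------------------------------------
# chi-square machinery

def _effective_observations(data: ResidueDataset, cfg: FitConfig):
    """Apply the s2_mode policy; returns (observations, weights)."""
    obs, weights = [], []
    for o in data.observations:
        if o.kind == "S2dip":
            if cfg.s2_mode == "free":
                continue
            w = cfg.dipolar_weight if cfg.s2_mode == "fixed_to_dipolar" else 1.0
        else:
            w = 1.0
        obs.append(o)
        weights.append(w)
    return obs, np.asarray(weights, dtype=float)


def _calc_observable(kind: str, fieldctx, model) -> np.ndarray:
    if kind == "S2dip":
        return model.s2_total
    k = InteractionConstants.for_field(fieldctx)
    if kind == "R1":
        return rate_R1(model, fieldctx, k)
    if kind == "R2":
        return rate_R2(model, fieldctx, k)
    if kind == "eta":
        return rate_eta(model, fieldctx, k)
    raise ValueError(f"unknown observable kind {kind!r}")


def _calc_table(observations, model) -> np.ndarray:
    """Back-calculated observables, shape (n_obs,) + param broadcast shape."""
    rows = [np.broadcast_to(_calc_observable(o.kind, o.field, model),
                            np.shape(model.s2_total)) for o in observations]
    return np.stack([np.asarray(r, dtype=float) for r in rows])


def chi2(model, data: ResidueDataset, weights=None) -> float:
    """Weighted chi-square of a motion model against one residue's data.

    ``weights`` defaults to 1 for every observation; ``model`` may hold array
    parameters, in which case an array of chi2 values is returned.
    """
    obs = data.observations
    if weights is None:
        weights = np.ones(len(obs))
    weights = np.asarray(weights, dtype=float)
    vals = np.array([o.value for o in obs])
    sig = np.array([o.sigma for o in obs])
    calc = _calc_table(obs, model)
    resid2 = (calc - vals.reshape((-1,) + (1,) * (calc.ndim - 1))) ** 2
    coeff = (weights / sig**2).reshape((-1,) + (1,) * (calc.ndim - 1))
    return np.sum(coeff * resid2, axis=0)


def _chi2_from_table(calc, values, sigmas, weights):
    coeff = weights / sigmas**2
    return np.einsum("i,ij->j", coeff, (calc - values[:, None]) ** 2)


# ---------------------------------------------------------------------------
# grid construction

def _smf_grid(cfg: FitConfig):
    s2, tau = np.meshgrid(cfg.s2_grid, cfg.tau_grid, indexing="ij")
    return {"S2": s2.ravel(), "tau": tau.ravel()}


def _emf_grid(cfg: FitConfig):
    if cfg.fixed_tauf is not None:
        sf2, ss2, taus = np.meshgrid(cfg.sf2_grid, cfg.ss2_grid, cfg.taus_grid,
                                     indexing="ij")
        tauf = np.full_like(sf2, cfg.fixed_tauf)
    else:
        sf2, ss2, tauf, taus = np.meshgrid(cfg.sf2_grid, cfg.ss2_grid,
                                           cfg.tauf_grid, cfg.taus_grid,
                                           indexing="ij")
    keep = (tauf <= taus).ravel()
    grid = {"Sf2": sf2.ravel()[keep], "Ss2": ss2.ravel()[keep],
            "tauf": tauf.ravel()[keep], "taus": taus.ravel()[keep]}
    return grid


def _grid_model(cfg: FitConfig, grid: dict):
    if cfg.model == "SMF":
        return MotionModelSMF(grid["S2"], grid["tau"])
    return MotionModelEMF(grid["Sf2"], grid["Ss2"], grid["tauf"], grid["taus"])


def _coarsen(cfg: FitConfig) -> "FitConfig":
    """Config with every-``mc_grid_stride``-th grid node, for MC resampling."""
    k = max(1, int(cfg.mc_grid_stride))
    if k == 1:
        return cfg
    sub = FitConfig(model=cfg.model, s2_mode=cfg.s2_mode,
                    dipolar_weight=cfg.dipolar_weight, fixed_tauf=cfg.fixed_tauf,
                    min_data=cfg.min_data, n_mc=cfg.n_mc, seed=cfg.seed,
                    refine=False,
                    s2_grid=cfg.s2_grid[::k], tau_grid=cfg.tau_grid[::k],
                    sf2_grid=cfg.sf2_grid[::k], ss2_grid=cfg.ss2_grid[::k],
                    tauf_grid=cfg.tauf_grid[::k], taus_grid=cfg.taus_grid[::k],
                    mc_grid_stride=1)
    return sub


# ---------------------------------------------------------------------------
# refinement

def _pack(cfg, params):
    if cfg.model == "SMF":
        return np.array([params["S2"], np.log10(params["tau"])])
    x = [params["Sf2"], params["Ss2"]]
    if cfg.fixed_tauf is None:
        x.append(np.log10(params["tauf"]))
    x.append(np.log10(params["taus"]))
    return np.array(x)


def _unpack(cfg, x):
    if cfg.model == "SMF":
        return {"S2": x[0], "tau": 10.0 ** x[1]}
    if cfg.fixed_tauf is None:
        return {"Sf2": x[0], "Ss2": x[1], "tauf": 10.0 ** x[2], "taus": 10.0 ** x[3]}
    return {"Sf2": x[0], "Ss2": x[1], "tauf": cfg.fixed_tauf, "taus": 10.0 ** x[2]}


def _penalty(cfg, p) -> float:
    pen = 0.0
    if cfg.model == "SMF":
        pen += max(0.0, -p["S2"]) + max(0.0, p["S2"] - 1.0)
        pen += max(0.0, np.log10(TAU_BOUNDS[0] / p["tau"]))
        pen += max(0.0, np.log10(p["tau"] / TAU_BOUNDS[1]))
    else:
        for key in ("Sf2", "Ss2"):
            pen += max(0.0, -p[key]) + max(0.0, p[key] - 1.0)
        pen += max(0.0, np.log10(p["tauf"] / TAUF_MAX))
        pen += max(0.0, np.log10(TAU_BOUNDS[0] / p["tauf"]))
        pen += max(0.0, np.log10(TAUS_MIN / p["taus"]))
        pen += max(0.0, np.log10(p["taus"] / TAU_BOUNDS[1]))
        pen += max(0.0, np.log10(p["tauf"] / p["taus"]))
    return pen


def _refine(cfg, start_params, observations, values, sigmas, weights):
    obs_ds = ResidueDataset("_refine", observations)

    def objective(x):
        p = _unpack(cfg, x)
        pen = _penalty(cfg, p)
        pc = {k: float(np.clip(v, *TAU_BOUNDS)) if k.startswith("tau")
              else float(np.clip(v, 0.0, 1.0)) for k, v in p.items()}
        if cfg.model == "EMF":
            pc["tauf"] = min(pc["tauf"], pc["taus"])
        model = (MotionModelSMF(pc["S2"], pc["tau"]) if cfg.model == "SMF"
                 else MotionModelEMF(pc["Sf2"], pc["Ss2"], pc["tauf"], pc["taus"]))
        return float(chi2(model, obs_ds, weights)) + 1e6 * pen

    res = minimize(objective, _pack(cfg, start_params), method="Nelder-Mead",
                   options={"xatol": 1e-6, "fatol": 1e-12, "maxiter": 800})
    p = _unpack(cfg, res.x)
    p = {k: float(np.clip(v, *TAU_BOUNDS)) if k.startswith("tau")
         else float(np.clip(v, 0.0, 1.0)) for k, v in p.items()}
    if cfg.model == "EMF":
        p["tauf"] = min(p["tauf"], p["taus"])
    return p, float(res.fun)


# ---------------------------------------------------------------------------
# fitting

def _refine_starts(cfg, grid, chi_all, best_params, observations, values,
                   sigmas, weights):
    """Multi-start seeds for the local refinement: the grid optimum, a few
    low-chi2 nodes from distinct basins, and (for EMF) the best SMF solution
    embedded in the larger model, which guards the nesting chi2_EMF <= chi2_SMF."""
    starts = [best_params]
    order = np.argsort(chi_all)[:200]
    for idx in order[1:]:
        cand = {k: float(np.asarray(v)[idx]) for k, v in grid.items()}
        distinct = all(_param_distance(cand, s) > 0.5 for s in starts)
        if distinct:
            starts.append(cand)
        if len(starts) >= 3:
            break
    if cfg.model == "EMF" and cfg.fixed_tauf is None:
        smf_cfg = FitConfig(model="SMF", s2_mode=cfg.s2_mode,
                            dipolar_weight=cfg.dipolar_weight, n_mc=0,
                            refine=False)
        sgrid = _smf_grid(smf_cfg)
        sparams, _, _, _ = _grid_argmin(smf_cfg, sgrid, observations, values,
                                        sigmas, weights)
        s2, tau = sparams["S2"], sparams["tau"]
        if tau >= TAUS_MIN:
            starts.append({"Sf2": min(0.999, 1.0 - 1e-4), "Ss2": s2,
                           "tauf": min(1e-10, tau), "taus": tau})
        if tau <= TAUF_MAX:
            starts.append({"Sf2": s2, "Ss2": min(0.999, 1.0 - 1e-4),
                           "tauf": tau, "taus": max(tau, TAUS_MIN)})
    return starts


def _param_distance(a: dict, b: dict) -> float:
    d = 0.0
    for k in a:
        if k.startswith("tau"):
            d = max(d, abs(math.log10(a[k] / b[k])))
        else:
            d = max(d, abs(a[k] - b[k]) / 0.4)
    return d


def _obs_signature(observations):
    return tuple((o.kind, None if o.field is None else round(o.field.b0, 9))
                 for o in observations)


def _grid_argmin(cfg, grid, observations, values, sigmas, weights):
    # the grid back-calculation depends only on the observable kinds/fields,
    # so it is cached on the config across residues
    cache = getattr(cfg, "_calc_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(cfg, "_calc_cache", cache)
    key = (cfg.model, _obs_signature(observations))
    calc = cache.get(key)
    if calc is None:
        calc = _calc_table(observations, _grid_model(cfg, grid))
        cache.clear()           # one observable set at a time is typical
        cache[key] = calc
    chi = _chi2_from_table(calc, values, sigmas, weights)
    i = int(np.argmin(chi))
    params = {k: float(v[i]) for k, v in grid.items()}
    return params, float(chi[i]), calc, chi


def _edge_flags(cfg, params) -> list:
    flags = []
    tol = 1.001
    if cfg.model == "SMF":
        if params["tau"] <= TAU_BOUNDS[0] * tol or params["tau"] >= TAU_BOUNDS[1] / tol:
            flags.append("edge_of_grid")
    else:
        edge = (params["taus"] <= TAUS_MIN * tol or params["taus"] >= TAU_BOUNDS[1] / tol)
        if cfg.fixed_tauf is None:
            edge = edge or params["tauf"] <= TAU_BOUNDS[0] * tol
        if edge:
            flags.append("edge_of_grid")
    return flags


def _min_data(cfg: FitConfig, has_dipolar: bool) -> int:
    if cfg.min_data is not None:
        return cfg.min_data
    return 3 if has_dipolar else 4


def fit_residue(data: ResidueDataset, cfg: FitConfig) -> FitResult:
    """Grid search + local refinement + Monte-Carlo errors for one residue."""
    observations, weights = _effective_observations(data, cfg)
    has_dipolar = any(o.kind == "S2dip" for o in observations)
    need = _min_data(cfg, has_dipolar)
    if len(observations) < need or len(observations) < cfg.n_free:
        raise InsufficientDataError(
            f"residue {data.residue}: {len(observations)} observations, "
            f"minimum is {max(need, cfg.n_free)}")
    values = np.array([o.value for o in observations])
    sigmas = np.array([o.sigma for o in observations])

    grid = _smf_grid(cfg) if cfg.model == "SMF" else _emf_grid(cfg)
    params, chi_min, calc, chi_all = _grid_argmin(cfg, grid, observations,
                                                  values, sigmas, weights)
    flags = _edge_flags(cfg, params)

    # underdetermined detection: the statistically indistinguishable region
    # (delta chi2 <= 2) spans a large part of the parameter space
    near = chi_all <= chi_min + 2.0
    for key, vals_grid in grid.items():
        sel = np.asarray(vals_grid)[near]
        if key.startswith("tau"):
            wide = np.log10(sel.max() / max(sel.min(), 1e-300)) > 1.5
        else:
            wide = (sel.max() - sel.min()) > 0.3
        if wide:
            flags.append("underdetermined")
            break

    if cfg.refine:
        for start in _refine_starts(cfg, grid, chi_all, params, observations,
                                    values, sigmas, weights):
            ref_params, ref_chi = _refine(cfg, start, observations, values,
                                          sigmas, weights)
            if ref_chi < chi_min:
                params, chi_min = ref_params, ref_chi
        flags = _edge_flags(cfg, params) + [f for f in flags
                                            if f == "underdetermined"]

    dof = len(observations) - (2 if cfg.model == "SMF" else 4)
    errors, mc_params = {k: float("nan") for k in params}, None
    if cfg.n_mc > 0:
        errors, mc_params = _mc_errors(cfg, data, observations, sigmas, weights)
    return FitResult(residue=data.residue, model=cfg.model, params=params,
                     errors=errors, chi2=chi_min, dof=dof, flags=flags,
                     n_obs=len(observations), mc_params=mc_params)


def _mc_errors(cfg, data, observations, sigmas, weights):
    """Monte-Carlo parameter spreads from grid fits of resampled observations."""
    sub = _coarsen(cfg)
    grid = _smf_grid(sub) if sub.model == "SMF" else _emf_grid(sub)
    cache = getattr(cfg, "_calc_cache", None)
    if cache is None:
        cache = {}
        object.__setattr__(cfg, "_calc_cache", cache)
    key = ("mc", cfg.model, _obs_signature(observations))
    calc = cache.get(key)
    if calc is None:
        calc = _calc_table(observations, _grid_model(sub, grid)).astype(np.float32)
        cache[key] = calc
    values = np.array([o.value for o in observations])
    rng = np.random.default_rng(cfg.seed)
    draws = values[:, None] + rng.normal(size=(len(values), cfg.n_mc)) * sigmas[:, None]
    coeff = (weights / sigmas**2).astype(np.float32)
    # chi2(grid, draw) = q - 2 C b + const; const does not move the argmin
    q = (calc**2 * coeff[:, None]).sum(axis=0)
    best = np.empty(cfg.n_mc, dtype=np.int64)
    chunk = max(1, int(2e8 // (8 * calc.shape[1])))
    for lo in range(0, cfg.n_mc, chunk):
        b = (coeff[:, None] * draws[:, lo:lo + chunk]).astype(np.float32)
        scores = q[:, None] - 2.0 * (calc.T @ b)
        best[lo:lo + chunk] = np.argmin(scores, axis=0)
    mc = {k: np.asarray(v)[best] for k, v in grid.items()}
    errors = {k: float(np.std(v)) for k, v in mc.items()}
    return errors, mc


def f_test(fit_smf: FitResult, fit_emf: FitResult):
    """F-ratio comparing nested SMF/EMF fits and its p-value.

    Returns ``(F, p, flags)``; a zero EMF chi-square makes the ratio a limit
    and is flagged rather than raised.
    """
    dfs, dfe = fit_smf.dof, fit_emf.dof
    if dfs <= dfe:
        raise ValueError("DF_SMF must exceed DF_EMF")
    flags = []
    if fit_emf.chi2 == 0.0:
        if fit_smf.chi2 == 0.0:
            return 0.0, 1.0, ["zero_chi2_both"]
        flags.append("zero_chi2_emf")
        return float("inf"), 0.0, flags
    F = ((fit_smf.chi2 - fit_emf.chi2) / fit_emf.chi2) / ((dfs - dfe) / dfe)
    p = float(f_dist.sf(F, dfs - dfe, dfe))
    return float(F), p, flags


def aic_compare(fit_smf: FitResult, fit_emf: FitResult,
                k_smf: int = 2, k_emf: int = 4) -> str:
    """Akaike comparison AIC = chi2 + 2k; ties prefer the simpler model."""
    aic_s = fit_smf.chi2 + 2 * k_smf
    aic_e = fit_emf.chi2 + 2 * k_emf
    return "EMF" if aic_e < aic_s else "SMF"


def restrict_to_field(data: ResidueDataset, b0: float,
                      tol: float = 0.05) -> ResidueDataset:
    """Keep S2dip plus only the observations measured at B0 ~ ``b0`` tesla."""
    keep = [o for o in data.observations
            if o.kind == "S2dip" or abs(o.field.b0 - b0) <= tol]
    return ResidueDataset(data.residue, keep)


def fit_protein(datasets, cfg: FitConfig, single_field_b0: float | None = None):
    """Fit every residue; returns (results table, report dict).

    ``single_field_b0`` restricts the observations to one static field (plus
    the field-independent S2dip) before fitting.
    """
    rows, results, skipped = [], {}, {}
    for ds in datasets:
        if single_field_b0 is not None:
            ds = restrict_to_field(ds, single_field_b0)
        try:
            fr = fit_residue(ds, cfg)
        except InsufficientDataError as err:
            skipped[ds.residue] = str(err)
            continue
        results[ds.residue] = fr
        row = {"residue": fr.residue, "model": fr.model, "chi2": fr.chi2,
               "dof": fr.dof, "n_obs": fr.n_obs, "s2_total": fr.s2_total,
               "flags": ";".join(fr.flags)}
        for k, v in fr.params.items():
            row[k] = v
            row[f"{k}_err"] = fr.errors.get(k, float("nan"))
        rows.append(row)
    table = pd.DataFrame(rows)
    report = {"model": cfg.model, "s2_mode": cfg.s2_mode,
              "n_fit": len(rows), "n_skipped": len(skipped), "skipped": skipped}
    return table, report, results
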