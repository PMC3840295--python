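"""Delimited-text readers/writers for observation, decay, and dephasing tables.

All files are TSV by default (CSV accepted via the ``sep`` argument) with a
header row.  Observation tables carry an explicit field-unit column because
static fields are quoted either as tesla or as the 1H Larmor frequency in MHz.
Parse errors name the offending line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import field_from_value
from .dataset import KINDS, Observation, ResidueDataset
from .decay import DecaySeries

OBS_COLUMNS = ["residue_id", "kind", "field", "field_unit", "value", "sigma"]


class TableFormatError(ValueError):
    pass


def _read_table(path, sep="\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip() for c in df.columns]
    return df


def read_observations(path, sep="\t") -> list:
    """Parse a per-residue observation table into ResidueDataset objects.

    Expected columns: residue_id, kind, field, field_unit, value, sigma.
    The field columns are empty for S2dip rows.
    """
    df = _read_table(path, sep)
    missing = [c for c in OBS_COLUMNS if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    per_residue: dict = {}
    for irow, row in enumerate(df.itertuples(index=False), start=2):
        kind = row.kind.strip()
        if kind not in KINDS:
            raise TableFormatError(f"{path} line {irow}: unknown kind {kind!r}")
        try:
            value = float(row.value)
            sigma = float(row.sigma)
        except ValueError:
            raise TableFormatError(
                f"{path} line {irow}: non-numeric value/sigma") from None
        if sigma <= 0:
            raise TableFormatError(f"{path} line {irow}: sigma must be > 0")
        if kind == "S2dip":
            fieldctx = None
        else:
            try:
                fieldctx = field_from_value(float(row.field), row.field_unit)
            except ValueError as err:
                raise TableFormatError(f"{path} line {irow}: {err}") from None
        per_residue.setdefault(str(row.residue_id), []).append(
            Observation(kind, fieldctx, value, sigma))
    datasets = []
    for residue, obs in per_residue.items():
        try:
            datasets.append(ResidueDataset(residue, obs))
        except ValueError as err:
            raise TableFormatError(f"{path}: {err}") from None
    return datasets


def write_observations(datasets, path, sep="\t") -> None:
    rows = []
    for ds in datasets:
        for o in ds.observations:
            rows.append({
                "residue_id": ds.residue, "kind": o.kind,
                "field": "" if o.field is None else repr(o.field.b0),
                "field_unit": "" if o.field is None else "T",
                "value": repr(o.value), "sigma": repr(o.sigma),
            })
    pd.DataFrame(rows, columns=OBS_COLUMNS).to_csv(path, sep=sep, index=False)


def read_decays(path, sep="\t") -> dict:
    """Batch decay table (residue_id, duration_s, intensity, sigma) ->
    {residue_id: DecaySeries}."""
    df = _read_table(path, sep)
    need = ["residue_id", "duration_s", "intensity", "sigma"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise TableFormatError(f"{path}: missing columns {missing}")
    out = {}
    for residue, grp in df.groupby("residue_id", sort=False):
        try:
            out[str(residue)] = DecaySeries(
                grp["duration_s"].astype(float).to_numpy(),
                grp["intensity"].astype(float).to_numpy(),
                grp["sigma"].astype(float).to_numpy())
        except ValueError as err:
            raise TableFormatError(f"{path} residue {residue}: {err}") from None
    return out


def write_dephasing_curve(curve, path, sep="\t") -> None:
    df = pd.DataFrame({"time_s": curve.times, "dS_over_S0": curve.values})
    if curve.sigma is not None:
        df["sigma"] = curve.sigma
    df.to_csv(path, sep=sep, index=False, float_format="%.10g")


def read_dephasing_curve(path, sep="\t"):
    from .redor import DephasingCurve
    df = _read_table(path, sep)
    if "time_s" not in df.columns or "dS_over_S0" not in df.columns:
        raise TableFormatError(f"{path}: need columns time_s, dS_over_S0")
    sigma = df["sigma"].astype(float).to_numpy() if "sigma" in df.columns else None
    return DephasingCurve(df["time_s"].astype(float).to_numpy(),
                          df["dS_over_S0"].astype(float).to_numpy(), sigma)


def write_results(table: pd.DataFrame, path, report: dict | None = None,
                  sep="\t") -> None:
    """Write a fit-results table (and an optional JSON report next to it);
    numeric fields are written at full precision for lossless round-trips."""
    table.to_csv(path, sep=sep, index=False, float_format="%.17g")
    if report is not None:
        Path(path).with_suffix(".report.json").write_text(
            json.dumps(report, indent=2, default=_jsonable))


def read_results(path, sep="\t") -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, float_precision="round_trip")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
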