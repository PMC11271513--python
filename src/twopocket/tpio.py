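"""Plain-text artifact I/O: trajectories, hills, profiles, assays, bundles.

All tabular artifacts are CSV/TSV written with 17-significant-digit
floats so numeric round-trips are bit-exact; every simulated artifact
carries a JSON sidecar recording seed and provenance.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assays import AssayDataset
from .dynamics import Trajectory
from .metad import BiasState, FreeEnergyProfile

SCHEMA_VERSION = "1"
FLOAT_FMT = "%.17g"


class SchemaError(RuntimeError):
    pass


# -- trajectories -----------------------------------------------------------

def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    cols = {"time": traj.times}
    dim = traj.cf3.shape[1]
    axes = "xyz"[:dim]
    for i, ax in enumerate(axes):
        cols[f"cf3_{ax}"] = traj.cf3[:, i]
    for i, ax in enumerate(axes):
        cols[f"o1_{ax}"] = traj.o1[:, i]
    pd.DataFrame(cols).to_csv(path, index=False, float_format=FLOAT_FMT)
    meta = {
        "schema_version": SCHEMA_VERSION,
        "seed": traj.seed,
        "config_hash": traj.config_hash,
        "bond_length": traj.bond_length,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_trajectory(path: str | Path) -> Trajectory:
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path} for {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {meta.get('schema_version')}")
    df = pd.read_csv(path, float_precision="round_trip")
    axes = [c.split("_")[1] for c in df.columns if c.startswith("cf3_")]
    cf3 = df[[f"cf3_{a}" for a in axes]].to_numpy()
    o1 = df[[f"o1_{a}" for a in axes]].to_numpy()
    return Trajectory(
        times=df["time"].to_numpy(),
        cf3=cf3,
        o1=o1,
        bond_length=float(meta["bond_length"]),
        seed=int(meta["seed"]),
        config_hash=str(meta["config_hash"]),
    )


# -- hills and profiles -----------------------------------------------------

def write_hills(bias: BiasState, path: str | Path) -> None:
    c, h, w, t = bias.as_arrays()
    pd.DataFrame({"time": t, "center": c, "height": h, "width": w}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_hills(path: str | Path) -> BiasState:
    df = pd.read_csv(path, float_precision="round_trip")
    bias = BiasState()
    bias.times = df["time"].tolist()
    bias.centers = df["center"].tolist()
    bias.heights = df["height"].tolist()
    bias.widths = df["width"].tolist()
    return bias


def write_profile(profile: FreeEnergyProfile, path: str | Path) -> None:
    pd.DataFrame({"cv": profile.grid, "free_energy": profile.f}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_profile(path: str | Path) -> FreeEnergyProfile:
    df = pd.read_csv(path, float_precision="round_trip")
    return FreeEnergyProfile(grid=df["cv"].to_numpy(), f=df["free_energy"].to_numpy())


# -- assay datasets ---------------------------------------------------------

def write_assay(dataset: AssayDataset, path: str | Path) -> None:
    path = Path(path)
    pd.DataFrame({"x": dataset.x, "y": dataset.y}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
    meta = {
        "schema_version": SCHEMA_VERSION,
        "kind": dataset.kind,
        "noise_sd": dataset.noise_sd,
        "seed": dataset.seed,
        "true_params": dataset.true_params,
    }
    path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))


def read_assay(path: str | Path) -> AssayDataset:
    path = Path(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar {meta_path} for {path}")
    meta = json.loads(meta_path.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {meta.get('schema_version')}")
    df = pd.read_csv(path, float_precision="round_trip")
    return AssayDataset(
        kind=meta["kind"],
        x=df["x"].to_numpy(),
        y=df["y"].to_numpy(),
        noise_sd=float(meta["noise_sd"]),
        seed=int(meta["seed"]),
        true_params=meta["true_params"],
    )


# -- result bundles ---------------------------------------------------------

def write_results(bundle: dict, directory: str | Path) -> None:
    """Write a pipeline result bundle (summary JSON + CSV tables)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    head = {
        "schema_version": SCHEMA_VERSION,
        "seed": bundle["seed"],
        "summary": bundle["summary"],
        "tables": sorted(bundle.get("tables", {})),
    }
    (directory / "summary.json").write_text(json.dumps(head, indent=1, sort_keys=True))
    for name, table in bundle.get("tables", {}).items():
        table.to_csv(directory / f"{name}.csv", index=False, float_format=FLOAT_FMT)


def read_results(directory: str | Path) -> dict:
    """Read a bundle written by :func:`write_results`."""
    directory = Path(directory)
    summary_path = directory / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(
            f"missing {summary_path}; expected summary.json plus per-table CSVs"
        )
    head = json.loads(summary_path.read_text())
    if head.get("schema_version") != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {head.get('schema_version')}")
    tables = {}
    missing = []
    for name in head.get("tables", []):
        p = directory / f"{name}.csv"
        if not p.exists():
            missing.append(str(p))
            continue
        df = pd.read_csv(p, float_precision="round_trip")
        # CSV cannot distinguish 1.0 from 1; numeric columns are float64
        for col in df.columns:
            if pd.api.types.is_numeric_dtype(df[col]):
                df[col] = df[col].astype(float)
        tables[name] = df
    if missing:
        raise FileNotFoundError(f"bundle incomplete; missing: {', '.join(missing)}")
    return {"seed": head["seed"], "summary": head["summary"], "tables": tables}
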