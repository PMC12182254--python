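"""Readers/writers for the delimited-text artifact formats, the Fisher-z
connectivity constructor, and run configuration.

Conventions: node indices are 1-based in all files; unordered edge keys are
stored once with x < y; missing behavior is an empty cell (no sentinel
numbers); matrices are plain numeric text (whitespace- or comma-delimited).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .datatypes import BehaviorTable, ConnectomeSet

__all__ = [
    "connectivity_from_timeseries",
    "read_connectomes",
    "write_connectomes",
    "read_edge_list",
    "read_behavior",
    "write_behavior",
    "read_atlas",
    "RunConfig",
]

#: correlations are clipped to +/-(1 - CORR_CLIP) before atanh so that
#: numerically perfect correlations stay finite on the z scale
CORR_CLIP = 1e-7


def connectivity_from_timeseries(ts: np.ndarray) -> np.ndarray:
    """Fisher-z connectivity matrix from a T x V node time-series array.

    Off-diagonal entries are atanh of the Pearson correlation; the
    diagonal is set to 0 by convention.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be T x V")
    t, v = ts.shape
    if t < 3:
        raise ValueError("need at least 3 time points")
    sd = ts.std(axis=0)
    constant = np.nonzero(sd == 0)[0]
    if constant.size:
        raise ValueError(
            f"constant time series for node(s) {[int(i)+1 for i in constant]}"
        )
    r = np.corrcoef(ts, rowvar=False)
    r = np.clip(r, -1.0 + CORR_CLIP, 1.0 - CORR_CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    return z


def _load_matrix(path: Path) -> np.ndarray:
    with open(path) as fh:
        first = fh.readline()
    delim = "," if "," in first else None
    return np.loadtxt(path, delimiter=delim, ndmin=2)


def read_connectomes(manifest: str | Path, condition: str | None = None
                     ) -> ConnectomeSet:
    """Read a connectome stack from a manifest CSV (subject_id, path).

    Paths are resolved relative to the manifest's directory; subject order
    follows the manifest.  Each file must be square, symmetric within 1e-6
    and free of NaNs.
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest, dtype={"subject_id": str})
    if not {"subject_id", "path"} <= set(table.columns):
        raise ValueError("manifest needs columns subject_id, path")
    mats, ids = [], []
    v = None
    for row in table.itertuples():
        path = Path(row.path)
        if not path.is_absolute():
            path = manifest.parent / path
        mat = _load_matrix(path)
        if mat.shape[0] != mat.shape[1]:
            raise ValueError(f"{path}: matrix is not square "
                             f"(shape {mat.shape})")
        if v is None:
            v = mat.shape[0]
        elif mat.shape[0] != v:
            raise ValueError(f"{path}: expected {v} nodes, got "
                             f"{mat.shape[0]}")
        if np.any(~np.isfinite(mat)):
            bad = np.argwhere(~np.isfinite(mat))[0]
            raise ValueError(f"{path}: non-finite value at "
                             f"({bad[0]+1}, {bad[1]+1})")
        if not np.allclose(mat, mat.T, atol=1e-6, rtol=0.0):
            bad = np.argwhere(~np.isclose(mat, mat.T, atol=1e-6))[0]
            raise ValueError(f"{path}: asymmetric at ({bad[0]+1}, "
                             f"{bad[1]+1})")
        mats.append(mat)
        ids.append(str(row.subject_id))
    if not mats:
        raise ValueError(f"{manifest}: empty manifest")
    cond = condition or manifest.stem.removesuffix("_manifest")
    return ConnectomeSet(np.stack(mats), subject_ids=ids, condition=cond)


def write_connectomes(cset: ConnectomeSet, outdir: str | Path,
                      fmt: str = "%.17g") -> Path:
    """Write one matrix file per subject plus a manifest CSV; returns the
    manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for j, sid in enumerate(cset.subject_ids):
        fname = f"{sid}.txt"
        np.savetxt(outdir / fname, cset.values[j], fmt=fmt)
        rows.append((sid, fname))
    manifest = outdir / f"{cset.condition}_manifest.csv"
    pd.DataFrame(rows, columns=["subject_id", "path"]).to_csv(
        manifest, index=False)
    return manifest


def read_edge_list(path: str | Path, condition: str = "unknown"
                   ) -> ConnectomeSet:
    """Read a stacked edge list (subject_id, node_x, node_y, value) with
    1-based node indices, each unordered pair stored once with x < y."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    need = {"subject_id", "node_x", "node_y", "value"}
    if not need <= set(df.columns):
        raise ValueError(f"edge list needs columns {sorted(need)}")
    if (df["node_x"] >= df["node_y"]).any():
        raise ValueError("edge list must store pairs with node_x < node_y")
    v = int(df["node_y"].max())
    ids = list(dict.fromkeys(df["subject_id"]))
    mats = np.zeros((len(ids), v, v))
    pos = {s: i for i, s in enumerate(ids)}
    j = df["subject_id"].map(pos).to_numpy()
    x = df["node_x"].to_numpy(dtype=int) - 1
    y = df["node_y"].to_numpy(dtype=int) - 1
    mats[j, x, y] = df["value"].to_numpy(dtype=float)
    mats += mats.transpose(0, 2, 1)
    return ConnectomeSet(mats, subject_ids=ids, condition=condition)


def read_behavior(path: str | Path, category: str | None = None
                  ) -> BehaviorTable:
    """Read a behavior table: first column subject_id, remaining columns
    named indicators; empty cells are missing."""
    df = pd.read_csv(path, dtype={0: str})
    first = df.columns[0]
    ids = df[first].astype(str).tolist()
    vals = df.drop(columns=[first]).to_numpy(dtype=float)
    return BehaviorTable(vals, indicator_names=list(df.columns[1:]),
                         category=category or Path(path).stem,
                         subject_ids=ids)


def write_behavior(B: BehaviorTable, path: str | Path) -> None:
    df = pd.DataFrame(B.values, columns=B.indicator_names)
    df.insert(0, "subject_id", B.subject_ids)
    df.to_csv(path, index=False)


def read_atlas(path: str | Path) -> pd.DataFrame:
    """Read a node -> system table (node_id, system[, x, y, z])."""
    df = pd.read_csv(path)
    if not {"node_id", "system"} <= set(df.columns):
        raise ValueError("atlas needs columns node_id, system")
    return df


@dataclass
class RunConfig:
    """Flat key-value run configuration (YAML-compatible subset).

    Thresholds default to the study protocol: 0.9 train fraction, CPM
    p-threshold 0.001, top 10+10 nodes, 5000 burn-in, 15,000 samples,
    10 initializations, 5 repeats.
    """

    connectomes: dict = field(default_factory=dict)  # condition -> manifest
    behavior: str | None = None
    atlas: str | None = None
    categories: dict = field(default_factory=dict)   # category -> indicators
    n_burn: int = 5000
    n_samples: int = 15000
    thin: int = 1
    n_inits: int = 10
    seed: int = 0
    split_fraction: float = 0.9
    n_repeats: int = 5
    cpm_p_threshold: float = 0.001
    k_pos: int = 10
    k_neg: int = 10
    reference_condition: str = "Rest1"

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        base = Path(path).parent
        for label, man in list(cfg.connectomes.items()):
            p = base / man if not os.path.isabs(man) else Path(man)
            if not p.exists():
                raise FileNotFoundError(f"connectome manifest for "
                                        f"'{label}' not found: {p}")
            cfg.connectomes[label] = str(p)
        for attr in ("behavior", "atlas"):
            val = getattr(cfg, attr)
            if val is not None:
                p = base / val if not os.path.isabs(val) else Path(val)
                if not p.exists():
                    raise FileNotFoundError(f"{attr} file not found: {p}")
                setattr(cfg, attr, str(p))
        return cfg
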