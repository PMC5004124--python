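"""Plain-text I/O: spike tables, trajectories, binned matrices, models.

Formats
-------
* spikes: TSV with columns ``cell_id`` and ``time_s``
* trajectory: TSV with ``time_s``, ``x_cm`` and optionally ``y_cm``
* spike-count matrix: dense TSV (rows = cells) plus a JSON sidecar
  ``<path>.json`` holding ``delta``, ``t0``, ``cell_ids`` and
  ``source_bins``
* fitted HMM: single JSON document
* topology graph: edge-list TSV ``i, j, w_ij``
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SpikeMatrix, Trajectory
from .hmm import HDPHMMConfig, HMMModel

__all__ = [
    "write_spike_times",
    "read_spike_times",
    "write_trajectory",
    "read_trajectory",
    "write_spike_matrix",
    "read_spike_matrix",
    "write_model",
    "read_model",
    "write_edge_list",
    "bin_spike_times",
]


def write_spike_times(path, spikes: pd.DataFrame) -> None:
    """Write a (cell_id, time_s) spike table as TSV."""
    spikes[["cell_id", "time_s"]].to_csv(path, sep="\t", index=False)


def read_spike_times(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"cell_id", "time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"spike table missing columns: {sorted(missing)}")
    if df["time_s"].lt(0).any():
        bad = int(df.index[df["time_s"] < 0][0]) + 2  # header + 1-based
        raise ValueError(f"negative spike time at line {bad}")
    return df


def bin_spike_times(spikes: pd.DataFrame, delta: float, t0: float = 0.0,
                    t_end: float | None = None) -> SpikeMatrix:
    """Bin a spike-time table into a cells x bins count matrix."""
    cells = np.sort(spikes["cell_id"].unique())
    row = {c: i for i, c in enumerate(cells)}
    if t_end is None:
        t_end = float(spikes["time_s"].max()) + 1e-9
    n_bins = int(np.ceil((t_end - t0) / delta))
    counts = np.zeros((len(cells), n_bins), dtype=np.int64)
    k = np.floor((spikes["time_s"].to_numpy() - t0) / delta).astype(int)
    ok = (k >= 0) & (k < n_bins)
    r = spikes["cell_id"].map(row).to_numpy()[ok]
    np.add.at(counts, (r, k[ok]), 1)
    return SpikeMatrix(counts, delta, t0=t0, cell_ids=cells)


def write_trajectory(path, traj: Trajectory) -> None:
    pos = np.atleast_2d(traj.pos.T).T
    cols = {"time_s": traj.t, "x_cm": pos[:, 0]}
    if pos.shape[1] > 1:
        cols["y_cm"] = pos[:, 1]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def read_trajectory(path, env=None) -> Trajectory:
    df = pd.read_csv(path, sep="\t")
    if "time_s" not in df.columns or "x_cm" not in df.columns:
        raise ValueError("trajectory file needs time_s and x_cm columns")
    t = df["time_s"].to_numpy()
    if np.any(np.diff(t) <= 0):
        bad = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise ValueError(f"non-monotone trajectory time at line {bad}")
    if "y_cm" in df.columns:
        pos = df[["x_cm", "y_cm"]].to_numpy()
    else:
        pos = df["x_cm"].to_numpy()
    return Trajectory(t, pos, env=env)


def _sidecar(path) -> Path:
    return Path(str(path) + ".json")


def write_spike_matrix(path, sm: SpikeMatrix) -> None:
    np.savetxt(path, sm.counts, fmt="%d", delimiter="\t")
    meta = {
        "delta": sm.delta,
        "t0": sm.t0,
        "cell_ids": sm.cell_ids.tolist(),
        "source_bins": sm.source_bins.tolist(),
    }
    _sidecar(path).write_text(json.dumps(meta))


def read_spike_matrix(path) -> SpikeMatrix:
    side = _sidecar(path)
    if not side.exists():
        raise FileNotFoundError(f"missing sidecar {side}")
    meta = json.loads(side.read_text())
    counts = np.loadtxt(path, delimiter="\t", dtype=np.int64, ndmin=2)
    return SpikeMatrix(
        counts,
        float(meta["delta"]),
        t0=float(meta["t0"]),
        cell_ids=np.asarray(meta["cell_ids"]),
        source_bins=np.asarray(meta["source_bins"], dtype=int),
    )


def write_model(path, model: HMMModel) -> None:
    doc = {
        "m": model.m,
        "P": model.P.tolist(),
        "Lambda": model.Lambda.tolist(),
        "pi0": model.pi0.tolist(),
        "delta": model.delta,
        "active_states": model.active_states.tolist(),
        "config": {
            "L": model.config.L,
            "gamma": model.config.gamma,
            "alpha": model.config.alpha,
            "kappa": model.config.kappa,
            "rate_shape": model.config.rate_shape,
        },
        "diagnostics": {
            "best_logp": float(model.diagnostics.get("best_logp", np.nan)),
            "converged": bool(model.diagnostics.get("converged", True)),
        },
    }
    Path(path).write_text(json.dumps(doc))


def read_model(path) -> HMMModel:
    doc = json.loads(Path(path).read_text())
    cfg = HDPHMMConfig(**doc["config"])
    return HMMModel(
        m=int(doc["m"]),
        P=np.asarray(doc["P"]),
        Lambda=np.asarray(doc["Lambda"]),
        pi0=np.asarray(doc["pi0"]),
        delta=float(doc["delta"]),
        config=cfg,
        active_states=np.asarray(doc["active_states"], dtype=int),
        diagnostics=doc.get("diagnostics", {}),
    )


def write_event_table(path, results, intervals=None) -> None:
    """One row per scored replay event: statistics and criteria flags."""
    rows = []
    for i, r in enumerate(results):
        row = {
            "event": i,
            "t_start": intervals[i][0] if intervals else np.nan,
            "t_end": intervals[i][1] if intervals else np.nan,
            "n_bins": r.n_bins,
            "R": r.R,
            "abs_R": r.abs_R,
            "Z": r.Z,
            "p": r.p,
            "p_method": r.p_method,
            "avg_map_score": r.avg_map_score,
            "direction": r.direction,
        }
        row.update(r.flags)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_event_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "R" not in df.columns or "Z" not in df.columns:
        raise ValueError("not an event table: missing R/Z columns")
    return df


def write_edge_list(path, graph) -> None:
    """Topology graph as a TSV edge list (i, j, w_ij)."""
    rows = [
        {"i": i, "j": j, "w": d["weight"]} for i, j, d in graph.graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["i", "j", "w"]).to_csv(path, sep="\t", index=False)
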