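"""Monte-Carlo harness for representation- and detection-power experiments.

Each run draws an independent synthetic session (or replay event) from a
run-specific seed (``base_seed + run``), applies the requested sleep-like
degradations, decodes with the receptive-field (wRF) and/or
receptive-field-free (woRF) method, and records the median decoding
error or the replay statistics.  Grid cells within a run share the same
substrate, so comparisons across conditions are paired.  Summaries are
reported as mean +/- SEM over runs (SEM = SD / sqrt(n)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd

from .core import Environment, SpikeMatrix, Trajectory, bin_mean_positions
from .decode_rf import decode_epochs_error
from .hmm import (
    HDPHMMConfig,
    build_state_space_map,
    decode_position_from_states,
    fit_hdp_hmm,
)
from .placefields import estimate_place_fields, partition_by_information
from .replay import RFEventDecoder, score_event
from .synthetic import (
    GroundTruthFields,
    apply_speed_filter,
    make_population,
    make_replay_event,
    sample_spike_counts,
    simulate_trajectory,
    split_into_epochs,
    subsample_cells,
    thin_spikes,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Session",
    "make_session",
    "RepresentationConfig",
    "DetectionConfig",
    "ResultTable",
    "run_representation_experiment",
    "run_detection_experiment",
    "write_result_table",
    "read_result_table",
]


@dataclass
class Session:
    """A self-contained synthetic recording session."""

    env: Environment
    truth: GroundTruthFields
    traj: Trajectory
    counts: SpikeMatrix  # speed-filtered
    place_fields: "object"  # estimated PlaceFieldMap
    pos_all: np.ndarray  # per original-bin mean position
    delta: float


def make_session(
    seed: int,
    env: Environment | None = None,
    n_cells: int = 49,
    duration_s: float = 420.0,
    delta: float = 0.25,
    mean_speed: float = 25.0,
    speed_filter_cm_s: float = 15.0,
    truncate_to_multiple: int | None = None,
    n_nonplace: int = 0,
) -> Session:
    """Simulate a run session and estimate place fields from it.

    Defaults mimic an open-field foraging recording: ~49 place cells,
    250-ms bins, 15 cm/s speed filter, 15 x 15 cm spatial bins.
    ``truncate_to_multiple`` trims the filtered recording so the bin
    count divides evenly into epochs of that size.
    """
    rng = np.random.default_rng(seed)
    if env is None:
        env = Environment("open_field", (100.0, 100.0), 15.0)
    truth = make_population(env, n_cells=n_cells, n_nonplace=n_nonplace,
                            seed=rng.integers(2**31))
    traj = simulate_trajectory(env, duration_s, mean_speed, seed=rng.integers(2**31))
    counts = sample_spike_counts(truth, traj, delta, seed=rng.integers(2**31))
    counts = apply_speed_filter(counts, traj, threshold=speed_filter_cm_s)
    if truncate_to_multiple:
        T = (counts.n_bins // truncate_to_multiple) * truncate_to_multiple
        counts = counts.select_bins(np.arange(T))
    fields = estimate_place_fields(counts, traj, env)
    n_src = int(counts.source_bins.max()) + 1
    pos_all = bin_mean_positions(traj, delta, counts.t0, n_src)
    return Session(env, truth, traj, counts, fields, pos_all, delta)


@dataclass
class ResultTable:
    """Run-level raw values plus the mean +/- SEM summary."""

    raw: pd.DataFrame
    summary: pd.DataFrame
    n_runs: int


def _summarize(raw: pd.DataFrame, keys: list[str], value: str) -> pd.DataFrame:
    g = raw.groupby(keys, dropna=False)[value]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["sem"] = out["std"] / np.sqrt(out["count"])
    return out.rename(columns={"count": "n"}).drop(columns=["std"])


@dataclass
class RepresentationConfig:
    """Grid for the representation-power (decoding-error) experiments."""

    sweeps: tuple[str, ...] = ("rho",)  # subset of {"T0", "rho", "rho_per_epoch", "info_split", "delta"}
    T0_grid: tuple[int, ...] = (10, 50, 100)
    rho_grid: tuple[float, ...] = (0.3, 0.5, 0.8, 1.0)
    delta_grid: tuple[float, ...] = (0.05, 0.15, 0.25)
    T0: int = 10  # fixed T0 for the rho / delta / info sweeps
    thinning: bool = False
    n_runs: int = 50
    base_seed: int = 0
    decoders: tuple[str, ...] = ("wrf", "worf")
    # session substrate
    n_cells: int = 49
    duration_s: float = 420.0
    delta: float = 0.25
    # woRF sampler scale
    hmm: HDPHMMConfig = dfield(default_factory=lambda: HDPHMMConfig(L=25))
    hmm_iters: int = 40
    hmm_burn: int = 20

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be at least 2")


def _worf_error(epochs, session: Session, cfg: RepresentationConfig, seed) -> float:
    model = fit_hdp_hmm(epochs, config=cfg.hmm, n_iter=cfg.hmm_iters,
                        burn_in=cfg.hmm_burn, seed=seed)
    smap = build_state_space_map(model, epochs, session.pos_all, session.env)
    err, _ = decode_position_from_states(model, smap, epochs, session.pos_all, session.env)
    return err


def run_representation_experiment(config: RepresentationConfig) -> ResultTable:
    """Run the configured decoding-error sweeps.

    Emits one raw row per (run, sweep, condition, decoder) holding the
    median decoding error in cm, and a mean +/- SEM summary in the shape
    of the published comparison tables.  Infeasible grid cells are
    recorded as NaN with a reason.
    """
    rows = []
    for run in range(config.n_runs):
        seed = config.base_seed + run
        rng = np.random.default_rng(seed)
        session = make_session(
            rng.integers(2**31),
            n_cells=config.n_cells,
            duration_s=config.duration_s,
            delta=config.delta,
        )
        counts = session.counts
        if config.thinning:
            counts = thin_spikes(counts)
        logger.info("representation run %d/%d (T=%d bins)", run + 1,
                    config.n_runs, counts.n_bins)

        def record(sweep, param, variant, decoder, value, reason=""):
            rows.append({
                "run": run, "sweep": sweep, "param": param, "variant": variant,
                "decoder": decoder, "median_error_cm": value, "note": reason,
            })

        if "T0" in config.sweeps:
            for T0 in config.T0_grid:
                if T0 > counts.n_bins:
                    record("T0", T0, "fixed", "na", np.nan, "T0 exceeds recording")
                    continue
                epochs = split_into_epochs(counts, T0, seed=rng.integers(2**31))
                if "wrf" in config.decoders:
                    record("T0", T0, "fixed", "wrf",
                           decode_epochs_error(epochs, session.place_fields,
                                               session.env, session.traj))
                if "worf" in config.decoders:
                    record("T0", T0, "fixed", "worf",
                           _worf_error(epochs, session, config, rng.integers(2**31)))

        rho_sweeps = [s for s in ("rho", "rho_per_epoch") if s in config.sweeps]
        if rho_sweeps:
            epochs = split_into_epochs(counts, config.T0, seed=rng.integers(2**31))
            for sweep in rho_sweeps:
                per_epoch = sweep == "rho_per_epoch"
                variant = "per_epoch" if per_epoch else "fixed"
                for rho in config.rho_grid:
                    sub_seed = rng.integers(2**31)
                    try:
                        if "wrf" in config.decoders:
                            sub = subsample_cells(epochs, rho, per_epoch=per_epoch,
                                                  mode="remove", seed=sub_seed)
                            record(sweep, rho, variant, "wrf",
                                   decode_epochs_error(sub, session.place_fields,
                                                       session.env, session.traj))
                        if "worf" in config.decoders:
                            sub = subsample_cells(epochs, rho, per_epoch=per_epoch,
                                                  mode="zero", seed=sub_seed)
                            record(sweep, rho, variant, "worf",
                                   _worf_error(sub, session, config, rng.integers(2**31)))
                    except ValueError as e:
                        record(sweep, rho, variant, "na", np.nan, str(e))

        if "info_split" in config.sweeps:
            high, low = partition_by_information(session.place_fields)
            epochs = split_into_epochs(counts, config.T0, seed=rng.integers(2**31))
            for name, sel in (("high", high), ("low", low)):
                sub = type(epochs)(
                    [e.select_cells(sel) for e in epochs.epochs], T0=epochs.T0,
                    reversed_flags=list(epochs.reversed_flags),
                )
                if "wrf" in config.decoders:
                    record("info_split", name, "fixed", "wrf",
                           decode_epochs_error(sub, session.place_fields,
                                               session.env, session.traj))
                if "worf" in config.decoders:
                    record("info_split", name, "fixed", "worf",
                           _worf_error(sub, session, config, rng.integers(2**31)))

        if "delta" in config.sweeps:
            for dlt in config.delta_grid:
                c2 = sample_spike_counts(session.truth, session.traj, dlt,
                                         seed=rng.integers(2**31))
                c2 = apply_speed_filter(c2, session.traj)
                if config.thinning:
                    c2 = thin_spikes(c2)
                f2 = estimate_place_fields(c2, session.traj, session.env)
                epochs = split_into_epochs(c2, config.T0, seed=rng.integers(2**31))
                if "wrf" in config.decoders:
                    record("delta", dlt, "fixed", "wrf",
                           decode_epochs_error(epochs, f2, session.env, session.traj))
                if "worf" in config.decoders:
                    n_src = int(c2.source_bins.max()) + 1
                    pos2 = bin_mean_positions(session.traj, dlt, c2.t0, n_src)
                    s2 = Session(session.env, session.truth, session.traj, c2,
                                 f2, pos2, dlt)
                    record("delta", dlt, "fixed", "worf",
                           _worf_error(epochs, s2, config, rng.integers(2**31)))

    raw = pd.DataFrame(rows)
    summary = _summarize(raw[raw["decoder"] != "na"],
                         ["sweep", "param", "variant", "decoder"], "median_error_cm")
    return ResultTable(raw, summary, config.n_runs)


@dataclass
class DetectionConfig:
    """Grid for the detection-power (replay-statistics) experiments."""

    rho_grid: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8, 1.0)
    removed_bins_grid: tuple[int, ...] = (0, 2, 4, 6, 8, 10)
    n_runs: int = 100
    base_seed: int = 0
    n_shuffle: int = 1000
    event_bins: int = 20
    delta: float = 0.02
    gain: float = 5.0
    n_cells: int = 50
    min_cells: int = 5  # floor for event-level cell subsampling

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be at least 2")


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def run_detection_experiment(config: DetectionConfig) -> ResultTable:
    """Replay detection power under cell removal and bin removal.

    A reference run session on a linear track defines the place fields;
    every run draws a fresh compressed traversal event and degrades it
    by (a) keeping a random fraction rho of cells or (b) zeroing a
    number of randomly chosen time bins, then runs the full shuffle
    pipeline and records |R|, Z and the significance call.
    """
    env = Environment("linear_track", 200.0, 10.0)
    base_rng = np.random.default_rng(config.base_seed)
    session = make_session(base_rng.integers(2**31), env=env,
                           n_cells=config.n_cells, duration_s=300.0,
                           delta=0.25, mean_speed=25.0)
    fields = session.place_fields
    path = np.array([5.0, 195.0])
    rows = []
    for run in range(config.n_runs):
        rng = np.random.default_rng(config.base_seed + 1 + run)
        ev = make_replay_event(
            session.truth, path, delta=config.delta, gain=config.gain,
            direction="forward", duration=config.event_bins * config.delta,
            seed=rng.integers(2**31),
        )
        logger.info("detection run %d/%d", run + 1, config.n_runs)

        def record(sweep, param, res):
            rows.append({
                "run": run, "sweep": sweep, "param": param,
                "abs_R": res.abs_R, "Z": res.Z,
                "significant": res.significant,
            })

        for rho in config.rho_grid:
            n_keep = max(_round_half_up(rho * config.n_cells), config.min_cells)
            keep = np.sort(rng.choice(config.n_cells, n_keep, replace=False))
            sub = ev.counts.select_cells(keep)
            dec = RFEventDecoder(fields.select_cells(keep), config.delta)
            res = score_event(sub, dec, n_shuffle=config.n_shuffle,
                              seed=rng.integers(2**31))
            record("rho", rho, res)
        dec_full = RFEventDecoder(fields, config.delta)
        for nb in config.removed_bins_grid:
            from .synthetic import remove_time_bins

            degraded = remove_time_bins(ev.counts, nb, seed=rng.integers(2**31))
            res = score_event(degraded, dec_full, n_shuffle=config.n_shuffle,
                              seed=rng.integers(2**31))
            record("removed_bins", nb, res)

    raw = pd.DataFrame(rows)
    pieces = []
    for value in ("abs_R", "Z", "significant"):
        s = _summarize(raw, ["sweep", "param"], value)
        s = s.rename(columns={"mean": f"{value}_mean", "sem": f"{value}_sem"})
        pieces.append(s.set_index(["sweep", "param"])[[f"{value}_mean", f"{value}_sem"]])
    summary = pd.concat(pieces, axis=1).reset_index()
    summary["n"] = config.n_runs
    return ResultTable(raw, summary, config.n_runs)


def write_result_table(prefix, table: ResultTable) -> None:
    """Write raw and summary tables as TSV (``<prefix>.raw.tsv`` etc.)."""
    table.raw.to_csv(f"{prefix}.raw.tsv", sep="\t", index=False)
    table.summary.to_csv(f"{prefix}.summary.tsv", sep="\t", index=False)


def read_result_table(prefix) -> ResultTable:
    raw = pd.read_csv(f"{prefix}.raw.tsv", sep="\t")
    summary = pd.read_csv(f"{prefix}.summary.tsv", sep="\t")
    n_runs = int(raw["run"].nunique())
    return ResultTable(raw, summary, n_runs)
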