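"""Synthetic place-cell data and sleep-like transformations.

This module is the generative twin of the decoding model: given
Gaussian-bump tuning curves ``lambda_c(S)`` and a simulated trajectory,
population spike counts are drawn as independent Poisson variates with
mean ``lambda_c(pos) * delta`` per cell and time bin.  On top of that it
implements the manipulations used to turn continuous run data into
sleep-like material: speed filtering, splitting into short epochs with
random time reversal, cell subsampling (fixed or per-epoch), spike
thinning, bin removal, flattening cells into non-place cells, and
compressed-timescale replay events at the 20-ms ripple timescale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import (
    Environment,
    EpochSet,
    SpikeMatrix,
    Trajectory,
    bin_mean_positions,
    bin_mean_speed,
)

__all__ = [
    "GroundTruthFields",
    "ReplayEvent",
    "make_population",
    "simulate_trajectory",
    "tuning_rates",
    "sample_spike_counts",
    "make_nonplace_cells",
    "apply_speed_filter",
    "split_into_epochs",
    "subsample_cells",
    "thin_spikes",
    "remove_time_bins",
    "make_replay_event",
]

SPEED_FILTER_CM_S = 15.0  # immobility cutoff applied to run data
TRACKING_HZ = 60.0  # position sampling rate of the simulated tracker


@dataclass
class GroundTruthFields:
    """True tuning curves of a simulated population.

    Each cell fires as an inhomogeneous Poisson process with rate
    ``baseline + (peak - baseline) * exp(-d(pos, center)^2 / (2 width^2))``
    where ``d`` is the environment's metric.  A non-place cell has a flat
    curve (peak == baseline).
    """

    env: Environment
    centers: np.ndarray  # (C,) or (C, 2) cm
    widths: np.ndarray  # (C,) cm
    peak_rates: np.ndarray  # (C,) Hz
    baseline: np.ndarray  # (C,) Hz
    is_place_cell: np.ndarray  # (C,) bool

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        self.peak_rates = np.asarray(self.peak_rates, dtype=float)
        self.baseline = np.broadcast_to(
            np.asarray(self.baseline, dtype=float), self.widths.shape
        ).copy()
        self.is_place_cell = np.asarray(self.is_place_cell, dtype=bool)
        if np.any(self.widths <= 0):
            raise ValueError("tuning widths must be positive")
        if np.any(self.peak_rates < 0) or np.any(self.baseline < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_cells(self) -> int:
        return len(self.widths)


def make_population(
    env: Environment,
    n_cells: int = 49,
    peak_rate_median: float = 10.0,
    peak_rate_sigma: float = 0.6,
    width_range: tuple[float, float] = (8.0, 15.0),
    baseline_median: float = 0.15,
    baseline_sigma: float = 1.0,
    n_nonplace: int = 0,
    seed: int | np.random.Generator = 0,
) -> GroundTruthFields:
    """Draw a heterogeneous population of Gaussian-bump place cells.

    Peak in-field rates are lognormal (median ``peak_rate_median`` Hz,
    log-SD ``peak_rate_sigma``) and out-of-field baselines are lognormal
    as well, reflecting the strongly skewed, lognormal-like firing-rate
    distribution of CA1 pyramidal cells: a population mixes sharply
    tuned, quiet cells with noisy, high-baseline ones.  Defaults give
    session-averaged rates around 1-1.5 Hz with a wide spread in a
    100 x 100 cm field.  Field centers are uniform over the environment;
    ``n_nonplace`` cells are made flat at a typical mean rate.
    """
    rng = np.random.default_rng(seed)
    if env.is_1d:
        centers = rng.uniform(0, env.extent, size=n_cells)
    else:
        centers = np.column_stack(
            [rng.uniform(0, env.extent[0], n_cells), rng.uniform(0, env.extent[1], n_cells)]
        )
    widths = rng.uniform(*width_range, size=n_cells)
    peaks = np.clip(peak_rate_median * rng.lognormal(0.0, peak_rate_sigma, n_cells),
                    2.0, 40.0)
    baseline = np.clip(baseline_median * rng.lognormal(0.0, baseline_sigma, n_cells),
                       0.01, 2.0)
    baseline = np.minimum(baseline, 0.8 * peaks)
    is_pc = np.ones(n_cells, dtype=bool)
    if n_nonplace > 0:
        flat = rng.choice(n_cells, size=n_nonplace, replace=False)
        # flat cells keep a plausible overall rate but no spatial modulation
        peaks[flat] = 1.0
        baseline[flat] = 1.0
        is_pc[flat] = False
    return GroundTruthFields(env, centers, widths, peaks, baseline, is_pc)


def _lognormal_speed(rng, n, mean_speed, sigma=0.3, ar=0.98):
    """AR(1)-correlated lognormal speed trace with mean ``mean_speed``."""
    z = np.empty(n)
    z[0] = rng.normal(0, sigma)
    eps = rng.normal(0, sigma * math.sqrt(1 - ar**2), size=n - 1)
    for i in range(1, n):
        z[i] = ar * z[i - 1] + eps[i - 1]
    return mean_speed * np.exp(z - sigma**2 / 2)


def simulate_trajectory(
    env: Environment,
    duration: float,
    mean_speed: float = 25.0,
    seed: int | np.random.Generator = 0,
    sample_hz: float = TRACKING_HZ,
) -> Trajectory:
    """Simulate foraging (open field) or lap running (tracks).

    Open field: a smooth random walk (correlated heading, lognormal
    speed) with reflecting walls.  Tracks: constant-direction laps at a
    slowly varying speed, reflected at the ends of a linear track and
    wrapped on a circular one.  Positions are sampled at ``sample_hz``
    (default 60 Hz, the usual video-tracking rate).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if mean_speed <= 0:
        raise ValueError("mean_speed must be positive")
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_hz
    n = int(round(duration * sample_hz)) + 1
    t = np.arange(n) * dt
    speed = _lognormal_speed(rng, n, mean_speed)

    if env.kind == "circular_track":
        pos = np.mod(np.concatenate([[0.0], np.cumsum(speed[:-1] * dt)]), env.extent)
        return Trajectory(t, pos, env=env)

    if env.kind == "linear_track":
        L = env.extent
        x = np.concatenate([[0.0], np.cumsum(speed[:-1] * dt)])
        # reflect: fold the unbounded coordinate into [0, L]
        m = np.mod(x, 2 * L)
        pos = np.where(m <= L, m, 2 * L - m)
        return Trajectory(t, pos, env=env)

    # open field: integrate heading with angular diffusion, reflect at walls
    w, h = env.extent
    pos = np.empty((n, 2))
    pos[0] = (rng.uniform(0.2 * w, 0.8 * w), rng.uniform(0.2 * h, 0.8 * h))
    theta = rng.uniform(0, 2 * np.pi)
    dtheta = rng.normal(0, 1.2 * math.sqrt(dt), size=n - 1)
    for i in range(1, n):
        theta += dtheta[i - 1]
        step = speed[i - 1] * dt
        x = pos[i - 1, 0] + step * math.cos(theta)
        y = pos[i - 1, 1] + step * math.sin(theta)
        if x < 0 or x > w:
            x = min(max(-x if x < 0 else 2 * w - x, 0), w)
            theta = math.pi - theta
        if y < 0 or y > h:
            y = min(max(-y if y < 0 else 2 * h - y, 0), h)
            theta = -theta
        pos[i] = (x, y)
    return Trajectory(t, pos, env=env)


def tuning_rates(fields: GroundTruthFields, pos: np.ndarray) -> np.ndarray:
    """True firing rate of every cell at each position: (C, n_pos) Hz."""
    pos = np.asarray(pos, dtype=float)
    env = fields.env
    if env.is_1d:
        d = env.distance(pos[None, :], fields.centers[:, None])
    else:
        diff = pos[None, :, :] - fields.centers[:, None, :]
        d = np.linalg.norm(diff, axis=-1)
    bump = np.exp(-(d**2) / (2 * fields.widths[:, None] ** 2))
    return fields.baseline[:, None] + (fields.peak_rates - fields.baseline)[:, None] * bump


def sample_spike_counts(
    fields: GroundTruthFields,
    traj: Trajectory,
    delta: float,
    seed: int | np.random.Generator = 0,
) -> SpikeMatrix:
    """Draw Poisson spike counts from the tuning curves along a trajectory.

    Bin k gets, for each cell c independently,
    ``count ~ Poisson(lambda_c(mean position in bin k) * delta)``.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    n_bins = int(math.floor(traj.duration / delta + 1e-12))
    if n_bins < 1:
        raise ValueError("trajectory shorter than one time bin")
    rng = np.random.default_rng(seed)
    pos = bin_mean_positions(traj, delta, traj.t[0], n_bins)
    lam = tuning_rates(fields, pos)
    counts = rng.poisson(lam * delta)
    return SpikeMatrix(counts, delta, t0=float(traj.t[0]))


def make_nonplace_cells(
    counts: SpikeMatrix,
    traj: Trajectory,
    cell_ids: np.ndarray,
    occupancy: np.ndarray,
    env: Environment,
    seed: int | np.random.Generator = 0,
) -> SpikeMatrix:
    """Flatten selected cells' spatial tuning while preserving their rate.

    Each selected cell's total spike count is redistributed over time
    bins by a multinomial draw whose per-bin probability is proportional
    to the spatial occupancy of the position the animal holds in that
    bin.  The resulting tuning curve (spikes at S / time at S) is flat in
    expectation and the cell's session-average firing rate is unchanged
    exactly.
    """
    cell_ids = np.asarray(cell_ids, dtype=int)
    if cell_ids.size == 0:
        return counts.copy()
    occupancy = np.asarray(occupancy, dtype=float)
    if not math.isclose(float(occupancy.sum()), 1.0, rel_tol=1e-6):
        raise ValueError("occupancy must sum to 1")
    rng = np.random.default_rng(seed)
    pos = bin_mean_positions(traj, counts.delta, counts.t0, counts.n_bins)
    sbin = env.position_to_bin(pos)
    w = occupancy[sbin]
    w = w / w.sum()
    out = counts.copy()
    rows = np.flatnonzero(np.isin(out.cell_ids, cell_ids))
    for r in rows:
        total = int(out.counts[r].sum())
        out.counts[r] = rng.multinomial(total, w)
    return out


def apply_speed_filter(
    counts: SpikeMatrix,
    traj: Trajectory,
    threshold: float = SPEED_FILTER_CM_S,
) -> SpikeMatrix:
    """Drop time bins whose mean running speed is below ``threshold``.

    Remaining bins are concatenated in original order; ``source_bins``
    keeps the map back to the original binning.
    """
    sp = bin_mean_speed(traj, counts.delta, counts.t0, counts.n_bins)
    keep = np.flatnonzero(sp >= threshold)
    if keep.size == 0:
        raise ValueError("no data above speed threshold")
    return counts.select_bins(keep)


def split_into_epochs(
    counts: SpikeMatrix,
    T0: int,
    reverse_prob: float = 0.5,
    shuffle_order: bool = True,
    seed: int | np.random.Generator = 0,
) -> EpochSet:
    """Evenly split a recording into epochs of ``T0`` bins.

    Each contiguous block is independently time-reversed with
    probability ``reverse_prob`` and the epoch order is optionally
    permuted.  A trailing partial block (when T mod T0 != 0) is dropped.
    """
    T = counts.n_bins
    if not (1 <= T0 <= T):
        raise ValueError("T0 must be in [1, n_bins]")
    rng = np.random.default_rng(seed)
    n_epochs = T // T0
    epochs: list[SpikeMatrix] = []
    flags: list[bool] = []
    for i in range(n_epochs):
        idx = np.arange(i * T0, (i + 1) * T0)
        rev = bool(rng.random() < reverse_prob)
        if rev:
            idx = idx[::-1]
        epochs.append(counts.select_bins(idx))
        flags.append(rev)
    if shuffle_order:
        order = rng.permutation(n_epochs)
        epochs = [epochs[i] for i in order]
        flags = [flags[i] for i in order]
    return EpochSet(epochs, T0=T0, reversed_flags=flags)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def subsample_cells(
    epochs: EpochSet,
    rho: float,
    per_epoch: bool = False,
    min_cells: int = 10,
    mode: str = "remove",
    seed: int | np.random.Generator = 0,
) -> EpochSet:
    """Keep only a random fraction ``rho`` of cells active.

    The active set has ``max(round(rho * C), min_cells)`` cells.  With
    ``per_epoch=False`` one subset is drawn and applied to every epoch;
    with ``per_epoch=True`` an independent subset is drawn per epoch,
    emulating distinct subpopulations participating in individual sleep
    episodes.  ``mode='remove'`` drops the inactive rows (receptive-field
    decoding restricts its likelihood to the surviving cells);
    ``mode='zero'`` zeroes them while keeping cell identity (the
    receptive-field-free decoder always sees the full matrix).
    """
    if not (0 < rho <= 1):
        raise ValueError("rho must be in (0, 1]")
    if mode not in ("remove", "zero"):
        raise ValueError("mode must be 'remove' or 'zero'")
    rng = np.random.default_rng(seed)
    C = epochs.epochs[0].n_cells
    n_active = min(max(_round_half_up(rho * C), min_cells), C)
    if C < min_cells:
        raise ValueError(f"population of {C} cells below the {min_cells}-cell floor")
    if rho >= 1.0 and not per_epoch:
        return EpochSet(
            [e.copy() for e in epochs.epochs],
            T0=epochs.T0,
            reversed_flags=list(epochs.reversed_flags),
            active_cells=[np.arange(C) for _ in epochs.epochs],
        )

    def _one_subset():
        return np.sort(rng.choice(C, size=n_active, replace=False))

    new_epochs: list[SpikeMatrix] = []
    active: list[np.ndarray] = []
    shared = None if per_epoch else _one_subset()
    for e in epochs.epochs:
        sel = _one_subset() if per_epoch else shared
        if mode == "remove":
            new_epochs.append(e.select_cells(sel))
        else:
            z = e.copy()
            mask = np.ones(C, dtype=bool)
            mask[sel] = False
            z.counts[mask] = 0
            new_epochs.append(z)
        active.append(sel.copy())
    return EpochSet(new_epochs, T0=epochs.T0,
                    reversed_flags=list(epochs.reversed_flags), active_cells=active)


def thin_spikes(
    counts: SpikeMatrix,
    seed: int | np.random.Generator = 0,
    mode: str = "clip",
    keep_prob: float = 0.5,
) -> SpikeMatrix:
    """Downsample so that no time bin holds more than one spike.

    ``mode='clip'`` maps any count >= 1 to 1.  ``mode='binomial'`` first
    thins each spike independently with probability ``keep_prob`` and
    then clips, which also lowers the overall rate the way sparse sleep
    firing does.
    """
    out = counts.copy()
    if mode == "clip":
        out.counts = np.minimum(out.counts, 1)
    elif mode == "binomial":
        rng = np.random.default_rng(seed)
        out.counts = np.minimum(rng.binomial(out.counts, keep_prob), 1)
    else:
        raise ValueError("mode must be 'clip' or 'binomial'")
    return out


def remove_time_bins(
    event: SpikeMatrix,
    n_bins: int,
    seed: int | np.random.Generator = 0,
) -> SpikeMatrix:
    """Zero all cells in ``n_bins`` randomly chosen time bins."""
    if not (0 <= n_bins <= event.n_bins):
        raise ValueError("n_bins must be in [0, event bins]")
    out = event.copy()
    if n_bins == 0:
        return out
    rng = np.random.default_rng(seed)
    drop = rng.choice(event.n_bins, size=n_bins, replace=False)
    out.counts[:, drop] = 0
    return out


@dataclass
class ReplayEvent:
    """A synthetic compressed-replay event plus its screening context."""

    counts: SpikeMatrix
    mua: np.ndarray  # population multi-unit counts per bin, event embedded
    onset_bin: int  # index of the event's first bin within the MUA trace
    direction: str
    path: np.ndarray  # positions traversed, one per event bin


def make_replay_event(
    fields: GroundTruthFields,
    path: np.ndarray,
    delta: float = 0.02,
    gain: float = 5.0,
    direction: str = "forward",
    duration: float = 0.2,
    baseline_s: float = 2.0,
    baseline_rate_hz: float = 50.0,
    seed: int | np.random.Generator = 0,
) -> ReplayEvent:
    """Generate a time-compressed traversal of ``path`` at the ripple timescale.

    The path is resampled to ``round(duration / delta)`` bins (a 200-ms
    event at 20 ms gives 10 bins); per bin each cell fires
    ``Poisson(gain * lambda_c(path_k) * delta)``.  ``direction='reverse'``
    flips the path.  The returned MUA trace embeds the event's population
    counts in a Poisson baseline so candidate-event detectors can be
    exercised end to end.
    """
    path = np.asarray(path, dtype=float)
    if path.ndim == 0 or len(path) == 0:
        raise ValueError("path must be non-empty")
    if len(np.atleast_1d(path)) < 2:
        raise ValueError("path needs at least 2 positions")
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    rng = np.random.default_rng(seed)
    n_bins = int(round(duration / delta))
    if n_bins < 1:
        raise ValueError("duration shorter than one bin")
    s = np.linspace(0, 1, n_bins)
    u = np.linspace(0, 1, len(path))
    if path.ndim == 1:
        rpath = np.interp(s, u, path)
    else:
        rpath = np.column_stack([np.interp(s, u, path[:, d]) for d in range(path.shape[1])])
    if direction == "reverse":
        rpath = rpath[::-1].copy()
    lam = gain * tuning_rates(fields, rpath)
    counts = rng.poisson(lam * delta)
    event = SpikeMatrix(counts, delta)

    n_base = int(round(baseline_s / delta))
    mua = rng.poisson(baseline_rate_hz * delta, size=n_base).astype(float)
    onset = n_base // 2
    mua[onset : onset + n_bins] += counts.sum(axis=0)
    return ReplayEvent(event, mua, onset, direction, rpath)
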