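"""Core domain containers shared across the decoding pipeline.

The package works with four basic objects: an :class:`Environment`
(the spatial domain the animal moves in), a :class:`Trajectory`
(time-stamped positions with derived running speed), a
:class:`SpikeMatrix` (cells x time-bins non-negative spike counts at a
fixed bin width ``delta``) and an :class:`EpochSet` (a collection of
short spike-count segments emulating the fragmented structure of
sleep data).

Conventions: bin indices are 0-based, time bins are half-open
``[t0 + k*delta, t0 + (k+1)*delta)``, and the position attributed to a
time bin is the mean trajectory position of the samples falling inside
it.  Every ``SpikeMatrix`` carries ``source_bins``, the indices of its
columns in the original (unfiltered, unsplit) binning, so that
downstream transforms (speed filtering, epoch splitting, reversal)
remain alignable with ground-truth positions for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Environment",
    "Trajectory",
    "SpikeMatrix",
    "EpochSet",
    "bin_mean_positions",
    "bin_mean_speed",
]

_ENV_KINDS = ("linear_track", "circular_track", "open_field")


@dataclass(frozen=True)
class Environment:
    """Spatial domain: a 1-D track (linear or circular) or a 2-D open field.

    Parameters
    ----------
    kind
        One of ``linear_track``, ``circular_track``, ``open_field``.
    extent
        Track length in cm (1-D) or ``(width, height)`` in cm (open field).
    spatial_bin_cm
        Side of the spatial discretization bin in cm.
    """

    kind: str
    extent: float | tuple[float, float]
    spatial_bin_cm: float

    def __post_init__(self):
        if self.kind not in _ENV_KINDS:
            raise ValueError(f"unknown environment kind {self.kind!r}")
        ext = np.atleast_1d(np.asarray(self.extent, dtype=float))
        if np.any(ext <= 0):
            raise ValueError("environment extent must be positive")
        if self.kind == "open_field":
            if ext.size == 1:
                object.__setattr__(self, "extent", (float(ext[0]), float(ext[0])))
            else:
                object.__setattr__(self, "extent", (float(ext[0]), float(ext[1])))
        else:
            object.__setattr__(self, "extent", float(ext[0]))
        if self.spatial_bin_cm <= 0 or self.spatial_bin_cm > float(np.max(ext)):
            raise ValueError("spatial_bin_cm must be in (0, extent]")

    @property
    def is_1d(self) -> bool:
        return self.kind in ("linear_track", "circular_track")

    @property
    def n_spatial_bins(self) -> int:
        if self.is_1d:
            return int(np.ceil(self.extent / self.spatial_bin_cm))
        nx = int(np.ceil(self.extent[0] / self.spatial_bin_cm))
        ny = int(np.ceil(self.extent[1] / self.spatial_bin_cm))
        return nx * ny

    @property
    def grid_shape(self) -> tuple[int, int] | None:
        """(nx, ny) for an open field, None for tracks."""
        if self.is_1d:
            return None
        nx = int(np.ceil(self.extent[0] / self.spatial_bin_cm))
        ny = int(np.ceil(self.extent[1] / self.spatial_bin_cm))
        return nx, ny

    @property
    def bin_centers(self) -> np.ndarray:
        """Centers of the spatial bins: shape (n,) for 1-D, (n, 2) for 2-D."""
        h = self.spatial_bin_cm
        if self.is_1d:
            return (np.arange(self.n_spatial_bins) + 0.5) * h
        nx, ny = self.grid_shape
        cx = (np.arange(nx) + 0.5) * h
        cy = (np.arange(ny) + 0.5) * h
        gx, gy = np.meshgrid(cx, cy, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel()])

    def position_to_bin(self, pos: np.ndarray) -> np.ndarray:
        """Flattened spatial-bin index for each position."""
        pos = np.asarray(pos, dtype=float)
        h = self.spatial_bin_cm
        if self.is_1d:
            if self.kind == "circular_track":
                pos = np.mod(pos, self.extent)
            idx = np.clip((pos / h).astype(int), 0, self.n_spatial_bins - 1)
            return idx
        nx, ny = self.grid_shape
        ix = np.clip((pos[..., 0] / h).astype(int), 0, nx - 1)
        iy = np.clip((pos[..., 1] / h).astype(int), 0, ny - 1)
        return ix * ny + iy

    def distance(self, a: np.ndarray, b: np.ndarray) -> np.ndarray:
        """Position distance in cm: linear, wrap-around, or Euclidean."""
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if self.kind == "linear_track":
            return np.abs(a - b)
        if self.kind == "circular_track":
            d = np.abs(np.mod(a, self.extent) - np.mod(b, self.extent))
            return np.minimum(d, self.extent - d)
        return np.linalg.norm(a - b, axis=-1)

    def contains(self, pos: np.ndarray) -> np.ndarray:
        pos = np.asarray(pos, dtype=float)
        if self.is_1d:
            if self.kind == "circular_track":
                return np.ones(pos.shape, dtype=bool)
            return (pos >= 0) & (pos <= self.extent)
        return (
            (pos[..., 0] >= 0)
            & (pos[..., 0] <= self.extent[0])
            & (pos[..., 1] >= 0)
            & (pos[..., 1] <= self.extent[1])
        )


@dataclass
class Trajectory:
    """Time-stamped positions sampled at a uniform rate, with derived speed.

    ``pos`` has shape (n,) on tracks (arc-length/linear coordinate in cm)
    or (n, 2) in an open field.  Speed is a centered finite difference;
    on circular tracks displacement is computed modulo the track length.
    """

    t: np.ndarray
    pos: np.ndarray
    env: Environment | None = None
    speed: np.ndarray = field(init=False)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.pos = np.asarray(self.pos, dtype=float)
        if self.t.ndim != 1 or len(self.t) < 2:
            raise ValueError("trajectory needs at least two samples")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise ValueError("trajectory times must be strictly increasing")
        if self.env is not None and not np.all(self.env.contains(self.pos)):
            raise ValueError("trajectory positions outside environment extent")
        disp = np.diff(self.pos, axis=0)
        if self.env is not None and self.env.kind == "circular_track":
            L = self.env.extent
            disp = (disp + L / 2) % L - L / 2
        step = np.linalg.norm(np.atleast_2d(disp.T).T, axis=-1) if disp.ndim > 1 else np.abs(disp)
        inst = step / dt
        # centered: average of adjacent interval speeds, endpoints copied
        sp = np.empty(len(self.t))
        sp[1:-1] = 0.5 * (inst[:-1] + inst[1:])
        sp[0], sp[-1] = inst[0], inst[-1]
        self.speed = sp

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0])


def _bin_index(t: np.ndarray, t0: float, delta: float) -> np.ndarray:
    return np.floor((t - t0) / delta + 1e-12).astype(int)


def bin_mean_positions(traj: Trajectory, delta: float, t0: float, n_bins: int) -> np.ndarray:
    """Mean trajectory position inside each time bin.

    Bins with no trajectory sample inherit the nearest sampled bin's
    position (relevant only at the very edges of a recording).
    """
    k = _bin_index(traj.t, t0, delta)
    ok = (k >= 0) & (k < n_bins)
    k = k[ok]
    pos = traj.pos[ok]
    counts = np.bincount(k, minlength=n_bins).astype(float)
    if pos.ndim == 1:
        sums = np.bincount(k, weights=pos, minlength=n_bins)
        out = np.divide(sums, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    else:
        out = np.full((n_bins, pos.shape[1]), np.nan)
        for d in range(pos.shape[1]):
            s = np.bincount(k, weights=pos[:, d], minlength=n_bins)
            out[:, d] = np.divide(s, counts, out=np.full(n_bins, np.nan), where=counts > 0)
    if np.any(counts == 0):
        filled = np.flatnonzero(counts > 0)
        if filled.size == 0:
            raise ValueError("trajectory does not overlap the binning")
        empty = np.flatnonzero(counts == 0)
        nearest = filled[np.searchsorted(filled, empty).clip(0, filled.size - 1)]
        out[empty] = out[nearest]
    return out


def bin_mean_speed(traj: Trajectory, delta: float, t0: float, n_bins: int) -> np.ndarray:
    """Mean running speed inside each time bin (cm/s); empty bins -> 0."""
    k = _bin_index(traj.t, t0, delta)
    ok = (k >= 0) & (k < n_bins)
    k = k[ok]
    counts = np.bincount(k, minlength=n_bins).astype(float)
    sums = np.bincount(k, weights=traj.speed[ok], minlength=n_bins)
    return np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)


@dataclass
class SpikeMatrix:
    """Cells x time-bins spike counts at bin width ``delta`` seconds."""

    counts: np.ndarray
    delta: float
    t0: float = 0.0
    cell_ids: np.ndarray | None = None
    source_bins: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (cells x bins)")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("spike counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.cell_ids is None:
            self.cell_ids = np.arange(self.counts.shape[0])
        else:
            self.cell_ids = np.asarray(self.cell_ids)
            if len(self.cell_ids) != self.counts.shape[0]:
                raise ValueError("cell_ids length mismatch")
        if self.source_bins is None:
            self.source_bins = np.arange(self.counts.shape[1])
        else:
            self.source_bins = np.asarray(self.source_bins, dtype=int)
            if len(self.source_bins) != self.counts.shape[1]:
                raise ValueError("source_bins length mismatch")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]

    @property
    def total_spikes(self) -> int:
        return int(self.counts.sum())

    def select_bins(self, idx: np.ndarray) -> "SpikeMatrix":
        idx = np.asarray(idx)
        return SpikeMatrix(
            self.counts[:, idx],
            self.delta,
            self.t0,
            cell_ids=self.cell_ids.copy(),
            source_bins=self.source_bins[idx],
        )

    def select_cells(self, idx: np.ndarray) -> "SpikeMatrix":
        idx = np.asarray(idx)
        return SpikeMatrix(
            self.counts[idx],
            self.delta,
            self.t0,
            cell_ids=self.cell_ids[idx],
            source_bins=self.source_bins.copy(),
        )

    def copy(self) -> "SpikeMatrix":
        return SpikeMatrix(
            self.counts.copy(),
            self.delta,
            self.t0,
            cell_ids=self.cell_ids.copy(),
            source_bins=self.source_bins.copy(),
        )


@dataclass
class EpochSet:
    """Sleep-like collection of short spike-count segments.

    ``reversed_flags[i]`` records whether epoch i was time-reversed when
    it was cut out of the parent recording; ``active_cells[i]`` records
    the per-epoch active subpopulation (None means all cells).  Both are
    ground-truth metadata for evaluation, never inputs to decoding.
    """

    epochs: list[SpikeMatrix]
    T0: int
    reversed_flags: list[bool] = field(default_factory=list)
    active_cells: list[np.ndarray | None] = field(default_factory=list)

    def __post_init__(self):
        if not self.reversed_flags:
            self.reversed_flags = [False] * len(self.epochs)
        if not self.active_cells:
            self.active_cells = [None] * len(self.epochs)
        if not (len(self.epochs) == len(self.reversed_flags) == len(self.active_cells)):
            raise ValueError("epoch metadata length mismatch")

    def __len__(self) -> int:
        return len(self.epochs)

    def __iter__(self):
        return iter(self.epochs)

    @property
    def delta(self) -> float:
        return self.epochs[0].delta

    def concatenated(self) -> SpikeMatrix:
        """All epochs glued back together in their current order."""
        counts = np.concatenate([e.counts for e in self.epochs], axis=1)
        src = np.concatenate([e.source_bins for e in self.epochs])
        return SpikeMatrix(counts, self.delta, self.epochs[0].t0,
                           cell_ids=self.epochs[0].cell_ids.copy(), source_bins=src)
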