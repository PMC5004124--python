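"""Occupancy-normalized place fields and spatial information rates.

The supervised encoding stage: firing-rate maps
``lambda_c(S) = spikes of cell c at S / time spent at S`` over the
environment's spatial bins, lightly smoothed with a small Gaussian
template (5x1 in 1-D, 3x3 in 2-D, SD half a bin).  Smoothing is applied
to the spike-count and occupancy-time maps separately with a
mass-preserving kernel (each source bin's weight is renormalized over
the visited bins it can reach), so total spike count and total time are
conserved and the rate map never divides by zero on visited bins.
Never-visited bins are masked, not set to zero, and are excluded from
the decoding support.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import Environment, SpikeMatrix, Trajectory, bin_mean_positions

__all__ = [
    "OccupancyMap",
    "PlaceFieldMap",
    "estimate_place_fields",
    "spatial_information_rate",
    "partition_by_information",
]

KERNEL_SD_BINS = 0.5  # Gaussian template SD, in units of spatial bins


@dataclass
class OccupancyMap:
    """Probability of finding the animal in each spatial bin."""

    p: np.ndarray  # (n_spatial_bins,), sums to 1 over visited bins
    time_s: np.ndarray  # occupancy time per bin, seconds
    env: Environment

    def __post_init__(self):
        if np.any(self.p < 0):
            raise ValueError("occupancy probabilities must be non-negative")
        if not np.isclose(self.p.sum(), 1.0):
            raise ValueError("occupancy must sum to 1")


@dataclass
class PlaceFieldMap:
    """Per-cell firing-rate maps over the spatial bins."""

    rates: np.ndarray  # (C, n_spatial_bins) Hz; masked bins hold NaN
    occupancy: OccupancyMap
    mask: np.ndarray  # (n_spatial_bins,) bool, True = visited
    env: Environment
    cell_ids: np.ndarray
    smoothed: bool = True

    @property
    def n_cells(self) -> int:
        return self.rates.shape[0]

    @property
    def support_positions(self) -> np.ndarray:
        """Centers of the visited spatial bins (the decoding support)."""
        return self.env.bin_centers[self.mask]

    def support_rates(self) -> np.ndarray:
        """(C, n_visited) rate matrix restricted to visited bins."""
        return self.rates[:, self.mask]

    def select_cells(self, idx: np.ndarray) -> "PlaceFieldMap":
        idx = np.asarray(idx)
        return PlaceFieldMap(self.rates[idx], self.occupancy, self.mask,
                             self.env, self.cell_ids[idx], self.smoothed)


def _smoothing_matrix(env: Environment, visited: np.ndarray) -> np.ndarray:
    """Mass-preserving Gaussian smoothing operator over visited bins.

    K[target, source]: each visited source bin spreads its mass over the
    visited bins within the template footprint, renormalized per source
    so column sums are exactly 1 (nothing leaks off edges or into
    unvisited bins).  On circular tracks the template wraps.
    """
    n = env.n_spatial_bins
    sd = KERNEL_SD_BINS
    if env.is_1d:
        offsets = np.arange(-2, 3)  # 5x1 template
        w = np.exp(-(offsets.astype(float) ** 2) / (2 * sd**2))
        K = np.zeros((n, n))
        for s in np.flatnonzero(visited):
            tgt = s + offsets
            ww = w
            if env.kind == "circular_track":
                tgt = np.mod(tgt, n)
            else:
                inside = (tgt >= 0) & (tgt < n)
                tgt, ww = tgt[inside], w[inside]
            ok = visited[tgt]
            tw = ww[ok]
            np.add.at(K[:, s], tgt[ok], tw / tw.sum())
        return K
    nx, ny = env.grid_shape
    off = [(dx, dy) for dx in (-1, 0, 1) for dy in (-1, 0, 1)]  # 3x3 template
    w = np.array([np.exp(-(dx**2 + dy**2) / (2 * sd**2)) for dx, dy in off])
    K = np.zeros((n, n))
    vis_idx = np.flatnonzero(visited)
    for s in vis_idx:
        sx, sy = divmod(s, ny)
        tgts, tws = [], []
        for (dx, dy), wk in zip(off, w):
            tx, ty = sx + dx, sy + dy
            if 0 <= tx < nx and 0 <= ty < ny:
                t = tx * ny + ty
                if visited[t]:
                    tgts.append(t)
                    tws.append(wk)
        tws = np.asarray(tws)
        K[np.asarray(tgts), s] = tws / tws.sum()
    return K


def estimate_place_fields(
    counts: SpikeMatrix,
    traj: Trajectory,
    env: Environment,
    smooth: bool = True,
) -> PlaceFieldMap:
    """Estimate occupancy-normalized rate maps from binned spikes.

    The position of each time bin is the mean trajectory position within
    it (looked up through ``source_bins``, so speed-filtered input maps
    correctly).  Occupancy uses the same bins that contribute spikes.
    """
    n_src = int(counts.source_bins.max()) + 1
    pos_all = bin_mean_positions(traj, counts.delta, counts.t0, n_src)
    pos = pos_all[counts.source_bins]
    sbin = env.position_to_bin(pos)
    n = env.n_spatial_bins

    time_s = np.bincount(sbin, minlength=n).astype(float) * counts.delta
    if time_s.sum() <= 0:
        raise ValueError("zero total occupancy")
    spikes = np.zeros((counts.n_cells, n))
    np.add.at(spikes.T, sbin, counts.counts.T.astype(float))
    visited = time_s > 0

    if smooth:
        K = _smoothing_matrix(env, visited)
        time_sm = K @ time_s
        spikes_sm = spikes @ K.T
    else:
        time_sm, spikes_sm = time_s, spikes

    rates = np.full((counts.n_cells, n), np.nan)
    rates[:, visited] = spikes_sm[:, visited] / time_sm[visited]
    occ = OccupancyMap(p=time_sm / time_sm.sum(), time_s=time_sm, env=env)
    return PlaceFieldMap(rates, occ, visited, env, counts.cell_ids.copy(), smoothed=smooth)


def spatial_information_rate(
    field: PlaceFieldMap, cell: int | None = None
) -> tuple[np.ndarray, np.ndarray] | tuple[float, float]:
    """Spatial information carried by each cell's rate map.

    ``I_c = sum_S p(S) lambda_c(S) log2(lambda_c(S) / mean rate)`` in
    bits/s, with the convention 0*log(0) = 0, and the normalized rate
    ``I_c / mean rate`` in bits/spike.  A silent cell gets 0 with a
    warning.
    """
    p = field.occupancy.p[field.mask]
    p = p / p.sum()
    lam = field.support_rates()
    lbar = lam @ p
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = lam / lbar[:, None]
        term = np.where(lam > 0, lam * np.log2(np.where(ratio > 0, ratio, 1.0)), 0.0)
    I = term @ p
    silent = lbar <= 0
    if np.any(silent):
        warnings.warn("cell(s) with zero mean rate: information set to 0")
        I = np.where(silent, 0.0, I)
    with np.errstate(divide="ignore", invalid="ignore"):
        I_norm = np.where(silent, 0.0, I / np.where(lbar > 0, lbar, 1.0))
    if cell is not None:
        return float(I[cell]), float(I_norm[cell])
    return I, I_norm


def partition_by_information(field: PlaceFieldMap) -> tuple[np.ndarray, np.ndarray]:
    """Median split of the cells by normalized information rate.

    Returns (high_ids, low_ids) as row indices into the field map.  The
    low group receives the extra cell when C is odd; ties at the median
    are broken by cell index (stable sort), so the split is
    deterministic.
    """
    if field.n_cells < 2:
        raise ValueError("need at least 2 cells to partition")
    _, I_norm = spatial_information_rate(field)
    order = np.argsort(I_norm, kind="stable")  # ascending, index-stable
    n_low = int(np.ceil(field.n_cells / 2))
    low = np.sort(order[:n_low])
    high = np.sort(order[n_low:])
    return high, low
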