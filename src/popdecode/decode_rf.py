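"""Receptive-field-based Bayesian decoding of position from spike counts.

Given place fields ``lambda_c(S)`` and a binned spike-count matrix, the
population likelihood is an independent-Poisson model per time bin:

    log p(y_t | S) = sum_c [ y_tc log(lambda_c(S) delta)
                             - lambda_c(S) delta - log(y_tc!) ]

The posterior ``p(S_t | y)`` is the row-normalized likelihood under a
uniform spatial prior, or a forward (filtering) recursion under a
Markov transition prior.  All computation is in the log domain with
per-row max subtraction.  A small rate floor (0.01 Hz by default) keeps
finite-sample empty field bins from producing -inf log-likelihoods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .core import Environment, SpikeMatrix, EpochSet, Trajectory, bin_mean_positions
from .placefields import PlaceFieldMap

__all__ = [
    "PosteriorMatrix",
    "DecodedTrajectory",
    "poisson_loglik",
    "decode_posterior",
    "map_path",
    "median_decoding_error",
    "decode_epochs_error",
]

RATE_FLOOR_HZ = 0.01


@dataclass
class PosteriorMatrix:
    """Time-bins x support posterior probabilities (rows sum to 1)."""

    probs: np.ndarray  # (T, n_support)
    support_positions: np.ndarray  # (n_support,) cm or (n_support, 2)
    support_kind: str = "spatial"  # "spatial" bins or latent "state"s

    def __post_init__(self):
        if np.any(self.probs < 0):
            raise ValueError("posterior probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("posterior rows must sum to 1")

    @property
    def n_bins(self) -> int:
        return self.probs.shape[0]

    @property
    def n_support(self) -> int:
        return self.probs.shape[1]


@dataclass
class DecodedTrajectory:
    """MAP path through the support with per-bin posterior mass."""

    map_index: np.ndarray  # support index per time bin
    map_prob: np.ndarray  # posterior mass at the MAP per bin
    avg_map_score: float  # mean of map_prob


def poisson_loglik(
    y: np.ndarray,
    rates: np.ndarray,
    delta: float,
    rate_floor: float = 0.0,
) -> np.ndarray:
    """Poisson population log-likelihood per support bin.

    Parameters
    ----------
    y
        Spike counts, shape (C,) for one time bin or (T, C).
    rates
        Rate matrix (C, n_support) in Hz.
    delta
        Bin width in seconds.
    rate_floor
        Added to every rate before use; 0 keeps the likelihood exact
        (a zero rate with a nonzero count then gives -inf).

    Returns
    -------
    (n_support,) or (T, n_support) log-likelihoods including the
    -log(y!) term.
    """
    y = np.asarray(y)
    if np.any(y < 0):
        raise ValueError("negative spike counts")
    rates = np.asarray(rates, dtype=float) + rate_floor
    mu = rates * delta  # (C, S)
    single = y.ndim == 1
    Y = np.atleast_2d(y).astype(float)
    zero = mu == 0
    with np.errstate(divide="ignore"):
        logmu = np.where(zero, 0.0, np.log(mu))  # 0*log0 handled below
    ll = Y @ logmu - mu.sum(axis=0) - gammaln(Y + 1).sum(axis=1)[:, None]
    if np.any(zero):
        # a nonzero count against a zero rate has zero likelihood
        impossible = (Y > 0).astype(float) @ zero.astype(float) > 0
        ll = np.where(impossible, -np.inf, ll)
    return ll[0] if single else ll


def decode_posterior(
    counts: SpikeMatrix,
    fields: PlaceFieldMap,
    prior: str = "uniform",
    transition: np.ndarray | None = None,
    rate_floor: float = RATE_FLOOR_HZ,
) -> PosteriorMatrix:
    """Posterior over visited spatial bins for every time bin.

    ``prior='uniform'``: each bin decoded independently (no temporal
    prior).  ``prior='markov'``: forward filtering
    ``p(S_t | y_{1:t})`` with the supplied transition matrix over the
    support bins.
    """
    id_to_row = {cid: r for r, cid in enumerate(fields.cell_ids)}
    try:
        rows = np.array([id_to_row[c] for c in counts.cell_ids])
    except KeyError as e:
        raise ValueError(f"cell {e} of the spike matrix has no place field") from None
    lam = fields.support_rates()[rows]  # (C_active, n_support)
    ll = poisson_loglik(counts.counts.T, lam, counts.delta, rate_floor=rate_floor)
    ll = np.atleast_2d(ll)

    if prior == "uniform":
        probs = _normalize_rows(ll)
    elif prior == "markov":
        if transition is None:
            raise ValueError("markov prior requires a transition matrix")
        probs = _forward_filter(ll, transition)
    else:
        raise ValueError("prior must be 'uniform' or 'markov'")
    return PosteriorMatrix(probs, fields.support_positions, support_kind="spatial")


def _normalize_rows(ll: np.ndarray) -> np.ndarray:
    mx = ll.max(axis=1, keepdims=True)
    bad = ~np.isfinite(mx[:, 0])
    if np.any(bad):
        warnings.warn("time bin(s) with all -inf likelihood: uniform posterior used")
        ll = ll.copy()
        ll[bad] = 0.0
        mx = ll.max(axis=1, keepdims=True)
    w = np.exp(ll - mx)
    return w / w.sum(axis=1, keepdims=True)


def _forward_filter(ll: np.ndarray, P: np.ndarray) -> np.ndarray:
    T, S = ll.shape
    if P.shape != (S, S):
        raise ValueError("transition matrix does not match the support")
    probs = np.empty((T, S))
    lik = np.exp(ll - ll.max(axis=1, keepdims=True))
    alpha = lik[0] / S
    alpha = alpha / alpha.sum()
    probs[0] = alpha
    for t in range(1, T):
        alpha = lik[t] * (P.T @ alpha)
        s = alpha.sum()
        if s == 0:
            alpha = np.full(S, 1.0 / S)
        else:
            alpha = alpha / s
        probs[t] = alpha
    return probs


def map_path(post: PosteriorMatrix) -> DecodedTrajectory:
    """MAP support index per bin; ties broken toward the lowest index."""
    idx = post.probs.argmax(axis=1)
    mp = post.probs[np.arange(post.n_bins), idx]
    return DecodedTrajectory(idx, mp, float(mp.mean()))


def median_decoding_error(
    post: PosteriorMatrix,
    true_pos: np.ndarray,
    env: Environment,
) -> float:
    """Median distance (cm) between the MAP position and the truth."""
    if post.n_bins == 0:
        raise ValueError("empty posterior")
    true_pos = np.asarray(true_pos, dtype=float)
    if len(true_pos) != post.n_bins:
        raise ValueError("true positions do not match the posterior length")
    dec = map_path(post)
    est = post.support_positions[dec.map_index]
    return float(np.median(env.distance(est, true_pos)))


def decode_epochs_error(
    epochs: EpochSet,
    fields: PlaceFieldMap,
    env: Environment,
    traj: Trajectory,
    prior: str = "uniform",
) -> float:
    """Median decoding error across all epoch bins (uniform prior default).

    The ground-truth position of each epoch bin is recovered through its
    ``source_bins`` back-reference into the original recording.
    """
    first = epochs.epochs[0]
    n_src = max(int(e.source_bins.max()) for e in epochs.epochs) + 1
    pos_all = bin_mean_positions(traj, first.delta, first.t0, n_src)
    errs = []
    for e in epochs.epochs:
        post = decode_posterior(e, fields, prior=prior)
        dec = map_path(post)
        est = post.support_positions[dec.map_index]
        errs.append(env.distance(est, pos_all[e.source_bins]))
    return float(np.median(np.concatenate(errs)))
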