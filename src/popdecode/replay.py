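"""Candidate-event screening and replay significance testing.

A candidate ripple event is screened from the multi-unit activity (MUA)
trace (and optionally the ripple-band power) at mean + 3 SD, with a
minimum active-cell criterion of max(6, 10% of the population).  Each
event's posterior (from either decoder) is summarized by the weighted
correlation R between time-bin index and decoded position, compared
against a null built from 1000 joint time-bin + cell-identity shuffles
of the spike-count matrix, and classified significant by three criteria:
|R| > 0.5, at least five 20-ms bins (100 ms) with an above-chance MAP
probability score, and Z > 1.65 (or Monte-Carlo p < 0.05 when the
shuffle null fails a Shapiro-Wilk normality test).

The Z-score is computed on |R| so forward and reverse events are
treated symmetrically; the signed R is kept for the direction call.

``weighted_correlation`` uses exactly rounded summation (math.fsum)
with a reversal-symmetric (centered) time index, which makes the
identity R(time-reversed event) = -R(event) hold bit-exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import SpikeMatrix
from .decode_rf import PosteriorMatrix, map_path, poisson_loglik, _normalize_rows
from .placefields import PlaceFieldMap

__all__ = [
    "CandidateEvent",
    "ShuffleNull",
    "ReplayResult",
    "RFEventDecoder",
    "StateEventDecoder",
    "detect_candidate_events",
    "weighted_correlation",
    "weighted_correlation_batch",
    "shuffle_null",
    "zscore_and_pvalue",
    "classify_significance",
    "score_event",
    "compare_epoch_populations",
    "min_event_duration_s",
]

MIN_EVENT_BINS = 5  # replay length criterion: shorter events are not scored
R_THRESHOLD = 0.5  # replay strength criterion on |R|
Z_THRESHOLD = 1.65  # replay Z criterion, one-sided 5% under a normal null
MUA_SD_THRESHOLD = 3.0
N_SHUFFLE_DEFAULT = 1000


def min_event_duration_s(delta: float) -> float:
    """Shortest scorable event in seconds (5 bins; 100 ms at 20-ms bins)."""
    return MIN_EVENT_BINS * delta


@dataclass
class CandidateEvent:
    """A screened putative replay event."""

    interval_s: tuple[float, float]
    counts: SpikeMatrix
    active_cell_fraction: float
    T0: int


@dataclass
class ShuffleNull:
    """Null distribution of R from joint temporal + cell shuffles."""

    r_shuffle: np.ndarray
    kinds: tuple[str, ...]
    normal: bool
    normality_p: float
    normality_test: str

    @property
    def n(self) -> int:
        return len(self.r_shuffle)


@dataclass
class ReplayResult:
    """Per-event replay statistics and three-criteria flags."""

    R: float
    Z: float
    p: float
    p_method: str  # "normal" or "monte_carlo"
    avg_map_score: float
    n_bins: int
    n_support_bins: int
    flags: dict = field(default_factory=dict)
    direction: str = "forward"
    null: ShuffleNull | None = None

    @property
    def abs_R(self) -> float:
        return abs(self.R)

    @property
    def significant(self) -> bool:
        return bool(self.flags.get("significant", False))


# ---------------------------------------------------------------------------
# candidate screening
# ---------------------------------------------------------------------------

def detect_candidate_events(
    mua: np.ndarray,
    ripple_power: np.ndarray | None,
    cell_activity: SpikeMatrix,
    n_sd: float = MUA_SD_THRESHOLD,
    smooth_sd_bins: float = 1.0,
    min_active_fraction: float = 0.10,
    min_active_floor: int = 6,
) -> tuple[list[CandidateEvent], dict]:
    """Screen candidate events from MUA (and optional ripple power).

    Intervals where the smoothed MUA exceeds mean + ``n_sd`` SD (and the
    ripple power does too, when provided) are expanded outwards to the
    nearest sub-mean crossings.  Events activating fewer than
    ``max(min_active_floor, min_active_fraction * C)`` cells, or with an
    active-cell fraction below ``min_active_fraction``, are dropped.
    Returns the retained events and screening counts.
    """
    mua = np.asarray(mua, dtype=float)
    if mua.std() == 0:
        warnings.warn("flat MUA trace: no events detectable")
        return [], {"n_total": 0, "n_retained": 0}
    from scipy.ndimage import gaussian_filter1d

    sm = gaussian_filter1d(mua, smooth_sd_bins)
    mean, sd = sm.mean(), sm.std()
    hot = sm > mean + n_sd * sd
    if ripple_power is not None:
        rp = gaussian_filter1d(np.asarray(ripple_power, dtype=float), smooth_sd_bins)
        hot &= rp > rp.mean() + n_sd * rp.std()
    above_mean = sm > mean

    C = cell_activity.n_cells
    delta = cell_activity.delta
    min_active = max(min_active_floor, int(math.ceil(min_active_fraction * C)))

    events: list[CandidateEvent] = []
    n_total = 0
    i = 0
    n = len(sm)
    while i < n:
        if not hot[i]:
            i += 1
            continue
        # expand to nearest sub-mean crossings
        a = i
        while a > 0 and above_mean[a - 1]:
            a -= 1
        b = i
        while b < n - 1 and above_mean[b + 1]:
            b += 1
        n_total += 1
        i = b + 1
        seg = cell_activity.select_bins(np.arange(a, b + 1))
        n_active = int((seg.counts.sum(axis=1) > 0).sum())
        rho = n_active / C
        if n_active < min_active or rho < min_active_fraction:
            continue
        t_a = cell_activity.t0 + a * delta
        events.append(
            CandidateEvent((t_a, t_a + seg.n_bins * delta), seg, rho, seg.n_bins)
        )
    return events, {"n_total": n_total, "n_retained": len(events)}


# ---------------------------------------------------------------------------
# weighted correlation
# ---------------------------------------------------------------------------

def weighted_correlation(post: PosteriorMatrix | np.ndarray, x: np.ndarray | None = None) -> float:
    """Weighted Pearson correlation between time-bin index and position.

    Weights are the posterior probabilities; the time variable is the
    centered bin index and ``x`` defaults to the support column index
    (pass mapped state positions for a state-space posterior).  Returns
    NaN when either weighted variance vanishes (single-bin events).

    Sums use math.fsum (exactly rounded), so the statistic is invariant
    to summation order and exactly antisymmetric under time reversal.
    """
    W = post.probs if isinstance(post, PosteriorMatrix) else np.asarray(post, dtype=float)
    T, S = W.shape
    if x is None:
        x = np.arange(S, dtype=float)
    else:
        x = np.asarray(x, dtype=float)
    u = np.arange(T, dtype=float) - (T - 1) / 2.0  # reversal flips sign of u
    Wl = W.ravel()
    ux = (u[:, None] * np.ones(S)).ravel()
    xx = (np.ones(T)[:, None] * x).ravel()
    sw = math.fsum(Wl)
    mu_u = math.fsum((Wl * ux).tolist()) / sw
    mu_x = math.fsum((Wl * xx).tolist()) / sw
    cov = math.fsum((Wl * ux * xx).tolist()) / sw - mu_u * mu_x
    var_u = math.fsum((Wl * ux * ux).tolist()) / sw - mu_u * mu_u
    var_x = math.fsum((Wl * xx * xx).tolist()) / sw - mu_x * mu_x
    if var_u <= 0 or var_x <= 0:
        return float("nan")
    return cov / math.sqrt(var_u * var_x)


def weighted_correlation_batch(W: np.ndarray, x: np.ndarray | None = None) -> np.ndarray:
    """Vectorized weighted correlation over a stack of posteriors (n, T, S)."""
    W = np.asarray(W, dtype=float)
    n, T, S = W.shape
    if x is None:
        x = np.arange(S, dtype=float)
    u = np.arange(T, dtype=float) - (T - 1) / 2.0
    sw = W.sum(axis=(1, 2))
    mu_u = np.einsum("nts,t->n", W, u) / sw
    mu_x = np.einsum("nts,s->n", W, x) / sw
    cov = np.einsum("nts,t,s->n", W, u, x) / sw - mu_u * mu_x
    var_u = np.einsum("nts,t->n", W, u**2) / sw - mu_u**2
    var_x = np.einsum("nts,s->n", W, x**2) / sw - mu_x**2
    denom = np.sqrt(np.maximum(var_u, 0) * np.maximum(var_x, 0))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(denom > 0, cov / denom, np.nan)


# ---------------------------------------------------------------------------
# event decoders
# ---------------------------------------------------------------------------

class RFEventDecoder:
    """Per-bin Bayesian event decoder from place fields (uniform prior)."""

    def __init__(self, fields: PlaceFieldMap, delta: float, rate_floor: float = 0.01):
        self.delta = delta
        self.rates = fields.support_rates()  # (C, S)
        self.rate_floor = rate_floor
        self.support_positions = fields.support_positions
        mu = (self.rates + rate_floor) * delta
        self._logmu = np.log(mu)
        self._musum = mu.sum(axis=0)
        # order support by position so R uses a monotone spatial axis
        pos = self.support_positions
        self.x = pos if pos.ndim == 1 else None

    def decode(self, counts: SpikeMatrix | np.ndarray) -> np.ndarray:
        Y = counts.counts if isinstance(counts, SpikeMatrix) else np.asarray(counts)
        ll = Y.T.astype(float) @ self._logmu - self._musum
        return _normalize_rows(ll)

    def decode_batch(self, Ys: np.ndarray) -> np.ndarray:
        """(n, C, T) count stacks -> (n, T, S) posteriors."""
        ll = np.einsum("nct,cs->nts", Ys.astype(float), self._logmu) - self._musum
        mx = ll.max(axis=2, keepdims=True)
        w = np.exp(ll - mx)
        return w / w.sum(axis=2, keepdims=True)


class StateEventDecoder:
    """Event decoder over latent HMM states, ordered by mapped position."""

    def __init__(self, model, smap=None, use_transitions: bool = True):
        self.model = model
        self.delta = model.delta
        self.use_transitions = use_transitions
        mu = np.maximum(model.Lambda * model.delta, 1e-300)  # (m, C)
        self._logmu = np.log(mu).T
        self._musum = mu.sum(axis=1)
        self.x = None
        if smap is not None:
            self.x = smap.positions if smap.positions.ndim == 1 else None

    def decode(self, counts: SpikeMatrix | np.ndarray) -> np.ndarray:
        Y = counts.counts if isinstance(counts, SpikeMatrix) else np.asarray(counts)
        ll = Y.T.astype(float) @ self._logmu - self._musum
        if not self.use_transitions:
            return _normalize_rows(ll)
        from .hmm import state_posteriors

        sm = counts if isinstance(counts, SpikeMatrix) else SpikeMatrix(Y, self.delta)
        return state_posteriors(self.model, sm).probs

    def decode_batch(self, Ys: np.ndarray) -> np.ndarray:
        if not self.use_transitions:
            ll = np.einsum("nct,cm->ntm", Ys.astype(float), self._logmu) - self._musum
            mx = ll.max(axis=2, keepdims=True)
            w = np.exp(ll - mx)
            return w / w.sum(axis=2, keepdims=True)
        return np.stack([self.decode(Y) for Y in Ys])


# ---------------------------------------------------------------------------
# shuffles, Z-score, classification
# ---------------------------------------------------------------------------

def shuffle_event(counts: np.ndarray, rng, kinds=("temporal", "cell")) -> np.ndarray:
    """One joint shuffle: permute whole time bins and cell identities."""
    out = counts
    if "temporal" in kinds:
        out = out[:, rng.permutation(out.shape[1])]
    if "cell" in kinds:
        out = out[rng.permutation(out.shape[0]), :]
    return out


def shuffle_null(
    event: SpikeMatrix,
    decoder,
    n_shuffle: int = N_SHUFFLE_DEFAULT,
    kinds: tuple[str, ...] = ("temporal", "cell"),
    seed: int | np.random.Generator = 0,
    x: np.ndarray | None = None,
) -> ShuffleNull:
    """Null R distribution from re-decoded shuffled spike matrices.

    Temporal shuffling permutes whole population column vectors; cell
    shuffling permutes row identities.  Every sample preserves the
    multiset of matrix entries, per-cell totals (temporal) and per-bin
    population counts (cell) exactly.
    """
    if event.n_bins < 2:
        raise ValueError("cannot shuffle an event with fewer than 2 bins")
    if n_shuffle < 100:
        raise ValueError("n_shuffle must be at least 100")
    rng = np.random.default_rng(seed)
    Y = event.counts
    stacks = np.empty((n_shuffle,) + Y.shape, dtype=Y.dtype)
    for i in range(n_shuffle):
        stacks[i] = shuffle_event(Y, rng, kinds)
    if x is None:
        x = getattr(decoder, "x", None)
    if hasattr(decoder, "decode_batch"):
        posts = decoder.decode_batch(stacks)
        r = weighted_correlation_batch(posts, x)
    else:
        r = np.array([weighted_correlation(decoder.decode(s), x) for s in stacks])
    r = np.asarray(r, dtype=float)
    fin = r[np.isfinite(r)]
    if fin.size >= 3 and fin.std() > 0 and fin.size <= 5000:
        stat_p = float(stats.shapiro(fin).pvalue)
        test = "shapiro-wilk"
    elif fin.size > 5000:
        res = stats.anderson(fin)  # pragma: no cover
        stat_p = 0.0 if res.statistic > res.critical_values[2] else 1.0  # pragma: no cover
        test = "anderson-darling"  # pragma: no cover
    else:
        stat_p, test = 0.0, "degenerate"
    return ShuffleNull(r, tuple(kinds), normal=stat_p >= 0.05,
                       normality_p=stat_p, normality_test=test)


def zscore_and_pvalue(r_raw: float, null: ShuffleNull) -> tuple[float, float, str]:
    """Z-score of |R| against the shuffle null, and the matching p-value.

    Z = (|R| - mean R_shuffle) / SD(R_shuffle), the shuffle-null
    standardization applied to the magnitude of R so forward and
    reverse events score alike (the signed shuffle distribution is
    centered near zero).  If the null passes the normality test the
    p-value is the one-sided normal tail; if not (or the SD vanishes)
    the Monte-Carlo add-one estimator
    (1 + #{|R_s| >= |R|}) / (n + 1) is used.
    """
    fin = null.r_shuffle[np.isfinite(null.r_shuffle)]
    abs_null = np.abs(fin)
    mu, sd = float(fin.mean()), float(fin.std(ddof=0))
    a = abs(r_raw)
    if sd == 0:
        z = float("nan")
        p = (1 + int((abs_null >= a).sum())) / (len(abs_null) + 1)
        return z, p, "monte_carlo"
    z = (a - mu) / sd
    if null.normal:
        return z, float(stats.norm.sf(z)), "normal"
    p = (1 + int((abs_null >= a).sum())) / (len(abs_null) + 1)
    return z, p, "monte_carlo"


def classify_significance(result: ReplayResult, n_support_bins: int | None = None) -> dict:
    """Apply the three replay criteria and store the flags on the result.

    r_pass: |R| > 0.5; length_pass: >= 5 bins AND MAP probability score
    above the 5 / n_support chance level; z_pass: Z > 1.65 (normal
    branch) or Monte-Carlo p < 0.05.  ``significant`` is the conjunction.
    """
    if n_support_bins is None:
        n_support_bins = result.n_support_bins
    r_ok = np.isfinite(result.R) and abs(result.R) > R_THRESHOLD
    length_ok = result.n_bins >= MIN_EVENT_BINS
    map_ok = result.avg_map_score > 5.0 / n_support_bins
    if result.p_method == "normal":
        z_ok = np.isfinite(result.Z) and result.Z > Z_THRESHOLD
    else:
        z_ok = result.p < 0.05
    flags = {
        "r_pass": bool(r_ok),
        "length_pass": bool(length_ok),
        "map_pass": bool(map_ok),
        "z_pass": bool(z_ok),
        "significant": bool(r_ok and length_ok and map_ok and z_ok),
    }
    result.flags = flags
    return flags


def score_event(
    event: SpikeMatrix,
    decoder,
    n_shuffle: int = N_SHUFFLE_DEFAULT,
    seed: int | np.random.Generator = 0,
    x: np.ndarray | None = None,
    keep_null: bool = False,
) -> ReplayResult:
    """Full per-event pipeline: decode, R, shuffle null, Z/p, criteria."""
    post = decoder.decode(event)
    if x is None:
        x = getattr(decoder, "x", None)
    r = weighted_correlation(post, x)
    mp = post.max(axis=1)
    avg_map = float(mp.mean())
    null = shuffle_null(event, decoder, n_shuffle=n_shuffle, seed=seed, x=x)
    z, p, method = zscore_and_pvalue(r, null)
    res = ReplayResult(
        R=float(r),
        Z=float(z),
        p=float(p),
        p_method=method,
        avg_map_score=avg_map,
        n_bins=event.n_bins,
        n_support_bins=post.shape[1],
        direction="forward" if (np.isfinite(r) and r >= 0) else "reverse",
        null=null if keep_null else None,
    )
    classify_significance(res)
    return res


def compare_epoch_populations(
    results_a: list[ReplayResult],
    results_b: list[ReplayResult],
    labels: tuple[str, str] = ("A", "B"),
) -> dict:
    """Summary table and rank-sum tests between two event populations.

    Per set: total events, events with |R| > 0.5, with Z > 1.65, and
    fully significant; medians of |R| and Z among significant events.
    Rank-sum (Mann-Whitney / Wilcoxon) tests compare |R| and Z between
    the sets.
    """
    def _row(results):
        absr = np.array([r.abs_R for r in results])
        zs = np.array([r.Z for r in results])
        sig = [r for r in results if r.significant]
        return {
            "n_total": len(results),
            "n_r_gt_0.5": int((absr > R_THRESHOLD).sum()),
            "n_z_gt_1.65": int((zs > Z_THRESHOLD).sum()),
            "n_significant": len(sig),
            "median_abs_R_sig": float(np.median([r.abs_R for r in sig])) if sig else np.nan,
            "median_Z_sig": float(np.median([r.Z for r in sig])) if sig else np.nan,
        }

    table = pd.DataFrame([_row(results_a), _row(results_b)], index=list(labels))
    out = {"table": table}
    if results_a and results_b:
        ra = [r.abs_R for r in results_a]
        rb = [r.abs_R for r in results_b]
        za = [r.Z for r in results_a if np.isfinite(r.Z)]
        zb = [r.Z for r in results_b if np.isfinite(r.Z)]
        out["ranksum_absR_p"] = float(stats.ranksums(ra, rb).pvalue)
        if za and zb:
            out["ranksum_Z_p"] = float(stats.ranksums(za, zb).pvalue)
    return out
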