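"""Receptive-field-free decoding: HDP-HMM with Poisson spike-count emissions.

The latent position is a discrete state with first-order Markov
dynamics; conditional on the state, the population spike counts are
independent Poisson.  The number of states is inferred with a
hierarchical-Dirichlet-process prior over the transition rows, sampled
by a weak-limit (truncated) blocked Gibbs sampler:

* state sequences per epoch by forward-filter / backward-sample,
  treating epochs as independent chains that share the transition
  matrix and the state rate matrix;
* conjugate gamma-Poisson updates for the state firing rates;
* HDP stick-breaking weights via the usual auxiliary table counts, with
  an optional sticky self-transition bias kappa.

The reported model is the posterior sample with the highest collapsed joint
probability p(y, z) (rates and transitions integrated out) after burn-in, with the effective state count m
taken as the number of states occupying at least 0.5% of the time bins
in that sample.  Positions never enter the fit; they are used only
afterwards, to build the state-space map for evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math

import numpy as np
import networkx as nx
from scipy.special import gammaln

from .core import Environment, EpochSet, SpikeMatrix
from .decode_rf import PosteriorMatrix

__all__ = [
    "HDPHMMConfig",
    "HMMModel",
    "StateSpaceMap",
    "TopologyGraph",
    "fit_hdp_hmm",
    "state_posteriors",
    "viterbi_path",
    "build_state_space_map",
    "decode_position_from_states",
    "topology_layout",
]

OCCUPANCY_CUTOFF = 0.005  # a state must hold >= 0.5% of bins to count toward m


@dataclass(frozen=True)
class HDPHMMConfig:
    """Hyperparameters of the weak-limit HDP-HMM sampler.

    gamma and alpha are the top- and bottom-level DP concentrations,
    kappa the sticky self-transition mass (0 = plain HDP-HMM), L the
    weak-limit truncation.  The gamma prior on rates has shape
    ``rate_shape``; its rate parameter is matched so the prior mean
    equals the grand mean firing rate of the data.
    """

    L: int = 100
    gamma: float = 1.0
    alpha: float = 1.0
    kappa: float = 0.0
    rate_shape: float = 1.0


@dataclass
class HMMModel:
    """Fitted HMM: m states, transition matrix P, state rate matrix Lambda."""

    m: int
    P: np.ndarray  # (m, m), rows sum to 1
    Lambda: np.ndarray  # (m, C) state firing rates, Hz
    pi0: np.ndarray  # (m,) initial/stationary distribution
    delta: float
    config: HDPHMMConfig
    active_states: np.ndarray  # indices into the truncated arrays
    P_full: np.ndarray = field(repr=False, default=None)
    Lambda_full: np.ndarray = field(repr=False, default=None)
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_cells(self) -> int:
        return self.Lambda.shape[1]


def _stationary(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix."""
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    s = v.sum()
    if s <= 0 or not np.isfinite(s):
        return np.full(len(P), 1.0 / len(P))
    return v / s


def _emission_loglik(Y: np.ndarray, Lambda: np.ndarray, delta: float) -> np.ndarray:
    """(T, L) log p(y_t | state) up to the shared -log(y!) constant."""
    mu = np.maximum(Lambda * delta, 1e-300)
    return Y @ np.log(mu).T - mu.sum(axis=1)


def _ffbs(ll: np.ndarray, P: np.ndarray, pi0: np.ndarray, rng) -> np.ndarray:
    """Forward filter, backward sample one state sequence."""
    T, L = ll.shape
    lik = np.exp(ll - ll.max(axis=1, keepdims=True))
    alpha = np.empty((T, L))
    a = pi0 * lik[0]
    a_sum = a.sum()
    a = a / a_sum if a_sum > 0 else np.full(L, 1.0 / L)
    alpha[0] = a
    for t in range(1, T):
        a = lik[t] * (P.T @ a)
        s = a.sum()
        a = a / s if s > 0 else np.full(L, 1.0 / L)
        alpha[t] = a
    z = np.empty(T, dtype=int)
    u = rng.random(T)
    z[-1] = min(int(np.searchsorted(np.cumsum(alpha[-1]), u[-1] * alpha[-1].sum())), L - 1)
    for t in range(T - 2, -1, -1):
        w = alpha[t] * P[:, z[t + 1]]
        s = w.sum()
        if s <= 0:
            w = np.full(L, 1.0 / L)
            s = 1.0
        z[t] = min(int(np.searchsorted(np.cumsum(w), u[t] * s)), L - 1)
    return z


def _sample_tables(n_jk: np.ndarray, alpha_beta: np.ndarray, rng) -> np.ndarray:
    """Auxiliary CRF table counts m_jk for the HDP stick weights."""
    L = n_jk.shape[0]
    m = np.zeros_like(n_jk)
    js, ks = np.nonzero(n_jk)
    for j, k in zip(js, ks):
        n = n_jk[j, k]
        ab = max(alpha_beta[j, k], 1e-12)
        probs = ab / (ab + np.arange(n))
        m[j, k] = int((rng.random(n) < probs).sum())
    return np.maximum(m, (n_jk > 0).astype(int))


def _collapsed_logp(zs, Ys, beta, config, a0, b0, delta) -> float:
    """Joint log p(y, z | beta, hyperparameters) with Lambda and P integrated out.

    Emissions use the gamma-Poisson marginal per (state, cell);
    transitions use the Dirichlet-multinomial marginal per row.  The
    shared -sum log(y!) constant is dropped.  Integrating the parameters
    out penalizes allocations that split states without likelihood
    support, so the selected sample is parsimonious.
    """
    L = len(beta)
    C = Ys[0].shape[1]
    S_jc = np.zeros((L, C))
    N_j = np.zeros(L)
    n_jk = np.zeros((L, L))
    init = 0.0
    logbeta = np.log(np.maximum(beta, 1e-300))
    for Y, z in zip(Ys, zs):
        np.add.at(S_jc, z, Y)
        N_j += np.bincount(z, minlength=L)
        np.add.at(n_jk, (z[:-1], z[1:]), 1)
        init += logbeta[z[0]]
    emis = (
        a0 * math.log(b0)
        + gammaln(a0 + S_jc)
        - gammaln(a0)
        - (a0 + S_jc) * np.log(b0 + N_j[:, None] * delta)
    ).sum()
    ab = config.alpha * np.tile(beta, (L, 1))
    if config.kappa > 0:
        ab[np.diag_indices(L)] += config.kappa
    row_tot = config.alpha + config.kappa
    trans = (
        gammaln(np.maximum(ab + n_jk, 1e-300)) - gammaln(np.maximum(ab, 1e-300))
    ).sum() + (gammaln(row_tot) - gammaln(row_tot + n_jk.sum(axis=1))).sum()
    return float(emis + trans + init)


def fit_hdp_hmm(
    epochs: EpochSet | SpikeMatrix,
    delta: float | None = None,
    config: HDPHMMConfig = HDPHMMConfig(),
    n_iter: int = 150,
    burn_in: int = 75,
    seed: int | np.random.Generator = 0,
) -> HMMModel:
    """Fit the HDP-HMM to one or more spike-count epochs by Gibbs sampling.

    Epochs are modeled as independent chains sharing P and Lambda; each
    chain starts from the stationary distribution of the current P.
    Returns the sample maximizing the collapsed joint p(y, z) after burn-in,
    reduced to the occupied states.  Diagnostics include the log-joint
    trace and a crude trend check flagging non-convergence.
    """
    if isinstance(epochs, SpikeMatrix):
        epochs = EpochSet([epochs], T0=epochs.n_bins)
    if len(epochs) == 0:
        raise ValueError("no epochs to fit")
    if delta is None:
        delta = epochs.delta
    rng = np.random.default_rng(seed)
    Ys = [e.counts.T.astype(float) for e in epochs.epochs]  # (T_i, C)
    C = Ys[0].shape[1]
    total_bins = sum(Y.shape[0] for Y in Ys)
    total_spikes = sum(Y.sum() for Y in Ys)
    if total_spikes == 0:
        raise ValueError("no spikes in the data")
    L = config.L
    if total_bins < L:
        L = max(2, total_bins)

    grand_rate = total_spikes / (C * total_bins * delta)
    a0 = config.rate_shape
    b0 = a0 / grand_rate  # prior mean = grand mean rate

    # init: random states, prior draws
    beta = rng.dirichlet(np.full(L, config.gamma / L))
    P = rng.dirichlet(np.full(L, 1.0), size=L)
    Lambda = rng.gamma(a0, 1.0 / b0, size=(L, C))
    zs = [rng.integers(0, L, size=Y.shape[0]) for Y in Ys]

    best = {"logp": -np.inf}
    logp_trace = np.empty(n_iter)

    for it in range(n_iter):
        # 1) rates | z  (conjugate gamma-Poisson)
        S_jc = np.zeros((L, C))
        N_j = np.zeros(L)
        for Y, z in zip(Ys, zs):
            np.add.at(S_jc, z, Y)
            N_j += np.bincount(z, minlength=L)
        Lambda = rng.gamma(a0 + S_jc, 1.0 / (b0 + N_j[:, None] * delta))

        # 2) transitions | z  (HDP stick-breaking with aux table counts)
        n_jk = np.zeros((L, L), dtype=int)
        for z in zs:
            np.add.at(n_jk, (z[:-1], z[1:]), 1)
        ab = config.alpha * np.tile(beta, (L, 1))
        if config.kappa > 0:
            ab[np.diag_indices(L)] += config.kappa
        m_jk = _sample_tables(n_jk, ab, rng)
        beta = rng.dirichlet(config.gamma / L + m_jk.sum(axis=0))
        conc = config.alpha * beta + n_jk
        if config.kappa > 0:
            conc = conc + config.kappa * np.eye(L)
        # Dirichlet rows via normalized gammas (vectorized over rows)
        G = rng.standard_gamma(np.maximum(conc, 1e-6))
        rowsum = G.sum(axis=1, keepdims=True)
        bad = rowsum[:, 0] <= 0
        if np.any(bad):
            G[bad] = 1.0
            rowsum = G.sum(axis=1, keepdims=True)
        P = G / rowsum

        # 3) states | P, Lambda  (blocked FFBS per epoch)
        pi0 = _stationary(P)
        lls = [_emission_loglik(Y, Lambda, delta) for Y in Ys]
        zs = [_ffbs(ll, P, pi0, rng) for ll in lls]

        logp = _collapsed_logp(zs, Ys, beta, config, a0, b0, delta)
        logp_trace[it] = logp
        if it >= burn_in and logp > best["logp"]:
            best = {"logp": logp, "P": P.copy(), "Lambda": Lambda.copy(),
                    "zs": [z.copy() for z in zs], "pi0": pi0.copy()}

    if "P" not in best:  # burn_in >= n_iter safeguard
        best = {"logp": logp, "P": P, "Lambda": Lambda, "zs": zs, "pi0": pi0}

    occ = np.zeros(L)
    for z in best["zs"]:
        occ += np.bincount(z, minlength=L)
    occ = occ / occ.sum()
    active = np.flatnonzero(occ >= OCCUPANCY_CUTOFF)
    if active.size == 0:
        active = np.array([int(np.argmax(occ))])
    P_red = best["P"][np.ix_(active, active)]
    P_red = P_red / P_red.sum(axis=1, keepdims=True)
    Lambda_red = best["Lambda"][active]

    half = burn_in + (n_iter - burn_in) // 2
    tail = logp_trace[half:]
    headp = logp_trace[burn_in:half]
    converged = True
    if len(tail) > 3 and len(headp) > 3:
        drift = tail.mean() - headp.mean()
        scale = tail.std(ddof=1) + 1e-12
        converged = bool(abs(drift) < 3 * scale)

    return HMMModel(
        m=int(active.size),
        P=P_red,
        Lambda=Lambda_red,
        pi0=_stationary(P_red),
        delta=delta,
        config=config,
        active_states=active,
        P_full=best["P"],
        Lambda_full=best["Lambda"],
        diagnostics={
            "logp_trace": logp_trace,
            "best_logp": best["logp"],
            "occupancy": occ,
            "converged": converged,
            "truncation_used": L,
        },
    )


def _check_cells(model: HMMModel, counts: SpikeMatrix):
    if counts.n_cells != model.n_cells:
        raise ValueError(
            f"spike matrix has {counts.n_cells} cells, model expects {model.n_cells}"
        )


def state_posteriors(model: HMMModel, counts: SpikeMatrix) -> PosteriorMatrix:
    """Forward-backward smoothed state posteriors gamma_t(s)."""
    _check_cells(model, counts)
    Y = counts.counts.T.astype(float)
    ll = _emission_loglik(Y, model.Lambda, counts.delta)
    lik = np.exp(ll - ll.max(axis=1, keepdims=True))
    T, m = ll.shape
    alpha = np.empty((T, m))
    cnorm = np.empty(T)
    a = model.pi0 * lik[0]
    cnorm[0] = a.sum()
    alpha[0] = a / cnorm[0] if cnorm[0] > 0 else np.full(m, 1 / m)
    for t in range(1, T):
        a = lik[t] * (model.P.T @ alpha[t - 1])
        cnorm[t] = a.sum()
        alpha[t] = a / cnorm[t] if cnorm[t] > 0 else np.full(m, 1 / m)
    beta = np.ones((T, m))
    for t in range(T - 2, -1, -1):
        b = model.P @ (lik[t + 1] * beta[t + 1])
        s = b.sum()
        beta[t] = b / s if s > 0 else np.full(m, 1 / m)
    gamma = alpha * beta
    gamma = gamma / gamma.sum(axis=1, keepdims=True)
    return PosteriorMatrix(gamma, np.arange(m).astype(float), support_kind="state")


def viterbi_path(model: HMMModel, counts: SpikeMatrix) -> tuple[np.ndarray, float]:
    """MAP state sequence (log-domain max-product) and average MAP score.

    The average MAP probability score is the mean, over time bins, of
    the smoothed posterior mass at the Viterbi state.
    """
    _check_cells(model, counts)
    Y = counts.counts.T.astype(float)
    ll = _emission_loglik(Y, model.Lambda, counts.delta)
    T, m = ll.shape
    logP = np.log(np.maximum(model.P, 1e-300))
    logpi = np.log(np.maximum(model.pi0, 1e-300))
    dp = np.empty((T, m))
    back = np.zeros((T, m), dtype=int)
    dp[0] = logpi + ll[0]
    for t in range(1, T):
        cand = dp[t - 1][:, None] + logP
        back[t] = cand.argmax(axis=0)
        dp[t] = cand[back[t], np.arange(m)] + ll[t]
    z = np.empty(T, dtype=int)
    z[-1] = int(dp[-1].argmax())
    for t in range(T - 2, -1, -1):
        z[t] = back[t + 1][z[t + 1]]
    gamma = state_posteriors(model, counts).probs
    avg_map = float(gamma[np.arange(T), z].mean())
    return z, avg_map


@dataclass
class StateSpaceMap:
    """Evaluation-time assignment of each latent state to a position."""

    positions: np.ndarray  # (m,) or (m, 2); NaN for unassigned states
    dispersion: np.ndarray  # (m,) mean distance of assigned bins to the centroid
    counts: np.ndarray  # (m,) number of Viterbi-assigned bins per state
    env: Environment

    @property
    def assigned(self) -> np.ndarray:
        return self.counts > 0


def _circular_mean(pos: np.ndarray, L: float) -> float:
    ang = pos / L * 2 * np.pi
    return float(np.mod(np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()), 2 * np.pi) / (2 * np.pi) * L)


def build_state_space_map(
    model: HMMModel,
    epochs: EpochSet | SpikeMatrix,
    positions: np.ndarray,
    env: Environment,
) -> StateSpaceMap:
    """Map each state to the centroid of its Viterbi-assigned positions.

    ``positions`` is the per-bin ground-truth position of the *original*
    recording, indexed by each epoch's ``source_bins``.  This is the only
    place behavioral data touches the unsupervised decoder, and it is
    used purely for evaluation.  Circular tracks use the circular mean.
    """
    if isinstance(epochs, SpikeMatrix):
        epochs = EpochSet([epochs], T0=epochs.n_bins)
    positions = np.asarray(positions, dtype=float)
    m = model.m
    assign: list[list[np.ndarray]] = [[] for _ in range(m)]
    for e in epochs.epochs:
        z, _ = viterbi_path(model, e)
        pos = positions[e.source_bins]
        for s in range(m):
            sel = z == s
            if np.any(sel):
                assign[s].append(np.atleast_1d(pos[sel]) if pos.ndim == 1 else pos[sel])
    is_1d = env.is_1d
    out_pos = np.full(m if is_1d else (m, 2), np.nan)
    disp = np.full(m, np.nan)
    nbins = np.zeros(m, dtype=int)
    for s in range(m):
        if not assign[s]:
            continue
        pos = np.concatenate(assign[s], axis=0)
        nbins[s] = len(pos)
        if env.kind == "circular_track":
            c = _circular_mean(pos, env.extent)
        elif is_1d:
            c = float(pos.mean())
        else:
            c = pos.mean(axis=0)
        out_pos[s] = c
        ref = np.full(len(pos), c) if is_1d else np.broadcast_to(c, pos.shape)
        disp[s] = float(env.distance(pos, ref).mean())
    return StateSpaceMap(out_pos, disp, nbins, env)


def decode_position_from_states(
    model: HMMModel,
    smap: StateSpaceMap,
    epochs: EpochSet | SpikeMatrix,
    positions: np.ndarray,
    env: Environment,
) -> tuple[float, float]:
    """Median decoding error (cm) via the state-space map.

    Bins whose Viterbi state has no mapped position are excluded;
    the excluded fraction is returned alongside the error.
    """
    if isinstance(epochs, SpikeMatrix):
        epochs = EpochSet([epochs], T0=epochs.n_bins)
    positions = np.asarray(positions, dtype=float)
    errs = []
    total = 0
    kept = 0
    for e in epochs.epochs:
        z, _ = viterbi_path(model, e)
        ok = smap.assigned[z]
        total += len(z)
        kept += int(ok.sum())
        if not np.any(ok):
            continue
        est = smap.positions[z[ok]]
        truth = positions[e.source_bins][ok]
        errs.append(env.distance(est, truth))
    if not errs:
        raise ValueError("no decodable bins (all states unmapped)")
    return float(np.median(np.concatenate(errs))), 1.0 - kept / total


@dataclass
class TopologyGraph:
    """Force-directed layout of the state-transition connectivity."""

    graph: "nx.Graph"
    layout: dict  # node -> (x, y), normalized to the unit bounding box
    strengths: np.ndarray  # nonzero off-diagonal P_ij + P_ji values
    degrees_above_threshold: np.ndarray  # per-node count of strong edges
    strength_mean: float
    strength_sd: float


def topology_layout(
    model: HMMModel,
    strength_threshold: float = 0.2,
    layout_seed: int = 0,
) -> TopologyGraph:
    """Undirected topology graph with edge weight ``P_ij + P_ji``.

    Uses a Fruchterman-Reingold (spring) layout with a fixed seed and
    rescales coordinates into the unit bounding box so the result is
    scale-invariant.  Also reports per-node degree counting only edges
    above ``strength_threshold`` and the nonzero-strength statistics.
    """
    m = model.m
    W = model.P + model.P.T
    np.fill_diagonal(W, 0.0)
    G = nx.Graph()
    G.add_nodes_from(range(m))
    strengths = []
    for i in range(m):
        for j in range(i + 1, m):
            if W[i, j] > 0:
                G.add_edge(i, j, weight=float(W[i, j]))
                strengths.append(W[i, j])
    strengths = np.asarray(strengths)
    if m == 1:
        layout = {0: np.array([0.5, 0.5])}
    else:
        layout = nx.spring_layout(G, weight="weight", seed=layout_seed)
        xy = np.array([layout[i] for i in range(m)])
        span = xy.max(axis=0) - xy.min(axis=0)
        span[span == 0] = 1.0
        xy = (xy - xy.min(axis=0)) / span
        layout = {i: xy[i] for i in range(m)}
    deg = np.array([
        sum(1 for j in G.neighbors(i) if G[i][j]["weight"] > strength_threshold)
        for i in range(m)
    ])
    mean = float(strengths.mean()) if strengths.size else 0.0
    sd = float(strengths.std(ddof=1)) if strengths.size > 1 else 0.0
    return TopologyGraph(G, layout, strengths, deg, mean, sd)
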