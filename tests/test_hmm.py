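"""HDP-HMM fitting, state inference, and topology-graph tests."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from popdecode.core import Environment, EpochSet, SpikeMatrix
from popdecode.hmm import (
    HDPHMMConfig,
    HMMModel,
    build_state_space_map,
    decode_position_from_states,
    fit_hdp_hmm,
    state_posteriors,
    topology_layout,
    viterbi_path,
    _emission_loglik,
)


def make_model(P, Lambda, delta=0.25):
    P = np.asarray(P, dtype=float)
    Lambda = np.asarray(Lambda, dtype=float)
    m = len(P)
    pi0 = np.full(m, 1.0 / m)
    return HMMModel(m=m, P=P, Lambda=Lambda, pi0=pi0, delta=delta,
                    config=HDPHMMConfig(L=m), active_states=np.arange(m))


def sample_hmm(P, Lambda, T, delta, rng):
    m = len(P)
    z = np.zeros(T, dtype=int)
    z[0] = rng.integers(m)
    for t in range(1, T):
        z[t] = rng.choice(m, p=P[z[t - 1]])
    Y = rng.poisson(Lambda[z] * delta)
    return z, SpikeMatrix(Y.T, delta)


def brute_force_viterbi(model, counts):
    """Exhaustive max over all state paths (tiny instances only)."""
    ll = _emission_loglik(counts.counts.T.astype(float), model.Lambda, counts.delta)
    T, m = ll.shape
    logP = np.log(model.P)
    logpi = np.log(model.pi0)
    best, best_path = -np.inf, None
    for path in itertools.product(range(m), repeat=T):
        lp = logpi[path[0]] + ll[0, path[0]]
        for t in range(1, T):
            lp += logP[path[t - 1], path[t]] + ll[t, path[t]]
        if lp > best:
            best, best_path = lp, path
    return best, np.array(best_path)


def viterbi_joint_logp(model, counts, z):
    ll = _emission_loglik(counts.counts.T.astype(float), model.Lambda, counts.delta)
    lp = np.log(model.pi0[z[0]]) + ll[0, z[0]]
    lp += np.log(model.P[z[:-1], z[1:]]).sum()
    lp += ll[np.arange(1, len(z)), z[1:]].sum()
    return lp


class TestViterbi:
    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            P = rng.dirichlet(np.ones(3), size=3)
            Lam = rng.uniform(0.5, 10.0, size=(3, 4))
            model = make_model(P, Lam)
            _, sm = sample_hmm(P, Lam, 6, 0.25, rng)
            z, _ = viterbi_path(model, sm)
            best, _ = brute_force_viterbi(model, sm)
            assert viterbi_joint_logp(model, sm, z) == pytest.approx(best, abs=1e-9)

    def test_disjoint_populations_recovered_exactly(self):
        """Two states firing disjoint halves of the population, P ~ I."""
        Lam = np.zeros((2, 10))
        Lam[0, :5] = 20.0
        Lam[1, 5:] = 20.0
        P = np.array([[0.95, 0.05], [0.05, 0.95]])
        rng = np.random.default_rng(1)
        z, sm = sample_hmm(P, Lam, 100, 0.25, rng)
        model = make_model(P, Lam)
        zhat, score = viterbi_path(model, sm)
        assert np.array_equal(zhat, z)
        assert 0.5 <= score <= 1.0

    def test_avg_map_score_bounds(self):
        rng = np.random.default_rng(2)
        P = rng.dirichlet(np.ones(4), size=4)
        Lam = rng.uniform(0.5, 5.0, size=(4, 6))
        model = make_model(P, Lam)
        _, sm = sample_hmm(P, Lam, 50, 0.25, rng)
        _, score = viterbi_path(model, sm)
        assert 1.0 / 4 <= score <= 1.0


class TestStatePosteriors:
    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(3)
        P = rng.dirichlet(np.ones(5), size=5)
        Lam = rng.uniform(0.5, 5.0, size=(5, 8))
        model = make_model(P, Lam)
        _, sm = sample_hmm(P, Lam, 60, 0.25, rng)
        post = state_posteriors(model, sm)
        assert np.allclose(post.probs.sum(axis=1), 1.0, atol=1e-9)

    def test_single_state_posterior_is_one(self):
        model = make_model(np.array([[1.0]]), np.array([[2.0, 3.0]]))
        sm = SpikeMatrix(np.random.default_rng(0).poisson(0.5, size=(2, 20)), 0.25)
        post = state_posteriors(model, sm)
        assert np.allclose(post.probs, 1.0)

    def test_matches_hmmlearn_forward_backward(self):
        """Independent smoother oracle on the same fixed parameters."""
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(4)
        m, C, T, delta = 3, 5, 40, 0.25
        P = rng.dirichlet(np.full(m, 2.0), size=m)
        Lam = rng.uniform(0.5, 8.0, size=(m, C))
        model = make_model(P, Lam, delta)
        _, sm = sample_hmm(P, Lam, T, delta, rng)
        ref = hmmlearn.PoissonHMM(n_components=m)
        ref.startprob_ = model.pi0
        ref.transmat_ = P
        ref.lambdas_ = Lam * delta
        expected = ref.predict_proba(sm.counts.T)
        got = state_posteriors(model, sm).probs
        assert np.allclose(got, expected, atol=1e-8)

    def test_cell_mismatch_rejected(self):
        model = make_model(np.array([[1.0]]), np.array([[2.0, 3.0]]))
        sm = SpikeMatrix(np.zeros((3, 5), dtype=int), 0.25)
        with pytest.raises(ValueError):
            state_posteriors(model, sm)


class TestFitHDPHMM:
    def test_single_state_data(self):
        rng = np.random.default_rng(5)
        sm = SpikeMatrix(rng.poisson(0.8, size=(10, 400)), 0.25)
        model = fit_hdp_hmm(sm, config=HDPHMMConfig(L=8), n_iter=200, burn_in=100, seed=0)
        assert model.m == 1

    def test_four_state_recovery(self):
        rng = np.random.default_rng(6)
        K = 4
        P = np.full((K, K), 0.05)
        np.fill_diagonal(P, 0.85)
        Lam = rng.uniform(1.0, 10.0, size=(K, 20))
        _, sm = sample_hmm(P, Lam, 2000, 0.25, rng)
        models = [fit_hdp_hmm(sm, config=HDPHMMConfig(L=10), n_iter=250,
                              burn_in=125, seed=s) for s in range(3)]
        ms = [m.m for m in models]
        assert max(set(ms), key=ms.count) == K  # modal state count over chains
        model = next(m for m in models if m.m == K)
        cost = np.linalg.norm(model.Lambda[:, None, :] - Lam[None, :, :], axis=2)
        r, c = linear_sum_assignment(cost)
        order = r[np.argsort(c)]
        assert np.linalg.norm(model.P[np.ix_(order, order)] - P) < 0.2

    def test_transition_recovery_improves_with_data(self):
        """Hungarian-matched error of P shrinks as the recording grows."""
        rng = np.random.default_rng(7)
        K = 3
        P = np.full((K, K), 0.1)
        np.fill_diagonal(P, 0.8)
        Lam = rng.uniform(1.0, 9.0, size=(K, 15))
        errs = []
        for T in (300, 2400):
            _, sm = sample_hmm(P, Lam, T, 0.25, np.random.default_rng(8))
            model = fit_hdp_hmm(sm, config=HDPHMMConfig(L=8), n_iter=150,
                                burn_in=75, seed=2)
            idx = np.argsort(model.diagnostics["occupancy"][model.active_states])[::-1][:K]
            LamK = model.Lambda[idx]
            cost = np.linalg.norm(LamK[:, None, :] - Lam[None, :, :], axis=2)
            r, c = linear_sum_assignment(cost)
            order = r[np.argsort(c)]
            PK = model.P[np.ix_(idx, idx)][np.ix_(order, order)]
            PK = PK / PK.sum(axis=1, keepdims=True)
            errs.append(np.linalg.norm(PK - P))
        assert errs[1] < errs[0]

    def test_seed_determinism(self):
        rng = np.random.default_rng(9)
        sm = SpikeMatrix(rng.poisson(0.6, size=(8, 150)), 0.25)
        m1 = fit_hdp_hmm(sm, config=HDPHMMConfig(L=6), n_iter=40, burn_in=20, seed=3)
        m2 = fit_hdp_hmm(sm, config=HDPHMMConfig(L=6), n_iter=40, burn_in=20, seed=3)
        assert m1.m == m2.m
        assert np.array_equal(m1.P, m2.P)
        assert np.array_equal(m1.Lambda, m2.Lambda)

    def test_no_spikes_rejected(self):
        sm = SpikeMatrix(np.zeros((4, 50), dtype=int), 0.25)
        with pytest.raises(ValueError):
            fit_hdp_hmm(sm, seed=0)


class TestLabelPermutationEquivariance:
    def test_permuting_states_changes_no_scalar(self, linear_track):
        rng = np.random.default_rng(10)
        m, C = 4, 12
        P = rng.dirichlet(np.full(m, 2.0), size=m)
        Lam = rng.uniform(0.5, 10.0, size=(m, C))
        model = make_model(P, Lam)
        _, sm = sample_hmm(P, Lam, 80, 0.25, rng)
        perm = np.array([2, 0, 3, 1])
        model_p = make_model(P[np.ix_(perm, perm)], Lam[perm])

        z, s = viterbi_path(model, sm)
        zp, sp = viterbi_path(model_p, sm)
        inv = np.argsort(perm)
        assert np.array_equal(inv[z], zp)
        assert s == pytest.approx(sp, abs=1e-9)

        positions = np.linspace(5, 195, sm.n_bins)
        smap = build_state_space_map(model, sm, positions, linear_track)
        smap_p = build_state_space_map(model_p, sm, positions, linear_track)
        assert np.allclose(smap.positions[perm], smap_p.positions, equal_nan=True)
        err, _ = decode_position_from_states(model, smap, sm, positions, linear_track)
        err_p, _ = decode_position_from_states(model_p, smap_p, sm, positions, linear_track)
        assert err == pytest.approx(err_p, abs=1e-9)


class TestStateSpaceMap:
    def test_disjoint_segments_give_centroids_inside(self, linear_track):
        Lam = np.zeros((2, 10))
        Lam[0, :5] = 15.0
        Lam[1, 5:] = 15.0
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        rng = np.random.default_rng(11)
        z, sm = sample_hmm(P, Lam, 200, 0.25, rng)
        model = make_model(P, Lam)
        # state 0 lives on [0, 100), state 1 on [100, 200)
        positions = np.where(z == 0, rng.uniform(0, 100, len(z)),
                             rng.uniform(100, 200, len(z)))
        smap = build_state_space_map(model, sm, positions, linear_track)
        assert 0 <= smap.positions[0] < 100
        assert 100 <= smap.positions[1] < 200
        err, excl = decode_position_from_states(model, smap, sm, positions, linear_track)
        assert err <= np.nanmax(smap.dispersion) + 1e-9
        assert excl == 0.0

    def test_unassigned_state_masked(self, linear_track):
        Lam = np.array([[10.0, 0.1], [0.1, 10.0], [30.0, 30.0]])
        P = np.eye(3) * 0.9 + 0.05
        P = P / P.sum(axis=1, keepdims=True)
        model = make_model(P, Lam)
        sm = SpikeMatrix(np.array([[5, 5], [0, 0]]), 0.25)  # only state 0 plausible
        positions = np.array([10.0, 12.0])
        smap = build_state_space_map(model, sm, positions, linear_track)
        assert smap.assigned.sum() >= 1
        assert np.all(np.isnan(np.atleast_1d(smap.positions)[~smap.assigned]))


class TestTopologyGraph:
    def test_ring_topology(self):
        m = 8
        P = np.zeros((m, m))
        for i in range(m):
            P[i, (i + 1) % m] = 0.3
            P[i, (i - 1) % m] = 0.3
            P[i, i] = 0.4
        model = make_model(P, np.ones((m, 4)))
        g = topology_layout(model, strength_threshold=0.2)
        assert np.all(g.degrees_above_threshold == 2)
        assert g.graph.number_of_edges() == m
        xy = np.array([g.layout[i] for i in range(m)])
        assert xy.min() >= -1e-9 and xy.max() <= 1 + 1e-9

    def test_single_state_graph(self):
        model = make_model(np.array([[1.0]]), np.array([[2.0]]))
        g = topology_layout(model)
        assert g.graph.number_of_nodes() == 1
        assert g.graph.number_of_edges() == 0

    def test_strength_stats(self):
        P = np.array([[0.5, 0.5], [0.25, 0.75]])
        model = make_model(P, np.ones((2, 3)))
        g = topology_layout(model)
        assert g.strengths.tolist() == [0.75]
        assert g.strength_mean == pytest.approx(0.75)


class TestEpochFitting:
    def test_fit_on_epochs_shares_parameters(self):
        rng = np.random.default_rng(12)
        K = 2
        P = np.array([[0.9, 0.1], [0.1, 0.9]])
        Lam = np.array([[8.0, 0.2, 6.0, 0.2], [0.2, 8.0, 0.2, 6.0]])
        mats = []
        for s in range(6):
            _, sm = sample_hmm(P, Lam, 50, 0.25, rng)
            mats.append(sm)
        es = EpochSet(mats, T0=50)
        model = fit_hdp_hmm(es, config=HDPHMMConfig(L=6), n_iter=300, burn_in=150, seed=0)
        assert model.m == K
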