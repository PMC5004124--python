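"""Generative-model and sleep-like-transform tests."""

import numpy as np
import pytest
from scipy import stats

from popdecode.core import Environment, SpikeMatrix, Trajectory
from popdecode import synthetic as syn
from popdecode.placefields import estimate_place_fields

from conftest import constant_speed_trajectory


class TestSimulateTrajectory:
    def test_linear_track_stays_in_bounds(self, linear_track):
        traj = syn.simulate_trajectory(linear_track, 600.0, 25.0, seed=0)
        assert np.all(traj.pos >= 0) and np.all(traj.pos <= 200.0)

    def test_circular_arc_length_matches_mean_speed(self, circular_track):
        traj = syn.simulate_trajectory(circular_track, 60.0, 20.0, seed=1)
        L = circular_track.extent
        d = np.diff(traj.pos)
        arc = np.abs((d + L / 2) % L - L / 2).sum()
        # E[arc] = mean_speed * duration = 1200 cm, lognormal speed jitter
        assert 800 < arc < 1700

    def test_open_field_containment(self, open_field):
        traj = syn.simulate_trajectory(open_field, 120.0, 25.0, seed=2)
        assert np.all(open_field.contains(traj.pos))

    @pytest.mark.parametrize("duration,speed", [(0.0, 10.0), (-5.0, 10.0), (10.0, 0.0)])
    def test_invalid_parameters(self, open_field, duration, speed):
        with pytest.raises(ValueError):
            syn.simulate_trajectory(open_field, duration, speed)


class TestSampleSpikeCounts:
    def test_flat_cell_mean_count(self, linear_track):
        """A 2-Hz homogeneous cell at 0.25 s bins averages 0.5 spikes/bin."""
        truth = syn.GroundTruthFields(
            linear_track, centers=np.array([100.0]), widths=np.array([10.0]),
            peak_rates=np.array([2.0]), baseline=np.array([2.0]),
            is_place_cell=np.array([False]))
        traj = constant_speed_trajectory(linear_track, 20.0, 2500.0)
        sm = syn.sample_spike_counts(truth, traj, 0.25, seed=0)
        mean = sm.counts.mean()
        se = np.sqrt(0.5 / sm.n_bins)
        assert abs(mean - 0.5) < 3 * se

    def test_poisson_goodness_of_fit(self, linear_track):
        """Counts of a flat cell pass a chi-square test against Poisson."""
        truth = syn.GroundTruthFields(
            linear_track, centers=np.array([0.0]), widths=np.array([5.0]),
            peak_rates=np.array([4.0]), baseline=np.array([4.0]),
            is_place_cell=np.array([False]))
        traj = constant_speed_trajectory(linear_track, 20.0, 2000.0)
        sm = syn.sample_spike_counts(truth, traj, 0.25, seed=5)
        mu = 1.0
        k = np.arange(6)
        probs = stats.poisson.pmf(k, mu)
        probs[-1] = 1 - probs[:-1].sum()
        obs = np.bincount(np.minimum(sm.counts[0], 5), minlength=6)
        chi2 = (((obs - sm.n_bins * probs) ** 2) / (sm.n_bins * probs)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=5)

    def test_zero_rates_give_empty_matrix(self, linear_track):
        truth = syn.GroundTruthFields(
            linear_track, centers=np.array([50.0]), widths=np.array([10.0]),
            peak_rates=np.array([0.0]), baseline=np.array([0.0]),
            is_place_cell=np.array([True]))
        traj = constant_speed_trajectory(linear_track, 20.0, 60.0)
        assert syn.sample_spike_counts(truth, traj, 0.25, seed=0).total_spikes == 0

    def test_seed_determinism(self, track_session):
        a = syn.sample_spike_counts(track_session["truth"], track_session["traj"], 0.25, seed=9)
        b = syn.sample_spike_counts(track_session["truth"], track_session["traj"], 0.25, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_too_short_trajectory(self, linear_track, track_session):
        traj = Trajectory(np.array([0.0, 0.05]), np.array([0.0, 1.0]), env=linear_track)
        with pytest.raises(ValueError):
            syn.sample_spike_counts(track_session["truth"], traj, 0.25)


class TestNonPlaceCells:
    def test_total_count_conserved_and_tuning_flattened(self, linear_track):
        truth = syn.make_population(linear_track, n_cells=6, seed=3)
        traj = syn.simulate_trajectory(linear_track, 1200.0, 25.0, seed=4)
        counts = syn.sample_spike_counts(truth, traj, 0.25, seed=5)
        fields = estimate_place_fields(counts, traj, linear_track)
        flat = syn.make_nonplace_cells(counts, traj, np.array([0]),
                                       fields.occupancy.p, linear_track, seed=6)
        assert flat.counts[0].sum() == counts.counts[0].sum()
        assert np.array_equal(flat.counts[1:], counts.counts[1:])
        f2 = estimate_place_fields(flat, traj, linear_track)
        lam_before = fields.support_rates()[0]
        lam_after = f2.support_rates()[0]
        # flattening shrinks the modulation depth a lot
        assert lam_after.max() / max(lam_after.min(), 1e-9) \
            < 0.25 * lam_before.max() / max(lam_before.min(), 1e-9)

    def test_empty_selection_is_identity(self, track_session, linear_track):
        counts = track_session["counts"]
        occ = track_session["fields"].occupancy.p
        out = syn.make_nonplace_cells(counts, track_session["traj"],
                                      np.array([], dtype=int), occ, linear_track)
        assert np.array_equal(out.counts, counts.counts)


class TestSpeedFilter:
    def test_fast_constant_speed_unchanged(self, linear_track, track_session):
        traj = constant_speed_trajectory(linear_track, 20.0, 60.0)
        counts = syn.sample_spike_counts(track_session["truth"], traj, 0.25, seed=0)
        out = syn.apply_speed_filter(counts, traj, threshold=15.0)
        assert np.array_equal(out.counts, counts.counts)

    def test_all_slow_raises(self, linear_track, track_session):
        traj = constant_speed_trajectory(linear_track, 5.0, 60.0)
        counts = syn.sample_spike_counts(track_session["truth"], traj, 0.25, seed=0)
        with pytest.raises(ValueError, match="speed threshold"):
            syn.apply_speed_filter(counts, traj, threshold=15.0)

    def test_alternating_speed_keeps_half(self, linear_track):
        # speed alternates 30 / 0 cm/s per 0.25-s bin
        sample_hz, delta = 60.0, 0.25
        n_bins = 40
        t = np.arange(int(n_bins * delta * sample_hz) + 1) / sample_hz
        x = np.zeros_like(t)
        for k in range(1, len(t)):
            moving = int(t[k - 1] / delta) % 2 == 0
            x[k] = x[k - 1] + (30.0 / sample_hz if moving else 0.0)
        traj = Trajectory(t, x, env=None)
        counts = SpikeMatrix(np.ones((3, n_bins), dtype=int), delta)
        out = syn.apply_speed_filter(counts, traj, threshold=15.0)
        assert out.n_bins == n_bins // 2


class TestSplitIntoEpochs:
    def test_epoch_count(self, track_session):
        counts = track_session["counts"].select_bins(np.arange(100))
        es = syn.split_into_epochs(counts, 10, seed=0)
        assert len(es) == 10 and all(e.n_bins == 10 for e in es)

    def test_identity_when_t0_is_t(self, track_session):
        counts = track_session["counts"]
        es = syn.split_into_epochs(counts, counts.n_bins, reverse_prob=0.0,
                                   shuffle_order=False, seed=0)
        assert len(es) == 1
        assert np.array_equal(es.epochs[0].counts, counts.counts)
        assert np.array_equal(es.epochs[0].source_bins, counts.source_bins)

    def test_reversal_is_involution(self, track_session):
        counts = track_session["counts"].select_bins(np.arange(20))
        rev = counts.select_bins(np.arange(20)[::-1])
        back = rev.select_bins(np.arange(20)[::-1])
        assert np.array_equal(back.counts, counts.counts)
        assert np.array_equal(back.source_bins, counts.source_bins)

    def test_remainder_dropped_and_t0_too_large(self, track_session):
        counts = track_session["counts"].select_bins(np.arange(25))
        es = syn.split_into_epochs(counts, 10, seed=1)
        assert len(es) == 2
        with pytest.raises(ValueError):
            syn.split_into_epochs(counts, 26)

    def test_source_bins_track_reversal(self, track_session):
        counts = track_session["counts"].select_bins(np.arange(30))
        es = syn.split_into_epochs(counts, 10, reverse_prob=1.0,
                                   shuffle_order=False, seed=2)
        for i, e in enumerate(es.epochs):
            assert es.reversed_flags[i]
            assert np.array_equal(e.source_bins,
                                  counts.source_bins[np.arange(i * 10, (i + 1) * 10)[::-1]])


class TestSubsampleCells:
    def _epochs(self, C, T=30):
        sm = SpikeMatrix(np.ones((C, T), dtype=int), 0.25)
        return syn.split_into_epochs(sm, 10, reverse_prob=0, shuffle_order=False)

    def test_rho_one_is_identity(self):
        es = self._epochs(20)
        out = syn.subsample_cells(es, 1.0, seed=0)
        assert all(np.array_equal(a.counts, b.counts)
                   for a, b in zip(out.epochs, es.epochs))

    def test_active_count_rounding(self):
        out = syn.subsample_cells(self._epochs(50), 0.3, seed=0)
        assert out.epochs[0].n_cells == 15

    def test_min_cell_floor(self):
        out = syn.subsample_cells(self._epochs(20), 0.3, seed=0)
        assert out.epochs[0].n_cells == 10

    def test_per_epoch_draws_distinct_subsets(self):
        out = syn.subsample_cells(self._epochs(40), 0.5, per_epoch=True, seed=0)
        sets = [tuple(a) for a in out.active_cells]
        assert len(set(sets)) > 1

    def test_zero_mode_keeps_identity(self):
        es = self._epochs(40)
        out = syn.subsample_cells(es, 0.5, mode="zero", seed=0)
        e = out.epochs[0]
        assert e.n_cells == 40
        inactive = np.setdiff1d(np.arange(40), out.active_cells[0])
        assert e.counts[inactive].sum() == 0

    def test_population_below_floor_raises(self):
        with pytest.raises(ValueError):
            syn.subsample_cells(self._epochs(5), 0.5, seed=0)


class TestThinSpikes:
    def test_clip(self):
        sm = SpikeMatrix(np.array([[3, 0, 1], [2, 5, 0]]), 0.02)
        out = syn.thin_spikes(sm)
        assert np.array_equal(out.counts, [[1, 0, 1], [1, 1, 0]])

    def test_all_zero_unchanged(self):
        sm = SpikeMatrix(np.zeros((2, 4), dtype=int), 0.02)
        assert syn.thin_spikes(sm).total_spikes == 0

    def test_clipped_poisson_rate(self):
        rng = np.random.default_rng(0)
        sm = SpikeMatrix(rng.poisson(1.0, size=(1, 20000)), 0.02)
        out = syn.thin_spikes(sm)
        frac = out.counts.mean()
        expected = 1 - np.exp(-1)  # P(Poisson(1) >= 1)
        assert abs(frac - expected) < 3 * np.sqrt(expected * (1 - expected) / 20000)

    def test_never_increases(self):
        rng = np.random.default_rng(1)
        sm = SpikeMatrix(rng.poisson(2.0, size=(4, 200)), 0.02)
        for mode in ("clip", "binomial"):
            out = syn.thin_spikes(sm, seed=2, mode=mode)
            assert np.all(out.counts <= sm.counts)


class TestRemoveTimeBins:
    def test_identity_and_half(self):
        sm = SpikeMatrix(np.ones((3, 20), dtype=int), 0.02)
        assert np.array_equal(syn.remove_time_bins(sm, 0).counts, sm.counts)
        out = syn.remove_time_bins(sm, 10, seed=0)
        assert out.n_bins == 20
        assert (out.counts.sum(axis=0) == 0).sum() == 10
        assert out.total_spikes <= sm.total_spikes

    def test_too_many_bins_raises(self):
        sm = SpikeMatrix(np.ones((3, 20), dtype=int), 0.02)
        with pytest.raises(ValueError):
            syn.remove_time_bins(sm, 21)


class TestMakeReplayEvent:
    def test_bin_count_at_ripple_timescale(self, track_session):
        ev = syn.make_replay_event(track_session["truth"], np.array([5.0, 195.0]),
                                   delta=0.02, duration=0.2, seed=0)
        assert ev.counts.n_bins == 10

    def test_zero_gain_empty(self, track_session):
        truth = track_session["truth"]
        ev = syn.make_replay_event(truth, np.array([5.0, 195.0]), gain=0.0, seed=0)
        assert ev.counts.total_spikes == 0

    def test_reverse_flips_path(self, track_session):
        f = syn.make_replay_event(track_session["truth"], np.array([5.0, 195.0]),
                                  direction="forward", seed=0)
        r = syn.make_replay_event(track_session["truth"], np.array([5.0, 195.0]),
                                  direction="reverse", seed=0)
        assert np.allclose(f.path, r.path[::-1])
        assert f.direction == "forward" and r.direction == "reverse"

    def test_empty_path_raises(self, track_session):
        with pytest.raises(ValueError):
            syn.make_replay_event(track_session["truth"], np.array([5.0]), seed=0)
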