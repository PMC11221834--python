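"""Synthetic-data generator: determinism, calibration, rate fidelity."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import spearmanr

from ripplenf.offline import ConsensusRippleDetector
from ripplenf.signals import RippleSeries
from ripplenf.synth import (
    SessionConfig,
    SizeDistribution,
    gen_background_lfp,
    gen_event_times,
    gen_movement_spikes,
    gen_place_model,
    gen_replay_spikes,
    GroundTruthEvent,
    inject_ripple,
)
from ripplenf.track import TrackGraph, make_eight_arm_maze


class TestBackground:
    def test_empty_duration_gives_empty_traces(self):
        lfp = gen_background_lfp(SessionConfig(duration=0.0))
        assert lfp.n_samples == 0

    def test_deterministic_under_seed(self):
        a = gen_background_lfp(SessionConfig(duration=2.0, rng_seed=1))
        b = gen_background_lfp(SessionConfig(duration=2.0, rng_seed=1))
        np.testing.assert_array_equal(a.data, b.data)

    def test_length_arithmetic(self):
        lfp = gen_background_lfp(SessionConfig(duration=10.0, fs=1500.0, n_tetrodes=3))
        assert lfp.data.shape == (3, 15000)

    def test_tetrodes_independent(self):
        lfp = gen_background_lfp(SessionConfig(duration=5.0, rng_seed=2))
        c = np.corrcoef(lfp.data)
        off = c[~np.eye(c.shape[0], dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SessionConfig(duration=-1.0)
        with pytest.raises(ValueError):
            SessionConfig(fs=400.0)  # below twice the upper ripple frequency
        with pytest.raises(ValueError):
            SessionConfig(swr_rate_by_state={"moving": -0.1})


class TestInjectRipple:
    def test_zero_amplitude_leaves_trace_unchanged(self, background_600):
        lfp, stats, _ = background_600
        trace = RippleSeries(lfp.data[:, :30000].copy(), lfp.fs)
        before = trace.data.copy()
        inject_ripple(trace, 10.0, 0.0, 0.08, 200.0, np.random.default_rng(0), stats)
        np.testing.assert_array_equal(trace.data, before)

    def test_disjoint_injections_additive_and_order_independent(self, background_600):
        lfp, stats, _ = background_600
        base = lfp.data[:, :90000]
        a = RippleSeries(base.copy(), lfp.fs)
        b = RippleSeries(base.copy(), lfp.fs)
        inject_ripple(a, 20.0, 5.0, 0.08, 200.0, np.random.default_rng(1), stats)
        inject_ripple(a, 40.0, 8.0, 0.06, 180.0, np.random.default_rng(2), stats)
        inject_ripple(b, 40.0, 8.0, 0.06, 180.0, np.random.default_rng(2), stats)
        inject_ripple(b, 20.0, 5.0, 0.08, 200.0, np.random.default_rng(1), stats)
        np.testing.assert_allclose(a.data, b.data, rtol=0, atol=1e-9)

    def test_out_of_bounds_injection_rejected(self, background_600):
        lfp, stats, _ = background_600
        trace = RippleSeries(lfp.data[:, :3000].copy(), lfp.fs)
        with pytest.raises(ValueError):
            inject_ripple(trace, 1.99, 5.0, 0.08, 200.0, np.random.default_rng(0), stats)

    def test_mean_measured_size_matches_requested(self):
        # Single-event measurement is noise-limited by phase interference
        # with in-band background (~±1.5 SD per realization), so the
        # calibration contract is checked on the mean over realizations.
        measured = {6.0: [], 8.0: []}
        for seed in range(40):
            cfg = SessionConfig(duration=60.0, rng_seed=1000 + seed)
            lfp = gen_background_lfp(cfg)
            rng = np.random.default_rng(seed)
            inject_ripple(lfp, 20.0, 6.0, 0.08, 200.0, rng)
            inject_ripple(lfp, 40.0, 8.0, 0.08, 200.0, rng)
            det = ConsensusRippleDetector().fit(lfp)
            for amp, t in ((6.0, 20.0), (8.0, 40.0)):
                hits = [e.size for e in det.events_ if e.t_start < t < e.t_end]
                if hits:
                    measured[amp].append(hits[0])
        for amp, window in ((6.0, (5.4, 6.6)), (8.0, (7.2, 8.8))):
            vals = measured[amp]
            assert len(vals) >= 35
            assert window[0] <= np.mean(vals) <= window[1]

    def test_calibration_spearman_over_amplitude_sweep(self, background_600):
        lfp, stats, _ = background_600
        trace = lfp.copy()
        trace._bg_stats = stats
        rng = np.random.default_rng(3)
        amps = np.linspace(2, 20, 50)
        times = np.linspace(5, 595, 50)
        for a, t in zip(amps, times):
            inject_ripple(trace, t, a, rng.uniform(0.04, 0.12) * 0 + 0.08,
                          rng.uniform(150, 250), rng, stats)
        det = ConsensusRippleDetector().fit(trace)
        measured = np.full(50, np.nan)
        for i, t in enumerate(times):
            hits = [e.size for e in det.events_ if e.t_start < t < e.t_end]
            if hits:
                measured[i] = hits[0]
        ok = ~np.isnan(measured)
        assert ok.sum() >= 45
        rho = spearmanr(amps[ok], measured[ok]).statistic
        assert rho > 0.95


class TestEventTimes:
    def test_zero_rate_gives_no_events(self, rng):
        out = gen_event_times([(0, 100, "rest")], {"rest": 0.0}, rng)
        assert out.size == 0

    def test_poisson_count_within_3sd(self, rng):
        out = gen_event_times(
            [(0, 2000, "rest")], {"rest": 0.5}, rng, min_gap=0.0
        )
        assert abs(out.size - 1000) < 3 * np.sqrt(1000)

    def test_min_gap_enforced(self, rng):
        out = gen_event_times([(0, 500, "rest")], {"rest": 2.0}, rng, min_gap=0.1)
        assert np.all(np.diff(out) >= 0.1)

    def test_overlapping_intervals_rejected(self, rng):
        with pytest.raises(ValueError):
            gen_event_times(
                [(0, 10, "rest"), (5, 15, "moving")], {"rest": 1, "moving": 1}, rng
            )

    def test_negative_rate_rejected(self, rng):
        with pytest.raises(ValueError):
            gen_event_times([(0, 10, "rest")], {"rest": -1.0}, rng)

    def test_state_rates_respected(self, rng):
        intervals = [(0, 1000, "rest"), (1000, 2000, "moving")]
        out = gen_event_times(
            intervals, {"rest": 0.4, "moving": 0.02}, rng, min_gap=0.0
        )
        n_rest = np.sum(out < 1000)
        n_move = out.size - n_rest
        assert abs(n_rest - 400) < 3 * np.sqrt(400)
        assert abs(n_move - 20) < 3 * np.sqrt(20) + 3


class TestPlaceModel:
    def test_single_cell_valid(self, track, rng):
        model = gen_place_model(1, track, rng)
        assert model.n_cells == 1
        assert np.all(np.linalg.eigvalsh(model.mark_cov[0]) > 0)

    def test_centers_lie_on_track_bins(self, track, rng):
        model = gen_place_model(25, track, rng)
        assert np.all(np.isin(model.field_center, track.bin_centers_linear))

    def test_mean_spacing_on_three_meter_track(self, rng):
        # a single straight 300 cm corridor: 30 cells -> ~10 cm spacing
        g = TrackGraph(
            segment_names=["home", "center"] + [f"arm{i}" for i in range(1, 9)],
            segment_lengths=np.array([5.0, 300.0] + [5.0] * 8),
            segment_p0=np.array([(0, -5)] + [(0, 0)] * 9, dtype=float),
            segment_p1=np.array([(0, 0)] + [(0, 300)] + [(0, 300)] * 8, dtype=float),
            bin_size=5.0,
        )
        centers = np.sort(
            gen_place_model(30, g, rng, mark_range=(60, 500)).field_center
        )
        spacing = np.diff(centers)
        assert 7.0 < spacing.mean() < 14.0

    def test_mark_means_separated(self, track, rng):
        model = gen_place_model(30, track, rng, min_mark_separation=6.0, mark_sd=20.0)
        d = np.linalg.norm(
            model.mark_mean[:, None, :] - model.mark_mean[None, :, :], axis=2
        )
        np.fill_diagonal(d, np.inf)
        assert d.min() / 20.0 >= 6.0

    def test_invalid_cell_count_rejected(self, track, rng):
        with pytest.raises(ValueError):
            gen_place_model(0, track, rng)


class TestMovementSpikes:
    def test_parked_at_field_center_poisson_count(self, track, rng):
        model = gen_place_model(1, track, rng)
        model.peak_rate[:] = 20.0
        t = np.arange(0, 10, 1 / 30)
        x = np.full(t.size, model.field_center[0])
        trains = gen_movement_spikes(t, x, model, rng)
        n = sum(tr.n_spikes for tr in trains)
        assert abs(n - 200) < 3 * np.sqrt(200)

    def test_parked_far_from_field_is_silent(self, track, rng):
        model = gen_place_model(1, track, rng, field_width=8.0)
        center_bin = track.bin_of_linear(model.field_center)[0]
        far = np.argmax(track.bin_distances[center_bin])
        t = np.arange(0, 10, 1 / 30)
        x = np.full(t.size, track.bin_centers_linear[far])
        trains = gen_movement_spikes(t, x, model, rng)
        assert sum(tr.n_spikes for tr in trains) == 0

    def test_mark_sample_mean_matches_model(self, track):
        rng = np.random.default_rng(5)
        model = gen_place_model(1, track, rng, mark_sd=20.0)
        model.peak_rate[:] = 40.0
        t = np.arange(0, 60, 1 / 30)
        x = np.full(t.size, model.field_center[0])
        trains = gen_movement_spikes(t, x, model, rng)
        marks = np.concatenate([tr.marks for tr in trains if tr.n_spikes])
        se = 20.0 / np.sqrt(marks.shape[0])
        assert np.all(np.abs(marks.mean(axis=0) - model.mark_mean[0]) < 3 * se)

    def test_out_of_bounds_trajectory_rejected(self, track, rng):
        model = gen_place_model(2, track, rng)
        t = np.arange(0, 1, 1 / 30)
        with pytest.raises(ValueError):
            gen_movement_spikes(t, np.full(t.size, track.total_length + 50), model, rng)

    def test_slow_sampling_rejected(self, track, rng):
        model = gen_place_model(2, track, rng)
        t = np.arange(0, 10, 0.1)  # 10 Hz
        with pytest.raises(ValueError):
            gen_movement_spikes(t, np.full(t.size, 10.0), model, rng)


class TestReplaySpikes:
    def test_single_bin_path_spikes_only_from_resident_cells(self, track, rng):
        model = gen_place_model(30, track, rng)
        ev = GroundTruthEvent(time=1.0, amplitude=8.0, duration=0.1)
        target = track.bin_of("arm3", 40.0)
        trains = gen_replay_spikes(ev, np.array([target]), model, rng, rate_gain=20.0)
        cells = np.concatenate(
            [tr.cell_ids for tr in trains if tr.n_spikes]
        ).astype(int)
        assert cells.size > 0
        d = track.bin_distances[
            track.bin_of_linear(model.field_center[cells]), target
        ]
        assert np.all(d <= 4 * model.field_width[cells])

    def test_reversed_path_flips_spike_order_correlation(self, track):
        # spike times rank-correlate with position along the replayed path;
        # reversing the path flips the sign (positions measured from the
        # forward path's start, cells restricted to the path neighborhood)
        rng = np.random.default_rng(9)
        model = gen_place_model(30, track, rng)
        ev = GroundTruthEvent(time=0.0, amplitude=8.0, duration=0.2)
        path = np.flatnonzero(track.bin_segment == track.segment_index("arm1"))
        center_bins = track.bin_of_linear(model.field_center)
        path_dist = track.bin_distances[path[0], center_bins]
        near = track.bin_distances[np.ix_(center_bins, path)].min(axis=1) <= (
            2 * model.field_width
        )

        def mean_rank_corr(p):
            rhos = []
            for rep in range(40):
                trains = gen_replay_spikes(
                    ev, p, model, np.random.default_rng(rep), rate_gain=30.0
                )
                times = np.concatenate([t.times for t in trains])
                cells = np.concatenate(
                    [t.cell_ids for t in trains if t.n_spikes]
                ).astype(int)
                keep = near[cells]
                if keep.sum() < 5:
                    continue
                rho = spearmanr(times[keep], path_dist[cells[keep]]).statistic
                if np.isfinite(rho):
                    rhos.append(rho)
            return np.mean(rhos)

        fwd = mean_rank_corr(path)
        rev = mean_rank_corr(path[::-1])
        assert fwd > 0.3
        assert rev < -0.3

    def test_traversal_length_arithmetic(self, track, rng):
        model = gen_place_model(30, track, rng)
        ev = GroundTruthEvent(time=0.0, amplitude=8.0, duration=0.1)
        seg = track.segment_index("arm2")
        path = np.flatnonzero(track.bin_segment == seg)
        # compression 20 x 30 cm/s x 0.1 s = 60 cm = 12 bins of the 16-bin arm
        trains = gen_replay_spikes(
            ev, path, model, rng, compression=20.0, run_speed=30.0, rate_gain=40.0
        )
        cells = np.concatenate([t.cell_ids for t in trains if t.n_spikes]).astype(int)
        on_arm = cells[track.bin_segment[track.bin_of_linear(model.field_center[cells])] == seg]
        assert on_arm.size > 0
        max_arc = (
            model.field_center[on_arm].max() - track.bin_centers_linear[path[0]]
        )
        assert max_arc <= 60.0 + 3 * model.field_width.max()

    def test_empty_path_rejected(self, track, rng):
        model = gen_place_model(3, track, rng)
        ev = GroundTruthEvent(time=0.0, amplitude=5.0, duration=0.1)
        with pytest.raises(ValueError):
            gen_replay_spikes(ev, np.array([], dtype=int), model, rng)

    def test_disconnected_path_rejected(self, track, rng):
        model = gen_place_model(3, track, rng)
        ev = GroundTruthEvent(time=0.0, amplitude=5.0, duration=0.1)
        arm1 = np.flatnonzero(track.bin_segment == 2)
        arm2 = np.flatnonzero(track.bin_segment == 3)
        with pytest.raises(ValueError):
            gen_replay_spikes(ev, np.array([arm1[3], arm2[3]]), model, rng)


class TestPipelineSelfConsistency:
    def test_pre_reward_rate_contrast_recovered_through_detection(self):
        # two sessions whose pre-reward injection rates differ 10x; the
        # offline pipeline recovers the contrast on >= 4 SD events (the
        # detector's ~0.25/s false-event floor lives below 4 SD and would
        # otherwise compress the ratio)
        from ripplenf.behavior import period_metrics
        from ripplenf.task import AgentPolicy, SessionSimulator, TaskConfig

        rates = []
        for pre_rate, seed in ((0.6, 301), (0.06, 302)):
            cfg = SessionConfig(duration=0, rng_seed=seed)
            task = TaskConfig(threshold_start=8.0, threshold_max=8.0, ramp_days=1)
            agent = AgentPolicy(
                travel_time_range=(0.5, 1.0),
                post_dwell_mean={"neurofeedback": 1.0, "delay": 1.0, "control": 1.0},
            )
            sim = SessionSimulator(
                cfg, task, agent=agent, cohort="control",
                rate_overrides={("control", "pre"): pre_rate},
            )
            sess = sim.run_epoch(n_trials=30)
            events = ConsensusRippleDetector().fit(sess.lfp).events_
            big = [e for e in events if e.size >= 4.0]
            m = period_metrics(sess.trials, big)
            rates.append(m["pre_rate"].mean())
        assert 5.0 < rates[0] / rates[1] < 20.0


class TestSizeDistribution:
    def test_sample_matches_survival_function(self):
        d = SizeDistribution()
        x = d.sample(np.random.default_rng(0), 200000)
        for q in (5.0, 10.0, 20.0):
            emp = np.mean(x >= q)
            assert abs(emp - d.sf(q)) < 0.005

    def test_long_tailed(self):
        d = SizeDistribution()
        assert d.sf(10) > d.sf(20) > d.sf(40) > 0
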