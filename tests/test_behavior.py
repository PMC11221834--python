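"""Behavior metrics and the statistics layer."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from ripplenf.behavior import (
    benjamini_hochberg,
    groupwise_model,
    performance_metrics,
    period_metrics,
    prepost_correlation,
    sign_test_fraction,
    speed_quartile_analysis,
    timewise_rate,
    within_subject_compare,
)
from ripplenf.signals import SwrEvent
from ripplenf.task import Trial


def _trial(index, ttype="neurofeedback", poke=0.0, reward=8.0, exit_=12.0,
           trigger=None, supra=()):
    t = Trial(index=index, type=ttype)
    t.t_center_poke = poke
    t.t_reward = reward
    t.t_center_exit = exit_
    t.trigger_event = trigger
    t.online_suprathreshold_times = list(supra)
    return t


def _event(t_peak, size=5.0):
    return SwrEvent(t_start=t_peak - 0.03, t_end=t_peak + 0.03, t_peak=t_peak, size=size)


class TestTimewiseRate:
    def test_rate_arithmetic_across_trials(self):
        # 200 identical trials; 3 events in the bin [-1.0, -0.5) of 3 trials
        trials = [
            _trial(i, poke=100.0 * i, reward=100.0 * i + 8, exit_=100.0 * i + 12)
            for i in range(200)
        ]
        events = [_event(100.0 * i + 7.2) for i in range(3)]
        out = timewise_rate(trials, events, min_trials=100)
        assert out.loc[-1.0, "n_trials"] == 200
        assert out.loc[-1.0, "rate"] == pytest.approx(3 / (200 * 0.5))

    def test_bins_with_few_trials_omitted(self):
        trials = [
            _trial(i, poke=100.0 * i, reward=100.0 * i + 8, exit_=100.0 * i + 12)
            for i in range(99)
        ]
        out = timewise_rate(trials, [], min_trials=100)
        assert out.empty

    def test_trigger_event_excluded(self):
        trigger = _event(7.9, size=10)
        trials = [_trial(0, trigger=trigger)]
        out = timewise_rate(trials, [trigger], min_trials=1)
        assert (out["rate"] == 0).all()
        out2 = timewise_rate(trials, [trigger], min_trials=1, exclude_trigger=False)
        assert out2.loc[-0.5, "rate"] > 0

    def test_constant_rate_generator_flat_curve(self):
        rng = np.random.default_rng(0)
        trials = []
        events = []
        for i in range(300):
            poke = 100.0 * i
            trials.append(_trial(i, poke=poke, reward=poke + 8, exit_=poke + 12))
            n = rng.poisson(0.6 * 12)
            for t in rng.uniform(poke, poke + 12, n):
                events.append(_event(t))
        out = timewise_rate(trials, events, min_trials=100)
        # all bins within their own 3-SEM band of the configured 0.6/s
        assert np.all(np.abs(out["rate"] - 0.6) < 3.5 * out["sem"] + 0.05)


class TestPeriodMetrics:
    def test_rate_arithmetic(self):
        trials = [_trial(0)]
        events = [_event(1.0), _event(3.0), _event(5.0), _event(7.0)]
        df = period_metrics(trials, events)
        assert df.loc[0, "pre_count"] == 4
        assert df.loc[0, "pre_rate"] == pytest.approx(0.5)

    def test_conservation_without_exclusions(self):
        rng = np.random.default_rng(1)
        trials = [_trial(0, exit_=20.0)]
        events = [_event(t) for t in rng.uniform(0, 20, 30)]
        df = period_metrics(trials, events, exclude_trigger=False)
        in_port = sum(1 for e in events if 0 <= e.t_peak < 20.0)
        assert df.loc[0, "pre_count"] + df.loc[0, "post_count"] == in_port

    def test_trigger_exclusion_removes_exactly_one_per_nf_trial(self):
        trials = []
        events = []
        for i in range(10):
            poke = 100.0 * i
            trig = _event(poke + 7.9, size=12)
            trials.append(
                _trial(i, poke=poke, reward=poke + 8, exit_=poke + 12, trigger=trig)
            )
            events.extend([trig, _event(poke + 2.0), _event(poke + 4.0)])
        with_excl = period_metrics(trials, events, exclude_trigger=True)
        without = period_metrics(trials, events, exclude_trigger=False)
        diff = without["pre_count"] - with_excl["pre_count"]
        assert (diff == 1).all()

    def test_suprathreshold_exclusion_applies_to_delay_trials(self):
        supra = _event(3.0, size=15)
        trials = [_trial(0, ttype="delay", supra=[3.0])]
        events = [supra, _event(5.0, size=4)]
        df = period_metrics(trials, events, exclude_suprathreshold=True)
        assert df.loc[0, "pre_count"] == 1
        df2 = period_metrics(trials, events)
        assert df2.loc[0, "pre_count"] == 2

    def test_negative_duration_rejected(self):
        bad = _trial(0, reward=5.0)
        bad.t_center_exit = 4.0
        with pytest.raises(ValueError):
            period_metrics([bad], [])

    def test_timeout_trial_skipped_with_flag(self):
        t = Trial(index=0, type="neurofeedback", timeout=True)
        df = period_metrics([t], [])
        assert df.loc[0, "skipped"]


class TestSpeedQuartiles:
    def _metrics(self, speeds_by_type):
        rows = []
        i = 0
        for ttype, speeds in speeds_by_type.items():
            for s in speeds:
                rows.append(
                    {
                        "trial": i, "type": ttype, "pre_speed": s,
                        "pre_rate": 0.5, "skipped": False,
                    }
                )
                i += 1
        return pd.DataFrame(rows)

    def test_quartile_selection_extremes(self):
        m = self._metrics(
            {
                "neurofeedback": [1, 2, 3, 4, 5, 6, 7, 8],
                "delay": [1, 2, 3, 4, 5, 6, 7, 8],
                "control": [1, 2, 3, 4, 5, 6, 7, 8],
            }
        )
        out = speed_quartile_analysis(m)
        assert sorted(out["subsets"]["neurofeedback"]["pre_speed"]) == [7, 8]
        assert sorted(out["subsets"]["delay"]["pre_speed"]) == [1, 2]
        assert "nf_vs_delay" in out["comparisons"]

    def test_ties_broken_by_trial_index(self):
        m = self._metrics({"neurofeedback": [2.0] * 8, "delay": [2.0] * 8})
        out = speed_quartile_analysis(m)
        nf = out["subsets"]["neurofeedback"]
        assert list(nf["trial"]) == sorted(nf["trial"])

    def test_too_few_trials_flagged(self):
        m = self._metrics({"neurofeedback": [1, 2], "delay": [1, 2, 3, 4, 5]})
        out = speed_quartile_analysis(m)
        assert any("neurofeedback" in f for f in out["flags"])


class TestPerformanceMetrics:
    @staticmethod
    def _seq(specs):
        trials = []
        for i, (ttype, phase, block, arm, goal) in enumerate(specs):
            t = Trial(index=i, type=ttype)
            t.t_center_poke, t.t_reward, t.t_center_exit = 0.0, 1.0, 2.0
            t.phase = phase
            t.goal_block = block
            t.arm_choice = arm
            t.goal_arm = goal
            trials.append(t)
        return trials

    def test_search_efficiency_counts_novel_choices(self):
        # 10 search trials, 7 of them novel arm choices
        specs = []
        arms = [1, 2, 3, 1, 4, 2, 5, 6, 3, 7]  # revisits at idx 3, 5, 8
        for a in arms:
            specs.append(("neurofeedback", "search", 1, a, 8))
        out = performance_metrics(self._seq(specs))
        assert out["search_efficiency"] == pytest.approx(0.7)
        assert out["n_redundant"] == 3

    def test_history_resets_at_goal_switch(self):
        specs = [
            ("delay", "search", 1, 1, 2),
            ("delay", "search", 1, 1, 2),  # redundant
            ("delay", "search", 2, 1, 3),  # new block: novel again
        ]
        out = performance_metrics(self._seq(specs))
        assert out["n_redundant"] == 1

    def test_correct_repeat_and_error_fractions(self):
        specs = [
            ("neurofeedback", "repeat", 1, 4, 4),
            ("delay", "repeat", 1, 4, 4),
            ("neurofeedback", "repeat", 1, 2, 4),  # NF error
            ("delay", "repeat", 1, 4, 4),
        ]
        out = performance_metrics(self._seq(specs))
        assert out["correct_repeat_fraction"] == pytest.approx(0.75)
        assert out["error_nf_fraction"] == 1.0

    def test_no_search_trials_flagged(self):
        out = performance_metrics(
            self._seq([("delay", "repeat", 1, 4, 4)])
        )
        assert np.isnan(out["search_efficiency"])
        assert "no search trials" in out["flags"]


class TestStatisticsLayer:
    def test_bh_hand_computed_stepup(self):
        adj = benjamini_hochberg(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_bh_matches_brute_force_on_random_vectors(self, rng):
        def brute(p):
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 30))
            np.testing.assert_allclose(benjamini_hochberg(p), brute(p), atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self, rng):
        p = rng.uniform(size=25)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_within_subject_null_p_uniform(self):
        rng = np.random.default_rng(2)
        pvals = []
        for _ in range(300):
            a = rng.standard_normal(60)
            b = rng.standard_normal(60)
            pvals.append(sstats.ranksums(a, b).pvalue)
        ks = sstats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_within_subject_frame_shape(self):
        df = within_subject_compare(
            [np.arange(10), np.arange(5), np.array([])],
            [np.arange(10) + 5, np.arange(5), np.arange(3)],
        )
        assert df.loc[2, "skipped"]
        assert (df.loc[~df["skipped"], "p_adjusted"] >= df.loc[~df["skipped"], "p_raw"] - 1e-15).all()

    def test_sign_test_values(self):
        assert sign_test_fraction(5, 10) == pytest.approx(1.0)
        assert sign_test_fraction(0, 10) == pytest.approx(2 * 0.5**10)
        assert sign_test_fraction(10, 10) == sign_test_fraction(0, 10)
        assert np.isnan(sign_test_fraction(0, 0))

    def test_prepost_correlation_signs(self):
        rng = np.random.default_rng(3)
        pre = rng.standard_normal(100)
        df = pd.DataFrame(
            {
                "subject": "a",
                "pre_count": pre,
                "post_count": pre,
                "pre_rate": pre,
                "post_rate": -pre + 0.01 * rng.standard_normal(100),
                "pre_dur": pre,
                "post_dwell": rng.standard_normal(100),
            }
        )
        out = prepost_correlation(df).set_index("measure")
        assert out.loc["count", "r"] == pytest.approx(1.0)
        assert out.loc["rate", "r"] < -0.99
        assert abs(out.loc["dwell", "r"]) < 0.3

    def test_prepost_degenerate_flagged(self):
        df = pd.DataFrame(
            {
                "subject": "a",
                "pre_count": [1.0, 1.0, 1.0],
                "post_count": [1.0, 2.0, 3.0],
            }
        )
        out = prepost_correlation(df)
        assert out.loc[out["measure"] == "count", "flagged"].item()


class TestGroupwiseModel:
    @staticmethod
    def _data(rng, effect_nf=0.0, effect_delay=0.0, n_subj=4, n_trials=60,
              subject_sd=0.2, counts=False):
        rows = []
        for cohort, label in (("control", "control"), ("manip", None)):
            for s in range(n_subj):
                intercept = 1.0 + subject_sd * rng.standard_normal()
                for i in range(n_trials):
                    if cohort == "control":
                        group = "control"
                        mu = intercept
                    else:
                        group = "manip-NF" if i % 2 == 0 else "manip-delay"
                        mu = intercept + (
                            effect_nf if group == "manip-NF" else effect_delay
                        )
                    val = (
                        rng.poisson(max(mu, 0.05))
                        if counts
                        else mu + 0.5 * rng.standard_normal()
                    )
                    rows.append(
                        {"subject": f"{cohort}{s}", "group": group, "value": val}
                    )
        return pd.DataFrame(rows)

    def test_effect_recovery(self):
        rng = np.random.default_rng(4)
        data = self._data(rng, effect_nf=0.5, n_trials=200)
        comp = groupwise_model(data, family="linear")
        assert comp.coefficients["nf_vs_control"] == pytest.approx(0.5, abs=0.15)
        assert comp.p_values["nf_vs_control"] < 0.01
        assert comp.p_values["delay_vs_control"] > 0.01

    def test_poisson_family_on_counts(self):
        rng = np.random.default_rng(5)
        data = self._data(rng, effect_nf=1.0, counts=True, n_trials=150)
        comp = groupwise_model(data, family="poisson")
        assert comp.coefficients["nf_vs_control"] > 0.2
        assert comp.p_values["nf_vs_control"] < 0.05

    def test_poisson_family_requires_integer_counts(self):
        rng = np.random.default_rng(6)
        data = self._data(rng)
        with pytest.raises(ValueError):
            groupwise_model(data, family="poisson")

    def test_single_subject_cohort_refused(self):
        rng = np.random.default_rng(7)
        data = self._data(rng, n_subj=1)
        comp = groupwise_model(data, family="linear")
        assert comp.flags
        assert not comp.p_values

    def test_unknown_family_rejected(self):
        rng = np.random.default_rng(8)
        with pytest.raises(ValueError):
            groupwise_model(self._data(rng), family="gamma")
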