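"""Closed-loop neurofeedback task engine.

Simulates the eight-arm spatial memory task with an embedded SWR
neurofeedback contingency, driving the online detector against streamed
synthetic LFP:

* Each trial: home-port poke → center-port poke → pre-reward period →
  reward → post-reward dwell → arm choice → (large reward at the goal arm).
* On **neurofeedback trials** the pre-reward period runs until the online
  detector triggers on the live LFP stream; tone/reward follow after the
  per-subject feedback delay (50–100 ms).
* On **delay trials** the pre-reward duration is *yoked*: drawn uniformly
  from the trigger latencies of the 8 most recent neurofeedback trials, so
  total waiting time at the two center ports is approximately matched.
* **Control** trials (control cohort) wait a random delay independent of
  neural activity.
* The detection threshold ramps across days from ``threshold_start`` to
  ``threshold_max`` and, within each epoch, from ``threshold_start`` to the
  day's maximum over the first ~10 neurofeedback trials.
* One of eight arms is rewarded at a time; after a drawn quota of 4–12
  rewarded visits the goal moves to a different arm (a new *goal block*,
  opening with *search* trials until the goal is found, then *repeat*
  trials).

The module also owns the wait-time prediction analysis: size-binned SWR
occurrence rates and the renewal-style predicted wait per trigger size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .offline import RIPPLE_BAND
from .online import OnlineRippleDetector
from .signals import MarkedSpikeTrain, RippleSeries, SwrEvent
from .synth import (
    RUN_SPEED,
    BackgroundNoise,
    BackgroundStats,
    GroundTruthEvent,
    PlaceModel,
    SessionConfig,
    estimate_background_stats,
    gen_place_model,
    gen_replay_spikes,
    gen_movement_spikes,
    merge_spike_trains,
    ripple_waveform,
)
from .track import TrackGraph, make_eight_arm_maze

N_ARMS = 8


# ---------------------------------------------------------------------------
# configuration


@dataclass
class TaskConfig:
    """Task rules and closed-loop settings."""

    threshold_start: float = 4.0
    threshold_max: float = 18.0  # protocol ceiling, 16–20 SD
    ramp_days: int = 16  # across-day ramp, 14–20 days
    within_epoch_ramp_trials: int = 10
    yoke_window: int = 8
    feedback_delay: float = 0.075  # s; per-subject constant in 0.05–0.10
    reward_small: float = 50.0  # µL
    reward_large: float = 150.0  # µL
    repeats_per_goal: tuple[int, int] = (4, 12)
    timeout_range: tuple[float, float] = (30.0, 45.0)
    immobility_cutoff: float = 4.0  # cm/s
    bootstrap_delay_range: tuple[float, float] = (2.0, 10.0)
    control_delay_range: tuple[float, float] = (2.0, 10.0)
    nf_trigger_cap: float = 300.0  # s; NF trial aborted if no trigger
    min_coincident_tetrodes: int = 2
    online_n_tetrodes: int = 4  # subset used by the online detector

    def __post_init__(self) -> None:
        if self.threshold_start > self.threshold_max:
            raise ValueError("threshold_start must be <= threshold_max")
        if self.yoke_window < 1:
            raise ValueError("yoke_window must be >= 1")


@dataclass
class AgentPolicy:
    """Parametric behavioral policy with controllable ground truth.

    The knobs exist so that task-performance metrics have known expected
    values: ``p_repeat_sample`` directly sets (one minus) search efficiency,
    ``p_correct_repeat`` the correct-repeat fraction.
    """

    p_correct_repeat: float = 0.85
    p_repeat_sample: float = 0.2
    post_dwell_mean: dict = field(
        default_factory=lambda: {"neurofeedback": 4.0, "delay": 5.0, "control": 8.0}
    )
    post_dwell_shape: float = 4.0  # gamma shape
    pre_speed_mean: dict = field(
        default_factory=lambda: {"neurofeedback": 1.5, "delay": 2.0, "control": 2.0}
    )
    post_speed_mean: float = 2.0
    speed_sd: float = 0.8
    travel_time_range: tuple[float, float] = (2.0, 4.0)
    p_violation: float = 0.0  # trial-order violation -> timeout

    def choose_arm(self, goal_state: "GoalState", rng: np.random.Generator) -> int:
        if goal_state.phase == "repeat":
            if rng.random() < self.p_correct_repeat:
                return goal_state.goal_arm
            others = [a for a in range(1, N_ARMS + 1) if a != goal_state.goal_arm]
            return int(rng.choice(others))
        sampled = goal_state.sampled_arms
        unsampled = [a for a in range(1, N_ARMS + 1) if a not in sampled]
        if sampled and (not unsampled or rng.random() < self.p_repeat_sample):
            return int(rng.choice(sorted(sampled)))
        if not unsampled:
            return int(rng.integers(1, N_ARMS + 1))
        return int(rng.choice(unsampled))

    def post_dwell(self, trial_type: str, rng: np.random.Generator) -> float:
        mean = self.post_dwell_mean[trial_type]
        k = self.post_dwell_shape
        return float(rng.gamma(k, mean / k))

    def speed_trace(
        self, duration: float, mean: float, rng: np.random.Generator, fs: float = 30.0
    ) -> np.ndarray:
        n = max(int(round(duration * fs)), 1)
        return np.abs(mean + self.speed_sd * rng.standard_normal(n))


# ---------------------------------------------------------------------------
# trial bookkeeping


@dataclass
class GoalState:
    """Goal-block bookkeeping: which arm pays, and where in the block we are."""

    goal_arm: int
    quota: int
    rewarded_count: int = 0
    phase: str = "search"  # search until first rewarded visit of the block
    block: int = 1
    sampled_arms: set = field(default_factory=set)
    prev_goal_arm: int | None = None


def goal_controller(
    state: GoalState, arm_choice: int, rng: np.random.Generator,
    repeats_per_goal: tuple[int, int] = (4, 12),
) -> tuple[bool, GoalState]:
    """Settle one arm visit: reward iff the goal arm was chosen.

    After the block's drawn quota of rewarded visits the goal is redrawn
    uniformly from the other seven arms and a new block begins in *search*
    phase with the sampling history cleared.
    """
    if not 1 <= arm_choice <= N_ARMS:
        raise ValueError(f"arm_choice must be in 1..{N_ARMS}")
    new = GoalState(
        goal_arm=state.goal_arm,
        quota=state.quota,
        rewarded_count=state.rewarded_count,
        phase=state.phase,
        block=state.block,
        sampled_arms=set(state.sampled_arms),
        prev_goal_arm=state.prev_goal_arm,
    )
    rewarded = arm_choice == new.goal_arm
    if new.phase == "search":
        new.sampled_arms.add(arm_choice)
    if rewarded:
        new.rewarded_count += 1
        if new.phase == "search":
            new.phase = "repeat"
        if new.rewarded_count >= new.quota:
            new.prev_goal_arm = new.goal_arm
            others = [a for a in range(1, N_ARMS + 1) if a != new.goal_arm]
            new.goal_arm = int(rng.choice(others))
            new.quota = int(rng.integers(repeats_per_goal[0], repeats_per_goal[1] + 1))
            new.rewarded_count = 0
            new.phase = "search"
            new.block += 1
            new.sampled_arms = set()
    return rewarded, new


@dataclass
class Trial:
    """One behavioral trial with its latent state and event bookkeeping."""

    index: int
    type: str  # neurofeedback | delay | control
    t_home_poke: float = np.nan
    t_center_poke: float = np.nan
    t_reward: float = np.nan
    t_center_exit: float = np.nan
    t_arm_poke: float = np.nan
    center_port: int = 0
    arm_choice: int = 0
    goal_arm: int = 0
    prev_arm: int | None = None
    prev_goal_arm: int | None = None
    rewarded: bool = False
    phase: str = "search"
    goal_block: int = 1
    threshold_sd: float = np.nan  # online threshold in force during this trial
    trigger_event: SwrEvent | None = None
    online_suprathreshold_times: list = field(default_factory=list)
    timeout: bool = False
    aborted: bool = False
    pre_speed: np.ndarray | None = None
    post_speed: np.ndarray | None = None

    @property
    def pre_reward_dur(self) -> float:
        """Center-poke to trigger (NF) / to reward delivery (delay, control)."""
        if self.type == "neurofeedback" and self.trigger_event is not None:
            return self.trigger_event.t_peak - self.t_center_poke
        return self.t_reward - self.t_center_poke

    @property
    def post_reward_dur(self) -> float:
        return self.t_center_exit - self.t_reward


def threshold_schedule(
    day: int, nf_trial_index_in_epoch: int, config: TaskConfig
) -> float:
    """Online detection threshold (SD units) for a given day and NF trial.

    The day's maximum interpolates linearly from ``threshold_start`` to
    ``threshold_max`` across ``ramp_days`` and is clamped afterwards (the
    stable period); within an epoch the threshold steps linearly from
    ``threshold_start`` up to the day's maximum over the first
    ``within_epoch_ramp_trials`` neurofeedback trials.
    """
    if day < 1:
        raise ValueError("day must be >= 1")
    if config.ramp_days > 1:
        frac = min(1.0, (day - 1) / (config.ramp_days - 1))
    else:
        frac = 1.0
    day_max = config.threshold_start + frac * (
        config.threshold_max - config.threshold_start
    )
    r = config.within_epoch_ramp_trials
    i = min(max(nf_trial_index_in_epoch, 0), r)
    return config.threshold_start + (day_max - config.threshold_start) * i / r


def sample_yoked_delay(
    history: list[float], config: TaskConfig, rng: np.random.Generator
) -> float:
    """Uniform draw from the most recent ``yoke_window`` NF trigger latencies.

    With no history yet (epoch start), falls back to a uniform draw from the
    configured bootstrap range.
    """
    if not history:
        return float(rng.uniform(*config.bootstrap_delay_range))
    recent = history[-config.yoke_window :]
    return float(recent[rng.integers(len(recent))])


# ---------------------------------------------------------------------------
# wait-time prediction analysis


def size_rate_table(
    events: list[SwrEvent] | np.ndarray,
    total_port_time: float,
    bin_width: float = 1.0,
    min_count: int = 10,
) -> dict[float, float]:
    """Size-binned SWR occurrence rates over center-port time.

    Returns ``{bin_left_edge: events/s}``; bins with fewer than ``min_count``
    events are absent.
    """
    if total_port_time <= 0:
        raise ValueError("total_port_time must be positive")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    sizes = np.asarray(
        [e.size if isinstance(e, SwrEvent) else float(e) for e in events]
    )
    table: dict[float, float] = {}
    if sizes.size == 0:
        return table
    lefts = np.floor(sizes / bin_width) * bin_width
    for left in np.unique(lefts):
        n = int(np.sum(lefts == left))
        if n >= min_count:
            table[float(left)] = n / total_port_time
    return table


def predicted_wait(
    trigger_size: float,
    table: dict[float, float],
    bin_width: float = 1.0,
    mode: str = "cumulative",
) -> float | None:
    """Predicted wait time (s) for a trigger of the given size.

    ``cumulative`` (default): the reciprocal of the summed rate of all
    tabulated bins at or above the trigger's bin — a threshold fires on the
    first event at-or-above it. ``own-bin``: the reciprocal of the trigger
    bin's own rate. Returns None (exclusion) if the trigger's size bin is
    not tabulated.
    """
    left = float(np.floor(trigger_size / bin_width) * bin_width)
    if left not in table:
        return None
    if mode == "own-bin":
        return 1.0 / table[left]
    if mode != "cumulative":
        raise ValueError("mode must be 'cumulative' or 'own-bin'")
    total = sum(rate for b, rate in table.items() if b >= left)
    return 1.0 / total


def moving_average(x: np.ndarray, window: int = 200) -> np.ndarray:
    """Centered moving average with shrinking edges (NaN-tolerant)."""
    import pandas as pd

    return (
        pd.Series(np.asarray(x, dtype=float))
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


# ---------------------------------------------------------------------------
# streaming event source


class _EventSource:
    """Draws SWR events on the fly and renders them into LFP chunks.

    Keeps an overlay buffer so waveforms can straddle chunk boundaries, and
    a running last-event time so the minimum inter-event gap holds across
    periods. Event times are drawn by sequential exponential gaps at the
    currently active rate (exact for a Poisson process, thanks to
    memorylessness at rate changes).
    """

    def __init__(
        self,
        config: SessionConfig,
        stats: BackgroundStats,
        rng: np.random.Generator,
        fs: float,
        n_tetrodes: int,
    ):
        self.config = config
        self.stats = stats
        self.rng = rng
        self.fs = fs
        self.n_tetrodes = n_tetrodes
        self.overlay = np.zeros((n_tetrodes, 0))
        self.cursor = 0  # absolute sample index of overlay[:, 0]
        self.last_event = -np.inf
        self._max_half = int(round(3 * (config.swr_duration_range[1] / 4) * fs))
        # events are drawn one waveform-half ahead of the emitted samples so
        # that no waveform ever needs samples that were already emitted
        self.drawn_until = self._max_half / fs

    def _render(self, event: GroundTruthEvent) -> None:
        phases = self.rng.uniform(0, 2 * np.pi, self.n_tetrodes)
        wave = np.stack(
            [ripple_waveform(self.fs, event.duration, event.freq, p) for p in phases]
        )
        # calibrated height: same power-additivity solution as inject_ripple
        from scipy.ndimage import gaussian_filter1d
        from scipy import signal as sps
        from .offline import _design_bandpass

        sos = _design_bandpass(RIPPLE_BAND, self.fs)
        pad = int(0.05 * self.fs)
        wf = sps.sosfiltfilt(sos, np.pad(wave, ((0, 0), (pad, pad))), axis=1)[
            :, pad:-pad
        ]
        power = gaussian_filter1d(np.sum(wf**2, axis=0), 0.004 * self.fs)
        p_unit = float(np.sqrt(power.max()))
        target = self.stats.epoch_mean + event.amplitude * self.stats.epoch_sd
        a = np.sqrt(max(target**2 - self.stats.mean_power, 0.0)) / p_unit
        m = wave.shape[1]
        center = int(round(event.time * self.fs))
        lo = center - m // 2 - self.cursor
        hi = lo + m
        if hi > self.overlay.shape[1]:
            grow = hi - self.overlay.shape[1]
            self.overlay = np.pad(self.overlay, ((0, 0), (0, grow)))
        if lo < 0:  # should not happen; clip defensively
            wave = wave[:, -lo:]
            lo = 0
        self.overlay[:, lo:hi] += a * wave

    def take(
        self, background: np.ndarray, rate: float, event_meta=None
    ) -> tuple[np.ndarray, list[GroundTruthEvent]]:
        """Add events for the span of ``background``; return chunk + events."""
        n = background.shape[1]
        t_hi = (self.cursor + n) / self.fs
        draw_to = t_hi + self._max_half / self.fs
        # pre-extend the overlay once per call: every event drawn in this
        # window renders within n + 4 half-widths of the cursor (avoids
        # quadratic reallocation when large spans are taken at once)
        need = n + 4 * self._max_half + 2
        if self.overlay.shape[1] < need:
            self.overlay = np.pad(
                self.overlay, ((0, 0), (0, need - self.overlay.shape[1]))
            )
        events: list[GroundTruthEvent] = []
        if rate > 0:
            t = self.drawn_until
            while True:
                t = t + self.rng.exponential(1.0 / rate)
                if t >= draw_to:
                    break
                if t - self.last_event < self.config.min_event_gap:
                    continue
                amp = float(self.config.swr_size_distribution.sample(self.rng, 1)[0])
                dur = float(self.rng.uniform(*self.config.swr_duration_range))
                freq = float(self.rng.uniform(*self.config.ripple_freq_range))
                ev = GroundTruthEvent(time=t, amplitude=amp, duration=dur, freq=freq)
                if event_meta is not None:
                    ev = event_meta(ev)
                self._render(ev)
                events.append(ev)
                self.last_event = t
        self.drawn_until = draw_to
        if self.overlay.shape[1] < n:
            self.overlay = np.pad(
                self.overlay, ((0, 0), (0, n - self.overlay.shape[1]))
            )
        chunk = background + self.overlay[:, :n]
        self.overlay = self.overlay[:, n:]
        self.cursor += n
        return chunk, events


# ---------------------------------------------------------------------------
# the session simulator


@dataclass
class SyntheticSession:
    """One simulated behavioral epoch with full ground truth."""

    lfp: RippleSeries
    trials: list[Trial]
    ground_truth: list[GroundTruthEvent]
    state_intervals: list[tuple[float, float, str]]
    config: SessionConfig
    task_config: TaskConfig
    spikes: list[MarkedSpikeTrain] | None = None
    position: dict | None = None
    track: TrackGraph | None = None
    place_model: PlaceModel | None = None
    day: int = 1

    @property
    def duration(self) -> float:
        return self.lfp.duration


class SessionSimulator:
    """Drives the closed loop: streamed LFP → online detector → trials.

    The background noise, the event overlay, the online band-pass filter and
    the envelope recursion all carry state across chunks, so the session LFP
    is one continuous record no matter how trial periods interleave.

    Parameters
    ----------
    config, task_config : generator and task settings.
    agent : AgentPolicy
    day : training day (sets the threshold ceiling via the ramp).
    cohort : "manipulation" (NF + delay trials) or "control".
    rate_overrides : optional ``{(trial_type, period): events/s}`` map that
        takes precedence over ``config.swr_rate_by_state`` during center-port
        periods (period in {"pre", "post"}); used to configure cohort-level
        effects with equalized totals.
    generate_spikes : also simulate place-cell movement spiking and replay
        spiking inside port SWRs (slower; needed for decoding analyses).
    replay_fractions : (local, remote, none) mix for port-period SWR content.
    """

    def __init__(
        self,
        config: SessionConfig,
        task_config: TaskConfig,
        agent: AgentPolicy | None = None,
        day: int | None = None,
        cohort: str = "manipulation",
        rate_overrides: dict | None = None,
        generate_spikes: bool = False,
        replay_fractions: tuple[float, float, float] = (0.3, 0.5, 0.2),
        remote_arm_weights: dict | None = None,
        chunk_seconds: float = 0.25,
        track: TrackGraph | None = None,
        p_nf: float = 0.5,
        total_rate_target: float | None = None,
        detector: OnlineRippleDetector | None = None,
    ):
        self.config = config
        self.task_config = task_config
        self.agent = agent or AgentPolicy()
        self.day = day if day is not None else task_config.ramp_days + 5
        self.cohort = cohort
        self.rate_overrides = rate_overrides or {}
        self.generate_spikes = generate_spikes
        self.replay_fractions = replay_fractions
        self.remote_arm_weights = remote_arm_weights or {}
        self.chunk = int(round(chunk_seconds * config.fs))
        self.track = track or make_eight_arm_maze()
        self.p_nf = p_nf
        # if set (events/s), the post-reward injection rate is solved per
        # trial so that the trial's total injected center-port rate hits the
        # target — the generator-level expression of "equalized total rates"
        self.total_rate_target = total_rate_target
        # a pre-fitted online detector pins the frozen baselines across
        # sessions (e.g. for renewal-consistency studies); by default each
        # epoch calibrates its own, as the real system does
        self.external_detector = detector

    # -- setup ------------------------------------------------------------

    def _setup(self) -> None:
        cfg = self.config
        root = np.random.default_rng(cfg.rng_seed)
        (self._bg_rng, self._ev_rng, self._agent_rng, self._calib_rng,
         self._spike_rng, self._model_rng) = root.spawn(6)
        # background statistics from a *separate* clean realization
        probe = BackgroundNoise(
            cfg.n_tetrodes, cfg.fs, cfg.background_sd, cfg.pink_fraction,
            seed=self._calib_rng.spawn(1)[0],
        )
        probe_series = RippleSeries(probe.take(int(120 * cfg.fs)), cfg.fs)
        self.stats = estimate_background_stats(probe_series)
        # the session's own continuous background
        self.background = BackgroundNoise(
            cfg.n_tetrodes, cfg.fs, cfg.background_sd, cfg.pink_fraction,
            seed=self._bg_rng,
        )
        self.events = _EventSource(cfg, self.stats, self._ev_rng, cfg.fs, cfg.n_tetrodes)
        # calibrate the online detector on a rest-box stream (with rest SWRs)
        settle = 60.0
        calib_bg = BackgroundNoise(
            cfg.n_tetrodes, cfg.fs, cfg.background_sd, cfg.pink_fraction,
            seed=self._calib_rng,
        )
        calib_src = _EventSource(cfg, self.stats, self._calib_rng, cfg.fs, cfg.n_tetrodes)
        calib_chunk, _ = calib_src.take(
            calib_bg.take(int((settle + 10) * cfg.fs)),
            cfg.swr_rate_by_state.get("rest", 0.0),
        )
        n_online = min(self.task_config.online_n_tetrodes, cfg.n_tetrodes)
        if self.external_detector is not None:
            self.detector = self.external_detector
            self._online_tetrodes = np.arange(self.detector.n_tetrodes_)
            self.detector.start_stream()
        else:
            self._online_tetrodes = self._calib_rng.choice(
                cfg.n_tetrodes, size=n_online, replace=False
            )
            self.detector = OnlineRippleDetector(
                threshold_sd=self.task_config.threshold_start,
                min_coincident_tetrodes=self.task_config.min_coincident_tetrodes,
                feedback_delay=self.task_config.feedback_delay,
                lockout=0.25,  # free-running logging; NF stops at the first
                settle=settle,
            ).fit(RippleSeries(calib_chunk[self._online_tetrodes], cfg.fs))
        # session state
        self._lfp_chunks: list[np.ndarray] = []
        self._gt: list[GroundTruthEvent] = []
        self._intervals: list[tuple[float, float, str]] = []
        self._t = 0.0
        self._pos_t: list[np.ndarray] = []
        self._pos_x: list[np.ndarray] = []
        self._replay_spikes: list[list[MarkedSpikeTrain]] = []
        self._move_spikes: list[list[MarkedSpikeTrain]] = []
        if self.generate_spikes:
            self.place_model = gen_place_model(
                cfg.n_cells, self.track, self._model_rng, n_tetrodes=cfg.n_tetrodes
            )
        else:
            self.place_model = None
        # port locations on the track (linear coordinate)
        tr = self.track
        self._home_pos = tr.segment_offsets[0] + 1.0
        self._center_pos = (
            tr.segment_offsets[1] + tr.segment_lengths[1] - tr.bin_size / 2
        )
        self._center_segment = 1

    # -- streaming helpers ------------------------------------------------

    def _rate_for(self, trial_type: str, period: str, state: str) -> float:
        if (trial_type, period) in self.rate_overrides:
            return self.rate_overrides[(trial_type, period)]
        return self.config.swr_rate_by_state[state]

    def _stream(
        self,
        duration: float,
        rate: float,
        run_detector: bool = False,
        stop_at_trigger: bool = False,
        event_meta=None,
    ) -> tuple[float, list[float], list[GroundTruthEvent]]:
        """Advance the session by up to ``duration`` seconds.

        Returns (elapsed, trigger_times, events). With ``stop_at_trigger``
        the stream ends within one chunk of the first online trigger.
        """
        fs = self.config.fs
        remaining = int(round(duration * fs))
        triggers: list[float] = []
        new_events: list[GroundTruthEvent] = []
        elapsed0 = self._t
        while remaining > 0:
            n = min(self.chunk, remaining)
            chunk, evs = self.events.take(
                self.background.take(n), rate, event_meta=event_meta
            )
            self._lfp_chunks.append(chunk)
            new_events.extend(evs)
            self._gt.extend(evs)
            self._t += n / fs
            remaining -= n
            # the detector consumes every sample (filter/envelope continuity
            # and a sample clock aligned with the session clock); triggers
            # are only acted upon during detection periods
            trig = self.detector.process(chunk[self._online_tetrodes])
            if run_detector:
                triggers.extend(trig.tolist())
                if stop_at_trigger and len(triggers):
                    break
        return self._t - elapsed0, triggers, new_events

    def _port_event_meta(self, trial_ctx: dict):
        """Attach replay content ground truth to port-period events."""
        frac_local, frac_remote, _ = self.replay_fractions
        rng = self._ev_rng

        def meta(ev: GroundTruthEvent) -> GroundTruthEvent:
            u = rng.random()
            if u < frac_local:
                kind, seg = "local", self._center_segment
            elif u < frac_local + frac_remote:
                kind = "remote"
                weights = np.ones(N_ARMS)
                for arm in range(1, N_ARMS + 1):
                    if arm == trial_ctx.get("prev_goal_arm"):
                        weights[arm - 1] *= self.remote_arm_weights.get(
                            "previous_goal", 1.0
                        )
                    if arm == trial_ctx.get("future_arm"):
                        weights[arm - 1] *= self.remote_arm_weights.get("future", 1.0)
                    if arm == trial_ctx.get("prev_arm"):
                        weights[arm - 1] *= self.remote_arm_weights.get("previous", 1.0)
                arm = int(rng.choice(np.arange(1, N_ARMS + 1), p=weights / weights.sum()))
                seg = 1 + arm  # segment index of armN
            else:
                kind, seg = "none", None
            ev = replace(ev, replay_kind=kind, replay_segment=seg)
            if self.generate_spikes:
                self._emit_replay_spikes(ev)
            return ev

        return meta

    def _emit_replay_spikes(self, ev: GroundTruthEvent) -> None:
        tr, model = self.track, self.place_model
        rng = self._spike_rng
        if ev.replay_kind == "none":
            # fragmented content: spikes with marks at random positions
            n_spk = rng.poisson(15 * ev.duration / 0.1)
            trains = []
            for tet in range(self.config.n_tetrodes):
                cells = np.flatnonzero(model.tetrode == tet)
                if cells.size == 0 or n_spk == 0:
                    trains.append(
                        MarkedSpikeTrain(tet, np.empty(0), np.empty((0, 4)))
                    )
                    continue
                k = rng.binomial(n_spk, 1.0 / self.config.n_tetrodes)
                chosen = rng.choice(cells, size=k)
                times = rng.uniform(ev.t_start, ev.t_end, k)
                marks = np.concatenate(
                    [model.draw_marks(int(c), 1, rng) for c in chosen]
                ) if k else np.empty((0, 4))
                trains.append(MarkedSpikeTrain(tet, times, marks))
            self._replay_spikes.append(trains)
            return
        if ev.replay_kind == "local":
            seg_bins = np.flatnonzero(tr.bin_segment == self._center_segment)
            start = tr.bin_of_linear(np.array([self._center_pos]))[0]
            path = seg_bins[seg_bins <= start][::-1]  # inward from the port
        else:
            seg_bins = np.flatnonzero(tr.bin_segment == ev.replay_segment)
            path = seg_bins  # outward traversal of the arm
        if path.size == 0:
            return
        trains = gen_replay_spikes(
            ev, path, self.place_model, rng, compression=self.config.replay_compression
        )
        self._replay_spikes.append(trains)

    def _movement(self, frm: float, to: float) -> None:
        """Travel between two linear positions; logs trajectory and spikes."""
        rng = self._agent_rng
        dur = float(rng.uniform(*self.agent.travel_time_range))
        t0 = self._t
        rate = self._rate_for("any", "move", "moving")
        self._stream(dur, rate)
        self._intervals.append((t0, self._t, "moving"))
        if self.generate_spikes:
            fs_pos = 30.0
            n = max(int(dur * fs_pos), 2)
            tt = t0 + np.arange(n) / fs_pos
            # piecewise path through the center junction if segments differ
            tr = self.track
            from .track import bin_path

            b_from = tr.bin_of_linear(np.array([frm]))[0]
            b_to = tr.bin_of_linear(np.array([to]))[0]
            path = bin_path(tr, int(b_from), int(b_to))
            arc = np.arange(path.size) * tr.bin_size
            s = np.linspace(0, arc[-1] if arc.size else 0.0, n)
            xs = tr.bin_centers_linear[path[np.searchsorted(arc, s, side="right") - 1]]
            self._pos_t.append(tt)
            self._pos_x.append(xs)
            self._move_spikes.append(
                gen_movement_spikes(tt, xs, self.place_model, self._spike_rng)
            )

    # -- trial loop -------------------------------------------------------

    def run_epoch(self, n_trials: int = 60) -> SyntheticSession:
        self._setup()
        cfg, task = self.config, self.task_config
        agent_rng = np.random.default_rng(self.config.rng_seed + 1)
        trials: list[Trial] = []
        nf_latencies: list[float] = []
        nf_count = 0
        goal = GoalState(
            goal_arm=int(agent_rng.integers(1, N_ARMS + 1)),
            quota=int(
                agent_rng.integers(task.repeats_per_goal[0], task.repeats_per_goal[1] + 1)
            ),
        )
        prev_arm: int | None = None
        cur_pos = self._home_pos
        for idx in range(n_trials):
            rng = self._agent_rng
            trial_type = (
                "control"
                if self.cohort == "control"
                else ("neurofeedback" if rng.random() < self.p_nf else "delay")
            )
            trial = Trial(index=idx, type=trial_type)
            trial.prev_arm = prev_arm
            trial.prev_goal_arm = goal.prev_goal_arm
            trial.goal_arm = goal.goal_arm
            trial.phase = goal.phase
            trial.goal_block = goal.block
            # order violation -> timeout, no reward anywhere
            if rng.random() < self.agent.p_violation:
                trial.timeout = True
                trial.t_home_poke = self._t
                self._movement(cur_pos, self._home_pos)
                timeout = float(rng.uniform(*task.timeout_range))
                self._stream(timeout, self._rate_for(trial_type, "move", "moving"))
                trials.append(trial)
                continue
            # home poke, travel to center
            self._movement(cur_pos, self._home_pos)
            trial.t_home_poke = self._t
            self._movement(self._home_pos, self._center_pos)
            trial.t_center_poke = self._t
            trial.center_port = 1 if trial_type == "neurofeedback" else 2
            # choose the arm now so event content can reference it
            arm = self.agent.choose_arm(goal, rng)
            ctx = {
                "prev_arm": prev_arm,
                "prev_goal_arm": goal.prev_goal_arm,
                "future_arm": arm,
            }
            meta = self._port_event_meta(ctx)
            pre_rate = self._rate_for(trial_type, "pre", "still_pre_reward")
            t_pre0 = self._t
            if trial_type == "neurofeedback":
                nf_count += 1
                thr = threshold_schedule(self.day, nf_count, task)
                trial.threshold_sd = thr
                self.detector.set_threshold(thr)
                elapsed, trig, evs_pre = self._stream(
                    task.nf_trigger_cap,
                    pre_rate,
                    run_detector=True,
                    stop_at_trigger=True,
                    event_meta=meta,
                )
                if not trig:
                    trial.aborted = True
                    trials.append(trial)
                    self._intervals.append((t_pre0, self._t, "still_pre_reward"))
                    continue
                t_trig = trig[0]
                trial.trigger_event = SwrEvent(
                    t_start=t_trig - 0.01,
                    t_end=t_trig + 0.05,
                    t_peak=t_trig,
                    size=thr,
                    source="online",
                )
                trial.online_suprathreshold_times = [t_trig]
                nf_latencies.append(t_trig - t_pre0)
                # feedback delay between trigger and tone/reward
                gap = max(0.0, (t_trig + task.feedback_delay) - self._t)
                if gap > 0:
                    _, _, more = self._stream(gap, pre_rate, event_meta=meta)
                    evs_pre.extend(more)
                trial.t_reward = t_trig + task.feedback_delay
            else:
                thr = threshold_schedule(self.day, max(nf_count, 1), task)
                trial.threshold_sd = thr
                self.detector.set_threshold(thr)
                if trial_type == "delay":
                    dur = sample_yoked_delay(nf_latencies, task, rng)
                else:
                    dur = float(rng.uniform(*task.control_delay_range))
                _, trig, evs_pre = self._stream(
                    dur, pre_rate, run_detector=True, event_meta=meta
                )
                trial.online_suprathreshold_times = list(trig)
                trial.t_reward = self._t
            self._intervals.append((t_pre0, trial.t_reward, "still_pre_reward"))
            trial.pre_speed = self.agent.speed_trace(
                trial.t_reward - t_pre0,
                self.agent.pre_speed_mean[trial_type],
                rng,
            )
            # post-reward dwell
            post_rate = self._rate_for(trial_type, "post", "still_post_reward")
            dwell = self.agent.post_dwell(trial_type, rng)
            if self.total_rate_target is not None:
                pre_dur_eff = trial.t_reward - t_pre0
                # the trigger SWR is excluded downstream, so it does not
                # count toward the trial's total
                n_pre = len(evs_pre) - (
                    1 if trial_type == "neurofeedback" else 0
                )
                need = max(
                    (self.total_rate_target * (pre_dur_eff + dwell) - n_pre)
                    / dwell,
                    0.0,
                )
                # compensate the min-gap thinning so the *realized* rate
                # hits the quota: thinned(r) = r / (1 + r * gap)
                gap = self.config.min_event_gap
                post_rate = need / (1 - need * gap) if need * gap < 0.9 else need
            self._stream(dwell, post_rate, event_meta=meta)
            trial.t_center_exit = self._t
            self._intervals.append((trial.t_reward, self._t, "still_post_reward"))
            trial.post_speed = self.agent.speed_trace(
                dwell, self.agent.post_speed_mean, rng
            )
            # arm visit
            arm_pos = (
                self.track.segment_offsets[1 + arm]
                + self.track.segment_lengths[1 + arm]
                - 1.0
            )
            self._movement(self._center_pos, arm_pos)
            trial.t_arm_poke = self._t
            trial.arm_choice = arm
            rewarded, goal = goal_controller(
                goal, arm, self._agent_rng, task.repeats_per_goal
            )
            trial.rewarded = rewarded
            prev_arm = arm
            cur_pos = arm_pos
            trials.append(trial)
        # assemble
        lfp = RippleSeries(np.concatenate(self._lfp_chunks, axis=1), cfg.fs)
        spikes = position = None
        if self.generate_spikes:
            spikes = merge_spike_trains(
                self._move_spikes + self._replay_spikes, cfg.n_tetrodes
            )
            if self._pos_t:
                position = {
                    "times": np.concatenate(self._pos_t),
                    "linear": np.concatenate(self._pos_x),
                }
        return SyntheticSession(
            lfp=lfp,
            trials=trials,
            ground_truth=self._gt,
            state_intervals=self._intervals,
            config=cfg,
            task_config=task,
            spikes=spikes,
            position=position,
            track=self.track,
            place_model=self.place_model,
            day=self.day,
        )


def simulate_trial(
    simulator: SessionSimulator, n_trials: int = 1
) -> list[Trial]:
    """Convenience wrapper: run a short epoch and return its trials."""
    return simulator.run_epoch(n_trials=n_trials).trials
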