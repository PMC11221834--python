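"""Ground-truthed synthetic session generation.

This module fabricates everything the analysis pipeline consumes — multi-
tetrode LFP with injected sharp-wave ripples, place-cell marked spikes,
movement trajectories — with known ground truth so that every downstream
stage can be scored against what was actually put in.

Statistical structure emulated:

* **Background LFP** is 1/f ("pink") noise plus white noise at a configurable
  mix, so the ripple band has a nonzero stationary baseline and SD-unit
  thresholds are meaningful. Generation is streaming (filter state carried
  across chunks), so a session's background is one continuous process no
  matter how it is consumed.
* **SWRs** are Gaussian-windowed sinusoids (frequency drawn per event from
  the ripple band, envelope SD = duration/4) injected coherently on all
  tetrodes with independent phases. The injection amplitude is calibrated
  internally so that the *offline consensus detector* measures the requested
  size in SD units.
* **Event sizes** follow a shifted lognormal — a long-tailed distribution in
  which larger events are increasingly rare — and event times follow an
  inhomogeneous Poisson process with state-dependent rates (movement versus
  pre-/post-reward stillness versus rest) and a minimum inter-event gap.
* **Spiking** comes from Gaussian place fields on the track graph, with 4-D
  spike-amplitude marks per tetrode; replay spiking replays a path over the
  graph at a time-compressed virtual speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .offline import bandpass_ripple, build_consensus
from .signals import MarkedSpikeTrain, RippleSeries
from .track import TrackGraph

# ---------------------------------------------------------------------------
# configuration

#: behavioral states with distinct SWR occurrence rates
STATES = ("moving", "still_pre_reward", "still_post_reward", "rest")

#: typical running speed used to convert replay compression into a virtual
#: replay speed (cm/s)
RUN_SPEED = 30.0


@dataclass(frozen=True)
class SizeDistribution:
    """Shifted lognormal over SWR size in consensus-SD units.

    ``size = shift + scale * exp(sigma * Z)``, Z standard normal. Long-tailed:
    larger events occur less frequently than smaller ones. The default tail
    is calibrated to the closed-loop regime the task assumes: online
    detection thresholds ramping from 4 up to 16–20 envelope-SD units remain
    reachable, with trigger waits growing from seconds to tens of seconds —
    the threshold-ramp training schedule presupposes exactly this.
    """

    shift: float = 2.5
    scale: float = 5.0
    sigma: float = 1.7

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return self.shift + self.scale * np.exp(self.sigma * rng.standard_normal(n))

    def sf(self, size: float) -> float:
        """Survival function P(S >= size)."""
        from scipy.stats import norm

        if size <= self.shift:
            return 1.0
        return float(norm.sf(np.log((size - self.shift) / self.scale) / self.sigma))


@dataclass
class SessionConfig:
    """Parameters of one synthetic session. The seed fully determines output."""

    n_tetrodes: int = 4
    fs: float = 1500.0
    duration: float = 60.0
    swr_rate_by_state: dict = field(
        default_factory=lambda: {
            "moving": 0.01,
            "still_pre_reward": 0.4,
            "still_post_reward": 0.6,
            "rest": 0.3,
        }
    )
    swr_size_distribution: SizeDistribution = field(default_factory=SizeDistribution)
    ripple_freq_range: tuple[float, float] = (150.0, 250.0)
    swr_duration_range: tuple[float, float] = (0.04, 0.12)
    n_cells: int = 30
    replay_compression: float = 20.0
    min_event_gap: float = 0.1
    background_sd: float = 50.0
    pink_fraction: float = 0.85
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 2 * self.ripple_freq_range[1]:
            raise ValueError("fs must exceed twice the upper ripple frequency")
        if self.n_tetrodes < 1:
            raise ValueError("need at least one tetrode")
        if self.duration < 0:
            raise ValueError("duration must be non-negative")
        for state, rate in self.swr_rate_by_state.items():
            if rate < 0:
                raise ValueError(f"negative SWR rate for state {state!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class GroundTruthEvent:
    """One injected SWR: where it went in and what it was."""

    time: float  # center, s
    amplitude: float  # consensus-SD units
    duration: float  # s
    freq: float = 200.0
    replay_segment: int | None = None
    replay_kind: str = "none"  # local | remote | none

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.replay_kind not in ("local", "remote", "none"):
            raise ValueError(f"bad replay_kind {self.replay_kind!r}")

    @property
    def t_start(self) -> float:
        return self.time - self.duration / 2

    @property
    def t_end(self) -> float:
        return self.time + self.duration / 2


# ---------------------------------------------------------------------------
# background LFP

# 1/f "pinking" IIR filter for white-noise input (audio-DSP classic)
_PINK_B = np.array([0.049922035, -0.095993537, 0.050612699, -0.004408786])
_PINK_A = np.array([1.0, -2.494956002, 2.017265875, -0.522189400])


def _pink_gain() -> float:
    """RMS output of the pinking filter for unit-variance white input."""
    impulse = np.zeros(8192)
    impulse[0] = 1.0
    h = sps.lfilter(_PINK_B, _PINK_A, impulse)
    return float(np.sqrt(np.sum(h**2)))


_PINK_RMS = _pink_gain()


class BackgroundNoise:
    """Streaming 1/f + white background, continuous across chunks.

    One independent stream per tetrode (spawned from the seed). ``take(n)``
    returns the next ``n`` samples for every tetrode; the concatenation of
    chunked takes is sample-identical to one large take.
    """

    def __init__(
        self,
        n_tetrodes: int,
        fs: float,
        sigma: float = 50.0,
        pink_fraction: float = 0.85,
        seed: int | np.random.Generator = 0,
    ):
        self.n_tetrodes = n_tetrodes
        self.fs = fs
        self.sigma = sigma
        self.pink_fraction = pink_fraction
        parent = (
            seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        )
        self._rngs = parent.spawn(n_tetrodes)
        self._zi = [
            np.zeros(max(len(_PINK_A), len(_PINK_B)) - 1) for _ in range(n_tetrodes)
        ]

    def take(self, n: int) -> np.ndarray:
        out = np.empty((self.n_tetrodes, n))
        a_pink = np.sqrt(self.pink_fraction) / _PINK_RMS
        a_white = np.sqrt(1.0 - self.pink_fraction)
        for t in range(self.n_tetrodes):
            white = self._rngs[t].standard_normal(n)
            pink, self._zi[t] = sps.lfilter(_PINK_B, _PINK_A, white, zi=self._zi[t])
            out[t] = self.sigma * (a_pink * pink + a_white * white)
        return out


def gen_background_lfp(config: SessionConfig) -> RippleSeries:
    """Event-free background LFP for a whole session, one trace per tetrode."""
    n = int(round(config.duration * config.fs))
    gen = BackgroundNoise(
        config.n_tetrodes,
        config.fs,
        sigma=config.background_sd,
        pink_fraction=config.pink_fraction,
        seed=config.rng_seed,
    )
    return RippleSeries(gen.take(n), config.fs)


# ---------------------------------------------------------------------------
# ripple injection, calibrated against the offline consensus detector


@dataclass(frozen=True)
class BackgroundStats:
    """Consensus-trace statistics of the (clean) background.

    ``epoch_mean``/``epoch_sd`` define the SD-unit scale; ``mean_power`` is
    the mean of the squared consensus, used for power-additive calibration.
    """

    epoch_mean: float
    epoch_sd: float
    mean_power: float


def estimate_background_stats(
    trace: RippleSeries,
    band: tuple[float, float] = (150.0, 250.0),
    smoothing_sd: float = 0.004,
    max_seconds: float = 120.0,
) -> BackgroundStats:
    """Consensus statistics of a background trace (cached on the trace).

    Uses up to ``max_seconds`` of signal — the background is stationary, so
    a long prefix pins the epoch statistics.
    """
    cached = getattr(trace, "_bg_stats", None)
    if cached is not None:
        return cached
    n = min(trace.n_samples, int(max_seconds * trace.fs))
    sub = RippleSeries(trace.data[:, :n], trace.fs, trace.t0)
    consensus = build_consensus(bandpass_ripple(sub, band), smoothing_sd)
    stats = BackgroundStats(
        epoch_mean=float(consensus.values.mean()),
        epoch_sd=float(consensus.values.std()),
        mean_power=float(np.mean(consensus.values**2)),
    )
    trace._bg_stats = stats
    return stats


def ripple_waveform(
    fs: float, duration: float, freq: float, phase: float = 0.0
) -> np.ndarray:
    """Unit-envelope Gaussian-windowed sinusoid (support ±3 envelope SDs)."""
    sd = duration / 4.0
    half = int(round(3 * sd * fs))
    t = np.arange(-half, half + 1) / fs
    return np.exp(-(t**2) / (2 * sd**2)) * np.sin(2 * np.pi * freq * t + phase)


def inject_ripple(
    trace: RippleSeries,
    time: float,
    amplitude: float,
    duration: float,
    freq: float,
    rng: np.random.Generator,
    stats: BackgroundStats | None = None,
    smoothing_sd: float = 0.004,
) -> tuple[RippleSeries, GroundTruthEvent]:
    """Add one SWR to all tetrodes, in place, calibrated to ``amplitude``.

    ``amplitude`` is the size in SD units that the offline consensus detector
    would measure on the otherwise-clean background. The waveform height
    ``A`` is solved against the *actual local background* at the injection
    site: the peak of the consensus of ``background + A * wave`` over the
    event span is matched to ``epoch_mean + amplitude * epoch_sd`` by a
    bracketed root search, so phase interference with the local in-band
    noise is calibrated away rather than left as bias. (A power-additivity
    closed form seeds the bracket; if the local background alone already
    exceeds the target — tiny amplitudes on a noisy stretch — the closed
    form is used as the best effort.)

    The per-tetrode carrier phases are drawn from ``rng``; the envelope is
    shared (an SWR is a network event). Injections at disjoint times are
    sample-wise additive and order-independent.
    """
    event = GroundTruthEvent(time=time, amplitude=amplitude, duration=duration, freq=freq)
    if amplitude == 0:
        return trace, event
    phases = rng.uniform(0, 2 * np.pi, trace.n_tetrodes)
    wave = np.stack([ripple_waveform(trace.fs, duration, freq, p) for p in phases])
    m = wave.shape[1]
    center = trace.sample_index(time)
    lo = center - m // 2
    hi = lo + m
    if lo < 0 or hi > trace.n_samples:
        raise ValueError("event extends past the trace bounds")
    if stats is None:
        stats = estimate_background_stats(trace, smoothing_sd=smoothing_sd)
    a = _calibrated_height(
        trace, wave, lo, hi, stats, amplitude, smoothing_sd
    )
    trace.data[:, lo:hi] += a * wave
    return trace, event


def _unit_consensus_peak(
    wave: np.ndarray, fs: float, smoothing_sd: float
) -> float:
    """Consensus peak of the clean unit-height ripple, as the offline
    band-pass sees it (off-center carriers are attenuated by the filter)."""
    from .offline import RIPPLE_BAND, _design_bandpass

    sos = _design_bandpass(RIPPLE_BAND, fs)
    pad = int(0.05 * fs)
    padded = np.pad(wave, ((0, 0), (pad, pad)))
    wave_filt = sps.sosfiltfilt(sos, padded, axis=1)[:, pad:-pad]
    power = gaussian_filter1d(np.sum(wave_filt**2, axis=0), smoothing_sd * fs)
    return float(np.sqrt(power.max()))


def _calibrated_height(
    trace: RippleSeries,
    wave: np.ndarray,
    lo: int,
    hi: int,
    stats: BackgroundStats,
    amplitude: float,
    smoothing_sd: float,
) -> float:
    """Waveform height whose local consensus peak hits the target size."""
    from scipy.optimize import brentq

    from .offline import RIPPLE_BAND, _design_bandpass

    fs = trace.fs
    target = stats.epoch_mean + amplitude * stats.epoch_sd
    p_unit = _unit_consensus_peak(wave, fs, smoothing_sd)
    a0 = np.sqrt(max(target**2 - stats.mean_power, 0.0)) / p_unit
    pad = int(0.075 * fs)
    s_lo, s_hi = max(lo - pad, 0), min(hi + pad, trace.n_samples)
    seg = trace.data[:, s_lo:s_hi]
    off = lo - s_lo
    m = hi - lo
    sos = _design_bandpass(RIPPLE_BAND, fs)

    def peak(a: float) -> float:
        x = seg.copy()
        x[:, off : off + m] += a * wave
        filt = sps.sosfiltfilt(sos, x, axis=1)
        power = gaussian_filter1d(np.sum(filt**2, axis=0), smoothing_sd * fs)
        core = power[off : off + m]
        return float(np.sqrt(core.max()))

    if peak(0.0) >= target:
        return a0  # local noise already above target; closed form best effort
    a_hi = max(3 * a0, 1.0)
    for _ in range(8):
        if peak(a_hi) > target:
            break
        a_hi *= 2
    else:
        return a0
    return float(brentq(lambda a: peak(a) - target, 0.0, a_hi, xtol=1e-3))


def gen_event_times(
    state_intervals: list[tuple[float, float, str]],
    swr_rate_by_state: dict,
    rng: np.random.Generator,
    min_gap: float = 0.1,
) -> np.ndarray:
    """Inhomogeneous-Poisson event times with a minimum inter-event gap.

    ``state_intervals`` is a list of non-overlapping ``(t_start, t_end,
    state)`` triples; each interval draws a homogeneous Poisson process at
    its state's rate, and the pooled, sorted times are thinned so that
    successive events are at least ``min_gap`` apart.
    """
    ordered = sorted(state_intervals)
    for (a0, a1, _), (b0, _, _) in zip(ordered, ordered[1:]):
        if b0 < a1:
            raise ValueError("state intervals overlap")
    times = []
    for t0, t1, state in ordered:
        rate = swr_rate_by_state[state]
        if rate < 0:
            raise ValueError(f"negative rate for state {state!r}")
        if t1 <= t0 or rate == 0:
            continue
        count = rng.poisson(rate * (t1 - t0))
        times.append(rng.uniform(t0, t1, count))
    if not times:
        return np.array([])
    pooled = np.sort(np.concatenate(times))
    kept = []
    last = -np.inf
    for t in pooled:
        if t - last >= min_gap:
            kept.append(t)
            last = t
    return np.asarray(kept)


# ---------------------------------------------------------------------------
# place cells and spiking


@dataclass
class PlaceModel:
    """Ground-truth encoding model: Gaussian place fields with 4-D marks.

    Field centers live on track bins; tuning falls off with *graph* distance,
    so a field at the end of one arm does not bleed onto a neighboring arm.
    Marks are multivariate normal per cell; mark means are mutually separated
    by a minimum Mahalanobis distance so clusterless decoding is feasible.
    """

    field_center: np.ndarray  # (n_cells,) global linear cm
    field_width: np.ndarray  # (n_cells,) cm
    peak_rate: np.ndarray  # (n_cells,) spikes/s
    mark_mean: np.ndarray  # (n_cells, 4) µV
    mark_cov: np.ndarray  # (n_cells, 4, 4) µV²
    tetrode: np.ndarray  # (n_cells,) int
    n_tetrodes: int
    track: TrackGraph

    def __post_init__(self) -> None:
        if np.any(self.peak_rate <= 0):
            raise ValueError("peak_rate must be positive")
        for c in range(self.n_cells):
            if not np.allclose(self.mark_cov[c], self.mark_cov[c].T):
                raise ValueError("mark_cov must be symmetric")
            if np.any(np.linalg.eigvalsh(self.mark_cov[c]) <= 0):
                raise ValueError("mark_cov must be positive-definite")
        self._center_bins = self.track.bin_of_linear(self.field_center)
        self._chol = np.linalg.cholesky(self.mark_cov)

    @property
    def n_cells(self) -> int:
        return self.field_center.size

    def rates_at_bins(self, bins: np.ndarray) -> np.ndarray:
        """Firing rate of every cell at the given track bins: (n_cells, n)."""
        d = self.track.bin_distances[np.ix_(self._center_bins, np.atleast_1d(bins))]
        return self.peak_rate[:, None] * np.exp(
            -(d**2) / (2 * self.field_width[:, None] ** 2)
        )

    def draw_marks(self, cell: int, n: int, rng: np.random.Generator) -> np.ndarray:
        z = rng.standard_normal((n, 4))
        return self.mark_mean[cell] + z @ self._chol[cell].T


def gen_place_model(
    n_cells: int,
    track: TrackGraph,
    rng: np.random.Generator,
    n_tetrodes: int = 4,
    field_width: float = 8.0,
    peak_rate_range: tuple[float, float] = (10.0, 25.0),
    mark_range: tuple[float, float] = (60.0, 350.0),
    mark_sd: float = 20.0,
    min_mark_separation: float = 6.0,
) -> PlaceModel:
    """Place fields tiling the track with well-separated mark clusters.

    Centers are evenly spaced over the track bins (snapped to bin centers);
    mark means are rejection-sampled until all pairwise Mahalanobis distances
    (w.r.t. the isotropic ``mark_sd²`` covariance) reach
    ``min_mark_separation``.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if track.n_bins < 1:
        raise ValueError("track must have at least one bin")
    idx = np.round(np.linspace(0, track.n_bins - 1, n_cells)).astype(int)
    centers = track.bin_centers_linear[idx]
    rates = rng.uniform(*peak_rate_range, n_cells)
    means = np.empty((n_cells, 4))
    placed = 0
    for _ in range(10000):
        if placed == n_cells:
            break
        cand = rng.uniform(*mark_range, 4)
        if placed == 0 or np.all(
            np.linalg.norm(means[:placed] - cand, axis=1) / mark_sd
            >= min_mark_separation
        ):
            means[placed] = cand
            placed += 1
    if placed < n_cells:
        raise RuntimeError(
            "could not separate mark means; widen mark_range or lower "
            "min_mark_separation"
        )
    cov = np.tile(mark_sd**2 * np.eye(4), (n_cells, 1, 1))
    return PlaceModel(
        field_center=centers,
        field_width=np.full(n_cells, field_width),
        peak_rate=rates,
        mark_mean=means,
        mark_cov=cov,
        tetrode=np.arange(n_cells) % n_tetrodes,
        n_tetrodes=n_tetrodes,
        track=track,
    )


def _spikes_from_rates(
    sample_times: np.ndarray,
    rates: np.ndarray,
    model: PlaceModel,
    rng: np.random.Generator,
) -> list[MarkedSpikeTrain]:
    """Poisson spikes (with marks) from per-cell, per-sample rates."""
    dt = np.diff(sample_times, append=sample_times[-1] + np.median(np.diff(sample_times)))
    trains: dict[int, list] = {t: [] for t in range(model.n_tetrodes)}
    for c in range(model.n_cells):
        counts = rng.poisson(rates[c] * dt)
        hot = np.flatnonzero(counts)
        if hot.size == 0:
            continue
        reps = counts[hot]
        t_spk = np.repeat(sample_times[hot], reps) + rng.uniform(
            0, np.repeat(dt[hot], reps)
        )
        marks = model.draw_marks(c, t_spk.size, rng)
        trains[int(model.tetrode[c])].append((t_spk, marks, np.full(t_spk.size, c)))
    out = []
    for tet in range(model.n_tetrodes):
        if trains[tet]:
            times = np.concatenate([x[0] for x in trains[tet]])
            marks = np.concatenate([x[1] for x in trains[tet]])
            cells = np.concatenate([x[2] for x in trains[tet]])
        else:
            times, marks, cells = np.empty(0), np.empty((0, 4)), np.empty(0, dtype=int)
        out.append(MarkedSpikeTrain(tet, times, marks, cells))
    return out


def gen_movement_spikes(
    times: np.ndarray,
    linear_pos: np.ndarray,
    model: PlaceModel,
    rng: np.random.Generator,
) -> list[MarkedSpikeTrain]:
    """Place-field spiking along a 1-D trajectory, one train per tetrode.

    Each cell is an inhomogeneous Poisson process whose rate follows its
    Gaussian tuning curve evaluated at the animal's position; each spike's
    mark is drawn from that cell's 4-D mark distribution.
    """
    times = np.asarray(times, dtype=float)
    linear_pos = np.asarray(linear_pos, dtype=float)
    if times.size < 2:
        raise ValueError("trajectory needs at least two samples")
    if np.median(np.diff(times)) > 0.04 + 1e-9:
        raise ValueError("trajectory must be sampled at >= 25 Hz")
    if linear_pos.min() < 0 or linear_pos.max() > model.track.total_length:
        raise ValueError("trajectory leaves the track bounds")
    bins = model.track.bin_of_linear(linear_pos)
    rates = model.rates_at_bins(bins)
    return _spikes_from_rates(times, rates, model, rng)


def gen_replay_spikes(
    event: GroundTruthEvent,
    path_bins: np.ndarray,
    model: PlaceModel,
    rng: np.random.Generator,
    compression: float = 20.0,
    run_speed: float = RUN_SPEED,
    rate_gain: float = 8.0,
    dt: float = 0.001,
) -> list[MarkedSpikeTrain]:
    """Time-compressed replay spiking for one SWR.

    Spikes are drawn as if the animal traversed ``path_bins`` (an ordered,
    graph-connected sequence of track bins) at ``compression × run_speed``
    within the event window, with instantaneous rates boosted by
    ``rate_gain`` to emulate the dense bursting seen inside ripples.
    """
    path_bins = np.asarray(path_bins, dtype=int)
    if path_bins.size == 0:
        raise ValueError("replay path must be non-empty")
    track = model.track
    for a, b in zip(path_bins, path_bins[1:]):
        if a != b and b not in track.neighbors[a]:
            raise ValueError("replay path must be connected on the track graph")
    arc = np.concatenate(
        ([0.0], np.cumsum(np.full(path_bins.size - 1, track.bin_size)))
    )
    t_rel = np.arange(0.0, event.duration, dt)
    if t_rel.size == 0:
        t_rel = np.array([0.0])
    s = np.minimum(compression * run_speed * t_rel, arc[-1] if arc.size else 0.0)
    virtual_bins = path_bins[np.searchsorted(arc, s, side="right") - 1]
    rates = rate_gain * model.rates_at_bins(virtual_bins)
    return _spikes_from_rates(event.t_start + t_rel, rates, model, rng)


def merge_spike_trains(
    groups: list[list[MarkedSpikeTrain]], n_tetrodes: int
) -> list[MarkedSpikeTrain]:
    """Pool several per-tetrode train lists into one sorted list per tetrode."""
    out = []
    for tet in range(n_tetrodes):
        times, marks, cells = [], [], []
        for g in groups:
            for train in g:
                if train.tetrode == tet and train.n_spikes:
                    times.append(train.times)
                    marks.append(train.marks)
                    cells.append(
                        train.cell_ids
                        if train.cell_ids is not None
                        else np.full(train.n_spikes, -1)
                    )
        if times:
            out.append(
                MarkedSpikeTrain(
                    tet,
                    np.concatenate(times),
                    np.concatenate(marks),
                    np.concatenate(cells),
                )
            )
        else:
            out.append(
                MarkedSpikeTrain(tet, np.empty(0), np.empty((0, 4)), np.empty(0, int))
            )
    return out


def gen_session(config: SessionConfig, task_config=None, agent=None):
    """End-to-end synthetic session: LFP + spikes + trials + ground truth.

    Thin composition layer: delegates the closed-loop trial structure to the
    task engine (`ripplenf.task.SessionSimulator`) and returns its
    :class:`~ripplenf.task.SyntheticSession`, which lists every injected SWR,
    its replay content, and every trial's latent state.
    """
    from .task import SessionSimulator, TaskConfig

    task_config = task_config if task_config is not None else TaskConfig()
    sim = SessionSimulator(config, task_config, agent=agent)
    return sim.run_epoch()
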