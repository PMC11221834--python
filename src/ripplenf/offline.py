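"""Offline consensus SWR detection.

All analyses rest on a single *consensus* ripple-power trace built from every
tetrode: the ripple-band (150–250 Hz) filtrate of each tetrode is squared,
summed over tetrodes, smoothed with a 4 ms SD Gaussian kernel, and the square
root taken. Events are intervals where this trace exceeds the behavioral
epoch mean by ``threshold_sd`` standard deviations for at least ``min_dur``,
extended outward to the nearest crossings of the epoch mean (the baseline).
Event *size* is the maximum threshold (in SD units) at which the event would
still have been detected; *length* is end − start.

Filtering is zero-phase (forward-backward IIR): offline analysis has no
causality constraint and unbiased event boundaries matter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d
from sklearn.base import BaseEstimator

from .signals import RippleSeries, SwrEvent

RIPPLE_BAND = (150.0, 250.0)


@dataclass
class ConsensusTrace:
    """Non-negative consensus ripple-power trace with its epoch statistics."""

    values: np.ndarray
    fs: float
    t0: float = 0.0
    epoch_mean: float = np.nan
    epoch_sd: float = np.nan

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if np.isnan(self.epoch_mean):
            self.epoch_mean = float(self.values.mean()) if self.values.size else 0.0
        if np.isnan(self.epoch_sd):
            self.epoch_sd = float(self.values.std()) if self.values.size else 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.values.size) / self.fs

    def sample_index(self, t: float) -> int:
        return int(round((t - self.t0) * self.fs))


def _design_bandpass(band: tuple[float, float], fs: float, order: int = 4):
    low, high = band
    if not 0 < low < high < fs / 2:
        raise ValueError(f"band {band} must lie inside (0, Nyquist={fs / 2})")
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_ripple(
    trace: RippleSeries, band: tuple[float, float] = RIPPLE_BAND, order: int = 4
) -> RippleSeries:
    """Zero-phase ripple-band filtrate, same length and clock."""
    sos = _design_bandpass(band, trace.fs, order)
    if trace.n_samples == 0:
        return trace.copy()
    filtered = sps.sosfiltfilt(sos, trace.data, axis=1)
    return RippleSeries(filtered, trace.fs, trace.t0)


def build_consensus(
    filtered: RippleSeries, smoothing_sd: float = 0.004
) -> ConsensusTrace:
    """Square → sum over tetrodes → Gaussian smooth (4 ms SD) → square root."""
    if filtered.n_tetrodes < 1:
        raise ValueError("need at least one tetrode")
    power = np.sum(filtered.data**2, axis=0)
    if power.size:
        power = gaussian_filter1d(power, sigma=smoothing_sd * filtered.fs, mode="nearest")
    return ConsensusTrace(np.sqrt(power), filtered.fs, filtered.t0)


def detect_events(
    consensus: ConsensusTrace,
    threshold_sd: float = 2.0,
    min_dur: float = 0.015,
) -> list[SwrEvent]:
    """Threshold the consensus trace and return baseline-extended events.

    Candidate intervals stay above ``epoch_mean + threshold_sd * epoch_sd``
    for at least ``min_dur`` seconds; each is extended backward/forward to
    the nearest samples at or below the epoch mean, overlapping extended
    spans are merged, and events are returned time-ordered with size/peak
    filled in by :func:`measure_event`.
    """
    if min_dur < 1.0 / consensus.fs:
        raise ValueError("min_dur must cover at least one sample")
    x = consensus.values
    if x.size == 0:
        return []
    threshold = consensus.epoch_mean + threshold_sd * consensus.epoch_sd
    above = x > threshold
    if not above.any():
        return []
    # run-length encode the suprathreshold mask
    d = np.diff(above.astype(np.int8))
    run_starts = np.flatnonzero(d == 1) + 1
    run_ends = np.flatnonzero(d == -1) + 1  # exclusive
    if above[0]:
        run_starts = np.concatenate(([0], run_starts))
    if above[-1]:
        run_ends = np.concatenate((run_ends, [above.size]))
    min_samples = min_dur * consensus.fs
    at_or_below = x <= consensus.epoch_mean
    spans: list[tuple[int, int]] = []
    for s, e in zip(run_starts, run_ends):
        if (e - s) < min_samples:
            continue
        # extend to the nearest baseline crossings
        left = np.flatnonzero(at_or_below[:s])
        lo = int(left[-1]) if left.size else 0
        right = np.flatnonzero(at_or_below[e:])
        hi = int(e + right[0]) if right.size else above.size - 1
        spans.append((lo, hi))
    if not spans:
        return []
    spans.sort()
    merged = [spans[0]]
    for lo, hi in spans[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    events = []
    for lo, hi in merged:
        ev = SwrEvent(
            t_start=consensus.t0 + lo / consensus.fs,
            t_end=consensus.t0 + hi / consensus.fs,
            source="offline",
        )
        events.append(measure_event(consensus, ev))
    return events


def measure_event(consensus: ConsensusTrace, event: SwrEvent) -> SwrEvent:
    """Fill in size (SD units), peak time, for an event interval.

    Size is ``(max consensus within the event − epoch_mean) / epoch_sd`` —
    the maximum threshold at which the event would have been detected.
    """
    if consensus.epoch_sd <= 0:
        raise ValueError("degenerate epoch_sd = 0; cannot express size in SD units")
    lo = max(consensus.sample_index(event.t_start), 0)
    hi = min(consensus.sample_index(event.t_end), consensus.values.size - 1)
    if hi < lo:
        raise ValueError("event lies outside the consensus trace")
    seg = consensus.values[lo : hi + 1]
    peak = int(np.argmax(seg))
    return replace(
        event,
        t_peak=consensus.t0 + (lo + peak) / consensus.fs,
        size=(float(seg[peak]) - consensus.epoch_mean) / consensus.epoch_sd,
    )


class ConsensusRippleDetector(BaseEstimator):
    """Consensus multi-tetrode SWR detector (offline, zero-phase).

    Parameters
    ----------
    band : (low, high) Hz
        Ripple band for the zero-phase filtrate.
    threshold_sd : float
        Detection threshold above the epoch mean, in epoch-SD units.
    min_dur : float
        Minimum suprathreshold duration in seconds.
    smoothing_sd : float
        SD of the Gaussian smoothing kernel applied to summed power, seconds.
    exclude_events_from_stats : bool
        If True (default), epoch mean/SD are iteratively re-estimated with
        detected event spans masked out until the event set stabilizes (at
        most ``max_stat_iterations`` passes). Long-tailed event-size
        distributions otherwise inflate the event-inclusive epoch SD enough
        to push small events below the detection threshold. ``False`` gives
        the single-pass statistics over all samples.

    Attributes
    ----------
    consensus_ : ConsensusTrace
    events_ : list of SwrEvent
    """

    def __init__(
        self,
        band: tuple[float, float] = RIPPLE_BAND,
        threshold_sd: float = 2.0,
        min_dur: float = 0.015,
        smoothing_sd: float = 0.004,
        exclude_events_from_stats: bool = True,
        max_stat_iterations: int = 6,
    ):
        self.band = band
        self.threshold_sd = threshold_sd
        self.min_dur = min_dur
        self.smoothing_sd = smoothing_sd
        self.exclude_events_from_stats = exclude_events_from_stats
        self.max_stat_iterations = max_stat_iterations

    def fit(self, lfp: RippleSeries, y=None) -> "ConsensusRippleDetector":
        filtered = bandpass_ripple(lfp, self.band)
        consensus = build_consensus(filtered, self.smoothing_sd)
        events = detect_events(consensus, self.threshold_sd, self.min_dur)
        if self.exclude_events_from_stats:
            for _ in range(self.max_stat_iterations):
                if not events:
                    break
                mask = np.ones(consensus.values.size, dtype=bool)
                for ev in events:
                    lo = max(consensus.sample_index(ev.t_start), 0)
                    hi = min(consensus.sample_index(ev.t_end), mask.size - 1)
                    mask[lo : hi + 1] = False
                if not mask.any():
                    break
                consensus = ConsensusTrace(
                    consensus.values,
                    consensus.fs,
                    consensus.t0,
                    epoch_mean=float(consensus.values[mask].mean()),
                    epoch_sd=float(consensus.values[mask].std()),
                )
                new_events = detect_events(consensus, self.threshold_sd, self.min_dur)
                stable = len(new_events) == len(events)
                events = new_events
                if stable:
                    break
        self.consensus_ = consensus
        self.events_ = events
        return self

    def predict(self, lfp: RippleSeries | None = None) -> list[SwrEvent]:
        """Detected events; refits first if a new series is given."""
        if lfp is not None:
            self.fit(lfp)
        return self.events_
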