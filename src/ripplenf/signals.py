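"""Shared time-series containers.

Everything downstream (detectors, the task engine, the session generator)
passes multi-tetrode LFP around as a :class:`RippleSeries`: a dense
``(n_tetrodes, n_samples)`` float array plus a sampling rate, all tetrodes on
a common clock starting at ``t0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class RippleSeries:
    """Multi-tetrode LFP (or its ripple-band filtrate) on a common clock.

    Parameters
    ----------
    data : ndarray, shape (n_tetrodes, n_samples)
        Signal in µV. A 1-D array is promoted to a single tetrode.
    fs : float
        Sampling rate in samples/s.
    t0 : float
        Time of the first sample, in seconds.
    """

    data: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim == 1:
            self.data = self.data[np.newaxis, :]
        if self.data.ndim != 2:
            raise ValueError("data must be 1-D or 2-D (n_tetrodes, n_samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_tetrodes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "RippleSeries":
        return RippleSeries(self.data.copy(), self.fs, self.t0)

    def sample_index(self, t: float) -> int:
        """Nearest sample index for time ``t`` (seconds)."""
        return int(round((t - self.t0) * self.fs))


@dataclass
class SwrEvent:
    """One detected sharp-wave ripple.

    ``size`` is in SD units of the consensus trace for offline events (the
    maximum threshold at which the event would still have been detected) and
    in online-envelope SD units for online triggers. ``source`` records the
    provenance.
    """

    t_start: float
    t_end: float
    t_peak: float = np.nan
    size: float = np.nan
    source: str = "offline"

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise ValueError("t_start must be < t_end")

    @property
    def length(self) -> float:
        return self.t_end - self.t_start


@dataclass
class MarkedSpikeTrain:
    """Per-tetrode spike times, each carrying a 4-D amplitude mark (µV).

    ``times`` is sorted ascending; ``marks`` has shape ``(n_spikes, 4)``
    (waveform peak amplitude on each of the four tetrode channels).
    ``cell_ids`` is simulation ground truth (which generating cell emitted
    each spike); real clusterless data would not carry it.
    """

    tetrode: int
    times: np.ndarray
    marks: np.ndarray
    cell_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.float64)
        self.marks = np.asarray(self.marks, dtype=np.float64)
        if self.marks.ndim != 2 or self.marks.shape[0] != self.times.size:
            raise ValueError("marks must have shape (n_spikes, n_channels)")
        order = np.argsort(self.times, kind="stable")
        if not np.all(order == np.arange(self.times.size)):
            self.times = self.times[order]
            self.marks = self.marks[order]
            if self.cell_ids is not None:
                self.cell_ids = np.asarray(self.cell_ids)[order]

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def in_window(self, t_start: float, t_end: float) -> "MarkedSpikeTrain":
        keep = (self.times >= t_start) & (self.times < t_end)
        cells = self.cell_ids[keep] if self.cell_ids is not None else None
        return MarkedSpikeTrain(self.tetrode, self.times[keep], self.marks[keep], cells)
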