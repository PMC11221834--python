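"""Streaming online SWR detection, exactly as run in the closed loop.

The real-time system monitors the causal ripple-band (100–400 Hz) filtrate of
a few CA1 tetrodes. Two iterative estimators drive detection, both operating
on the rectified filtrate ``|x|`` sampled at 1500 Hz:

* a slow baseline, frozen before each behavioral epoch::

      mu(n)    = mu(n-1) * (N-1)/N + |x|/N
      sigma(n) = (||x| - mu(n-1)| - sigma(n-1)) / N + sigma(n-1)

  with ``N = n_smooth`` (10 000 samples). Note sigma is a smoothed absolute
  deviation, not a true standard deviation — thresholds "in SD units" here
  mean units of this statistic.

* a fast asymmetric envelope: ``v(n) = v(n-1) + g * (|x| - v(n-1))`` where
  the gain ``g`` is 0.2 while the envelope is decreasing (``|x| <= v``) and
  the mean of {1.2} ∪ {the last 19 gains} while it is increasing — so attack
  is much faster than decay, for rapid detection of power increases.

Detection triggers when the envelope of at least ``min_coincident_tetrodes``
tetrodes exceeds ``mu + threshold_sd * sigma`` at the same sample.

Streaming contract: any chunking of the input produces bit-identical output;
the vectorized batch driver replays the per-sample recursion exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .signals import RippleSeries

ONLINE_BAND = (100.0, 400.0)
N_GAIN_HISTORY = 19
GAIN_DOWN = 0.2
GAIN_UP_ANCHOR = 1.2


# ---------------------------------------------------------------------------
# baseline recursion


@dataclass
class BaselineEstimate:
    """Iterative baseline of the rectified ripple filtrate (per tetrode).

    ``mu_est``/``sigma_est`` may be scalars or per-tetrode arrays. Once
    ``frozen`` the estimate is immutable and defines the epoch's detection
    threshold ``mu + threshold_sd * sigma``.
    """

    mu_est: float | np.ndarray = 0.0
    sigma_est: float | np.ndarray = 0.0
    n_smooth: int = 10000
    n_seen: int = 0
    frozen: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.n_smooth <= 0:
            raise ValueError("n_smooth must be positive")

    def threshold(self, threshold_sd: float):
        return self.mu_est + threshold_sd * self.sigma_est


def update_baseline(state: BaselineEstimate, x) -> BaselineEstimate:
    """One step of the iterative mean/deviation recursion (uses ``|x|``).

    The mean is updated with the previous mean; the deviation with the
    previous mean *and* previous deviation.
    """
    if state.frozen:
        raise ValueError("baseline is frozen")
    x = np.abs(np.asarray(x, dtype=float))
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite input sample")
    n = state.n_smooth
    mu_prev = state.mu_est
    mu = mu_prev * (n - 1) / n + x / n
    sigma = (np.abs(x - mu_prev) - state.sigma_est) / n + state.sigma_est
    return BaselineEstimate(
        mu_est=mu if np.ndim(mu) else float(mu),
        sigma_est=sigma if np.ndim(sigma) else float(sigma),
        n_smooth=n,
        n_seen=state.n_seen + 1,
    )


def _run_baseline(abs_x: np.ndarray, n_smooth: int) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized baseline recursion over (n_tet, n_samples) rectified input.

    Sample 0 initializes ``mu = |x0|``, ``sigma = 0``; the recursion applies
    from sample 1 on. Both recursions are linear given the input, so they
    reduce to first-order IIR filters.
    """
    alpha = (n_smooth - 1) / n_smooth
    mu = np.empty_like(abs_x)
    mu0 = abs_x[:, 0]
    # mu(n) = alpha*mu(n-1) + (1-alpha)*|x(n)|, mu(0)=|x(0)|
    zi = (alpha * mu0)[:, None]
    mu[:, 1:], _ = sps.lfilter(
        [1 - alpha], [1.0, -alpha], abs_x[:, 1:], axis=1, zi=zi
    )
    mu[:, 0] = mu0
    dev = np.abs(abs_x[:, 1:] - mu[:, :-1])
    sigma = np.zeros_like(abs_x)
    sigma[:, 1:], _ = sps.lfilter(
        [1.0 / n_smooth], [1.0, -alpha], dev, axis=1, zi=np.zeros((abs_x.shape[0], 1))
    )
    return mu, sigma


def calibrate_baseline(
    traces: RippleSeries,
    settle: float = 60.0,
    n_smooth: int = 10000,
    band: tuple[float, float] = ONLINE_BAND,
    filter_order: int = 4,
) -> BaselineEstimate:
    """Run the baseline recursion over calibration traces and freeze it.

    The traces (typically rest-box LFP preceding a behavioral epoch) must
    cover at least ``settle`` seconds; the final per-tetrode (mu, sigma) is
    returned frozen and defines the epoch's detection thresholds.
    """
    if traces.duration < settle:
        raise ValueError(
            f"calibration traces ({traces.duration:.1f}s) shorter than settle "
            f"({settle:.1f}s)"
        )
    sos = sps.butter(filter_order, band, btype="bandpass", fs=traces.fs, output="sos")
    filtered = sps.sosfilt(sos, traces.data, axis=1)  # causal, as in the loop
    mu, sigma = _run_baseline(np.abs(filtered), n_smooth)
    mu_f, sigma_f = mu[:, -1].copy(), sigma[:, -1].copy()
    return BaselineEstimate(
        mu_est=mu_f,
        sigma_est=sigma_f,
        n_smooth=n_smooth,
        n_seen=traces.n_samples,
        frozen=True,
        degenerate=bool(np.any(sigma_f <= 0)),
    )


# ---------------------------------------------------------------------------
# envelope recursion


def _hist_mean(buf: np.ndarray) -> float:
    # sequential sum, same order as the numba kernel, for bit-identity
    s = GAIN_UP_ANCHOR
    for i in range(buf.size):
        s += buf[i]
    return s / (buf.size + 1)


@dataclass
class EnvelopeState:
    """Asymmetric envelope estimator state for one tetrode.

    The gain history starts filled with the decay gain (0.2), and ``v_est``
    initializes to the first rectified sample, so calibration is not
    dominated by a startup transient.
    """

    v_est: float = 0.0
    g_history: np.ndarray = field(
        default_factory=lambda: np.full(N_GAIN_HISTORY, GAIN_DOWN)
    )
    g_current: float = GAIN_DOWN
    hist_pos: int = 0
    initialized: bool = False


def update_envelope(
    state: EnvelopeState, x: float, use_previous_gain: bool = False
) -> EnvelopeState:
    """One envelope step on rectified sample ``|x|``.

    Default indexing: the gain chosen by the branch for *this* sample is used
    in the same update, then pushed to history. With ``use_previous_gain``
    the literal alternative applies the previous step's gain and pushes the
    newly branched one.
    """
    ax = abs(float(x))
    if not np.isfinite(ax):
        raise ValueError("non-finite input sample")
    new = EnvelopeState(
        v_est=state.v_est,
        g_history=state.g_history.copy(),
        g_current=state.g_current,
        hist_pos=state.hist_pos,
        initialized=state.initialized,
    )
    if not new.initialized:
        new.v_est = ax
        new.initialized = True
        return new
    if ax <= new.v_est:
        g = GAIN_DOWN
    else:
        g = _hist_mean(new.g_history)
    g_apply = new.g_current if use_previous_gain else g
    new.v_est = new.v_est + g_apply * (ax - new.v_est)
    new.g_history[new.hist_pos] = g
    new.hist_pos = (new.hist_pos + 1) % N_GAIN_HISTORY
    new.g_current = g
    return new


@njit(cache=True)
def _stream_kernel(
    abs_x,  # (n_tet, n) rectified filtrate
    v,  # (n_tet,) envelope, updated in place
    g_hist,  # (n_tet, 19), updated in place
    g_cur,  # (n_tet,)
    hist_pos,  # (n_tet,) int64
    initialized,  # (n_tet,) bool
    thresholds,  # (n_tet,)
    min_coincident,
    lockout_samples,
    last_trigger,  # int64 scalar carried in a 1-element array, absolute sample
    n_start,  # absolute sample index of abs_x[:, 0]
    use_previous_gain,
):
    n_tet, n = abs_x.shape
    triggers = np.empty(n, np.int64)
    n_trig = 0
    for j in range(n):
        above = 0
        for t in range(n_tet):
            ax = abs_x[t, j]
            if not initialized[t]:
                v[t] = ax
                initialized[t] = True
            else:
                if ax <= v[t]:
                    g = GAIN_DOWN
                else:
                    s = GAIN_UP_ANCHOR
                    for i in range(N_GAIN_HISTORY):
                        s += g_hist[t, i]
                    g = s / (N_GAIN_HISTORY + 1)
                g_apply = g_cur[t] if use_previous_gain else g
                v[t] = v[t] + g_apply * (ax - v[t])
                g_hist[t, hist_pos[t]] = g
                hist_pos[t] = (hist_pos[t] + 1) % N_GAIN_HISTORY
                g_cur[t] = g
            if v[t] > thresholds[t]:
                above += 1
        if above >= min_coincident:
            abs_n = n_start + j
            if last_trigger[0] < 0 or abs_n - last_trigger[0] > lockout_samples:
                triggers[n_trig] = abs_n
                n_trig += 1
                last_trigger[0] = abs_n
    return triggers[:n_trig]


# ---------------------------------------------------------------------------
# configuration and estimator


@dataclass
class OnlineDetectorConfig:
    """Closed-loop detector settings.

    ``feedback_delay`` is the per-subject constant (50–100 ms) between the
    trigger and the tone/reward; ``lockout`` (default 0: the task ends the
    trial at the trigger) suppresses re-triggers for free-running use.
    """

    band: tuple[float, float] = ONLINE_BAND
    threshold_sd: float = 4.0
    min_coincident_tetrodes: int = 2
    feedback_delay: float = 0.075
    lockout: float = 0.0
    n_smooth: int = 10000
    filter_order: int = 4
    use_previous_gain: bool = False

    def __post_init__(self) -> None:
        if self.min_coincident_tetrodes < 1:
            raise ValueError("min_coincident_tetrodes must be >= 1")
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")


def step(
    states: list[EnvelopeState],
    frozen: BaselineEstimate,
    config: OnlineDetectorConfig,
    samples: np.ndarray,
    samples_since_trigger: int | None = None,
    fs: float = 1500.0,
) -> tuple[list[EnvelopeState], bool]:
    """Advance every tetrode's envelope by one sample; report coincidence.

    ``samples`` holds one rectified-filtrate value per tetrode. Triggering
    requires ``min_coincident_tetrodes`` envelopes above their frozen
    thresholds at this sample, and (if ``samples_since_trigger`` is given)
    the lockout to have elapsed.
    """
    samples = np.atleast_1d(np.asarray(samples, dtype=float))
    if samples.size != len(states):
        raise ValueError("one sample per tetrode required")
    thresholds = np.atleast_1d(np.asarray(frozen.threshold(config.threshold_sd)))
    if thresholds.size == 1:
        thresholds = np.repeat(thresholds, len(states))
    new_states = [
        update_envelope(s, x, config.use_previous_gain)
        for s, x in zip(states, samples)
    ]
    above = sum(s.v_est > th for s, th in zip(new_states, thresholds))
    triggered = above >= config.min_coincident_tetrodes
    if triggered and samples_since_trigger is not None:
        triggered = samples_since_trigger > int(round(config.lockout * fs))
    return new_states, bool(triggered)


class OnlineRippleDetector(BaseEstimator):
    """Streaming closed-loop SWR detector (sklearn-style estimator).

    ``fit`` calibrates and freezes the per-tetrode baselines from rest-box
    traces; ``process`` consumes raw LFP chunks and returns trigger times,
    carrying all filter/envelope state across chunks so that any chunking of
    the input yields bit-identical triggers; ``predict`` is the batch driver
    over a whole :class:`RippleSeries`.

    Attributes
    ----------
    baseline_ : BaselineEstimate (frozen)
    thresholds_ : ndarray (n_tetrodes,) — ``mu + threshold_sd * sigma``
    """

    def __init__(
        self,
        band: tuple[float, float] = ONLINE_BAND,
        threshold_sd: float = 4.0,
        min_coincident_tetrodes: int = 2,
        feedback_delay: float = 0.075,
        lockout: float = 0.0,
        n_smooth: int = 10000,
        settle: float = 60.0,
        filter_order: int = 4,
        use_previous_gain: bool = False,
    ):
        self.band = band
        self.threshold_sd = threshold_sd
        self.min_coincident_tetrodes = min_coincident_tetrodes
        self.feedback_delay = feedback_delay
        self.lockout = lockout
        self.n_smooth = n_smooth
        self.settle = settle
        self.filter_order = filter_order
        self.use_previous_gain = use_previous_gain

    def _config(self) -> OnlineDetectorConfig:
        return OnlineDetectorConfig(
            band=self.band,
            threshold_sd=self.threshold_sd,
            min_coincident_tetrodes=self.min_coincident_tetrodes,
            feedback_delay=self.feedback_delay,
            lockout=self.lockout,
            n_smooth=self.n_smooth,
            filter_order=self.filter_order,
            use_previous_gain=self.use_previous_gain,
        )

    def fit(self, calibration: RippleSeries, y=None) -> "OnlineRippleDetector":
        """Calibrate and freeze baselines from calibration traces."""
        self.baseline_ = calibrate_baseline(
            calibration,
            settle=self.settle,
            n_smooth=self.n_smooth,
            band=self.band,
            filter_order=self.filter_order,
        )
        self.thresholds_ = np.atleast_1d(
            np.asarray(self.baseline_.threshold(self.threshold_sd), dtype=float)
        )
        self.fs_ = calibration.fs
        self.n_tetrodes_ = calibration.n_tetrodes
        self.start_stream()
        return self

    def set_threshold(self, threshold_sd: float) -> None:
        """Re-derive thresholds from the frozen baseline (ramp support)."""
        self.threshold_sd = threshold_sd
        self.thresholds_ = np.atleast_1d(
            np.asarray(self.baseline_.threshold(threshold_sd), dtype=float)
        )

    def start_stream(self, t0: float = 0.0) -> None:
        """Reset envelope/filter state for a fresh stream starting at t0."""
        n_tet = self.n_tetrodes_
        sos = sps.butter(
            self.filter_order, self.band, btype="bandpass", fs=self.fs_, output="sos"
        )
        self._sos = sos
        self._zi = np.zeros((n_tet, sos.shape[0], 2))
        self._v = np.zeros(n_tet)
        self._g_hist = np.full((n_tet, N_GAIN_HISTORY), GAIN_DOWN)
        self._g_cur = np.full(n_tet, GAIN_DOWN)
        self._hist_pos = np.zeros(n_tet, dtype=np.int64)
        self._initialized = np.zeros(n_tet, dtype=np.bool_)
        self._last_trigger = np.array([-1], dtype=np.int64)
        self._n = 0
        self._t0 = t0

    def process(self, chunk: np.ndarray) -> np.ndarray:
        """Consume one raw-LFP chunk (n_tetrodes, n); return trigger times (s)."""
        chunk = np.atleast_2d(np.asarray(chunk, dtype=np.float64))
        if chunk.shape[0] != self.n_tetrodes_:
            raise ValueError("tetrode count mismatch")
        if chunk.shape[1] == 0:
            return np.array([])
        filtered = np.empty_like(chunk)
        for t in range(self.n_tetrodes_):
            filtered[t], self._zi[t] = sps.sosfilt(
                self._sos, chunk[t], zi=self._zi[t]
            )
        trig = _stream_kernel(
            np.abs(filtered),
            self._v,
            self._g_hist,
            self._g_cur,
            self._hist_pos,
            self._initialized,
            self.thresholds_,
            self.min_coincident_tetrodes,
            int(round(self.lockout * self.fs_)),
            self._last_trigger,
            self._n,
            self.use_previous_gain,
        )
        self._n += chunk.shape[1]
        return self._t0 + trig / self.fs_

    def predict(self, traces: RippleSeries) -> np.ndarray:
        """Batch driver: stream a whole series, return all trigger times."""
        if traces.n_tetrodes != self.n_tetrodes_:
            raise ValueError("tetrode count mismatch")
        self.start_stream(t0=traces.t0)
        return self.process(traces.data)

    @property
    def envelopes(self) -> np.ndarray:
        """Current per-tetrode envelope values (diagnostic)."""
        return self._v.copy()


def run_stream(
    traces: RippleSeries,
    frozen: BaselineEstimate,
    config: OnlineDetectorConfig | None = None,
) -> np.ndarray:
    """Functional batch driver: causal band-pass then the streaming core.

    Bit-identical to chunked invocation of the same detector.
    """
    config = config or OnlineDetectorConfig()
    det = OnlineRippleDetector(**{
        "band": config.band,
        "threshold_sd": config.threshold_sd,
        "min_coincident_tetrodes": config.min_coincident_tetrodes,
        "feedback_delay": config.feedback_delay,
        "lockout": config.lockout,
        "n_smooth": config.n_smooth,
        "filter_order": config.filter_order,
        "use_previous_gain": config.use_previous_gain,
    })
    det.baseline_ = frozen
    det.thresholds_ = np.atleast_1d(np.asarray(frozen.threshold(config.threshold_sd)))
    if det.thresholds_.size == 1:
        det.thresholds_ = np.repeat(det.thresholds_, traces.n_tetrodes)
    det.fs_ = traces.fs
    det.n_tetrodes_ = traces.n_tetrodes
    det.start_stream(t0=traces.t0)
    return det.process(traces.data)
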