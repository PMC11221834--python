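"""Clusterless marked-point-process decoding with a state-space movement model.

Position is decoded directly from spike *marks* (the 4-channel waveform peak
amplitudes), with no spike sorting. An encoding model is built from movement
periods (speed > 4 cm/s): per tetrode, a kernel-density estimate of the joint
mark×position intensity, plus a ground (mark-marginal) intensity and the
position occupancy. Decoding evaluates, in 2 ms bins, the Poisson
marked-point-process likelihood over position bins,

    log L_t(x) = sum_tet [ -dt * Lambda_tet(x)
                           + sum_{spikes s in bin} log lambda_tet(m_s, x) ],

and filters/smooths it through a latent movement model with two states:

* **continuous** — the representation random-walks at most one position bin
  per 2 ms step (equal probability of staying or moving to any graph-adjacent
  bin; junction bins have 3+ neighbors);
* **fragmented** — the representation may jump anywhere (uniform over bins).

A 2×2 discrete matrix couples the states. Although a uniform coupling is the
literal reading of the source method description, the default is diagonally
dominant (stay 0.98) so that sustained-state classification is meaningful;
``uniform_state_matrix=True`` selects the 0.5/0.5 coupling. The posterior is
acausal (forward-backward) by default; ``acausal=False`` gives the causal
filter only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from sklearn.base import BaseEstimator

from .signals import MarkedSpikeTrain
from .track import TrackGraph

STATES = ("continuous", "fragmented")


@dataclass
class PosteriorGrid:
    """Joint posterior over (movement state × position bin) per time bin.

    ``posterior`` has shape (n_time, 2, n_bins) and each time bin sums to 1
    over (state × position).
    """

    times: np.ndarray  # left edges of the time bins, s
    dt: float
    posterior: np.ndarray
    bin_centers_linear: np.ndarray
    bin_segment: np.ndarray

    @property
    def n_time(self) -> int:
        return self.posterior.shape[0]

    def p_continuous(self) -> np.ndarray:
        """Per-time-bin marginal probability of the continuous state."""
        return self.posterior[:, 0, :].sum(axis=1)

    def position_marginal(self) -> np.ndarray:
        """(n_time, n_bins) posterior over position, states marginalized."""
        return self.posterior.sum(axis=1)

    def map_bins(self) -> np.ndarray:
        return np.argmax(self.position_marginal(), axis=1)

    def map_positions(self) -> np.ndarray:
        return self.bin_centers_linear[self.map_bins()]

    def segment_density(self) -> dict[int, float]:
        """Time-averaged posterior mass per maze segment (sums to 1)."""
        avg = self.position_marginal().mean(axis=0)
        return {
            int(s): float(avg[self.bin_segment == s].sum())
            for s in np.unique(self.bin_segment)
        }


def continuous_transition(graph: TrackGraph) -> sparse.csr_matrix:
    """Row-stochastic one-bin random walk: uniform over {self} ∪ neighbors."""
    rows, cols, vals = [], [], []
    for b, nbrs in enumerate(graph.neighbors):
        targets = [b] + [int(x) for x in nbrs]
        p = 1.0 / len(targets)
        for t in targets:
            rows.append(b)
            cols.append(t)
            vals.append(p)
    n = graph.n_bins
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


def forward_backward(
    log_lik: np.ndarray,
    cont: sparse.csr_matrix,
    state_matrix: np.ndarray,
    acausal: bool = True,
) -> np.ndarray:
    """HMM smoother over the joint (state × position) chain.

    ``log_lik`` is (n_time, n_bins); the likelihood is shared by both states
    (it depends only on position). The joint transition kernel is
    ``T[(s,b),(s',b')] = S[s,s'] * M_{s'}[b,b']`` with ``M_cont`` the sparse
    one-bin walk and ``M_frag`` uniform — the structure is exploited so each
    step is O(n_bins). Initial prior: uniform. Returns (n_time, 2, n_bins).
    """
    n_time, n_bins = log_lik.shape
    s = state_matrix
    lik = np.exp(log_lik - log_lik.max(axis=1, keepdims=True))
    cont_t = cont.T.tocsr()
    alpha = np.empty((n_time, 2, n_bins))
    a = np.full((2, n_bins), 1.0 / (2 * n_bins))
    a = a * lik[0]
    a /= a.sum()
    alpha[0] = a
    for t in range(1, n_time):
        mix_c = s[0, 0] * a[0] + s[1, 0] * a[1]
        mix_f = s[0, 1] * a[0] + s[1, 1] * a[1]
        pred_c = cont_t @ mix_c
        pred_f = np.full(n_bins, mix_f.sum() / n_bins)
        a = np.stack((pred_c, pred_f)) * lik[t]
        a /= a.sum()
        alpha[t] = a
    if not acausal:
        return alpha
    post = np.empty_like(alpha)
    b = np.ones((2, n_bins))
    post[-1] = alpha[-1]
    for t in range(n_time - 2, -1, -1):
        w_c = lik[t + 1] * b[0]
        w_f = lik[t + 1] * b[1]
        cw = cont @ w_c
        fw = w_f.sum() / n_bins
        b = np.stack((s[0, 0] * cw + s[0, 1] * fw, s[1, 0] * cw + s[1, 1] * fw))
        b /= b.max()
        g = alpha[t] * b
        post[t] = g / g.sum()
    return post


class ClusterlessDecoder(BaseEstimator):
    """Kernel clusterless decoder over a linearized track graph.

    Parameters
    ----------
    graph : TrackGraph
    mark_bandwidth : float
        Gaussian kernel SD in mark space, µV (per channel).
    position_bandwidth : float
        Gaussian kernel SD along the track, cm (graph distances).
    dt : float
        Decoding time-bin width, s (2 ms).
    movement_speed_cutoff : float
        Only samples/spikes with speed above this (cm/s) enter the encoding
        model.
    state_stay_prob : float
        Diagonal of the 2×2 state coupling (ignored when
        ``uniform_state_matrix``).
    kernel_floor : float
        Small uniform intensity added to the joint intensity; prevents
        zero-likelihood collapse for marks outside the training support.

    Attributes
    ----------
    occupancy_ : ndarray (n_bins,) — movement occupancy time per bin, s
    ground_intensity_ : ndarray (n_tetrodes, n_bins) — spikes/s
    n_encoding_spikes_ : int
    """

    def __init__(
        self,
        graph: TrackGraph = None,
        mark_bandwidth: float = 20.0,
        position_bandwidth: float = 5.0,
        dt: float = 0.002,
        movement_speed_cutoff: float = 4.0,
        state_stay_prob: float = 0.98,
        uniform_state_matrix: bool = False,
        kernel_floor: float = 1e-10,
        acausal: bool = True,
    ):
        self.graph = graph
        self.mark_bandwidth = mark_bandwidth
        self.position_bandwidth = position_bandwidth
        self.dt = dt
        self.movement_speed_cutoff = movement_speed_cutoff
        self.state_stay_prob = state_stay_prob
        self.uniform_state_matrix = uniform_state_matrix
        self.kernel_floor = kernel_floor
        self.acausal = acausal

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        spikes: list[MarkedSpikeTrain],
        position_times: np.ndarray,
        position_linear: np.ndarray,
        speeds: np.ndarray | None = None,
        y=None,
    ) -> "ClusterlessDecoder":
        if self.graph is None:
            raise ValueError("a TrackGraph is required")
        g: TrackGraph = self.graph
        position_times = np.asarray(position_times, dtype=float)
        position_linear = np.asarray(position_linear, dtype=float)
        if speeds is None:
            speeds = np.abs(
                np.gradient(position_linear, position_times, edge_order=1)
            )
        moving = speeds > self.movement_speed_cutoff
        if not moving.any():
            raise ValueError("no movement samples above the speed cutoff")
        dt_pos = float(np.median(np.diff(position_times)))
        # smoothed occupancy time per bin (graph-aware Gaussian)
        d = g.bin_distances
        self._pos_kernel = np.exp(
            -(d**2) / (2 * self.position_bandwidth**2)
        ) / (np.sqrt(2 * np.pi) * self.position_bandwidth / g.bin_size)
        pos_bins = g.bin_of_linear(position_linear)
        counts = np.bincount(pos_bins[moving], minlength=g.n_bins).astype(float)
        self.occupancy_ = self._pos_kernel @ (counts * dt_pos)
        occ = np.maximum(self.occupancy_, 1e-12)
        # per-tetrode encoding spikes during movement
        self._enc: list[dict] = []
        ground = []
        n_enc = 0
        for train in spikes:
            idx = np.clip(
                np.searchsorted(position_times, train.times), 0, position_times.size - 1
            )
            keep = moving[idx]
            keep &= (train.times >= position_times[0]) & (
                train.times <= position_times[-1]
            )
            times = train.times[keep]
            marks = train.marks[keep]
            sbins = pos_bins[idx[keep]]
            kp = self._pos_kernel[sbins]  # (n_spikes, n_bins)
            lam_ground = kp.sum(axis=0) / occ
            ground.append(lam_ground)
            self._enc.append(
                {"times": times, "marks": marks, "bins": sbins, "kp": kp}
            )
            n_enc += times.size
        if n_enc == 0:
            raise ValueError("no spikes during movement; cannot fit encoding model")
        self.ground_intensity_ = np.stack(ground)
        self.n_encoding_spikes_ = n_enc
        self._occ = occ
        self._cont = continuous_transition(g)
        return self

    def state_matrix(self) -> np.ndarray:
        if self.uniform_state_matrix:
            return np.full((2, 2), 0.5)
        p = self.state_stay_prob
        return np.array([[p, 1 - p], [1 - p, p]])

    # -- decoding ---------------------------------------------------------

    def _mark_kernel(self, marks: np.ndarray, enc_marks: np.ndarray) -> np.ndarray:
        """(n_dec, n_enc) normalized 4-D Gaussian kernel."""
        bw = self.mark_bandwidth
        d2 = (
            np.sum(marks**2, axis=1)[:, None]
            + np.sum(enc_marks**2, axis=1)[None, :]
            - 2 * marks @ enc_marks.T
        )
        norm = (2 * np.pi * bw**2) ** (marks.shape[1] / 2)
        return np.exp(-d2 / (2 * bw**2)) / norm

    def log_likelihood(
        self,
        spikes: list[MarkedSpikeTrain],
        t_start: float,
        t_end: float,
        loo: bool = False,
    ) -> tuple[np.ndarray, np.ndarray]:
        """Per-time-bin log likelihood over position bins.

        With ``loo`` each decoded spike's own kernel contribution is removed
        from the joint-intensity evaluation (valid when the spike is part of
        the encoding set; used for movement-decoding validation).
        """
        n_time = max(int(np.ceil((t_end - t_start) / self.dt - 1e-9)), 1)
        edges = t_start + self.dt * np.arange(n_time + 1)
        ll = np.zeros((n_time, self.graph.n_bins))
        ll -= self.dt * self.ground_intensity_.sum(axis=0)[None, :]
        for tet, train in enumerate(spikes):
            enc = self._enc[tet]
            win = train.in_window(t_start, t_end)
            if win.n_spikes == 0:
                continue
            tbin = np.clip(
                ((win.times - t_start) / self.dt).astype(int), 0, n_time - 1
            )
            if enc["times"].size == 0:
                lam = np.full((win.n_spikes, self.graph.n_bins), self.kernel_floor)
            else:
                km = self._mark_kernel(win.marks, enc["marks"])
                num = km @ enc["kp"]
                if loo:
                    j = np.searchsorted(enc["times"], win.times)
                    j = np.clip(j, 0, enc["times"].size - 1)
                    own = np.isclose(enc["times"][j], win.times)
                    rows = np.flatnonzero(own)
                    norm0 = (2 * np.pi * self.mark_bandwidth**2) ** (
                        win.marks.shape[1] / 2
                    )
                    num[rows] -= enc["kp"][j[rows]] / norm0
                    num = np.maximum(num, 0.0)
                lam = num / self._occ[None, :] + self.kernel_floor
            np.add.at(ll, tbin, np.log(lam))
        return ll, edges[:-1]

    def decode(
        self,
        spikes: list[MarkedSpikeTrain],
        t_start: float,
        t_end: float,
        loo: bool = False,
    ) -> PosteriorGrid:
        """Posterior over (state × position) for a time window."""
        if not hasattr(self, "ground_intensity_"):
            raise ValueError("decoder is not fitted")
        if t_end <= t_start:
            raise ValueError("empty decode window")
        ll, times = self.log_likelihood(spikes, t_start, t_end, loo=loo)
        post = forward_backward(ll, self._cont, self.state_matrix(), self.acausal)
        return PosteriorGrid(
            times=times,
            dt=self.dt,
            posterior=post,
            bin_centers_linear=self.graph.bin_centers_linear,
            bin_segment=self.graph.bin_segment,
        )

    def decode_movement_loo(
        self,
        spikes: list[MarkedSpikeTrain],
        position_times: np.ndarray,
        position_linear: np.ndarray,
        t_start: float | None = None,
        t_end: float | None = None,
        speeds: np.ndarray | None = None,
    ) -> dict:
        """Leave-one-spike-out decoding error during movement.

        Decodes the window with each spike excluded from its own likelihood
        evaluation, takes the MAP position per 2 ms bin, and reports the
        graph-distance error (cm) against the animal's true position,
        restricted to bins where the animal is moving above the speed
        cutoff. ``low_spike_warning`` flags fewer than 100 decoded spikes.
        """
        position_times = np.asarray(position_times, dtype=float)
        position_linear = np.asarray(position_linear, dtype=float)
        t_start = position_times[0] if t_start is None else t_start
        t_end = position_times[-1] if t_end is None else t_end
        grid = self.decode(spikes, t_start, t_end, loo=True)
        if speeds is None:
            speeds = np.abs(np.gradient(position_linear, position_times, edge_order=1))
        idx = np.clip(
            np.searchsorted(position_times, grid.times), 0, position_times.size - 1
        )
        moving = speeds[idx] > self.movement_speed_cutoff
        true_bins = self.graph.bin_of_linear(position_linear[idx])
        map_bins = grid.map_bins()
        errors = self.graph.bin_distances[map_bins[moving], true_bins[moving]]
        n_spk = sum(t.in_window(t_start, t_end).n_spikes for t in spikes)
        return {
            "errors_cm": errors,
            "median_error_cm": float(np.median(errors)) if errors.size else np.nan,
            "n_spikes": int(n_spk),
            "low_spike_warning": n_spk < 100,
            "posterior": grid,
        }
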