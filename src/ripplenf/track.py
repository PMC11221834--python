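"""Maze geometry, 1-D linearization, and the position-bin graph.

The task environment is an eight-arm maze: a home segment leads to a central
corridor from whose far end eight arms radiate. For decoding, 2-D tracked
position is collapsed onto the 1-D skeleton of this graph and binned (5 cm
default). Bins carry the segment they belong to, and bin *adjacency follows
the graph*, not the concatenated 1-D coordinate: the last corridor bin is a
junction adjacent to the first bin of every arm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SEGMENT_NAMES = ["home", "center"] + [f"arm{i}" for i in range(1, 9)]


@dataclass
class TrackGraph:
    """Binned 1-D track skeleton embedded in 2-D.

    Attributes
    ----------
    segment_names : list of str
    segment_lengths : ndarray (n_segments,)
        Lengths in cm.
    segment_p0, segment_p1 : ndarray (n_segments, 2)
        2-D endpoints of each segment's skeleton line.
    bin_size : float
        Bin width in cm.
    bin_segment : ndarray (n_bins,) int
        Segment index of each bin.
    bin_centers : ndarray (n_bins,)
        Distance of each bin center along its own segment.
    bin_centers_linear : ndarray (n_bins,)
        Global 1-D coordinate (segments concatenated in canonical order).
    neighbors : list of ndarray
        Graph-adjacent bins of each bin (never includes the bin itself).
    """

    segment_names: list[str]
    segment_lengths: np.ndarray
    segment_p0: np.ndarray
    segment_p1: np.ndarray
    bin_size: float
    # derived
    bin_segment: np.ndarray = field(init=False)
    bin_centers: np.ndarray = field(init=False)
    bin_centers_linear: np.ndarray = field(init=False)
    segment_offsets: np.ndarray = field(init=False)
    neighbors: list = field(init=False)

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        self.segment_lengths = np.asarray(self.segment_lengths, dtype=float)
        self.segment_p0 = np.asarray(self.segment_p0, dtype=float)
        self.segment_p1 = np.asarray(self.segment_p1, dtype=float)
        n_bins_per_seg = np.maximum(
            np.round(self.segment_lengths / self.bin_size).astype(int), 1
        )
        seg_ids, centers = [], []
        for s, nb in enumerate(n_bins_per_seg):
            width = self.segment_lengths[s] / nb
            seg_ids.extend([s] * nb)
            centers.extend(((np.arange(nb) + 0.5) * width).tolist())
        self.bin_segment = np.asarray(seg_ids, dtype=int)
        self.bin_centers = np.asarray(centers, dtype=float)
        self.segment_offsets = np.concatenate(([0.0], np.cumsum(self.segment_lengths)))[:-1]
        self.bin_centers_linear = self.segment_offsets[self.bin_segment] + self.bin_centers
        self.neighbors = self._build_adjacency(n_bins_per_seg)

    def _build_adjacency(self, n_bins_per_seg: np.ndarray) -> list:
        n = self.n_bins
        adj: list[set[int]] = [set() for _ in range(n)]
        seg_first = np.concatenate(([0], np.cumsum(n_bins_per_seg)))[:-1]
        seg_last = seg_first + n_bins_per_seg - 1
        for b in range(n - 1):
            if self.bin_segment[b] == self.bin_segment[b + 1]:
                adj[b].add(b + 1)
                adj[b + 1].add(b)
        # junctions: home end <-> center start; center end <-> every arm start
        home, center = 0, 1
        adj[seg_last[home]].add(seg_first[center])
        adj[seg_first[center]].add(seg_last[home])
        for arm in range(2, len(self.segment_names)):
            adj[seg_last[center]].add(seg_first[arm])
            adj[seg_first[arm]].add(seg_last[center])
        return [np.array(sorted(a), dtype=int) for a in adj]

    @property
    def n_bins(self) -> int:
        return self.bin_segment.size

    @property
    def bin_distances(self) -> np.ndarray:
        """Pairwise graph distances between bin centers, cm (cached)."""
        if not hasattr(self, "_bin_distances"):
            from scipy.sparse import lil_matrix
            from scipy.sparse.csgraph import shortest_path

            n = self.n_bins
            w = lil_matrix((n, n))
            for b, nbrs in enumerate(self.neighbors):
                for nb in nbrs:
                    w[b, nb] = self.bin_size
            self._bin_distances = shortest_path(w.tocsr(), directed=False)
        return self._bin_distances

    @property
    def n_segments(self) -> int:
        return len(self.segment_names)

    @property
    def total_length(self) -> float:
        return float(self.segment_lengths.sum())

    def segment_index(self, name: str) -> int:
        return self.segment_names.index(name)

    def bin_of(self, segment: int | str, along: float) -> int:
        """Bin index for a within-segment coordinate."""
        if isinstance(segment, str):
            segment = self.segment_index(segment)
        in_seg = np.flatnonzero(self.bin_segment == segment)
        return int(in_seg[np.argmin(np.abs(self.bin_centers[in_seg] - along))])

    def bin_of_linear(self, linear: np.ndarray) -> np.ndarray:
        """Nearest bin for global 1-D coordinates."""
        linear = np.atleast_1d(np.asarray(linear, dtype=float))
        idx = np.searchsorted(self.bin_centers_linear, linear)
        idx = np.clip(idx, 1, self.n_bins - 1)
        left = idx - 1
        choose_left = np.abs(linear - self.bin_centers_linear[left]) <= np.abs(
            linear - self.bin_centers_linear[idx]
        )
        return np.where(choose_left, left, idx)

    def linear_to_xy(self, linear: np.ndarray) -> np.ndarray:
        """2-D skeleton coordinates of global 1-D positions."""
        linear = np.atleast_1d(np.asarray(linear, dtype=float))
        seg = np.clip(
            np.searchsorted(self.segment_offsets, linear, side="right") - 1,
            0,
            self.n_segments - 1,
        )
        along = linear - self.segment_offsets[seg]
        frac = np.clip(along / self.segment_lengths[seg], 0.0, 1.0)
        return self.segment_p0[seg] + frac[:, None] * (
            self.segment_p1[seg] - self.segment_p0[seg]
        )


def bin_path(graph: TrackGraph, b_from: int, b_to: int) -> np.ndarray:
    """Shortest bin-to-bin path on the track graph (BFS, inclusive ends)."""
    if b_from == b_to:
        return np.array([b_from], dtype=int)
    prev = {b_from: None}
    frontier = [b_from]
    while frontier and b_to not in prev:
        nxt = []
        for b in frontier:
            for nb in graph.neighbors[b]:
                if int(nb) not in prev:
                    prev[int(nb)] = b
                    nxt.append(int(nb))
        frontier = nxt
    if b_to not in prev:
        raise ValueError("track graph is disconnected")
    path = [b_to]
    while prev[path[-1]] is not None:
        path.append(prev[path[-1]])
    return np.array(path[::-1], dtype=int)


def make_eight_arm_maze(
    home_length: float = 30.0,
    center_length: float = 50.0,
    arm_length: float = 80.0,
    bin_size: float = 5.0,
    arm_fan_degrees: float = 154.0,
) -> TrackGraph:
    """Default eight-arm maze skeleton.

    The home segment runs up to the origin, the central corridor continues
    vertically, and eight arms fan out from the corridor's far end across
    ``arm_fan_degrees``.
    """
    p0 = [(0.0, -home_length), (0.0, 0.0)]
    p1 = [(0.0, 0.0), (0.0, center_length)]
    hub = np.array([0.0, center_length])
    angles = np.deg2rad(np.linspace(-arm_fan_degrees / 2, arm_fan_degrees / 2, 8))
    for a in angles:
        direction = np.array([np.sin(a), np.cos(a)])
        p0.append(tuple(hub))
        p1.append(tuple(hub + arm_length * direction))
    lengths = [home_length, center_length] + [arm_length] * 8
    return TrackGraph(
        segment_names=list(SEGMENT_NAMES),
        segment_lengths=np.array(lengths),
        segment_p0=np.array(p0),
        segment_p1=np.array(p1),
        bin_size=bin_size,
    )


def linearize(
    position_2d: np.ndarray,
    graph: TrackGraph,
    off_track_gate: float = 20.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Project 2-D positions onto the track skeleton.

    Each sample is projected to the nearest point on any segment's skeleton
    line; ties go to the lower-indexed segment. Returns ``(linear, segment,
    projection_error, off_track)`` where ``linear`` is the global 1-D
    coordinate, ``projection_error`` the perpendicular distance in cm, and
    ``off_track`` flags samples farther than ``off_track_gate`` from every
    segment.
    """
    xy = np.atleast_2d(np.asarray(position_2d, dtype=float))
    if xy.shape[1] != 2:
        raise ValueError("position_2d must have shape (n, 2)")
    n_seg = graph.n_segments
    d0 = graph.segment_p1 - graph.segment_p0  # (n_seg, 2)
    seg_len2 = np.sum(d0**2, axis=1)
    # t parameter of the projection of every point onto every segment
    rel = xy[:, None, :] - graph.segment_p0[None, :, :]  # (n, n_seg, 2)
    t = np.clip(np.sum(rel * d0[None], axis=2) / seg_len2[None], 0.0, 1.0)
    proj = graph.segment_p0[None] + t[..., None] * d0[None]
    dist = np.linalg.norm(xy[:, None, :] - proj, axis=2)  # (n, n_seg)
    # lower-indexed segment wins ties: argmin returns the first minimum
    seg = np.argmin(np.round(dist, 9), axis=1)
    rows = np.arange(xy.shape[0])
    along = t[rows, seg] * graph.segment_lengths[seg]
    linear = graph.segment_offsets[seg] + along
    err = dist[rows, seg]
    return linear, seg, err, err > off_track_gate
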