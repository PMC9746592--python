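"""Seeded synthetic panels with known over-time cluster structure.

The merge/split scenario emulates a benchmark for over-time stability
methods: four groups of 2-d series in [0, 1]^2, each member sampled
within a fixed radius of its group centroid at every timestamp, with a
schedule under which only three clusters are *visible* at any time —
two groups share a centroid before the switch timestamp and split
there, while two others merge from that timestamp on.  On top, a few
*transition outliers* are injected: series re-assigned to a uniformly
random group centroid at every timestamp, so they hop between the
visible clusters instead of staying with their peers.

Defaults: 4 groups x 10 members, 6 timestamps, radius 0.1, switch at
the 4th timestamp, 3 injected outliers — 43 series in total, with the
outliers carrying the highest entity ids (40..42).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .data_model import Cluster, OverTimeClustering, TimeSeriesPanel

__all__ = ["ScenarioSpec", "generate_merge_split", "generate_stable"]


#: centroid layout: the splitting pair (A, B) lives on the left, the
#: merging pair (C, D) on the right.  A cluster splits into two nearby
#: clusters (and two nearby clusters merge), so paired centroids sit a
#: modest distance apart while the pairs themselves are well separated.
_PRE_POSITIONS = np.array(
    [
        [0.2, 0.5],  # A (merged with B)
        [0.2, 0.5],  # B
        [0.8, 0.35],  # C
        [0.8, 0.65],  # D
    ]
)
_POST_POSITIONS = np.array(
    [
        [0.2, 0.35],  # A (split from B)
        [0.2, 0.65],  # B
        [0.8, 0.5],  # C (merged with D)
        [0.8, 0.5],  # D
    ]
)


@dataclass(frozen=True)
class ScenarioSpec:
    """Parameters of the merge/split scenario.

    ``switch_at`` is the 1-based timestamp position at which one
    visible cluster splits and two others merge (default 4, i.e. the
    fourth of six timestamps).
    """

    n_groups: int = 4
    per_group: int = 10
    n_timestamps: int = 6
    radius: float = 0.1
    n_outliers: int = 3
    dims: int = 2
    switch_at: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.n_groups != 4:
            raise ValueError("the merge/split schedule is defined for exactly 4 groups")
        if not (1 < self.switch_at <= self.n_timestamps):
            raise ValueError("switch timestamp must lie within the panel")
        if self.dims != 2:
            raise ValueError("the merge/split scenario is two-dimensional")


def _centroid_layout(spec: ScenarioSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-timestamp centroid position of each group plus visible-cluster labels.

    Returns ``positions`` of shape (n_timestamps, 4, dims) and integer
    ``visible`` labels of shape (n_timestamps, 4): groups sharing a
    position share a visible label, so exactly three clusters are
    visible at every timestamp.
    """
    # groups: A=0, B=1, C=2, D=3.  Before the switch A and B share one
    # centroid (one visible cluster) and C, D sit apart; from the
    # switch on, A and B split while C and D merge.
    pre_pos, post_pos = _PRE_POSITIONS, _POST_POSITIONS
    pre_vis = np.array([0, 0, 1, 2])
    post_vis = np.array([0, 1, 2, 2])
    positions = np.empty((spec.n_timestamps, 4, spec.dims))
    visible = np.empty((spec.n_timestamps, 4), dtype=int)
    for t in range(spec.n_timestamps):
        if t + 1 < spec.switch_at:
            positions[t], visible[t] = pre_pos, pre_vis
        else:
            positions[t], visible[t] = post_pos, post_vis
    # distinct visible centroids must be separated enough for the
    # visible-cluster ground truth to be unambiguous
    for t in range(spec.n_timestamps):
        uniq = np.unique(visible[t])
        for i, a in enumerate(uniq):
            for b in uniq[i + 1 :]:
                pa = positions[t][visible[t] == a][0]
                pb = positions[t][visible[t] == b][0]
                if np.linalg.norm(pa - pb) < 2 * spec.radius:
                    raise ValueError("centroids closer than 2*radius: visible clusters ambiguous")
    return positions, visible


def _sample_in_ball(rng: np.random.Generator, center: np.ndarray, radius: float) -> np.ndarray:
    """Uniform draw from the L2 ball around ``center``, rejected into [0, 1]^d."""
    d = center.shape[0]
    while True:
        u = rng.standard_normal(d)
        u /= np.linalg.norm(u)
        r = radius * rng.random() ** (1.0 / d)
        x = center + r * u
        if np.all(x >= 0.0) and np.all(x <= 1.0):
            return x


def generate_merge_split(
    spec: ScenarioSpec | None = None,
) -> tuple[TimeSeriesPanel, OverTimeClustering, frozenset]:
    """Generate the merge/split panel, its visible-cluster ground truth and the outlier ids.

    Regular series keep their group for the whole period; at every
    timestamp each injected outlier is independently re-assigned to a
    uniformly random group centroid.  The ground-truth labeling assigns
    every series (outliers included) to the visible cluster of the
    centroid it was sampled around.  Fully deterministic given the seed.
    """
    spec = spec or ScenarioSpec()
    rng = np.random.default_rng(spec.seed)
    positions, visible = _centroid_layout(spec)
    n_regular = spec.n_groups * spec.per_group
    entity_ids = tuple(range(n_regular + spec.n_outliers))
    outlier_ids = frozenset(range(n_regular, n_regular + spec.n_outliers))
    timestamps = tuple(range(1, spec.n_timestamps + 1))

    values: dict[tuple[Hashable, Hashable], np.ndarray] = {}
    labels: dict[tuple[Hashable, Hashable], int] = {}
    for t_idx, t in enumerate(timestamps):
        for e in entity_ids:
            if e < n_regular:
                group = e // spec.per_group
            else:
                group = int(rng.integers(spec.n_groups))
            values[(e, t)] = _sample_in_ball(rng, positions[t_idx, group], spec.radius)
            labels[(e, t)] = int(visible[t_idx, group])
    panel = TimeSeriesPanel(entity_ids=entity_ids, timestamps=timestamps, values=values)
    truth = OverTimeClustering.from_labels(labels, timestamps, panel=panel)
    return panel, truth, outlier_ids


def generate_stable(
    n_entities: int,
    n_timestamps: int,
    n_groups: int,
    seed: int = 0,
    radius: float = 0.05,
) -> tuple[TimeSeriesPanel, OverTimeClustering]:
    """Well-separated groups with constant membership: a perfectly stable clustering.

    Every subsequence score of the ground-truth labeling is 1, so CLOSE
    with a zero-deficiency quality equals ``1 - (n/N_C)^2`` exactly and
    FCSETS on the crisp-embedded labeling equals 1.
    """
    if n_groups < 1:
        raise ValueError("need at least one group")
    if n_entities < n_groups:
        raise ValueError("need at least one entity per group")
    rng = np.random.default_rng(seed)
    # centroids on a diagonal grid, pairwise distance > 2*radius
    base = np.linspace(0.1, 0.9, n_groups)
    centroids = np.column_stack([base, base[::-1]])
    if n_groups > 1:
        gap = np.linalg.norm(centroids[0] - centroids[1])
        if gap < 2 * radius:
            raise ValueError("groups too close for the given radius")
    timestamps = tuple(range(1, n_timestamps + 1))
    entity_ids = tuple(range(n_entities))
    values: dict[tuple[Hashable, Hashable], np.ndarray] = {}
    labels: dict[tuple[Hashable, Hashable], int] = {}
    for t in timestamps:
        for e in entity_ids:
            g = e % n_groups
            values[(e, t)] = _sample_in_ball(rng, centroids[g], radius)
            labels[(e, t)] = g
    panel = TimeSeriesPanel(entity_ids=entity_ids, timestamps=timestamps, values=values)
    truth = OverTimeClustering.from_labels(labels, timestamps, panel=panel)
    return panel, truth
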