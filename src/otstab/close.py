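"""CLOSE: over-time stability scoring of crisp per-timestamp clusterings.

The score rates how well the time series of a panel keep their cluster
peers over time ("team spirit").  Every data point is rated by the
average proportion of its earlier cluster peers that are grouped with
it again at the considered timestamp; clusters are rated by the mean of
their members' scores, normalized by how many earlier clusters merged
into them; the clustering score combines per-cluster stability and an
arbitrary [0, 1] quality measure with pre-factors ``1/N_C`` and
``1 - (n/N_C)^2`` and is clamped to 0 when the number of clusters does
not exceed the number of timestamps.

Variants: an *exploitation term* ``N_co/N_o`` multiplying the score
(penalizes noise-heavy clusterings), a clustering-level-quality form
(normalized by ``1/n``, quality evaluated per time clustering), the
Jaccard proportion and Gauss-weighted subsequence scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Hashable, Literal

import numpy as np
import pandas as pd

from .data_model import NOISE, Cluster, Noise, OverTimeClustering, TimeSeriesPanel

__all__ = [
    "CloseOptions",
    "CloseReport",
    "QualityMeasure",
    "temporal_intersection",
    "proportion",
    "cid",
    "subsequence_score",
    "merge_count",
    "cluster_ot_stability",
    "ot_stability_from_components",
    "mse_quality",
    "exploitation_quality",
    "close_score",
    "get_quality_measure",
]


# ---------------------------------------------------------------------------
# transition primitives
# ---------------------------------------------------------------------------


def temporal_intersection(cluster_a: Cluster, cluster_b: Cluster, clustering: OverTimeClustering) -> frozenset:
    """Entities in ``cluster_a`` at its timestamp AND in ``cluster_b`` at its later one."""
    if clustering.ordinal(cluster_a.timestamp) >= clustering.ordinal(cluster_b.timestamp):
        raise ValueError("temporal intersection requires cluster_a strictly before cluster_b")
    return cluster_a.members & cluster_b.members


def proportion(
    cluster_a: Cluster | None, cluster_b: Cluster | None, clustering: OverTimeClustering
) -> float:
    """Asymmetric proportion of ``cluster_a``'s members grouped together again in ``cluster_b``.

    ``None`` stands for the empty sentinel returned by :func:`cid` for
    noise points; the proportion of an empty earlier cluster is 0.
    """
    if cluster_a is None:
        return 0.0
    if cluster_b is None:
        return 0.0
    inter = temporal_intersection(cluster_a, cluster_b, clustering)
    return len(inter) / len(cluster_a)


def cid(
    entity: Hashable, timestamp: Hashable, clustering: OverTimeClustering
) -> Cluster | None:
    """Cluster-identity function: the point's cluster, or ``None`` for noise."""
    try:
        state = clustering.state(entity, timestamp)
    except KeyError:
        raise KeyError(f"entity {entity!r} is absent at timestamp {timestamp!r}") from None
    if state is NOISE:
        return None
    return clustering.clusters[state]


def _proportion_fn(kind: str) -> Callable:
    if kind == "asymmetric":
        return proportion
    if kind == "jaccard":
        from .doots import jaccard_proportion

        return jaccard_proportion
    raise ValueError(f"unknown proportion kind {kind!r}")


# ---------------------------------------------------------------------------
# options
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QualityMeasure:
    """A cluster- or clustering-level quality function on the unit interval.

    ``direction`` states how the value enters the score: a *deficiency*
    (lower is better) enters as ``1 - q``, a *quality* (higher is
    better) enters as ``q`` directly.
    """

    name: str
    level: Literal["cluster", "clustering"]
    direction: Literal["deficiency", "quality"]
    fn: Callable

    def factor(self, q: float) -> float:
        if not (0.0 <= q <= 1.0 + 1e-12):
            raise ValueError(f"quality measure {self.name!r} returned {q!r}, outside [0, 1]")
        return q if self.direction == "quality" else 1.0 - q


@dataclass(frozen=True)
class CloseOptions:
    """Configuration of the CLOSE score.

    Parameters
    ----------
    quality
        Name of a registered quality measure ("mse", "exploitation",
        "zero") or a :class:`QualityMeasure`.
    use_exploitation_term
        Multiply the score by ``N_co / N_o`` (clustered points over all
        existing points).
    clustering_level_quality
        Use the clustering-level form (``1/n`` normalization, average
        cluster stability and quality per time clustering).
    proportion_kind
        "asymmetric" (merges unpunished) or "jaccard" (merges punished).
    weighted_subsequences
        Gauss-weight the proportions inside subsequence scores so the
        nearer past counts more.
    """

    quality: str | QualityMeasure = "mse"
    use_exploitation_term: bool = False
    clustering_level_quality: bool = False
    proportion_kind: Literal["asymmetric", "jaccard"] = "asymmetric"
    weighted_subsequences: bool = False

    def resolve_quality(self) -> QualityMeasure:
        qm = get_quality_measure(self.quality) if isinstance(self.quality, str) else self.quality
        if qm.level == "clustering" and not self.clustering_level_quality:
            raise ValueError(
                f"{qm.name!r} is a clustering-level measure; set clustering_level_quality=True"
            )
        return qm


# ---------------------------------------------------------------------------
# subsequence and cluster scores
# ---------------------------------------------------------------------------


def subsequence_score(
    entity: Hashable,
    t_k: Hashable,
    clustering: OverTimeClustering,
    options: CloseOptions | None = None,
) -> float:
    """Full-history subsequence score of a data point.

    The mean (Gauss-weighted mean when ``weighted_subsequences``) of the
    proportions linking the entity's cluster at every earlier existing
    timestamp to its cluster at ``t_k``.  A noise point at ``t_k``
    scores 0.  The normalization divides by the number of summed
    proportion terms, i.e. the count of earlier timestamps where the
    entity exists.
    """
    options = options or CloseOptions()
    if not clustering.exists(entity, t_k):
        raise KeyError(f"entity {entity!r} absent at {t_k!r}")
    k_idx = clustering.ordinal(t_k)
    earlier = [
        t for t in clustering.timestamps[:k_idx] if clustering.exists(entity, t)
    ]
    if not earlier:
        raise ValueError(
            f"subsequence score undefined: {entity!r} has no earlier existing timestamp before {t_k!r}"
        )
    if clustering.state(entity, t_k) is NOISE:
        return 0.0
    prop = _proportion_fn(options.proportion_kind)
    target = cid(entity, t_k, clustering)
    props = [prop(cid(entity, t, clustering), target, clustering) for t in earlier]
    k = len(props)
    if options.weighted_subsequences:
        weights = gauss_weights(k)
        return float(sum(w * p for w, p in zip(weights, props)))
    return float(sum(props) / k)


def gauss_weights(k: int) -> list[float]:
    """Triangular recency weights ``2a / (k(k+1))`` for ``a = 1..k``; they sum to 1."""
    if k < 1:
        raise ValueError("gauss_weights requires k >= 1")
    return [2.0 * a / (k * (k + 1)) for a in range(1, k + 1)]


def merge_count(cluster: Cluster, clustering: OverTimeClustering) -> int:
    """Number of distinct earlier clusters sharing at least one entity with ``cluster``.

    Noise states at earlier timestamps are never counted.
    """
    k_idx = clustering.ordinal(cluster.timestamp)
    seen: set[str] = set()
    for t in clustering.timestamps[:k_idx]:
        for e in cluster.members:
            state = clustering.assignment.get((e, t))
            if state is not None and state is not NOISE:
                seen.add(state)
    return len(seen)


def ot_stability_from_components(
    member_scores: list[float] | tuple[float, ...],
    n_merged: int,
    n_prior_timestamps: int,
) -> float:
    """Cluster over-time stability from its ingredients.

    ``(mean member subsequence score) / (n_merged / n_prior_timestamps)``,
    where ``n_prior_timestamps`` is the number of panel timestamps
    strictly before the cluster's own.  Defined as 0 when no earlier
    cluster merged in (the numerator is then 0 as well).
    """
    if n_prior_timestamps < 1:
        raise ValueError("cluster must sit at the second timestamp or later")
    if n_merged == 0:
        return 0.0
    if not member_scores:
        return 0.0
    mean_score = sum(member_scores) / len(member_scores)
    return mean_score / (n_merged / n_prior_timestamps)


def cluster_ot_stability(
    cluster: Cluster,
    clustering: OverTimeClustering,
    options: CloseOptions | None = None,
) -> float:
    """Over-time stability of a cluster (1.0 for first-timestamp clusters).

    Members first appearing at the cluster's own timestamp have no
    history to score and are excluded from the member average.
    """
    options = options or CloseOptions()
    k_idx = clustering.ordinal(cluster.timestamp)
    if k_idx == 0:
        return 1.0
    scores = []
    for e in sorted(cluster.members, key=str):
        has_history = any(
            clustering.exists(e, t) for t in clustering.timestamps[:k_idx]
        )
        if has_history:
            scores.append(subsequence_score(e, cluster.timestamp, clustering, options))
    return ot_stability_from_components(scores, merge_count(cluster, clustering), k_idx)


# ---------------------------------------------------------------------------
# quality measures
# ---------------------------------------------------------------------------


def mse_quality(cluster: Cluster, panel: TimeSeriesPanel) -> float:
    """Mean squared member-to-centroid distance, scaled by the dimension.

    A deficiency in [0, 1]; requires features normalized to [0, 1]^d.
    """
    X = np.vstack([panel.vector(e, cluster.timestamp) for e in sorted(cluster.members, key=str)])
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValueError("MSE quality requires features normalized to [0, 1]^d")
    centroid = X.mean(axis=0)
    d = X.shape[1]
    return float(np.mean(np.sum((X - centroid) ** 2, axis=1)) / d)


def exploitation_quality(
    clustering: OverTimeClustering, timestamp: Hashable, panel: TimeSeriesPanel | None = None
) -> float:
    """Fraction of existing objects at a timestamp that are assigned to a cluster.

    A quality-direction, clustering-level measure suited to
    density-based clusterings where compactness is already enforced by
    the algorithm and the aim is to minimize noise.
    """
    states = [st for (e, t), st in clustering.assignment.items() if t == timestamp]
    if not states:
        raise ValueError(f"no existing objects at timestamp {timestamp!r}")
    return sum(1 for st in states if st is not NOISE) / len(states)


_QUALITY_REGISTRY: dict[str, QualityMeasure] = {
    "mse": QualityMeasure("mse", "cluster", "deficiency", mse_quality),
    "exploitation": QualityMeasure(
        "exploitation", "clustering", "quality", exploitation_quality
    ),
    # zero deficiency: scores pure over-time stability (useful for closed forms)
    "zero": QualityMeasure("zero", "cluster", "deficiency", lambda cluster, panel: 0.0),
}


def get_quality_measure(name: str) -> QualityMeasure:
    try:
        return _QUALITY_REGISTRY[name]
    except KeyError:
        raise ValueError(
            f"unknown quality measure {name!r}; available: {sorted(_QUALITY_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class CloseReport:
    """CLOSE score with its per-cluster and per-point decompositions."""

    score: float
    raw_score: float
    n_timestamps: int
    n_clusters: int
    n_clustered_points: int
    n_points: int
    per_cluster: pd.DataFrame
    per_point: pd.DataFrame
    options: CloseOptions
    warnings: list[str] = field(default_factory=list)

    @property
    def prefactor_average(self) -> float:
        denom = self.n_timestamps if self.options.clustering_level_quality else self.n_clusters
        return 1.0 / denom

    @property
    def prefactor_penalty(self) -> float:
        return 1.0 - (self.n_timestamps / self.n_clusters) ** 2

    def to_frame(self) -> pd.DataFrame:
        return self.per_cluster

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "raw_score": self.raw_score,
            "n_timestamps": self.n_timestamps,
            "n_clusters": self.n_clusters,
            "n_clustered_points": self.n_clustered_points,
            "n_points": self.n_points,
            "prefactor_average": self.prefactor_average,
            "prefactor_penalty": self.prefactor_penalty,
            "options": {
                "quality": self.options.quality
                if isinstance(self.options.quality, str)
                else self.options.quality.name,
                "use_exploitation_term": self.options.use_exploitation_term,
                "clustering_level_quality": self.options.clustering_level_quality,
                "proportion_kind": self.options.proportion_kind,
                "weighted_subsequences": self.options.weighted_subsequences,
            },
            "warnings": list(self.warnings),
            "per_cluster": self.per_cluster.to_dict(orient="records"),
            "per_point": self.per_point.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = [
            "CLOSE over-time stability report",
            "--------------------------------",
            f"score                 {self.score:.6f}",
            f"clusters (N_C)        {self.n_clusters}",
            f"timestamps (n)        {self.n_timestamps}",
            f"pre-factor 1/N_C      {self.prefactor_average:.6f}",
            f"pre-factor 1-(n/N_C)^2 {self.prefactor_penalty:.6f}",
            f"clustered/all points  {self.n_clustered_points}/{self.n_points}",
            f"proportion            {self.options.proportion_kind}",
            f"weighted subsequences {self.options.weighted_subsequences}",
        ]
        if self.warnings:
            lines.append("warnings: " + "; ".join(self.warnings))
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# the score
# ---------------------------------------------------------------------------


def close_score(
    clustering: OverTimeClustering,
    panel: TimeSeriesPanel | None = None,
    options: CloseOptions | None = None,
) -> CloseReport:
    """Compute the CLOSE over-time stability score of a crisp clustering.

    The standard form is

    ``(1/N_C) * (1 - (n/N_C)^2) * sum_C ot_stability(C) * (1 - quality(C))``

    clamped to 0 when ``N_C <= n``.  With ``use_exploitation_term`` the
    sum is further multiplied by ``N_co/N_o``; with
    ``clustering_level_quality`` the clustering-level form (``1/n``
    normalization, per-time-clustering average stability and quality)
    is used instead.
    """
    options = options or CloseOptions()
    qm = options.resolve_quality()
    n = clustering.n_timestamps
    if n < 2:
        raise ValueError("stability scoring requires at least 2 timestamps")
    n_clusters = clustering.n_clusters
    warnings: list[str] = []

    # per-point subsequence scores (wherever defined)
    point_rows = []
    for e in clustering.entities():
        existing = clustering.existing_timestamps(e)
        for t in existing[1:]:
            point_rows.append(
                {
                    "entity": e,
                    "time": t,
                    "subseq_score": subsequence_score(e, t, clustering, options),
                }
            )
    per_point = pd.DataFrame(point_rows, columns=["entity", "time", "subseq_score"])

    # per-cluster stability (+ quality for the cluster-level path)
    cluster_rows = []
    for c in clustering.iter_clusters():
        stab = cluster_ot_stability(c, clustering, options)
        row = {
            "cluster": c.cid,
            "time": c.timestamp,
            "n_members": len(c),
            "merge_count": merge_count(c, clustering),
            "ot_stability": stab,
        }
        if qm.level == "cluster":
            row["quality"] = qm.fn(c, panel)
        cluster_rows.append(row)
    per_cluster = pd.DataFrame(cluster_rows)

    if n_clusters == 0:
        warnings.append("clustering contains no clusters at all")
        return CloseReport(
            score=0.0,
            raw_score=0.0,
            n_timestamps=n,
            n_clusters=0,
            n_clustered_points=0,
            n_points=len(clustering.assignment),
            per_cluster=per_cluster,
            per_point=per_point,
            options=options,
            warnings=warnings,
        )

    for t in clustering.timestamps:
        if not clustering.clusters_at(t):
            warnings.append(f"timestamp {t!r} has zero clusters")

    penalty = 1.0 - (n / n_clusters) ** 2

    if options.clustering_level_quality:
        total = 0.0
        for t in clustering.timestamps:
            at_t = per_cluster[per_cluster["time"] == t] if len(per_cluster) else per_cluster
            if len(at_t) == 0:
                continue
            avg_stab = float(at_t["ot_stability"].mean())
            if qm.level == "clustering":
                q = qm.fn(clustering, t, panel)
            else:
                q = float(at_t["quality"].mean())
            total += avg_stab * qm.factor(q)
        raw = (1.0 / n) * penalty * total
    else:
        total = float(
            sum(
                row["ot_stability"] * qm.factor(row["quality"])
                for row in cluster_rows
            )
        )
        raw = (1.0 / n_clusters) * penalty * total

    n_points = len(clustering.assignment)
    n_clustered = sum(1 for st in clustering.assignment.values() if st is not NOISE)
    if options.use_exploitation_term:
        raw *= n_clustered / n_points if n_points else 0.0

    score = max(0.0, raw)
    return CloseReport(
        score=score,
        raw_score=raw,
        n_timestamps=n,
        n_clusters=n_clusters,
        n_clustered_points=n_clustered,
        n_points=n_points,
        per_cluster=per_cluster,
        per_point=per_point,
        options=options,
        warnings=warnings,
    )
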