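"""DOOTS: detection of transition-based anomalous subsequences.

A subsequence of a time series is anomalous when it is significantly
less over-time stable than its cluster peers at its final timestamp.
Every subsequence is scored against the *best* (leader) subsequence
score within its endpoint cluster; the gap is the outlier score, and a
subsequence is flagged when the gap reaches a user threshold ``tau``.

Four variants cross the proportion (asymmetric vs. Jaccard) with the
subsequence weighting (uniform vs. Gauss-weighted recency):
DOOTS, wDOOTS, jDOOTS, jwDOOTS.

Two further outlier types need no threshold: subsequences consisting
entirely of noise points (*intuitive outliers*) and single noise
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Literal

import pandas as pd

from .close import cid, gauss_weights, proportion, temporal_intersection
from .data_model import NOISE, Cluster, OverTimeClustering, TimeSeriesPanel

__all__ = [
    "DootsOptions",
    "OutlierRecord",
    "OutlierReport",
    "temporal_union",
    "jaccard_proportion",
    "windowed_subsequence_score",
    "weighted_subsequence_score",
    "best_score",
    "subsequence_outlier_scores",
    "outlier_score",
    "detect_outliers",
    "VARIANTS",
]


# ---------------------------------------------------------------------------
# Jaccard proportion
# ---------------------------------------------------------------------------


def temporal_union(
    cluster_a: Cluster, cluster_b: Cluster, clustering: OverTimeClustering
) -> frozenset:
    """Entities in ``cluster_a`` at its timestamp OR in ``cluster_b`` at its later one."""
    if clustering.ordinal(cluster_a.timestamp) >= clustering.ordinal(cluster_b.timestamp):
        raise ValueError("temporal union requires cluster_a strictly before cluster_b")
    return cluster_a.members | cluster_b.members


def jaccard_proportion(
    cluster_a: Cluster | None, cluster_b: Cluster | None, clustering: OverTimeClustering
) -> float:
    """Jaccard index of two clusters over time; punishes merges and splits alike.

    ``None`` is the empty sentinel for noise; the value is 0 when both
    clusters are empty (and, as |intersection| = 0, also when one is).
    """
    if cluster_a is None and cluster_b is None:
        return 0.0
    if cluster_a is None or cluster_b is None:
        return 0.0
    inter = temporal_intersection(cluster_a, cluster_b, clustering)
    union = temporal_union(cluster_a, cluster_b, clustering)
    return len(inter) / len(union)


# ---------------------------------------------------------------------------
# options
# ---------------------------------------------------------------------------

#: variant name -> (proportion_kind, weighted)
VARIANTS: dict[str, tuple[str, bool]] = {
    "doots": ("asymmetric", False),
    "wdoots": ("asymmetric", True),
    "jdoots": ("jaccard", False),
    "jwdoots": ("jaccard", True),
}


@dataclass(frozen=True)
class DootsOptions:
    """Configuration of the outlier detector.

    ``tau`` has no default: it is the application-level sensitivity and
    must be chosen by the user (values between 0.3 and 0.6 are typical).
    """

    tau: float
    proportion_kind: Literal["asymmetric", "jaccard"] = "asymmetric"
    weighted: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.tau <= 1.0):
            raise ValueError("tau must lie in [0, 1]")

    @classmethod
    def from_variant(cls, variant: str, tau: float) -> "DootsOptions":
        try:
            kind, weighted = VARIANTS[variant.lower()]
        except KeyError:
            raise ValueError(
                f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}"
            ) from None
        return cls(tau=tau, proportion_kind=kind, weighted=weighted)


def _prop_fn(kind: str):
    if kind == "asymmetric":
        return proportion
    if kind == "jaccard":
        return jaccard_proportion
    raise ValueError(f"unknown proportion kind {kind!r}")


# ---------------------------------------------------------------------------
# windowed subsequence scores
# ---------------------------------------------------------------------------


def windowed_subsequence_score(
    entity: Hashable,
    t_i: Hashable,
    t_j: Hashable,
    clustering: OverTimeClustering,
    options: DootsOptions | None = None,
) -> float:
    """Subsequence score over the window ``[t_i, t_j)`` ending at ``t_j``.

    The average proportion linking the entity's cluster at each existing
    in-window timestamp to its cluster at ``t_j``; 0 when the point at
    ``t_j`` is noise.  With ``options.weighted`` the proportions get
    Gauss recency weights (oldest existing timestamp weighs least).
    """
    options = options or DootsOptions(tau=0.0)
    i_idx, j_idx = clustering.ordinal(t_i), clustering.ordinal(t_j)
    if i_idx >= j_idx:
        raise ValueError("window start must precede window end")
    if not clustering.exists(entity, t_j):
        raise KeyError(f"entity {entity!r} absent at window end {t_j!r}")
    window = [
        t
        for t in clustering.timestamps[i_idx:j_idx]
        if clustering.exists(entity, t)
    ]
    if not window:
        raise ValueError(
            f"entity {entity!r} exists at no timestamp in window [{t_i!r}, {t_j!r})"
        )
    if clustering.state(entity, t_j) is NOISE:
        return 0.0
    prop = _prop_fn(options.proportion_kind)
    target = cid(entity, t_j, clustering)
    props = [prop(cid(entity, t, clustering), target, clustering) for t in window]
    if options.weighted:
        weights = gauss_weights(len(props))
        return float(sum(w * p for w, p in zip(weights, props)))
    return float(sum(props) / len(props))


def weighted_subsequence_score(
    entity: Hashable,
    t_i: Hashable,
    t_j: Hashable,
    clustering: OverTimeClustering,
    options: DootsOptions | None = None,
) -> float:
    """Gauss-weighted windowed subsequence score (the wDOOTS/jwDOOTS form)."""
    base = options or DootsOptions(tau=0.0)
    forced = DootsOptions(tau=base.tau, proportion_kind=base.proportion_kind, weighted=True)
    return windowed_subsequence_score(entity, t_i, t_j, clustering, forced)


# ---------------------------------------------------------------------------
# best score and outlier score
# ---------------------------------------------------------------------------


def best_score(
    t_i: Hashable,
    cluster: Cluster,
    clustering: OverTimeClustering,
    options: DootsOptions | None = None,
) -> float:
    """Best (leader) subsequence score among a cluster's members for windows starting at ``t_i``.

    Members with no existing in-window timestamp carry no subsequence;
    if no member has one, the best score is 0.
    """
    options = options or DootsOptions(tau=0.0)
    t_j = cluster.timestamp
    i_idx, j_idx = clustering.ordinal(t_i), clustering.ordinal(t_j)
    scores = []
    for e in cluster.members:
        if any(
            clustering.exists(e, t) for t in clustering.timestamps[i_idx:j_idx]
        ):
            scores.append(windowed_subsequence_score(e, t_i, t_j, clustering, options))
    return max(scores) if scores else 0.0


def outlier_score(
    entity: Hashable,
    t_i: Hashable,
    t_j: Hashable,
    clustering: OverTimeClustering,
    options: DootsOptions | None = None,
) -> float:
    """Gap between the endpoint cluster's best score and the entity's own score."""
    target = cid(entity, t_j, clustering)
    if target is None:
        raise ValueError(
            f"outlier score undefined: {entity!r} is noise at {t_j!r} (no cluster peers)"
        )
    own = windowed_subsequence_score(entity, t_i, t_j, clustering, options)
    return best_score(t_i, target, clustering, options) - own


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OutlierRecord:
    """An anomalous (entity, start, end) subsequence or noise point."""

    entity: Hashable
    start: Hashable
    end: Hashable
    type: Literal["score", "intuitive", "noise"]
    score: float | None = None

    def to_dict(self) -> dict:
        return {
            "entity": self.entity,
            "start": self.start,
            "end": self.end,
            "score": self.score,
            "type": self.type,
        }


@dataclass
class OutlierReport:
    """Detection result: all records plus bookkeeping for interpretation."""

    records: list[OutlierRecord]
    options: DootsOptions
    warnings: list[str] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def of_type(self, kind: str) -> list[OutlierRecord]:
        return [r for r in self.records if r.type == kind]

    def to_frame(self) -> pd.DataFrame:
        rows = [r.to_dict() for r in self.records]
        return pd.DataFrame(rows, columns=["entity", "start", "end", "score", "type"])

    def to_dict(self) -> dict:
        return {
            "tau": self.options.tau,
            "proportion_kind": self.options.proportion_kind,
            "weighted": self.options.weighted,
            "records": [r.to_dict() for r in self.records],
            "warnings": list(self.warnings),
        }

    def condensed(self) -> pd.DataFrame:
        """Per-entity maximal flagged intervals (score + intuitive types).

        Overlapping or touching flagged subsequences of one entity are
        merged into maximal [start, end] windows for readability; the
        full enumeration stays available in ``records``.
        """
        flagged: dict[Hashable, list[tuple[int, int]]] = {}
        order: dict[Hashable, None] = {}
        for r in self.records:
            if r.type == "noise":
                continue
            order.setdefault(r.entity, None)
            flagged.setdefault(r.entity, []).append((r.start, r.end))
        rows = []
        for e in order:
            spans = sorted(flagged[e])
            merged: list[list] = []
            for s, t in spans:
                if merged and s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], t)
                else:
                    merged.append([s, t])
            for s, t in merged:
                rows.append({"entity": e, "start": s, "end": t})
        return pd.DataFrame(rows, columns=["entity", "start", "end"])


def subsequence_outlier_scores(
    clustering: OverTimeClustering,
    options: DootsOptions,
) -> pd.DataFrame:
    """Outlier scores of every scorable subsequence, as a flat table.

    One row per (entity, start, end) with ``i < j``, the entity existing
    somewhere in the window and clustered at the endpoint.  Best scores
    are computed once per (start, endpoint-cluster) pair.
    """
    ts = clustering.timestamps
    best_cache: dict[tuple[int, str], float] = {}
    rows = []
    for e in sorted(clustering.entities(), key=str):
        for j_pos, t_j in enumerate(ts):
            if not clustering.exists(e, t_j):
                continue
            state = clustering.state(e, t_j)
            if state is NOISE:
                continue
            cluster = clustering.clusters[state]
            for i_pos in range(j_pos):
                t_i = ts[i_pos]
                if not any(
                    clustering.exists(e, t) for t in ts[i_pos:j_pos]
                ):
                    continue
                key = (i_pos, state)
                if key not in best_cache:
                    best_cache[key] = best_score(t_i, cluster, clustering, options)
                own = windowed_subsequence_score(e, t_i, t_j, clustering, options)
                rows.append(
                    {"entity": e, "start": t_i, "end": t_j, "score": best_cache[key] - own}
                )
    return pd.DataFrame(rows, columns=["entity", "start", "end", "score"])


def detect_outliers(
    clustering: OverTimeClustering,
    panel: TimeSeriesPanel | None = None,
    options: DootsOptions | None = None,
) -> OutlierReport:
    """Score every subsequence of every entity and emit outlier records.

    * ``type="score"``: outlier score >= tau at a clustered endpoint.
    * ``type="intuitive"``: the subsequence consists entirely of noise
      points (flagged regardless of tau).
    * ``type="noise"``: a single noise point.

    Records are ordered by (entity, start, end).  Entities whose final
    existing point is noise while the previous one was clustered cannot
    receive a score-type record ending there; they are listed in the
    report's warnings.
    """
    if options is None:
        raise ValueError("DootsOptions with an explicit tau is required")
    ts = clustering.timestamps
    records: list[OutlierRecord] = []
    warnings: list[str] = []
    scores = subsequence_outlier_scores(clustering, options)
    for row in scores.itertuples(index=False):
        if row.score >= options.tau:
            records.append(
                OutlierRecord(
                    entity=row.entity, start=row.start, end=row.end,
                    type="score", score=float(row.score),
                )
            )
    for e in sorted(clustering.entities(), key=str):
        existing = [t for t in ts if clustering.exists(e, t)]
        for t in existing:
            if clustering.state(e, t) is NOISE:
                records.append(OutlierRecord(entity=e, start=t, end=t, type="noise"))
        for j_pos, t_j in enumerate(ts):
            if not clustering.exists(e, t_j):
                continue
            for i_pos in range(j_pos):
                t_i = ts[i_pos]
                window = [
                    t for t in ts[i_pos : j_pos + 1] if clustering.exists(e, t)
                ]
                in_window = [t for t in window if t != t_j]
                if not in_window:
                    continue
                if clustering.exists(e, t_i) and all(
                    clustering.state(e, t) is NOISE for t in window
                ):
                    records.append(
                        OutlierRecord(entity=e, start=t_i, end=t_j, type="intuitive")
                    )
        if len(existing) >= 2:
            last, prev = existing[-1], existing[-2]
            if (
                clustering.state(e, last) is NOISE
                and clustering.state(e, prev) is not NOISE
            ):
                warnings.append(
                    f"entity {e!r}: final existing point {last!r} is noise after a clustered "
                    f"point; subsequences ending there receive no score-type record"
                )
    records.sort(key=lambda r: (str(r.entity), _ordinal_key(clustering, r.start), _ordinal_key(clustering, r.end)))
    return OutlierReport(records=records, options=options, warnings=warnings)


def _ordinal_key(clustering: OverTimeClustering, t: Hashable) -> int:
    return clustering.ordinal(t)
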