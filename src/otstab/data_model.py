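"""Data model for over-time clusterings of time-series panels.

A *panel* is a set of time series observed at a shared, ordered set of
timestamps; individual (entity, timestamp) cells may be absent.  An
*over-time clustering* is the union of independent per-timestamp
clusterings, where every cluster carries a label that is unique across
all timestamps and a data point may instead be marked as noise.  A
*fuzzy over-time clustering* stores, per timestamp, a membership matrix
whose rows (one per present entity) sum to one.

Timestamps may be arbitrary sortable labels; all scoring formulas use
only their ordinal positions.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "NOISE",
    "Noise",
    "TimeSeriesPanel",
    "Cluster",
    "OverTimeClustering",
    "FuzzyOverTimeClustering",
    "load_panel",
    "load_crisp_labels",
    "load_fuzzy_labels",
    "write_report",
]

#: sentinel label used in CSV files for noise points
NOISE_SENTINEL = -1

#: row-sum tolerance for fuzzy membership matrices
MEMBERSHIP_TOL = 1e-9


class Noise(enum.Enum):
    """Internal state of a data point not assigned to any cluster."""

    NOISE = "noise"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "NOISE"


NOISE = Noise.NOISE


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeSeriesPanel:
    """Entities x ordered timestamps x d features, with a presence mask.

    Parameters
    ----------
    entity_ids
        Entity identifiers, in a fixed (but arbitrary) order.
    timestamps
        Strictly increasing timestamp labels.
    values
        Mapping ``(entity, timestamp) -> 1-d feature vector``.  Pairs
        missing from the mapping are absent from the panel.
    """

    entity_ids: tuple[Hashable, ...]
    timestamps: tuple[Hashable, ...]
    values: Mapping[tuple[Hashable, Hashable], np.ndarray]

    def __post_init__(self) -> None:
        ts = list(self.timestamps)
        if sorted(set(ts)) != ts:
            raise ValueError("timestamps must be strictly increasing with no duplicates")
        dims = {v.shape for v in self.values.values()}
        if len(dims) > 1:
            raise ValueError(f"inconsistent feature dimension across cells: {dims}")
        for key, vec in self.values.items():
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite feature value at {key}")

    # -- basic queries ----------------------------------------------------

    @property
    def n_timestamps(self) -> int:
        return len(self.timestamps)

    @property
    def n_entities(self) -> int:
        return len(self.entity_ids)

    @property
    def n_features(self) -> int:
        return next(iter(self.values.values())).shape[0] if self.values else 0

    def is_present(self, entity: Hashable, timestamp: Hashable) -> bool:
        return (entity, timestamp) in self.values

    def vector(self, entity: Hashable, timestamp: Hashable) -> np.ndarray:
        return self.values[(entity, timestamp)]

    def present_entities(self, timestamp: Hashable) -> list[Hashable]:
        return [e for e in self.entity_ids if (e, timestamp) in self.values]

    def ordinal(self, timestamp: Hashable) -> int:
        """0-based ordinal position of a timestamp label."""
        try:
            return self.timestamps.index(timestamp)
        except ValueError:
            raise KeyError(f"unknown timestamp {timestamp!r}") from None

    def feature_matrix(self, timestamp: Hashable) -> tuple[list[Hashable], np.ndarray]:
        """Present entities at a timestamp and their stacked feature rows."""
        ents = self.present_entities(timestamp)
        if not ents:
            raise ValueError(f"no present entities at timestamp {timestamp!r}")
        return ents, np.vstack([self.values[(e, timestamp)] for e in ents])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame: object_id, time, feature_1..feature_d."""
        d = self.n_features
        rows = []
        for t in self.timestamps:
            for e in self.entity_ids:
                if (e, t) in self.values:
                    rows.append((e, t, *self.values[(e, t)]))
        cols = ["object_id", "time"] + [f"feature_{i + 1}" for i in range(d)]
        return pd.DataFrame(rows, columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeSeriesPanel":
        feat_cols = [c for c in df.columns if c.startswith("feature_")]
        if not feat_cols or "object_id" not in df.columns or "time" not in df.columns:
            raise ValueError("panel table needs columns object_id, time, feature_1..feature_d")
        if df.duplicated(subset=["object_id", "time"]).any():
            dup = df[df.duplicated(subset=["object_id", "time"])].iloc[0]
            raise ValueError(f"duplicate (entity, time) row: ({dup['object_id']}, {dup['time']})")
        feats = df[feat_cols].apply(pd.to_numeric, errors="coerce")
        if feats.isna().any().any():
            raise ValueError("non-numeric feature value in panel table")
        timestamps = tuple(sorted(df["time"].unique()))
        if len(timestamps) < 2:
            raise ValueError("panel needs at least 2 timestamps for stability scoring")
        entities = tuple(pd.unique(df["object_id"]))
        values = {
            (row.object_id, row.time): np.asarray(feat, dtype=float)
            for row, feat in zip(df.itertuples(index=False), feats.to_numpy())
        }
        return cls(entity_ids=entities, timestamps=timestamps, values=values)


def load_panel(path: str | Path) -> TimeSeriesPanel:
    """Read a long-format panel CSV (object_id, time, feature_1..feature_d).

    Rows missing for an (entity, time) pair mark that cell as absent.
    """
    return TimeSeriesPanel.from_frame(pd.read_csv(path))


def write_panel(panel: TimeSeriesPanel, path: str | Path) -> None:
    panel.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# crisp over-time clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Cluster:
    """A cluster at a single timestamp, with a globally unique id."""

    cid: str
    timestamp: Hashable
    members: frozenset

    def __len__(self) -> int:
        return len(self.members)


def _make_cid(timestamp: Hashable, label: Hashable) -> str:
    # namespacing by timestamp keeps labels distinct regardless of time
    return f"t{timestamp}|c{label}"


@dataclass(frozen=True)
class OverTimeClustering:
    """Per-(entity, timestamp) assignment to a timestamp-unique cluster.

    ``assignment`` maps present (entity, timestamp) pairs either to a
    cluster id or to :data:`NOISE`; pairs absent from the panel are
    absent from the mapping.
    """

    timestamps: tuple[Hashable, ...]
    assignment: Mapping[tuple[Hashable, Hashable], str | Noise]
    clusters: Mapping[str, Cluster]

    def __post_init__(self) -> None:
        for cid, cluster in self.clusters.items():
            if cluster.cid != cid:
                raise ValueError(f"cluster id mismatch: {cid} vs {cluster.cid}")
            if not cluster.members:
                raise ValueError(f"empty cluster {cid}")
            if cluster.timestamp not in self.timestamps:
                raise ValueError(f"cluster {cid} at unknown timestamp {cluster.timestamp!r}")
            for e in cluster.members:
                if self.assignment.get((e, cluster.timestamp)) != cid:
                    raise ValueError(
                        f"member {e!r} of {cid} not assigned to it at {cluster.timestamp!r}"
                    )
        for (e, t), state in self.assignment.items():
            if state is not NOISE and state not in self.clusters:
                raise ValueError(f"unknown cluster id {state!r} for ({e!r}, {t!r})")

    # -- queries ----------------------------------------------------------

    @property
    def n_timestamps(self) -> int:
        return len(self.timestamps)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def ordinal(self, timestamp: Hashable) -> int:
        try:
            return self.timestamps.index(timestamp)
        except ValueError:
            raise KeyError(f"unknown timestamp {timestamp!r}") from None

    def exists(self, entity: Hashable, timestamp: Hashable) -> bool:
        return (entity, timestamp) in self.assignment

    def state(self, entity: Hashable, timestamp: Hashable) -> str | Noise:
        """Cluster id or NOISE; raises KeyError for an absent point."""
        return self.assignment[(entity, timestamp)]

    def existing_timestamps(self, entity: Hashable) -> list[Hashable]:
        return [t for t in self.timestamps if (entity, t) in self.assignment]

    def clusters_at(self, timestamp: Hashable) -> list[Cluster]:
        out = [c for c in self.clusters.values() if c.timestamp == timestamp]
        out.sort(key=lambda c: c.cid)
        return out

    def entities(self) -> list[Hashable]:
        seen: dict[Hashable, None] = {}
        for e, _t in self.assignment:
            seen.setdefault(e, None)
        return list(seen)

    def iter_clusters(self) -> list[Cluster]:
        """All clusters, sorted by (timestamp ordinal, id) for determinism."""
        return sorted(self.clusters.values(), key=lambda c: (self.ordinal(c.timestamp), c.cid))

    # -- construction -----------------------------------------------------

    @classmethod
    def from_labels(
        cls,
        labels: Mapping[tuple[Hashable, Hashable], int],
        timestamps: Sequence[Hashable],
        panel: TimeSeriesPanel | None = None,
    ) -> "OverTimeClustering":
        """Build from per-timestamp local labels (sentinel -1 = noise).

        Local labels are namespaced by timestamp into globally unique
        cluster ids.  When a panel is given, labels are cross-checked
        against its presence mask.
        """
        timestamps = tuple(timestamps)
        assignment: dict[tuple[Hashable, Hashable], str | Noise] = {}
        members: dict[str, set] = {}
        for (e, t), lab in labels.items():
            if t not in timestamps:
                raise ValueError(f"label at unknown timestamp {t!r}")
            if panel is not None and not panel.is_present(e, t):
                raise ValueError(f"label for ({e!r}, {t!r}) absent from the panel")
            if lab == NOISE_SENTINEL:
                assignment[(e, t)] = NOISE
            else:
                cid = _make_cid(t, lab)
                assignment[(e, t)] = cid
                members.setdefault(cid, set()).add(e)
        clusters = {}
        for cid, mem in members.items():
            t = next(t for (e, t), st in assignment.items() if st == cid)
            clusters[cid] = Cluster(cid=cid, timestamp=t, members=frozenset(mem))
        return cls(timestamps=timestamps, assignment=assignment, clusters=clusters)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        local: dict[str, int] = {}
        for t in self.timestamps:
            counter = 0
            for c in self.clusters_at(t):
                local[c.cid] = counter
                counter += 1
        for t in self.timestamps:
            for (e, tt), state in sorted(self.assignment.items(), key=lambda kv: str(kv[0])):
                if tt != t:
                    continue
                lab = NOISE_SENTINEL if state is NOISE else local[state]
                rows.append((e, t, lab))
        return pd.DataFrame(rows, columns=["object_id", "time", "cluster"])


def load_crisp_labels(
    path: str | Path, panel: TimeSeriesPanel | None = None
) -> OverTimeClustering:
    """Read a crisp label CSV (object_id, time, cluster; -1 = noise)."""
    df = pd.read_csv(path)
    for col in ("object_id", "time", "cluster"):
        if col not in df.columns:
            raise ValueError(f"label table missing column {col!r}")
    if df.duplicated(subset=["object_id", "time"]).any():
        raise ValueError("duplicate (entity, time) label row")
    labels = {
        (row.object_id, row.time): int(row.cluster) for row in df.itertuples(index=False)
    }
    timestamps = (
        panel.timestamps if panel is not None else tuple(sorted(df["time"].unique()))
    )
    return OverTimeClustering.from_labels(labels, timestamps, panel=panel)


def write_crisp_labels(clustering: OverTimeClustering, path: str | Path) -> None:
    clustering.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# fuzzy over-time clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FuzzyOverTimeClustering:
    """Per-timestamp membership matrices over present entities.

    For every timestamp ``t`` the clustering stores the cluster-id list
    (length ``k_t >= 1``), the present entities (row order) and the
    membership matrix ``U_t`` of shape (entities, k_t).  Rows must sum
    to one (probabilistic partitions); possibilistic memberships are
    rejected.
    """

    timestamps: tuple[Hashable, ...]
    cluster_ids: Mapping[Hashable, tuple[str, ...]]
    row_entities: Mapping[Hashable, tuple[Hashable, ...]]
    memberships: Mapping[Hashable, np.ndarray]

    def __post_init__(self) -> None:
        if len(self.timestamps) < 1:
            raise ValueError("at least one timestamp required")
        for t in self.timestamps:
            U = self.memberships[t]
            if len(self.cluster_ids[t]) < 1:
                raise ValueError(f"timestamp {t!r} has no clusters")
            if U.shape != (len(self.row_entities[t]), len(self.cluster_ids[t])):
                raise ValueError(f"membership matrix shape mismatch at {t!r}")
            if np.any(U < -MEMBERSHIP_TOL) or np.any(U > 1 + MEMBERSHIP_TOL):
                raise ValueError(f"membership outside [0, 1] at {t!r}")
            sums = U.sum(axis=1)
            bad = np.abs(sums - 1.0) > MEMBERSHIP_TOL
            if bad.any():
                e = self.row_entities[t][int(np.argmax(bad))]
                raise ValueError(
                    f"memberships of {e!r} at {t!r} sum to {sums[np.argmax(bad)]:.6f}, not 1"
                )

    @property
    def n_timestamps(self) -> int:
        return len(self.timestamps)

    def exists(self, entity: Hashable, timestamp: Hashable) -> bool:
        return entity in self.row_entities[timestamp]

    def existing_timestamps(self, entity: Hashable) -> list[Hashable]:
        return [t for t in self.timestamps if entity in self.row_entities[t]]

    def row(self, entity: Hashable, timestamp: Hashable) -> np.ndarray:
        idx = self.row_entities[timestamp].index(entity)
        return self.memberships[timestamp][idx]

    def entities(self) -> list[Hashable]:
        seen: dict[Hashable, None] = {}
        for t in self.timestamps:
            for e in self.row_entities[t]:
                seen.setdefault(e, None)
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.timestamps:
            U = self.memberships[t]
            for i, e in enumerate(self.row_entities[t]):
                for j in range(U.shape[1]):
                    rows.append((e, t, j, U[i, j]))
        return pd.DataFrame(rows, columns=["object_id", "time", "cluster", "membership"])


def load_fuzzy_labels(
    path: str | Path, panel: TimeSeriesPanel | None = None
) -> FuzzyOverTimeClustering:
    """Read a fuzzy membership CSV (object_id, time, cluster, membership)."""
    df = pd.read_csv(path)
    for col in ("object_id", "time", "cluster", "membership"):
        if col not in df.columns:
            raise ValueError(f"membership table missing column {col!r}")
    if ((df["membership"] < 0) | (df["membership"] > 1)).any():
        raise ValueError("membership outside [0, 1]")
    timestamps = (
        panel.timestamps if panel is not None else tuple(sorted(df["time"].unique()))
    )
    cluster_ids: dict[Hashable, tuple[str, ...]] = {}
    row_entities: dict[Hashable, tuple[Hashable, ...]] = {}
    memberships: dict[Hashable, np.ndarray] = {}
    for t in timestamps:
        sub = df[df["time"] == t]
        labs = sorted(sub["cluster"].unique())
        ents = list(pd.unique(sub["object_id"]))
        if panel is not None:
            for e in ents:
                if not panel.is_present(e, t):
                    raise ValueError(f"membership for ({e!r}, {t!r}) absent from the panel")
        U = np.zeros((len(ents), len(labs)))
        pivot = sub.pivot_table(
            index="object_id", columns="cluster", values="membership", fill_value=0.0
        )
        for i, e in enumerate(ents):
            for j, lab in enumerate(labs):
                U[i, j] = pivot.loc[e, lab]
        cluster_ids[t] = tuple(_make_cid(t, lab) for lab in labs)
        row_entities[t] = tuple(ents)
        memberships[t] = U
    return FuzzyOverTimeClustering(
        timestamps=tuple(timestamps),
        cluster_ids=cluster_ids,
        row_entities=row_entities,
        memberships=memberships,
    )


def write_fuzzy_labels(fuzzy: FuzzyOverTimeClustering, path: str | Path) -> None:
    df = fuzzy.to_frame().copy()
    # round-trip through the same local-label convention as the loader
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------


def write_report(report, path: str | Path) -> None:
    """Write any report object to CSV (tables) or JSON (full payload).

    Report objects expose ``to_frame()`` (deterministic column order)
    and ``to_dict()``; lists of records are written as a flat table.
    The format is chosen by the path suffix.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        if hasattr(report, "to_dict"):
            payload = report.to_dict()
        elif isinstance(report, (list, tuple)):
            payload = [r.to_dict() if hasattr(r, "to_dict") else r for r in report]
        else:
            payload = report
        path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
        return
    if hasattr(report, "to_frame"):
        df = report.to_frame()
    elif isinstance(report, (list, tuple)):
        rows = [r.to_dict() if hasattr(r, "to_dict") else dict(r) for r in report]
        if rows:
            df = pd.DataFrame(rows)
        else:
            df = pd.DataFrame(columns=["entity", "start", "end", "score", "type"])
    elif isinstance(report, pd.DataFrame):
        df = report
    else:
        raise TypeError(f"cannot write report of type {type(report).__name__}")
    df.to_csv(path, index=False)
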