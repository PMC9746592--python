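"""Parameter sweeps: grid-evaluate per-timestamp clustering backends.

Each backend clusters every timestamp of a panel independently (no
history coupling — the stability scores are algorithm-agnostic, and
evolutionary backends can be plugged in by supplying their label CSVs).
A grid of backend parameters is evaluated against CLOSE or FCSETS and
the most over-time-stable setting is selected, mirroring the
hyperparameter-selection use of the scores (e.g. choosing k for K-Means
or eps/min_samples for DBSCAN).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans

from .close import CloseOptions, close_score
from .data_model import (
    NOISE,
    FuzzyOverTimeClustering,
    OverTimeClustering,
    TimeSeriesPanel,
)
from .fcsets import fcsets_score

__all__ = [
    "SweepResult",
    "cluster_per_timestamp",
    "evaluate_grid",
    "fuzzy_cmeans",
]


# ---------------------------------------------------------------------------
# backends
# ---------------------------------------------------------------------------


def _kmeans_labels(X: np.ndarray, k: int, seed: int, restarts: int) -> np.ndarray:
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} present points at a timestamp")
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed)
    return km.fit_predict(X)


def _dbscan_labels(X: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    return DBSCAN(eps=eps, min_samples=min_pts).fit_predict(X)


def fuzzy_cmeans(
    X: np.ndarray,
    c: int,
    fuzzifier: float = 2.0,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> np.ndarray:
    """Fuzzy c-means membership matrix (rows sum to 1), seeded and deterministic.

    Standard alternating updates: centroids are the fuzzified weighted
    means, memberships the inverse-distance partition with exponent
    ``2/(fuzzifier-1)``.  Points coinciding with a centroid get a crisp
    row for that centroid.
    """
    if fuzzifier <= 1.0:
        raise ValueError("fuzzifier must exceed 1")
    n = X.shape[0]
    if c > n:
        raise ValueError(f"c={c} exceeds the {n} present points at a timestamp")
    rng = np.random.default_rng(seed)
    U = rng.random((n, c))
    U /= U.sum(axis=1, keepdims=True)
    for _ in range(max_iter):
        Um = U**fuzzifier
        centroids = (Um.T @ X) / Um.sum(axis=0)[:, None]
        dist = np.linalg.norm(X[:, None, :] - centroids[None, :, :], axis=2)
        exact = dist < 1e-12
        U_new = np.zeros_like(U)
        hit = exact.any(axis=1)
        if hit.any():
            U_new[hit] = exact[hit] / exact[hit].sum(axis=1, keepdims=True)
        power = 2.0 / (fuzzifier - 1.0)
        with np.errstate(divide="ignore"):
            inv = dist[~hit] ** (-power)
        U_new[~hit] = inv / inv.sum(axis=1, keepdims=True)
        if np.abs(U_new - U).max() < tol:
            U = U_new
            break
        U = U_new
    return U


def cluster_per_timestamp(
    panel: TimeSeriesPanel,
    backend: str,
    params: Mapping[str, Any],
) -> OverTimeClustering | FuzzyOverTimeClustering:
    """Cluster each timestamp of a panel independently.

    Backends: ``kmeans(k, seed=0, restarts=10)``,
    ``dbscan(eps, min_pts)``, ``cmeans(c, fuzzifier=2.0, seed=0)``.
    Crisp backends return an :class:`OverTimeClustering` with labels
    namespaced per timestamp (DBSCAN's -1 becomes noise); ``cmeans``
    returns a :class:`FuzzyOverTimeClustering`.
    """
    if backend == "cmeans":
        c = int(params["c"])
        fuzzifier = float(params.get("fuzzifier", 2.0))
        seed = int(params.get("seed", 0))
        cluster_ids: dict[Hashable, tuple[str, ...]] = {}
        row_entities: dict[Hashable, tuple[Hashable, ...]] = {}
        memberships: dict[Hashable, np.ndarray] = {}
        for t in panel.timestamps:
            ents, X = panel.feature_matrix(t)
            U = fuzzy_cmeans(X, c=c, fuzzifier=fuzzifier, seed=seed)
            cluster_ids[t] = tuple(f"t{t}|c{j}" for j in range(c))
            row_entities[t] = tuple(ents)
            memberships[t] = U
        return FuzzyOverTimeClustering(
            timestamps=panel.timestamps,
            cluster_ids=cluster_ids,
            row_entities=row_entities,
            memberships=memberships,
        )

    labels: dict[tuple[Hashable, Hashable], int] = {}
    for t in panel.timestamps:
        ents, X = panel.feature_matrix(t)
        if backend == "kmeans":
            labs = _kmeans_labels(
                X,
                k=int(params["k"]),
                seed=int(params.get("seed", 0)),
                restarts=int(params.get("restarts", 10)),
            )
        elif backend == "dbscan":
            labs = _dbscan_labels(X, eps=float(params["eps"]), min_pts=int(params["min_pts"]))
        else:
            raise ValueError(f"unknown backend {backend!r}")
        for e, lab in zip(ents, labs):
            labels[(e, t)] = int(lab)
    return OverTimeClustering.from_labels(labels, panel.timestamps, panel=panel)


# ---------------------------------------------------------------------------
# grid evaluation
# ---------------------------------------------------------------------------


@dataclass
class SweepResult:
    """One row per grid point, plus the best setting by score.

    Ties in the score are broken by first-in-grid order, so the result
    is deterministic for a fixed grid and seeds.
    """

    table: pd.DataFrame
    best: dict
    measure: str
    backend: str

    def to_frame(self) -> pd.DataFrame:
        return self.table

    def to_dict(self) -> dict:
        return {
            "backend": self.backend,
            "measure": self.measure,
            "best": self.best,
            "rows": self.table.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = [
            f"Parameter sweep: {self.backend} scored by {self.measure}",
            "-" * 48,
            f"grid points  {len(self.table)}",
            f"best setting {self.best['params']}",
            f"best score   {self.best['score']:.6f}",
        ]
        return "\n".join(lines)


def evaluate_grid(
    panel: TimeSeriesPanel,
    backend: str,
    grid: Sequence[Mapping[str, Any]],
    measure: str = "close",
    close_options: CloseOptions | None = None,
    agreement_exponent: float | str = 2,
) -> SweepResult:
    """Score every grid point and select the most over-time-stable setting.

    ``grid`` is an ordered sequence of backend parameter mappings; the
    iteration order is the tie-break order.  ``measure`` is "close"
    (crisp backends) or "fcsets" (requires the ``cmeans`` backend).
    """
    if not grid:
        raise ValueError("empty parameter grid")
    if measure not in ("close", "fcsets"):
        raise ValueError(f"unknown measure {measure!r}")
    if measure == "fcsets" and backend != "cmeans":
        raise ValueError("the fcsets measure requires the cmeans backend")
    if measure == "close" and backend == "cmeans":
        raise ValueError("the close measure requires a crisp backend (kmeans or dbscan)")

    rows = []
    for params in grid:
        clustering = cluster_per_timestamp(panel, backend, params)
        row: dict[str, Any] = dict(params)
        if measure == "close":
            report = close_score(clustering, panel, close_options)
            row["score"] = report.score
            row["n_clusters"] = report.n_clusters
            row["noise_fraction"] = (
                1.0 - report.n_clustered_points / report.n_points if report.n_points else 0.0
            )
            row["clusters_per_timestamp"] = "/".join(
                str(len(clustering.clusters_at(t))) for t in clustering.timestamps
            )
        else:
            report = fcsets_score(clustering, agreement_exponent)
            row["score"] = report.score
            row["n_clusters"] = sum(
                len(clustering.cluster_ids[t]) for t in clustering.timestamps
            )
            row["noise_fraction"] = 0.0
            row["clusters_per_timestamp"] = "/".join(
                str(len(clustering.cluster_ids[t])) for t in clustering.timestamps
            )
        rows.append(row)
    table = pd.DataFrame(rows)
    best_idx = int(table["score"].to_numpy().argmax())  # argmax keeps first-in-grid on ties
    best = {"params": dict(grid[best_idx]), "score": float(table.iloc[best_idx]["score"])}
    return SweepResult(table=table, best=best, measure=measure, backend=backend)
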