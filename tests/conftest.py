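"""Shared fixtures: hand-built clusterings and random instance builders.

Random instances come in two parallel representations — the library's
objects and the plain dicts the brute-force oracles consume — built
from the same draw so equivalence tests compare like with like.
"""

from __future__ import annotations

import numpy as np
import pytest

from otstab import OverTimeClustering, TimeSeriesPanel


def random_instance(rng, n_entities=None, n_ts=None, p_absent=0.15, p_noise=0.2):
    """A random crisp over-time clustering instance plus its oracle dicts.

    Returns (clustering, panel, labels_dict, panel_dict, n_ts) with
    entities 0..n_entities-1 and integer timestamps 0..n_ts-1.  Every
    timestamp keeps at least one present entity so panels stay valid.
    """
    n_entities = n_entities or int(rng.integers(2, 7))
    n_ts = n_ts or int(rng.integers(2, 5))
    labels: dict[tuple[int, int], int | None] = {}
    values: dict[tuple[int, int], np.ndarray] = {}
    for t in range(n_ts):
        present = [e for e in range(n_entities) if rng.random() > p_absent]
        if not present:
            present = [int(rng.integers(n_entities))]
        k = int(rng.integers(1, min(3, len(present)) + 1))
        for e in present:
            lab = None if rng.random() < p_noise else int(rng.integers(k))
            labels[(e, t)] = lab
            values[(e, t)] = rng.random(2)
    panel = TimeSeriesPanel(
        entity_ids=tuple(range(n_entities)),
        timestamps=tuple(range(n_ts)),
        values=values,
    )
    lib_labels = {k: (-1 if v is None else v) for k, v in labels.items()}
    clustering = OverTimeClustering.from_labels(lib_labels, tuple(range(n_ts)), panel=panel)
    panel_dict = {k: tuple(v) for k, v in values.items()}
    return clustering, panel, labels, panel_dict, n_ts


def random_fuzzy_instance(rng, n_entities=None, n_ts=None, p_absent=0.1):
    """A random fuzzy clustering plus the oracle membership dict."""
    from otstab import FuzzyOverTimeClustering

    n_entities = n_entities or int(rng.integers(2, 7))
    n_ts = n_ts or int(rng.integers(2, 5))
    timestamps = tuple(range(n_ts))
    cluster_ids = {}
    row_entities = {}
    memberships = {}
    memb_dict = {}
    for t in timestamps:
        # entity 0 is always present so at least one series is scorable
        present = [e for e in range(n_entities) if e == 0 or rng.random() > p_absent]
        k = int(rng.integers(1, 4))
        U = rng.random((len(present), k))
        U /= U.sum(axis=1, keepdims=True)
        cluster_ids[t] = tuple(f"t{t}|c{j}" for j in range(k))
        row_entities[t] = tuple(present)
        memberships[t] = U
        for i, e in enumerate(present):
            memb_dict[(e, t)] = tuple(U[i])
    fuzzy = FuzzyOverTimeClustering(
        timestamps=timestamps,
        cluster_ids=cluster_ids,
        row_entities=row_entities,
        memberships=memberships,
    )
    return fuzzy, memb_dict


@pytest.fixture
def fig_clustering():
    """Five series over three timestamps with one noise point and a merge.

    Mirrors the hand example used throughout the docs: at t1 the series
    a, b form one cluster and c, d another while e is noise; at t2 the
    first cluster absorbs c; at t3 a, b regroup without c.
    """
    labels = {
        ("a", 1): 0, ("b", 1): 0, ("c", 1): 1, ("d", 1): 1, ("e", 1): -1,
        ("a", 2): 0, ("b", 2): 0, ("c", 2): 0, ("d", 2): 1, ("e", 2): 1,
        ("a", 3): 0, ("b", 3): 0, ("c", 3): 1, ("d", 3): 1, ("e", 3): 0,
    }
    return OverTimeClustering.from_labels(labels, (1, 2, 3))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
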