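"""FCSETS: over-time stability of fuzzy per-timestamp clusterings.

For each timestamp, the relative assignment agreement of two series is
one minus half the L1 distance between their membership rows (the
equivalence relation of the Hüllermeier-Rifqi index).  A time series is
stable when its agreements with the other series barely change between
timestamps: its stability is one minus the average, agreement-weighted
squared change of those agreements over all timestamp pairs.  The
clustering score is the mean series stability.

The weight on each peer is the agreement at the earlier timestamp
raised to a power.  The exponent is configurable (``agreement_exponent``,
default 2); passing ``"n_series"`` reproduces a literal reading in
which the exponent equals the number of time series, which collapses
the weights towards the self-pair on large panels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Hashable

import numpy as np
import pandas as pd

from .data_model import FuzzyOverTimeClustering

__all__ = [
    "FcsetsReport",
    "assignment_agreement",
    "agreement_difference",
    "series_stability",
    "fcsets_score",
]


def _resolve_exponent(agreement_exponent: float | str, fuzzy: FuzzyOverTimeClustering) -> float:
    if isinstance(agreement_exponent, str):
        if agreement_exponent == "n_series":
            return float(len(fuzzy.entities()))
        raise ValueError(
            f"unknown exponent spec {agreement_exponent!r}; use a number or 'n_series'"
        )
    if agreement_exponent < 0:
        raise ValueError("agreement_exponent must be non-negative")
    return float(agreement_exponent)


def assignment_agreement(row_l: np.ndarray, row_s: np.ndarray) -> float:
    """Relative assignment agreement ``1 - (1/2) sum_j |u_j(l) - u_j(s)|``.

    Both rows must range over the same clusters (same length, same
    order) and each sum to one; the result then lies in [0, 1].
    """
    row_l = np.asarray(row_l, dtype=float)
    row_s = np.asarray(row_s, dtype=float)
    if row_l.shape != row_s.shape:
        raise ValueError("membership rows range over different cluster sets")
    return float(1.0 - 0.5 * np.abs(row_l - row_s).sum())


def agreement_difference(
    l: Hashable,
    s: Hashable,
    t_i: Hashable,
    t_r: Hashable,
    fuzzy: FuzzyOverTimeClustering,
) -> float:
    """Absolute change of the pairwise agreement between two timestamps."""
    for e in (l, s):
        for t in (t_i, t_r):
            if not fuzzy.exists(e, t):
                raise KeyError(f"entity {e!r} absent at timestamp {t!r}")
    e_i = assignment_agreement(fuzzy.row(l, t_i), fuzzy.row(s, t_i))
    e_r = assignment_agreement(fuzzy.row(l, t_r), fuzzy.row(s, t_r))
    return abs(e_i - e_r)


def series_stability(
    entity: Hashable,
    fuzzy: FuzzyOverTimeClustering,
    agreement_exponent: float | str = 2,
) -> float:
    """Over-time stability of one series: 1 minus its average weighted agreement change.

    For every pair of timestamps where the series exists, the squared
    agreement changes to all peers existing at both timestamps are
    averaged with weights ``E^exponent`` taken at the earlier timestamp
    (the self-pair, with agreement 1 and change 0, is always included,
    so the weight denominator never vanishes).  Entities absent at a
    timestamp are dropped from the sums of that timestamp pair, and the
    pair normalization counts only timestamp pairs where the focal
    entity exists at both.
    """
    exp = _resolve_exponent(agreement_exponent, fuzzy)
    own_ts = fuzzy.existing_timestamps(entity)
    n = len(own_ts)
    if n < 2:
        raise ValueError(
            f"series stability undefined: {entity!r} exists at fewer than 2 timestamps"
        )
    total = 0.0
    for a in range(n - 1):
        for b in range(a + 1, n):
            t_i, t_r = own_ts[a], own_ts[b]
            peers = [
                s
                for s in fuzzy.row_entities[t_i]
                if fuzzy.exists(s, t_r)
            ]
            num = 0.0
            den = 0.0
            for s in peers:
                e_i = assignment_agreement(fuzzy.row(entity, t_i), fuzzy.row(s, t_i))
                e_r = assignment_agreement(fuzzy.row(entity, t_r), fuzzy.row(s, t_r))
                w = e_i**exp
                num += w * (e_i - e_r) ** 2
                den += w
            total += num / den
    return 1.0 - (2.0 / (n * (n - 1))) * total


@dataclass
class FcsetsReport:
    """FCSETS score with its per-series decomposition."""

    score: float
    per_series: pd.DataFrame
    agreement_exponent: float | str

    def to_frame(self) -> pd.DataFrame:
        return self.per_series

    def to_dict(self) -> dict:
        return {
            "score": self.score,
            "agreement_exponent": self.agreement_exponent,
            "per_series": self.per_series.to_dict(orient="records"),
        }

    def summary(self) -> str:
        lines = [
            "FCSETS over-time stability report",
            "---------------------------------",
            f"score               {self.score:.6f}",
            f"series scored       {len(self.per_series)}",
            f"agreement exponent  {self.agreement_exponent}",
        ]
        return "\n".join(lines)


def fcsets_score(
    fuzzy: FuzzyOverTimeClustering,
    agreement_exponent: float | str = 2,
) -> FcsetsReport:
    """Mean over-time stability of all series of a fuzzy clustering.

    Series existing at fewer than two timestamps carry no stability
    terms and are excluded from the mean.
    """
    if fuzzy.n_timestamps < 2:
        raise ValueError("stability scoring requires at least 2 timestamps")
    rows = []
    for e in fuzzy.entities():
        if len(fuzzy.existing_timestamps(e)) < 2:
            continue
        rows.append({"entity": e, "stability": series_stability(e, fuzzy, agreement_exponent)})
    if not rows:
        raise ValueError("no series exists at two or more timestamps")
    per_series = pd.DataFrame(rows, columns=["entity", "stability"])
    return FcsetsReport(
        score=float(per_series["stability"].mean()),
        per_series=per_series,
        agreement_exponent=agreement_exponent,
    )
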