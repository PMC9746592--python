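"""Brute-force reference implementations used only as independent test oracles.

Everything here is written straight from the defining formulas with
plain nested loops over dictionaries, deliberately sharing no code with
the library.  Representation: ``labels[(entity, t)] -> int`` local
label, ``None`` for noise; pairs missing from the dict are absent.
Timestamps are 0..n-1.  Fuzzy clusterings: ``memb[(entity, t)] ->
tuple of floats`` (row over that timestamp's clusters), missing pairs
absent.
"""

from __future__ import annotations

import math


# ---------------------------------------------------------------------------
# crisp machinery
# ---------------------------------------------------------------------------


def members(labels, t, lab):
    return {e for (e, tt), l in labels.items() if tt == t and l == lab and l is not None}


def cid(labels, e, t):
    lab = labels[(e, t)]
    return None if lab is None else (t, lab)


def prop_asym(labels, ca, cb):
    if ca is None:
        return 0.0
    if cb is None:
        return 0.0
    ma = members(labels, *ca)
    mb = members(labels, *cb)
    return len(ma & mb) / len(ma)


def prop_jaccard(labels, ca, cb):
    if ca is None and cb is None:
        return 0.0
    ma = members(labels, *ca) if ca is not None else set()
    mb = members(labels, *cb) if cb is not None else set()
    if not (ma | mb):
        return 0.0
    return len(ma & mb) / len(ma | mb)


def gauss_w(k):
    return [2.0 * a / (k * (k + 1)) for a in range(1, k + 1)]


def window_score(labels, e, i, j, jaccard=False, weighted=False):
    """Eq.-16/20 subsequence score over window [i, j) ending at j."""
    prop = prop_jaccard if jaccard else prop_asym
    window = [t for t in range(i, j) if (e, t) in labels]
    if not window:
        return None
    if labels[(e, j)] is None:
        return 0.0
    target = cid(labels, e, j)
    ps = [prop(labels, cid(labels, e, t), target) for t in window]
    if weighted:
        w = gauss_w(len(ps))
        return sum(wi * pi for wi, pi in zip(w, ps))
    return sum(ps) / len(ps)


def subseq_score(labels, e, t_k, jaccard=False, weighted=False):
    """Full-history score (window from timestamp 0)."""
    return window_score(labels, e, 0, t_k, jaccard=jaccard, weighted=weighted)


def merge_count(labels, t_k, lab):
    mem = members(labels, t_k, lab)
    earlier = set()
    for t in range(t_k):
        for e in mem:
            if (e, t) in labels and labels[(e, t)] is not None:
                earlier.add((t, labels[(e, t)]))
    return len(earlier)


def ot_stability(labels, t_k, lab, jaccard=False, weighted=False):
    if t_k == 0:
        return 1.0
    m = merge_count(labels, t_k, lab)
    if m == 0:
        return 0.0
    scores = []
    for e in members(labels, t_k, lab):
        s = subseq_score(labels, e, t_k, jaccard=jaccard, weighted=weighted)
        if s is not None:
            scores.append(s)
    if not scores:
        return 0.0
    return (sum(scores) / len(scores)) / (m / t_k)


def mse(panel, labels, t, lab):
    mem = sorted(members(labels, t, lab), key=str)
    pts = [panel[(e, t)] for e in mem]
    d = len(pts[0])
    cen = [sum(p[i] for p in pts) / len(pts) for i in range(d)]
    return sum(sum((p[i] - cen[i]) ** 2 for i in range(d)) for p in pts) / len(pts) / d


def all_clusters(labels, n_ts):
    out = []
    for t in range(n_ts):
        labs = sorted({l for (e, tt), l in labels.items() if tt == t and l is not None})
        out.extend((t, l) for l in labs)
    return out


def close(labels, n_ts, panel=None, quality="zero", jaccard=False, weighted=False,
          exploitation=False, clustering_level=False):
    """Eq.-9/10/11 CLOSE score, straight from the formulas."""
    clusters = all_clusters(labels, n_ts)
    n_c = len(clusters)
    if n_c == 0:
        return 0.0

    def q(t, lab):
        if quality == "zero":
            return 0.0
        if quality == "mse":
            return mse(panel, labels, t, lab)
        raise ValueError(quality)

    penalty = 1.0 - (n_ts / n_c) ** 2
    if clustering_level:
        total = 0.0
        for t in range(n_ts):
            at_t = [c for c in clusters if c[0] == t]
            if not at_t:
                continue
            avg_stab = sum(
                ot_stability(labels, tt, ll, jaccard, weighted) for tt, ll in at_t
            ) / len(at_t)
            if quality == "exploitation":
                pts = [l for (e, tt), l in labels.items() if tt == t]
                qual = sum(1 for l in pts if l is not None) / len(pts)
                factor = qual
            else:
                factor = 1.0 - sum(q(tt, ll) for tt, ll in at_t) / len(at_t)
            total += avg_stab * factor
        raw = (1.0 / n_ts) * penalty * total
    else:
        total = sum(
            ot_stability(labels, t, lab, jaccard, weighted) * (1.0 - q(t, lab))
            for t, lab in clusters
        )
        raw = (1.0 / n_c) * penalty * total
    if exploitation:
        pts = list(labels.values())
        raw *= sum(1 for l in pts if l is not None) / len(pts)
    return max(0.0, raw)


# ---------------------------------------------------------------------------
# DOOTS
# ---------------------------------------------------------------------------


def best_score(labels, i, t_j, lab, jaccard=False, weighted=False):
    scores = []
    for e in members(labels, t_j, lab):
        s = window_score(labels, e, i, t_j, jaccard=jaccard, weighted=weighted)
        if s is not None:
            scores.append(s)
    return max(scores) if scores else 0.0


def outlier_score(labels, e, i, j, jaccard=False, weighted=False):
    lab = labels[(e, j)]
    if lab is None:
        return None
    own = window_score(labels, e, i, j, jaccard=jaccard, weighted=weighted)
    if own is None:
        return None
    return best_score(labels, i, j, lab, jaccard=jaccard, weighted=weighted) - own


# ---------------------------------------------------------------------------
# FCSETS
# ---------------------------------------------------------------------------


def agreement(memb, l, s, t):
    ul, us = memb[(l, t)], memb[(s, t)]
    return 1.0 - 0.5 * sum(abs(a - b) for a, b in zip(ul, us))


def stability(memb, entities, l, exponent):
    own_ts = sorted({t for (e, t) in memb if e == l})
    n = len(own_ts)
    assert n >= 2
    total = 0.0
    for a in range(n - 1):
        for b in range(a + 1, n):
            ti, tr = own_ts[a], own_ts[b]
            num = den = 0.0
            for s in entities:
                if (s, ti) not in memb or (s, tr) not in memb:
                    continue
                e_i = agreement(memb, l, s, ti)
                e_r = agreement(memb, l, s, tr)
                w = e_i**exponent
                num += w * (e_i - e_r) ** 2
                den += w
            total += num / den
    return 1.0 - 2.0 / (n * (n - 1)) * total


def fcsets(memb, exponent):
    entities = sorted({e for (e, t) in memb}, key=str)
    vals = []
    for l in entities:
        if len({t for (e, t) in memb if e == l}) >= 2:
            vals.append(stability(memb, entities, l, exponent))
    return sum(vals) / len(vals)
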