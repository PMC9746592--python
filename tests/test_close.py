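"""CLOSE: worked examples, closed forms, properties and oracle equivalence."""

import numpy as np
import pytest

from otstab import (
    CloseOptions,
    OverTimeClustering,
    TimeSeriesPanel,
    cid,
    close_score,
    cluster_ot_stability,
    exploitation_quality,
    merge_count,
    mse_quality,
    ot_stability_from_components,
    proportion,
    subsequence_score,
    temporal_intersection,
)
from otstab.doots import jaccard_proportion

from tests import _oracles as oracle
from tests.conftest import random_instance


def cluster_of(clustering, entity, t):
    return cid(entity, t, clustering)


class TestTransitionPrimitives:
    def test_temporal_intersection_keeps_shared_members(self, fig_clustering):
        ca = cluster_of(fig_clustering, "a", 1)  # {a, b}
        cb = cluster_of(fig_clustering, "a", 2)  # {a, b, c}
        assert temporal_intersection(ca, cb, fig_clustering) == frozenset({"a", "b"})
        assert proportion(ca, cb, fig_clustering) == 1.0

    def test_intersection_requires_time_order(self, fig_clustering):
        ca = cluster_of(fig_clustering, "a", 1)
        cb = cluster_of(fig_clustering, "a", 2)
        with pytest.raises(ValueError):
            temporal_intersection(cb, ca, fig_clustering)
        with pytest.raises(ValueError):
            temporal_intersection(ca, ca, fig_clustering)

    def test_disjoint_and_superset_cases(self):
        labels = {("a", 1): 0, ("b", 1): 1, ("c", 1): 1, ("a", 2): 0, ("b", 2): 0, ("c", 2): 1}
        cl = OverTimeClustering.from_labels(labels, (1, 2))
        c_b1 = cid("b", 1, cl)  # {b, c}
        c_a2 = cid("a", 2, cl)  # {a, b}
        assert temporal_intersection(c_b1, c_a2, cl) == frozenset({"b"})
        assert proportion(c_b1, c_a2, cl) == pytest.approx(0.5)
        c_a1 = cid("a", 1, cl)  # {a}
        assert proportion(c_a1, c_a2, cl) == 1.0  # superset case

    def test_noise_gives_empty_sentinel_and_zero_proportion(self, fig_clustering):
        assert cid("e", 1, fig_clustering) is None
        cb = cluster_of(fig_clustering, "a", 2)
        assert proportion(None, cb, fig_clustering) == 0.0

    def test_cid_raises_for_absent_point(self):
        labels = {("a", 1): 0, ("a", 2): 0, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(labels, (1, 2))
        with pytest.raises(KeyError, match="absent"):
            cid("b", 1, cl)


class TestSubsequenceScore:
    def test_worked_example_two_thirds_then_full(self, fig_clustering):
        # proportions to the two preceding timestamps are 2/2 and 2/3
        assert subsequence_score("a", 3, fig_clustering) == pytest.approx(
            0.5 * (2 / 2 + 2 / 3)
        )
        assert round(subsequence_score("a", 3, fig_clustering), 2) == 0.83

    def test_noise_endpoint_scores_zero(self):
        labels = {("a", 1): 0, ("b", 1): 0, ("a", 2): -1, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(labels, (1, 2))
        assert subsequence_score("a", 2, cl) == 0.0

    def test_persistent_singleton_scores_one(self):
        labels = {("a", t): 0 for t in (1, 2, 3)}
        cl = OverTimeClustering.from_labels(labels, (1, 2, 3))
        assert subsequence_score("a", 3, cl) == 1.0

    def test_no_history_is_undefined(self):
        labels = {("a", 2): 0, ("b", 1): 0, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(labels, (1, 2))
        with pytest.raises(ValueError, match="undefined"):
            subsequence_score("a", 2, cl)


class TestClusterStability:
    def test_merge_count_worked_example(self, fig_clustering):
        # cluster {c, d} at t3 gathered members from {c,d}@t1, {a,b,c}@t2, {d,e}@t2
        c = cid("c", 3, fig_clustering)
        assert merge_count(c, fig_clustering) == 3

    def test_merge_count_ignores_noise_history(self):
        labels = {("a", 1): -1, ("b", 1): -1, ("a", 2): 0, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(labels, (1, 2))
        assert merge_count(cid("a", 2, cl), cl) == 0

    def test_persistent_cluster_merge_count_grows_per_timestamp(self):
        labels = {(e, t): 0 for e in ("a", "b") for t in (1, 2, 3, 4)}
        cl = OverTimeClustering.from_labels(labels, (1, 2, 3, 4))
        assert merge_count(cid("a", 4, cl), cl) == 3

    def test_component_formula_reproduces_printed_value(self):
        # member scores {0.83, 0.58, 0.25}, four merged clusters, third timestamp
        val = ot_stability_from_components([0.83, 0.58, 0.25], 4, 2)
        assert val == pytest.approx(((0.83 + 0.58 + 0.25) / 3) / (0.5 * 4))
        assert round(val, 2) == 0.28

    def test_first_timestamp_cluster_is_stable(self, fig_clustering):
        for c in fig_clustering.clusters_at(1):
            assert cluster_ot_stability(c, fig_clustering) == 1.0

    def test_perfectly_persistent_cluster_is_stable(self):
        labels = {(e, t): 0 for e in ("a", "b") for t in (1, 2, 3)}
        cl = OverTimeClustering.from_labels(labels, (1, 2, 3))
        assert cluster_ot_stability(cid("a", 3, cl), cl) == pytest.approx(1.0)

    def test_all_noise_history_cluster_scores_zero(self):
        labels = {("a", 1): -1, ("b", 1): -1, ("a", 2): 0, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(labels, (1, 2))
        assert cluster_ot_stability(cid("a", 2, cl), cl) == 0.0


class TestQualityMeasures:
    def test_mse_closed_forms(self):
        values = {("a", 1): np.array([0.0]), ("b", 1): np.array([1.0]),
                  ("a", 2): np.array([0.5]), ("b", 2): np.array([0.5])}
        panel = TimeSeriesPanel(("a", "b"), (1, 2), values)
        labels = {("a", 1): 0, ("b", 1): 0, ("a", 2): 0, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(labels, (1, 2), panel=panel)
        assert mse_quality(cid("a", 1, cl), panel) == pytest.approx(0.25)
        assert mse_quality(cid("a", 2, cl), panel) == 0.0  # identical members

    def test_mse_singleton_is_zero(self):
        values = {("a", 1): np.array([0.3, 0.4]), ("a", 2): np.array([0.3, 0.4])}
        panel = TimeSeriesPanel(("a",), (1, 2), values)
        cl = OverTimeClustering.from_labels({("a", 1): 0, ("a", 2): 0}, (1, 2), panel=panel)
        assert mse_quality(cid("a", 1, cl), panel) == 0.0

    def test_mse_requires_normalized_features(self):
        values = {("a", 1): np.array([1.5]), ("b", 1): np.array([0.5]),
                  ("a", 2): np.array([0.5]), ("b", 2): np.array([0.5])}
        panel = TimeSeriesPanel(("a", "b"), (1, 2), values)
        labels = {("a", 1): 0, ("b", 1): 0, ("a", 2): 0, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(labels, (1, 2), panel=panel)
        with pytest.raises(ValueError, match="normalized"):
            mse_quality(cid("a", 1, cl), panel)

    def test_exploitation_fraction(self, fig_clustering):
        # 4 of 5 points clustered at t1, all 5 at t2
        assert exploitation_quality(fig_clustering, 1) == pytest.approx(0.8)
        assert exploitation_quality(fig_clustering, 2) == 1.0

    def test_all_noise_timestamp_scores_zero_exploitation(self):
        labels = {("a", 1): -1, ("b", 1): -1, ("a", 2): 0, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(labels, (1, 2))
        assert exploitation_quality(cl, 1) == 0.0


class TestCloseScore:
    def test_clamped_to_zero_when_too_few_clusters(self):
        # one cluster per timestamp over 2 timestamps: N_C = n = 2
        labels = {(e, t): 0 for e in ("a", "b") for t in (1, 2)}
        cl = OverTimeClustering.from_labels(labels, (1, 2))
        rep = close_score(cl, None, CloseOptions(quality="zero"))
        assert rep.score == 0.0
        assert rep.raw_score <= 0.0

    def test_perfectly_stable_clustering_hits_closed_form(self):
        labels = {}
        for t in (1, 2, 3):
            for g, ents in enumerate((("a", "b"), ("c", "d"), ("e", "f"))):
                for e in ents:
                    labels[(e, t)] = g
        cl = OverTimeClustering.from_labels(labels, (1, 2, 3))
        rep = close_score(cl, None, CloseOptions(quality="zero"))
        n, n_c = 3, 9
        assert rep.score == pytest.approx(1 - (n / n_c) ** 2)

    def test_first_timestamp_clusters_report_stability_one(self, fig_clustering):
        rep = close_score(fig_clustering, None, CloseOptions(quality="zero"))
        first = rep.per_cluster[rep.per_cluster["time"] == 1]
        assert (first["ot_stability"] == 1.0).all()

    def test_exploitation_term_scales_by_clustered_fraction(self, fig_clustering):
        base = close_score(fig_clustering, None, CloseOptions(quality="zero"))
        expl = close_score(
            fig_clustering, None, CloseOptions(quality="zero", use_exploitation_term=True)
        )
        assert expl.score == pytest.approx(base.score * 14 / 15)

    def test_clustering_level_exploitation_quality(self, fig_clustering):
        rep = close_score(
            fig_clustering,
            None,
            CloseOptions(quality="exploitation", clustering_level_quality=True),
        )
        assert 0.0 <= rep.score <= 1.0
        got = oracle.close(
            _as_oracle_labels(fig_clustering), 3, quality="exploitation", clustering_level=True
        )
        assert rep.score == pytest.approx(got, abs=1e-12)

    def test_clustering_level_quality_needs_flag(self, fig_clustering):
        with pytest.raises(ValueError, match="clustering_level_quality"):
            close_score(fig_clustering, None, CloseOptions(quality="exploitation"))


def _as_oracle_labels(clustering):
    """Convert a library clustering into the oracle's dict representation."""
    from otstab import NOISE

    out = {}
    t_pos = {t: i for i, t in enumerate(clustering.timestamps)}
    local = {}
    for t in clustering.timestamps:
        for j, c in enumerate(clustering.clusters_at(t)):
            local[c.cid] = j
    for (e, t), state in clustering.assignment.items():
        out[(e, t_pos[t])] = None if state is NOISE else local[state]
    return out


class TestOracleEquivalence:
    @pytest.mark.parametrize("jaccard", [False, True])
    @pytest.mark.parametrize("weighted", [False, True])
    def test_close_matches_brute_force_on_random_instances(self, rng, jaccard, weighted):
        opts = CloseOptions(
            quality="mse",
            proportion_kind="jaccard" if jaccard else "asymmetric",
            weighted_subsequences=weighted,
        )
        for _ in range(30):
            clustering, panel, labels, panel_dict, n_ts = random_instance(rng)
            want = oracle.close(
                labels, n_ts, panel=panel_dict, quality="mse",
                jaccard=jaccard, weighted=weighted,
            )
            got = close_score(clustering, panel, opts).score
            assert got == pytest.approx(want, abs=1e-12)

    def test_subsequence_and_stability_match_brute_force(self, rng):
        for _ in range(30):
            clustering, panel, labels, _, n_ts = random_instance(rng)
            for (e, t), lab in labels.items():
                if t == 0 or not any((e, tt) in labels for tt in range(t)):
                    continue
                want = oracle.subseq_score(labels, e, t)
                got = subsequence_score(e, t, clustering)
                assert got == pytest.approx(want, abs=1e-12)
            for t in range(1, n_ts):
                for c in clustering.clusters_at(t):
                    j = oracle_local_label(clustering, c)
                    want = oracle.ot_stability(labels, t, j)
                    got = cluster_ot_stability(c, clustering)
                    assert got == pytest.approx(want, abs=1e-12)


def oracle_local_label(clustering, cluster):
    # cluster ids are namespaced as "t<ts>|c<label>"; recover the label
    return int(cluster.cid.rsplit("|c", 1)[1])


class TestInvariants:
    def test_scores_in_unit_interval_and_jaccard_below_asymmetric(self, rng):
        for _ in range(40):
            clustering, panel, labels, _, n_ts = random_instance(rng)
            rep = close_score(clustering, panel, CloseOptions(quality="mse"))
            assert 0.0 <= rep.score
            assert (rep.per_point["subseq_score"].between(0, 1)).all()
            for t in range(1, n_ts):
                for cb in clustering.clusters_at(t):
                    for ta in range(t):
                        for ca in clustering.clusters_at(ta):
                            p = proportion(ca, cb, clustering)
                            j = jaccard_proportion(ca, cb, clustering)
                            assert 0.0 <= j <= p <= 1.0

    def test_full_merge_unpunished_split_punished(self):
        # full merge: every asymmetric proportion into the merged cluster is 1
        merged = {("a", 1): 0, ("b", 1): 1, ("a", 2): 0, ("b", 2): 0}
        cl = OverTimeClustering.from_labels(merged, (1, 2))
        for c1 in cl.clusters_at(1):
            assert proportion(c1, cid("a", 2, cl), cl) == 1.0
        # split: at least one member's proportion drops below 1
        split = {("a", 1): 0, ("b", 1): 0, ("a", 2): 0, ("b", 2): 1}
        cl = OverTimeClustering.from_labels(split, (1, 2))
        props = [
            proportion(cid(e, 1, cl), cid(e, 2, cl), cl) for e in ("a", "b")
        ]
        assert min(props) < 1.0

    def test_label_renaming_and_entity_permutation_invariance(self, rng):
        for _ in range(10):
            clustering, panel, labels, _, n_ts = random_instance(rng)
            base = close_score(clustering, panel, CloseOptions(quality="mse")).score
            # rename labels with a random per-timestamp bijection
            renamed = {}
            for t in range(n_ts):
                at_t = sorted({l for (e, tt), l in labels.items() if tt == t and l is not None})
                perm = list(rng.permutation(len(at_t)))
                mapping = {lab: 100 + perm[i] for i, lab in enumerate(at_t)}
                for (e, tt), l in labels.items():
                    if tt == t:
                        renamed[(e, tt)] = -1 if l is None else mapping[l]
            cl2 = OverTimeClustering.from_labels(renamed, tuple(range(n_ts)), panel=panel)
            assert close_score(cl2, panel, CloseOptions(quality="mse")).score == pytest.approx(
                base, abs=1e-12
            )
            # permute entity identities consistently in panel and labels
            ents = list(panel.entity_ids)
            shuffled = list(rng.permutation(ents))
            rename = dict(zip(ents, shuffled))
            values = {(rename[e], t): v for (e, t), v in panel.values.items()}
            panel2 = TimeSeriesPanel(tuple(shuffled), panel.timestamps, values)
            labs2 = {(rename[e], t): (-1 if l is None else l) for (e, t), l in labels.items()}
            cl3 = OverTimeClustering.from_labels(labs2, tuple(range(n_ts)), panel=panel2)
            assert close_score(cl3, panel2, CloseOptions(quality="mse")).score == pytest.approx(
                base, abs=1e-12
            )
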