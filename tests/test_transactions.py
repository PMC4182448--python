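import numpy as np
import pytest
from hypothesis import assume, given, settings, strategies as st

from fuzzycrm.records import TFBSRecord
from fuzzycrm.transactions import (
    MembershipParams,
    build_crisp_database,
    build_database,
    cluster_sites,
    trapezoid_membership,
)


def sites_at(anchors, tf="A", chrom="chr1", length=10):
    # midpoint anchor: site [a-5, a+5) has midpoint a for even length
    return [
        TFBSRecord(tf, chrom, int(a - length // 2), int(a - length // 2) + length)
        for a in anchors
    ]


class TestClustering:
    def test_threshold_splits_far_singleton(self):
        # d({100,150},{500}) = (400+350)/2 = 375 > 300 -> no merge
        clusters = cluster_sites(sites_at([100, 150, 500]), MembershipParams())
        groups = [[s.midpoint for s in c.members] for c in clusters]
        assert groups == [[100, 150], [500]]

    def test_inclusive_threshold_and_tie_break(self):
        # first merge ties at 200 (leftmost wins), then (400+200)/2 = 300 <= 300
        clusters = cluster_sites(sites_at([1000, 1200, 1400]), MembershipParams())
        assert len(clusters) == 1
        assert [s.midpoint for s in clusters[0].members] == [1000, 1200, 1400]

    def test_single_site_is_singleton_with_own_centroid(self):
        (cl,) = cluster_sites(sites_at([1234]), MembershipParams())
        assert cl.centroid == 1234
        assert len(cl.members) == 1

    def test_chromosomes_cluster_independently(self):
        sites = sites_at([100, 150]) + sites_at([120], chrom="chr2")
        clusters = cluster_sites(sites, MembershipParams())
        assert [(c.chrom, len(c.members)) for c in clusters] == [("chr1", 2), ("chr2", 1)]

    def test_empty_input_gives_empty_list(self):
        assert cluster_sites([], MembershipParams()) == []

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_partition_and_non_interleaving(self, seed):
        """Every site lands in exactly one cluster; spans never interleave."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 60))
        anchors = sorted(int(x) for x in rng.integers(0, 20_000, size=n))
        sites = sites_at(anchors)
        clusters = cluster_sites(sites, MembershipParams())
        clustered = [s for c in clusters for s in c.members]
        assert sorted((s.start, s.end) for s in clustered) == sorted(
            (s.start, s.end) for s in sites)
        for prev, nxt in zip(clusters, clusters[1:]):
            assert max(s.midpoint for s in prev.members) < min(
                s.midpoint for s in nxt.members)


class TestTrapezoid:
    @pytest.mark.parametrize(
        "dist,expected",
        [(0, 1.0), (150, 1.0), (200, 0.5), (250, 0.0), (251, 0.0), (1000, 0.0)],
    )
    def test_values_on_ramp(self, dist, expected):
        assert trapezoid_membership(500 + dist, 500, 150, 100) == pytest.approx(expected)
        assert trapezoid_membership(500 - dist, 500, 150, 100) == pytest.approx(expected)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(x=st.floats(-1e6, 1e6), c=st.floats(-1e5, 1e5),
           a=st.floats(0, 1e4), b=st.floats(1e-3, 1e4))
    def test_bounded_and_symmetric(self, x, c, a, b):
        d = trapezoid_membership(x, c, a, b)
        assert 0.0 <= d <= 1.0
        assert d == pytest.approx(trapezoid_membership(2 * c - x, c, a, b))
        assert (d == 1.0) == (abs(x - c) <= a)

    def test_zero_ramp_rejected(self):
        with pytest.raises(ValueError):
            trapezoid_membership(0, 0, 10, 0)


class TestBuildDatabase:
    def test_even_cluster_centroid_gives_full_membership(self):
        # anchors {100,150}: c = 125, both |x-c| = 25 <= a -> degree 1
        db = build_database(sites_at([100, 150]), MembershipParams())
        (t,) = db.transactions
        assert t.items == {"A": 1.0}
        assert len(t.site_pool["A"]) == 2

    def test_same_tf_aggregates_by_max_and_keeps_pool(self):
        # anchors at c and on the ramp: degrees 1.0 and 0.5
        sites = sites_at([1000, 1100, 1300])  # median c = 1100
        db = build_database(sites, MembershipParams())
        (t,) = db.transactions
        assert t.items["A"] == 1.0
        degs = sorted(d for _, d in t.site_pool["A"])
        assert degs == pytest.approx([0.5, 1.0, 1.0])

    def test_out_of_support_sites_dropped_and_empty_clusters_counted(self):
        # one isolated pair whose ramp excludes a member is impossible with
        # threshold <= a+b defaults; force it with a tight trapezoid
        params = MembershipParams(cluster_threshold=300, core_halfwidth=10, ramp_width=20)
        sites = sites_at([100, 400])  # c = 250, both 150 away -> degree 0
        db = build_database(sites, params)
        assert db.N == 0
        assert db.n_empty_dropped == 1

    def test_transaction_ids_and_span(self):
        db = build_database(sites_at([100, 150]) + sites_at([5000], tf="B"),
                            MembershipParams())
        assert [t.id for t in db.transactions] == ["T1", "T2"]
        assert (db.transactions[0].span_start, db.transactions[0].span_end) == (95, 155)
        assert db.alphabet == {"A", "B"}

    def test_determinism(self):
        rng = np.random.default_rng(7)
        anchors = rng.integers(0, 100_000, size=200)
        tfs = rng.choice(["A", "B", "C"], size=200)
        sites = [TFBSRecord(str(tf), "chr1", int(a), int(a) + 10)
                 for tf, a in zip(tfs, anchors)]
        db1 = build_database(sites, MembershipParams())
        db2 = build_database(list(sites), MembershipParams())
        assert [(t.id, t.items) for t in db1.transactions] == [
            (t.id, t.items) for t in db2.transactions]


class TestCrispDatabase:
    def test_contained_site_in_window(self):
        db = build_crisp_database(sites_at([100, 150]), MembershipParams(), 150)
        (t,) = db.transactions
        assert t.items == {"A": 1.0}

    def test_straddling_site_excluded_even_if_anchor_inside(self):
        # c = 125 for anchors {100,150}; W=30 -> window [95,155];
        # site [145,155) fits, a longer site anchored at 150 does not
        sites = [TFBSRecord("A", "chr1", 95, 105),
                 TFBSRecord("B", "chr1", 140, 160)]  # midpoint 150, end 160 > 155
        db = build_crisp_database(sites, MembershipParams(), 30)
        (t,) = db.transactions
        assert t.items == {"A": 1.0}

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_crisp_dominates_fuzzy_itemwise(self, seed):
        """With W >= a+b+max site length every crisp transaction's item set
        contains the fuzzy one, so per-itemset crisp support >= fuzzy."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 80))
        sites = [
            TFBSRecord(str(rng.choice(["A", "B", "C", "D"])), "chr1",
                       int(a), int(a) + 10)
            for a in rng.integers(0, 30_000, size=n)
        ]
        params = MembershipParams()
        W = params.core_halfwidth + params.ramp_width + 10
        fuzzy = build_database(sites, params)
        crisp = build_crisp_database(sites, params, W)
        # with this W any site inside the trapezoid support is fully inside
        # the crisp window, so crisp never drops a cluster fuzzy kept
        assume(fuzzy.n_empty_dropped == 0)
        assert crisp.N == fuzzy.N
        for tf, tc in zip(fuzzy.transactions, crisp.transactions):
            assert set(tf.items) <= set(tc.items)
            for item, deg in tf.items.items():
                assert tc.items[item] >= deg
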