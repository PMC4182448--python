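"""Clustering of binding sites and fuzzy transaction construction.

Closely located binding sites are grouped genome-wide by group-average
(UPGMA) agglomerative clustering of their 1-D anchor positions, run
independently per chromosome. Each cluster becomes one *fuzzy transaction*:
the set of transcription factors present, each with a membership degree in
``(0, 1]`` given by a trapezoidal function centred on the cluster centroid
(the median anchor position). The flat core of the trapezoid spans
``c ± a`` and each linear ramp is ``b`` wide, so degree falls from 1 to 0
between ``a`` and ``a + b`` away from the centroid.

A crisp variant assigns degree 1 to a site iff its whole interval lies
within ``c ± W`` and 0 otherwise; with ``W = a + b`` the crisp window is
the support of the trapezoid.
"""
from __future__ import annotations

import statistics
from dataclasses import dataclass, field

from .records import TFBSRecord

ANCHOR_MODES = ("midpoint", "start")


@dataclass(frozen=True)
class MembershipParams:
    """Clustering and trapezoidal-membership parameters (all in bp).

    cluster_threshold : stop merging once the closest pair of clusters is
        farther apart (average linkage) than this; 300 bp by default,
        matching the few-hundred-bp scale of regulatory modules.
    core_halfwidth : half-width ``a`` of the degree-1 core of the trapezoid.
    ramp_width : width ``b`` of each linear border.
    site_anchor : which point of a site is clustered and evaluated,
        ``midpoint`` (default) or ``start``.
    """

    cluster_threshold: int = 300
    core_halfwidth: int = 150
    ramp_width: int = 100
    site_anchor: str = "midpoint"

    def __post_init__(self) -> None:
        if self.cluster_threshold <= 0:
            raise ValueError("cluster_threshold must be > 0")
        if self.core_halfwidth < 0:
            raise ValueError("core_halfwidth must be >= 0")
        if self.ramp_width <= 0:
            raise ValueError("ramp_width must be > 0")
        if self.site_anchor not in ANCHOR_MODES:
            raise ValueError(f"site_anchor must be one of {ANCHOR_MODES}")


def anchor_position(site: TFBSRecord, site_anchor: str = "midpoint") -> float:
    """The 1-D point of a site used for clustering and membership."""
    if site_anchor == "midpoint":
        return site.midpoint
    if site_anchor == "start":
        return float(site.start)
    raise ValueError(f"unknown site_anchor {site_anchor!r}")


def trapezoid_membership(x: float, c: float, a: float, b: float) -> float:
    """Trapezoidal membership of position ``x`` in a cluster centred at ``c``.

    Returns 1 for ``|x - c| <= a``, falls linearly to 0 across the ramp
    ``a < |x - c| <= a + b``, and is 0 beyond. Total and symmetric in ``x``
    about ``c``.
    """
    if b <= 0:
        raise ValueError("ramp width b must be > 0")
    d = abs(x - c)
    if d <= a:
        return 1.0
    if d <= a + b:
        return (a + b - d) / b
    return 0.0


@dataclass
class SiteCluster:
    """One cluster of co-located sites on a single chromosome."""

    cluster_id: str
    chrom: str
    members: list[TFBSRecord]
    centroid: float  # median of member anchor positions


@dataclass
class FuzzyTransaction:
    """One cluster rendered as TF -> membership degree pairs.

    ``items`` maps each TF to its degree (the max over that TF's member
    sites); ``site_pool`` retains every member site with degree > 0 so the
    post-processing stage can resolve overlaps. Databases read back from a
    transaction file carry an empty ``site_pool``.
    """

    id: str
    chrom: str
    span_start: int
    span_end: int
    items: dict[str, float]
    site_pool: dict[str, list[tuple[TFBSRecord, float]]] = field(default_factory=dict)


@dataclass
class FuzzyTransactionDB:
    """Ordered collection of fuzzy transactions plus bookkeeping.

    ``n_empty_dropped`` counts clusters whose every site fell outside the
    membership support and which therefore produced no transaction; they
    are excluded from ``N``.
    """

    transactions: list[FuzzyTransaction]
    params: MembershipParams = field(default_factory=MembershipParams)
    mode: str = "fuzzy"
    n_empty_dropped: int = 0

    @property
    def N(self) -> int:
        return len(self.transactions)

    @property
    def alphabet(self) -> set[str]:
        out: set[str] = set()
        for t in self.transactions:
            out.update(t.items)
        return out


def _agglomerate_1d(anchors: list[float], threshold: float) -> list[tuple[int, int]]:
    """Group-average agglomeration of sorted 1-D points.

    For sorted 1-D points, average-linkage clusters stay contiguous and the
    average-linkage distance between two contiguous blocks equals the
    difference of their means, so only adjacent blocks need be considered.
    Merging continues while the smallest adjacent gap is <= threshold
    (inclusive); ties go to the leftmost pair. Returns [start, end) index
    ranges into the sorted anchor list.
    """
    n = len(anchors)
    if n == 0:
        return []
    bounds = [(i, i + 1) for i in range(n)]
    sums = list(anchors)
    counts = [1] * n
    while len(bounds) > 1:
        best_j = -1
        best_gap = None
        for j in range(len(bounds) - 1):
            gap = sums[j + 1] / counts[j + 1] - sums[j] / counts[j]
            if best_gap is None or gap < best_gap:
                best_gap = gap
                best_j = j
        if best_gap is None or best_gap > threshold:
            break
        j = best_j
        bounds[j] = (bounds[j][0], bounds[j + 1][1])
        sums[j] += sums[j + 1]
        counts[j] += counts[j + 1]
        del bounds[j + 1], sums[j + 1], counts[j + 1]
    return bounds


def cluster_sites(sites: list[TFBSRecord], params: MembershipParams) -> list[SiteCluster]:
    """Cluster sites per chromosome by average-linkage on anchor positions.

    Every input site lands in exactly one cluster; singletons are kept.
    Clusters are ordered by (chromosome, leftmost anchor) and their
    centroid is the median of member anchors.
    """
    by_chrom: dict[str, list[TFBSRecord]] = {}
    for s in sites:
        by_chrom.setdefault(s.chrom, []).append(s)

    clusters: list[SiteCluster] = []
    for chrom in sorted(by_chrom):
        chrom_sites = sorted(
            by_chrom[chrom],
            key=lambda s: (anchor_position(s, params.site_anchor), s.start, s.end, s.tf_label),
        )
        anchors = [anchor_position(s, params.site_anchor) for s in chrom_sites]
        for lo, hi in _agglomerate_1d(anchors, float(params.cluster_threshold)):
            members = chrom_sites[lo:hi]
            centroid = statistics.median(anchors[lo:hi])
            clusters.append(
                SiteCluster(
                    cluster_id=f"{chrom}:{len(clusters) + 1}",
                    chrom=chrom,
                    members=members,
                    centroid=float(centroid),
                )
            )
    # re-number globally in final order
    for i, cl in enumerate(clusters, start=1):
        cl.cluster_id = f"C{i}"
    return clusters


def _assemble(
    clusters: list[SiteCluster],
    degree_fn,
    params: MembershipParams,
    mode: str,
) -> FuzzyTransactionDB:
    transactions: list[FuzzyTransaction] = []
    dropped = 0
    for cl in clusters:
        pool: dict[str, list[tuple[TFBSRecord, float]]] = {}
        for s in cl.members:
            deg = degree_fn(s, cl)
            if deg > 0.0:
                pool.setdefault(s.tf_label, []).append((s, deg))
        if not pool:
            dropped += 1
            continue
        items = {tf: max(d for _, d in lst) for tf, lst in pool.items()}
        kept = [s for lst in pool.values() for s, _ in lst]
        transactions.append(
            FuzzyTransaction(
                id=f"T{len(transactions) + 1}",
                chrom=cl.chrom,
                span_start=min(s.start for s in kept),
                span_end=max(s.end for s in kept),
                items=items,
                site_pool=pool,
            )
        )
    return FuzzyTransactionDB(transactions, params=params, mode=mode, n_empty_dropped=dropped)


def build_database(sites: list[TFBSRecord], params: MembershipParams) -> FuzzyTransactionDB:
    """Cluster sites and build the fuzzy transactional database.

    Per cluster, each member site's degree is the trapezoidal membership of
    its anchor; a TF's item degree is the max over its sites, and every
    site with degree > 0 is retained in the transaction's site pool.
    Clusters whose sites all score 0 produce no transaction but are counted
    in the database's ``n_empty_dropped`` diagnostic.
    """
    clusters = cluster_sites(sites, params)
    a, b = float(params.core_halfwidth), float(params.ramp_width)

    def degree(site: TFBSRecord, cl: SiteCluster) -> float:
        return trapezoid_membership(anchor_position(site, params.site_anchor), cl.centroid, a, b)

    return _assemble(clusters, degree, params, mode="fuzzy")


def build_crisp_database(
    sites: list[TFBSRecord],
    params: MembershipParams,
    crisp_halfwidth: float | None = None,
) -> FuzzyTransactionDB:
    """Crisp-border variant: same clusters, all-or-nothing membership.

    A site belongs to its cluster (degree 1) iff its full interval
    ``[start, end)`` lies within ``[c - W, c + W]``; otherwise degree 0.
    Default ``W = a + b``, the trapezoid's support.
    """
    if crisp_halfwidth is None:
        crisp_halfwidth = float(params.core_halfwidth + params.ramp_width)
    W = float(crisp_halfwidth)
    clusters = cluster_sites(sites, params)

    def degree(site: TFBSRecord, cl: SiteCluster) -> float:
        return 1.0 if (site.start >= cl.centroid - W and site.end <= cl.centroid + W) else 0.0

    return _assemble(clusters, degree, params, mode="crisp")
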