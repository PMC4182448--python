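"""Overlap-aware fitting of itemsets into transactions.

Site predictions frequently overlap; simply discarding overlapping sites
would under-count co-occurrence. Instead, for every (itemset, transaction)
pair we look for the *optimal fit*: one concrete site per itemset TF, all
pairwise non-overlapping, maximizing the minimum membership degree of the
chosen sites. A successful fit is a concrete putative CRM instance; the
per-itemset average of fit degrees over all transactions is the post-fit
support, which can never exceed the unconstrained fuzzy support.
"""
from __future__ import annotations

from dataclasses import dataclass

from .mining import FuzzyItemset
from .records import TFBSRecord
from .transactions import FuzzyTransaction, FuzzyTransactionDB


@dataclass
class CRMInstance:
    """One concrete, non-overlapping placement of an itemset in a transaction."""

    itemset: tuple[str, ...]
    transaction_id: str
    chosen_sites: dict[str, TFBSRecord]
    fit_degree: float  # min degree over the chosen sites
    chrom: str
    start: int  # min start over chosen sites
    end: int  # max end over chosen sites


def fit_itemset(transaction: FuzzyTransaction, itemset: tuple[str, ...] | set[str]) -> CRMInstance | None:
    """Optimally fit an itemset into one transaction, or return None.

    Exact search over one-site-per-TF assignments with branch-and-bound on
    the running minimum degree. Ties on the maximal minimum degree are
    broken by higher total degree, then by leftmost locus start, then
    leftmost end. Returns None when some TF has no site in the transaction
    or no pairwise-disjoint assignment exists.
    """
    tfs = sorted(itemset)
    pools = []
    for tf in tfs:
        cands = transaction.site_pool.get(tf)
        if not cands:
            return None
        pools.append(sorted(cands, key=lambda sd: (-sd[1], sd[0].start, sd[0].end)))
    # fewest candidates first narrows the search
    order = sorted(range(len(tfs)), key=lambda i: len(pools[i]))

    best: dict = {"key": None, "sites": None, "fit": 0.0}

    def search(pos: int, chosen: list[tuple[TFBSRecord, float]], running_min: float) -> None:
        if pos == len(order):
            sites = {tfs[order[i]]: chosen[i][0] for i in range(len(order))}
            total = sum(d for _, d in chosen)
            start = min(s.start for s, _ in chosen)
            end = max(s.end for s, _ in chosen)
            key = (running_min, total, -start, -end)
            if best["key"] is None or key > best["key"]:
                best["key"] = key
                best["sites"] = sites
                best["fit"] = running_min
        else:
            for site, deg in pools[order[pos]]:
                new_min = min(running_min, deg)
                # candidates are degree-sorted: once strictly below the best
                # achievable min, the rest of this pool cannot win either
                if best["key"] is not None and new_min < best["key"][0]:
                    break
                if any(site.overlaps(s) for s, _ in chosen):
                    continue
                search(pos + 1, chosen + [(site, deg)], new_min)

    search(0, [], 1.0)
    if best["sites"] is None:
        return None
    sites = best["sites"]
    return CRMInstance(
        itemset=tuple(tfs),
        transaction_id=transaction.id,
        chosen_sites=sites,
        fit_degree=best["fit"],
        chrom=transaction.chrom,
        start=min(s.start for s in sites.values()),
        end=max(s.end for s in sites.values()),
    )


def refit_all(
    db: FuzzyTransactionDB,
    itemsets: list[FuzzyItemset],
    min_support: float = 0.0,
) -> tuple[list[CRMInstance], list[FuzzyItemset]]:
    """Fit every reported itemset into every transaction.

    Post-fit support is the average fit degree over all N transactions
    (failed fits contribute 0). Itemsets whose post-fit support drops below
    ``min_support`` are flagged ``postfit_dropped`` but remain listed, so
    both the unconstrained and the overlap-resolved numbers are visible.
    """
    instances: list[CRMInstance] = []
    refitted: list[FuzzyItemset] = []
    for s in itemsets:
        total = 0.0
        for t in db.transactions:
            inst = fit_itemset(t, s.items)
            if inst is not None and inst.fit_degree > 0.0:
                total += inst.fit_degree
                instances.append(inst)
        postfit = total / db.N if db.N else 0.0
        refitted.append(
            FuzzyItemset(
                s.items,
                s.fuzzy_support,
                p_value=s.p_value,
                postfit_support=postfit,
                postfit_dropped=postfit < min_support,
            )
        )
    return instances, refitted
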