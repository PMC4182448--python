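"""Fuzzy frequent-itemset mining with a fuzzy FP-tree.

An itemset's *fuzzy support* is the sigma-count under the minimum t-norm::

    support(I) = (1/N) * sum_t min_{i in I} degree_t(i)

with a missing item contributing degree 0 to a transaction. The miner
compresses the database into a prefix tree (FP-tree) whose nodes carry
sparse per-transaction degree vectors, then traverses the header table
top-down: for each item it walks from that item's nodes up towards the
root, propagating the running minimum degree in *copies* of the vectors so
that processing one item never perturbs another. A brute-force enumerator
over all subsets of the frequent items serves as the reference oracle for
small alphabets.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .transactions import FuzzyTransactionDB


@dataclass
class FuzzyItemset:
    """A TF combination with its fuzzy support and significance scores."""

    items: tuple[str, ...]  # sorted lexicographically
    fuzzy_support: float
    p_value: float | None = None
    postfit_support: float | None = None
    postfit_dropped: bool = False

    @property
    def size(self) -> int:
        return len(self.items)


@dataclass
class FPTreeNode:
    item: str | None  # None marks the root
    parent: "FPTreeNode | None" = None
    children: dict[str, "FPTreeNode"] = field(default_factory=dict)
    # transaction id -> membership degree of this node's item, for every
    # transaction routed through this node
    degrees: dict[str, float] = field(default_factory=dict)


@dataclass
class HeaderTableRow:
    """Per-item index row: support, per-transaction degrees, node links."""

    item: str
    item_support: float
    degree_vector: dict[str, float]  # transaction id -> degree
    node_link: list[FPTreeNode] = field(default_factory=list)


def find_frequent_items(db: FuzzyTransactionDB, min_support: float) -> list[HeaderTableRow]:
    """Scan the database for items with fuzzy support >= min_support.

    Item support is the sigma-count of the single item over N. Rows come
    back sorted by descending support, ties broken lexicographically.
    min_support = 0 is accepted as the degenerate keep-everything case.
    """
    if db.N == 0:
        raise ValueError("empty database")
    if not 0.0 <= min_support <= 1.0:
        raise ValueError("min_support must be in [0, 1]")
    vectors: dict[str, dict[str, float]] = {}
    for t in db.transactions:
        for item, deg in t.items.items():
            vectors.setdefault(item, {})[t.id] = deg
    rows = [
        HeaderTableRow(item, sum(vec.values()) / db.N, vec)
        for item, vec in vectors.items()
    ]
    rows = [r for r in rows if r.item_support >= min_support]
    rows.sort(key=lambda r: (-r.item_support, r.item))
    return rows


def build_fptree(
    db: FuzzyTransactionDB, header: list[HeaderTableRow]
) -> tuple[FPTreeNode, list[HeaderTableRow]]:
    """Insert every transaction's frequent items as a path from the root.

    Items are ordered by header rank so transactions sharing leading
    frequent items share their upper path; each traversed node records the
    transaction's degree for the node's item. Node links in the header are
    populated in node-creation order.
    """
    rank = {row.item: i for i, row in enumerate(header)}
    by_item = {row.item: row for row in header}
    for row in header:
        row.node_link = []
    root = FPTreeNode(item=None)
    for t in db.transactions:
        path_items = sorted((i for i in t.items if i in rank), key=rank.__getitem__)
        node = root
        for item in path_items:
            child = node.children.get(item)
            if child is None:
                child = FPTreeNode(item=item, parent=node)
                node.children[item] = child
                by_item[item].node_link.append(child)
            child.degrees[t.id] = child.degrees.get(t.id, 0.0) + t.items[item]
            node = child
    return root, header


def _extend(
    suffix: tuple[str, ...],
    entries: list[tuple[float, dict[str, float]]],
    rank: dict[str, int],
    N: int,
    min_support: float,
    min_size: int,
    out: list[FuzzyItemset],
) -> None:
    # entries: (running min degree from the suffix path, {higher-ranked
    # ancestor item -> its degree in this transaction}); each recursion
    # builds fresh entry lists, never mutating the tree's vectors.
    candidates: dict[str, float] = {}
    for mindeg, avail in entries:
        for item, deg in avail.items():
            candidates[item] = candidates.get(item, 0.0) + min(mindeg, deg)
    for item in sorted(candidates, key=lambda i: (-candidates[i], i)):
        support = candidates[item] / N
        if support < min_support:
            continue
        new_suffix = suffix + (item,)
        if len(new_suffix) >= min_size:
            out.append(FuzzyItemset(tuple(sorted(new_suffix)), support))
        r = rank[item]
        sub_entries = []
        for mindeg, avail in entries:
            if item in avail:
                higher = {k: v for k, v in avail.items() if rank[k] < r}
                if higher:
                    sub_entries.append((min(mindeg, avail[item]), higher))
        if sub_entries:
            _extend(new_suffix, sub_entries, rank, N, min_support, min_size, out)


def mine_topdown(
    tree: FPTreeNode,
    header: list[HeaderTableRow],
    db_size: int,
    min_support: float,
    min_size: int = 2,
) -> list[FuzzyItemset]:
    """Enumerate all frequent fuzzy itemsets from the FP-tree.

    Header rows are processed top-down; for each item the tree is walked
    from that item's nodes up to the root, each step taking the minimum of
    the propagated degree vector and the ancestor's degrees. Anti-monotone
    pruning on the running support keeps the search shallow. The traversal
    is non-destructive: mining twice from the same tree yields identical
    results.
    """
    rank = {row.item: i for i, row in enumerate(header)}
    results: list[FuzzyItemset] = []
    for row in header:
        if min_size <= 1:
            results.append(FuzzyItemset((row.item,), row.item_support))
        entries: list[tuple[float, dict[str, float]]] = []
        for node in row.node_link:
            ancestors: list[FPTreeNode] = []
            p = node.parent
            while p is not None and p.item is not None:
                ancestors.append(p)
                p = p.parent
            if not ancestors:
                continue
            for tid, deg in node.degrees.items():
                avail = {anc.item: anc.degrees[tid] for anc in ancestors}
                entries.append((deg, avail))
        if entries:
            _extend((row.item,), entries, rank, db_size, min_support, min_size, results)
    results.sort(key=lambda s: (-s.fuzzy_support, s.items))
    return results


def mine_database(
    db: FuzzyTransactionDB, min_support: float, min_size: int = 2
) -> tuple[list[HeaderTableRow], list[FuzzyItemset]]:
    """Convenience wrapper: header table, FP-tree, top-down mining."""
    header = find_frequent_items(db, min_support)
    tree, header = build_fptree(db, header)
    return header, mine_topdown(tree, header, db.N, min_support, min_size)


MAX_BRUTEFORCE_ALPHABET = 20


def mine_bruteforce(
    db: FuzzyTransactionDB, min_support: float, min_size: int = 2
) -> list[FuzzyItemset]:
    """Reference miner: exhaustive enumeration over the frequent items.

    Supports are computed by direct summation of per-transaction minima.
    Only feasible for small alphabets; use the FP-tree miner otherwise.
    """
    if len(db.alphabet) > MAX_BRUTEFORCE_ALPHABET:
        raise ValueError(
            f"alphabet has {len(db.alphabet)} items; brute-force enumeration is "
            f"capped at {MAX_BRUTEFORCE_ALPHABET} — use mine_database instead"
        )
    header = find_frequent_items(db, min_support)
    items = sorted(row.item for row in header)
    if not items:
        return []
    idx = {item: j for j, item in enumerate(items)}
    M = np.zeros((db.N, len(items)))
    for i, t in enumerate(db.transactions):
        for item, deg in t.items.items():
            if item in idx:
                M[i, idx[item]] = deg
    results: list[FuzzyItemset] = []
    for size in range(max(min_size, 1), len(items) + 1):
        for combo in itertools.combinations(items, size):
            cols = [idx[i] for i in combo]
            support = float(M[:, cols].min(axis=1).sum()) / db.N
            if support >= min_support:
                results.append(FuzzyItemset(combo, support))
    results.sort(key=lambda s: (-s.fuzzy_support, s.items))
    return results
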