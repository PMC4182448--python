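import numpy as np
import pytest

from fuzzycrm.records import TFBSRecord
from fuzzycrm.transactions import FuzzyTransaction, FuzzyTransactionDB


def random_fuzzy_db(rng, max_items=12, max_transactions=200, item_prob=0.4,
                    crisp=False) -> FuzzyTransactionDB:
    """Random small database for oracle-equivalence and property checks."""
    k = int(rng.integers(2, max_items + 1))
    n = int(rng.integers(2, max_transactions + 1))
    items = [f"I{j:02d}" for j in range(k)]
    transactions = []
    for i in range(n):
        degs = {}
        for item in items:
            if rng.random() < item_prob:
                degs[item] = 1.0 if crisp else float(np.round(rng.uniform(0.001, 1.0), 3))
        if degs:
            transactions.append(
                FuzzyTransaction(f"T{i}", "chr1", 0, 1, degs)
            )
    return FuzzyTransactionDB(transactions)


def supports_by_items(itemsets):
    return {s.items: s.fuzzy_support for s in itemsets}


def random_transaction(rng, n_tfs=4, max_sites=4, span=120):
    """Random transaction with possibly-overlapping sites, for fit tests."""
    pool = {}
    items = {}
    for j in range(n_tfs):
        tf = chr(ord("A") + j)
        sites = []
        for _ in range(int(rng.integers(0, max_sites + 1))):
            start = int(rng.integers(0, span))
            length = int(rng.integers(5, 25))
            deg = float(np.round(rng.uniform(0.05, 1.0), 3))
            sites.append((TFBSRecord(tf, "chr1", start, start + length), deg))
        if sites:
            pool[tf] = sites
            items[tf] = max(d for _, d in sites)
    if not items:
        items = {"A": 1.0}
        pool = {"A": [(TFBSRecord("A", "chr1", 0, 10), 1.0)]}
    return FuzzyTransaction("T1", "chr1", 0, span + 30, items, pool)


@pytest.fixture
def three_transaction_db() -> FuzzyTransactionDB:
    """The worked 3-transaction example used across the mining tests."""
    return FuzzyTransactionDB([
        FuzzyTransaction("T1", "chr1", 0, 10, {"A": 1.0, "B": 0.5}),
        FuzzyTransaction("T2", "chr1", 20, 30, {"A": 0.8, "C": 1.0}),
        FuzzyTransaction("T3", "chr1", 40, 50, {"A": 1.0, "B": 1.0}),
    ])


@pytest.fixture
def overlap_transaction() -> FuzzyTransaction:
    """A transaction where A's only site overlaps the better B site.

    The optimal non-overlapping fit of {A, B, C} must fall back to the
    weaker B site, giving fit degree 0.6.
    """
    pool = {
        "A": [(TFBSRecord("A", "chr1", 0, 10), 0.9)],
        "B": [(TFBSRecord("B", "chr1", 5, 15), 0.8),
              (TFBSRecord("B", "chr1", 20, 30), 0.6)],
        "C": [(TFBSRecord("C", "chr1", 35, 45), 0.7)],
    }
    items = {tf: max(d for _, d in lst) for tf, lst in pool.items()}
    return FuzzyTransaction("T1", "chr1", 0, 45, items, pool)
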