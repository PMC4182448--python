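"""Itemset significance under an independence null model.

The null model assumes items (TFs) occur independently across transactions
with their observed marginal supports. An itemset of marginals
``p_1, ..., p_m`` then co-occurs in a transaction with probability
``p0 = prod p_i``, and the number of co-occurrences in N transactions is
Binomial(N, p0). The fuzzy support is converted to an integer observed
count k (ceiling of the sigma-count by default — conservative, since
rounding the observed count up can only start the tail later), and the
p-value is the exact binomial upper tail P(X >= k).
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from scipy.stats import binom

from .mining import FuzzyItemset, HeaderTableRow
from .transactions import FuzzyTransactionDB

COUNT_ROUNDINGS = ("ceil", "floor", "round")
_EPS = 1e-9


@dataclass
class NullModel:
    """Independence null: transaction count and per-item marginal supports."""

    N: int
    item_marginals: dict[str, float]

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        for item, p in self.item_marginals.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"marginal for {item!r} outside [0, 1]: {p}")

    @classmethod
    def from_database(cls, db: FuzzyTransactionDB) -> "NullModel":
        """Self-calibrated null: marginals are the single-item fuzzy supports."""
        if db.N == 0:
            raise ValueError("empty database")
        totals: dict[str, float] = {}
        for t in db.transactions:
            for item, deg in t.items.items():
                totals[item] = totals.get(item, 0.0) + deg
        return cls(N=db.N, item_marginals={i: s / db.N for i, s in totals.items()})

    @classmethod
    def from_header(cls, header: list[HeaderTableRow], N: int) -> "NullModel":
        return cls(N=N, item_marginals={r.item: r.item_support for r in header})


def observed_count(N: int, itemset_support: float, count_rounding: str = "ceil") -> int:
    """Integer co-occurrence count from a fuzzy support (sigma-count / N)."""
    if count_rounding not in COUNT_ROUNDINGS:
        raise ValueError(f"count_rounding must be one of {COUNT_ROUNDINGS}")
    x = N * itemset_support
    if count_rounding == "ceil":
        return math.ceil(x - _EPS)
    if count_rounding == "floor":
        return math.floor(x + _EPS)
    return round(x)


def itemset_pvalue(
    itemset_support: float,
    items: frozenset[str] | set[str] | tuple[str, ...],
    null: NullModel,
    count_rounding: str = "ceil",
) -> float:
    """Binomial upper-tail p-value of an itemset under the independence null.

    ``p0`` is the product of the item marginals, ``k`` the integer observed
    count; returns ``P(X >= k)`` for ``X ~ Binomial(N, p0)`` (1 when k = 0).
    Evaluated via the regularized incomplete beta (scipy's survival
    function), numerically equivalent to exact term summation.
    """
    if not 0.0 <= itemset_support <= 1.0:
        raise ValueError("itemset_support must be in [0, 1]")
    p0 = 1.0
    for item in items:
        if item not in null.item_marginals:
            raise KeyError(f"item {item!r} missing from null-model marginals")
        p0 *= null.item_marginals[item]
    k = observed_count(null.N, itemset_support, count_rounding)
    if k <= 0:
        return 1.0
    if p0 == 0.0:
        warnings.warn(
            "degenerate null: zero marginal product with a positive observed count",
            stacklevel=2,
        )
        return 0.0
    return float(binom.sf(k - 1, null.N, p0))


def filter_report(
    itemsets: list[FuzzyItemset],
    null: NullModel,
    max_pvalue: float,
    min_support: float,
    count_rounding: str = "ceil",
    bh_correction: bool = False,
) -> list[FuzzyItemset]:
    """Attach p-values, apply the support and p-value thresholds, and rank.

    Kept itemsets satisfy ``fuzzy_support >= min_support`` and
    ``p <= max_pvalue``; with ``bh_correction`` the threshold is applied to
    Benjamini–Hochberg adjusted p-values (raw p-values stay attached).
    Output is sorted by ascending p-value, then descending support, then
    items.
    """
    scored: list[FuzzyItemset] = []
    for s in itemsets:
        p = itemset_pvalue(s.fuzzy_support, s.items, null, count_rounding)
        scored.append(
            FuzzyItemset(s.items, s.fuzzy_support, p_value=p,
                         postfit_support=s.postfit_support,
                         postfit_dropped=s.postfit_dropped)
        )
    if bh_correction and scored:
        from statsmodels.stats.multitest import multipletests

        reject, _, _, _ = multipletests(
            [s.p_value for s in scored], alpha=max_pvalue, method="fdr_bh"
        )
        kept = [s for s, r in zip(scored, reject) if r and s.fuzzy_support >= min_support]
    else:
        kept = [
            s for s in scored
            if s.fuzzy_support >= min_support and s.p_value <= max_pvalue
        ]
    kept.sort(key=lambda s: (s.p_value, -s.fuzzy_support, s.items))
    return kept
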