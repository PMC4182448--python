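# Methods

## Model

`fuzzycrm` treats genome-wide CRM discovery as fuzzy frequent-itemset
mining. Binding-site clusters play the role of market-basket
*transactions*; TFs are *items*; a candidate CRM is an *itemset*. Fuzzy
membership degrees encode how centrally a site sits in its cluster, so a
site near a cluster border contributes partially rather than being
arbitrarily included or excluded.

### Clustering

Sites are reduced to a 1-D anchor (interval midpoint by default; the
start coordinate optionally) and clustered per chromosome with
group-average (UPGMA) agglomeration. Merging stops when the smallest
inter-cluster average distance exceeds the threshold; a merge at exactly
the threshold is allowed. For 1-D data, average-linkage clusters remain
contiguous intervals and the average-linkage distance between two
contiguous clusters equals the difference of their means, so the
implementation merges adjacent blocks of the sorted anchor list directly —
exact, O(n²) per chromosome, and deterministic. Equal-distance candidates
are resolved in favour of the leftmost pair, making tree shape and output
platform-independent. Strand is carried through to output but never used:
cooperating TFs need not bind the same strand, and the method has no
strand-specific model.

### Membership

Each cluster's centroid *c* is the median anchor (mean of the two middle
values for even counts). A site's degree is trapezoidal in its anchor's
distance from *c*: 1 within *a*, linear from 1 to 0 over the next *b*,
0 beyond. When one TF has several sites in a cluster its item degree is
their maximum — the best single site represents the TF, and degrees stay
in [0, 1]. All positive-degree sites are retained per transaction for
post-processing. Clusters whose sites all fall outside the trapezoid
support produce no transaction; they are counted in a diagnostic but
excluded from N (with default parameters this is essentially impossible,
because the median site sits at the centroid).

Singleton and single-TF clusters *are* transactions and count toward N:
they carry the item-frequency information the independence null is
calibrated from.

Crisp mode keeps the identical clustering but assigns degree 1 exactly to
sites whose whole interval lies inside `[c − W, c + W]`. With
`W ≥ a + b + max site length` every site the fuzzy mode scores positively
is fully contained, so each crisp transaction's item set contains the
fuzzy one and per-itemset crisp support dominates fuzzy support.

### Mining

Fuzzy support uses the minimum t-norm with sigma-count normalization:
`supp(I) = (1/N) Σ_t min_{i∈I} μ_t(i)`, missing items contributing 0.
The minimum t-norm makes support anti-monotone (any superset is at most
as frequent), which both justifies FP-style pruning and matches the
intuition that a module is only as present as its least-present member.

The FP-tree inserts each transaction's frequent items in descending
global-support order (ties lexicographic), sharing prefixes; every node
stores a sparse map from transaction id to that item's degree. Mining
walks the header table top-down; for each item it collects the paths above
that item's nodes and recursively extends itemsets with higher-ranked
path items, propagating the running minimum degree in freshly built
structures. The tree is never mutated, so repeated mining from one tree is
reproducible, and pruning discards an extension as soon as its running
support falls below σ. A brute-force enumerator (alphabet capped at 20)
recomputes supports by direct summation and serves as the test oracle.

### Significance

The null model assumes TFs land in transactions independently with their
observed marginal supports (self-calibrated from the same database). The
observed fuzzy support is converted to an integer count k before the
binomial tail is taken. The ceiling is the default conversion: it starts
the tail at or above the fractional sigma-count, so fuzziness can never
*inflate* significance; `floor` and `round` are available for sensitivity
analysis. The tail `P(X ≥ k)` is evaluated with scipy's binomial survival
function (regularized incomplete beta), which agrees with direct term
summation to ~1e-15 in the tested N ≤ 50 range. A small epsilon (1e-9)
guards the count conversion against binary floating-point fuzz such as
`1000 × 0.013 = 13.000000000000002`.

Raw p-values are reported and thresholded by default. Benjamini–Hochberg
control (via statsmodels) is optional; results are ranked by ascending
p-value, then descending support, then label order.

### Post-processing

For each reported itemset and each transaction, the tool searches for one
site per TF, pairwise non-overlapping (half-open semantics: abutting
intervals do not overlap), maximizing the minimum degree. Itemsets in
practice have 2–4 TFs and clusters hold few sites per TF, so exact search
is cheap: candidates are tried in descending degree order with
branch-and-bound on the running minimum, which preserves exactness.
Ties are broken by larger total degree, then leftmost (then shortest-span)
locus, for deterministic output. The post-fit support averages fit degrees
over all N transactions (failed fits count 0), so it never exceeds the
unconstrained fuzzy support. Itemsets falling below the support threshold
after fitting are flagged rather than removed — the pre-fit p-value and
both supports stay visible. P-values are not recomputed after fitting by
default; `filter_report` can be re-applied to refitted supports if a user
wants post-fit significance.

## Parameter defaults

| parameter | default | meaning |
|---|---|---|
| `cluster_threshold` | 300 bp | merge stop distance; CRMs are generally a few hundred bp |
| `core_halfwidth` (*a*) | 150 bp | degree-1 core half-width; core diameter matches the 300 bp cluster scale |
| `ramp_width` (*b*) | 100 bp | linear border width |
| `crisp_halfwidth` (*W*) | 250 bp | crisp window = trapezoid support (*a* + *b*) |
| `min_support` (σ) | 0.01 | itemset must cover ≥1% of transactions (sigma-count) |
| `max_pvalue` | 0.01 | binomial-tail threshold |
| `min_size` | 2 | single TFs are not modules |
| `count_rounding` | ceil | conservative fuzzy-to-count conversion |

All are CLI flags and `RunConfig` fields; every run's manifest records
them.

## Synthetic data

The generator emulates a genome-wide site landscape: background sites
with uniform positions (chromosomes weighted by length) and uniform TF
labels — optionally a skewed frequency vector, since real annotation sets
have rare TFs prone to spurious itemsets — plus planted modules: loci
where a fixed TF subset is placed within a window, sites
rejection-sampled to be disjoint. It does **not** model sequence, PWM
score distributions, clustered background (e.g. promoter pile-ups),
strand structure, or overlapping planted sites, so passing tests show the
pipeline recovers co-occurrence structure under idealized placement noise
— not that it is robust to scanner-specific artefacts.

Study conditions used by the test suite and acceptance script: ten 1 Mb
chromosomes, a 10-TF alphabet, 950–1000 background sites (≈970 clusters,
mostly singletons), and 50 planted `{TF01,TF02,TF03}` loci within 200 bp
windows. At σ = 0.01 and α = 0.01 the planted triple's support (≈0.05) and
tail p-value (≈10⁻⁴⁰) make recovery essentially certain, while pure-noise
landscapes yield on average zero significant itemsets — the desk-scale
analogue of a randomized-genome control. These sizes keep the full suite
under ten seconds; they were chosen as the smallest landscape that still
separates planted structure from noise by orders of magnitude.

## Numerical and degenerate cases

- Degrees serialize at 4 decimals (transaction files round-trip to that
  quantization); supports print at 6 decimals, p-values at 4 significant
  digits.
- An empty site list yields an empty cluster list; an empty database is an
  error for mining but an empty *result* is a success with header-only
  outputs.
- A zero marginal with a positive observed count returns p = 0 with a
  warning (only reachable with inconsistent user-supplied nulls).
- `min_support = 0` with `min_size = 1` enumerates every itemset over the
  alphabet — supported for the brute-force oracle, not recommended
  otherwise.

## Known limitations

- The miner enumerates *all* frequent itemsets, not closed or maximal
  ones; low σ on dense databases can blow up output size.
- The independence null ignores the overlap between nested itemsets and
  between transactions on the same chromosome arm; p-values are scores for
  ranking, not calibrated genome-wide error rates (use the BH flag for
  multiplicity control).
- Clustering is 1-D and hard: a site belongs to exactly one cluster, so a
  CRM straddling two clusters is split.
- Transaction files do not carry site provenance, so post-processing
  (instances, post-fit support) is only available when starting from site
  annotations.
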