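# Methods notes

## Model and scoring

A chromosome of `n` bins at fixed bin size carries a symmetric,
non-negative contact matrix `A`. Bins are 0-based; a domain `[a, b]` is
inclusive of both endpoint bins and must cover at least two bins. The raw
sum of an interval is the total frequency over its strictly
upper-triangular pairs — the diagonal `A[g,g]` is never counted. The scaled
density divides the raw sum by `(l − k)^γ`, the *span* (number of bins
minus one), not by the bin count; at γ = 1 this is the weighted subgraph
density, at γ = 2 half the internal density of the interval as a graph
cluster.

Quality zero-centres the scaled density against `μ_s(span)`, the mean over
all `n − span` diagonal windows of equal span. The γ-independent mean raw
sum per span is precomputed once, so `μ_s` at any γ is a single division.
Spans with fewer than `min_mean_samples` windows (default 100) are
forbidden entirely: their background mean would rest on too few samples.
On real 40 kb data this only excludes domains longer than
`(n − 100)` bins — hundreds of megabases — but it makes matrices with
`n < 102` degenerate, so tests and small examples lower the parameter
(typically to 1). The threshold is exposed everywhere as
`min_mean_samples`.

All interval sums come from a padded 2-D prefix-sum table plus a diagonal
cumulative sum: `O(n²)` preprocessing, `O(1)` per query, `O(n²)` memory
(the same order as the input matrix). Cancellation in the prefix-sum
difference can leave residues of order `1e-16`, which are clamped to zero
so that empty intervals score exactly 0.

## Segmentation and ranked enumeration

Non-domains (gaps) contribute nothing to the objective, so two adjacent
gaps would let one set of domains correspond to arbitrarily many
equal-scoring tilings. Gaps are therefore maximal — after a gap a domain
must follow — which puts valid segmentations in bijection with sets of
non-overlapping positive-quality domains. The optimum is a highest-weight
path in a DAG whose nodes are bin boundaries in one of two states
("previous block was a domain/start" vs "previous block was a gap");
domain edges carry `q > 0`, gap edges carry 0, and forbidden spans are
`−∞`.

K-best enumeration is a lazy best-first search over that DAG using exact
optimal-completion values (computed by a backward DP) as the priority
bound, so solutions emerge in non-increasing score order without a
pre-set score cutoff. Distinct paths correspond to distinct domain sets by
construction; an explicit dedup guard remains as a safety net.
`solve_optimal` is defined as the first ranked solution, so the single
tie-break policy lives in one place: scores within `1e-9` are tied, and
tied solutions are ordered by fewer domains first, then the
lexicographically smallest interval list. The brute-force enumerator used
as a test oracle recursively tiles the chromosome and is capped at
`n ≤ 16`.

## Sweep, persistence, consensus

The γ grid is `{0, step, …, γ_max}` with `step = 0.05` by default; γ = 0
is included because domain growth as γ → 0 is part of the behaviour being
swept. Persistence counts *exact* interval repetitions across the single
optimal set per γ — near-duplicate merging is deliberately rejected, so
persistence is a lower bound. The consensus solves weighted interval
scheduling over endpoint-sorted candidates with a binary-searched
compatible predecessor (`O(m log m)`); two domains conflict only if they
share a bin, so touching domains can both enter the consensus. On equal
totals the DP prefers inclusion, which is deterministic given the sort.

`select_gamma_max` scans the grid upward from 0 and returns the first γ
whose optimal set has median domain size above `min_median_bins` (default
2 bins, i.e. > 80 kb at 40 kb bins), capped at γ = 2. The published
heuristic this implements is ambiguous about scan direction — read
literally, "smallest γ" conflicts with domain sizes shrinking as γ grows —
and the upward scan is adopted as the package's contract; with
`gamma_max=None` the consensus estimator uses it, and a grid that
degenerates to γ = 0 alone is handled as a single-resolution sweep.

## Variation of information

Each domain set is completed with its gap intervals into a partition of
`[0, L)`; block probabilities are lengths over `L`, joint probabilities
are intersection lengths over `L`, computed by a linear merge of the two
sorted tilings. Natural logarithms throughout; VI values are compared,
never interpreted in units, so the base is internal but fixed. Tiny
negative rounding residues are clipped to 0.

## Hierarchy score

The score asks: among comparable pairs of pooled domains, how often is one
completely inside the other? A pair *qualifies* when the two domains
(i) share at least one bin and (ii) differ in more than a fraction α
(default 0.1) of their union, measured as symmetric difference over union.
Condition (ii) discards near-identical duplicates that inevitably arise
when pooling similar solutions across resolutions; condition (i) excludes
disjoint pairs, which carry no information about nesting — without it,
pools of domains tiling a chromosome would be dominated by disjoint pairs
and the score would collapse toward 0 regardless of structure, making the
score's documented extremes (≈1 for strongly nested multiscale pools)
unreachable. δ is *proper* containment; pooling is a set union, so
duplicates collapse before pairing.

Conventions at the edges: a pool with fewer than two distinct domains has
no score (an error, not 0); a pool with pairs but no qualifying ones
scores 0 when no domain contains another (the "nothing is nested" limit),
and is undefined in the degenerate corner where the only containments are
α-similar near-duplicates. `max_pairs` (off by default) uniformly
subsamples the pair population with an explicit seed for very large pools.

Note: by construction, randomly scattered sparse pools score well below
0.5 here (≈0.3 for pools of 200 domains with lengths uniform in 5–50 bins
on 5,000 bins, where containment given overlap is
`E[(Δlen + 1)/(len_i + len_j − 1)]`); a mean of 0.5 arises only for length
distributions with much broader dispersion, such as pools mixing widely
different scales.

## Shuffle null and significance

The null preserves structure lengths exactly: domain lengths are permuted
among domain slots and gap lengths among gap slots, keeping the
alternation pattern, so both length multisets and total coverage are
unchanged. Each solution in a pool is shuffled independently and the
shuffles re-pooled, preserving the per-solution length distributions.
Empirical p-values use the add-one permutation correction
`p = (1 + #{null ≥ obs}) / (1 + R)` so p is never 0, and are
Benjamini–Hochberg adjusted across chromosomes (statsmodels).

## Boundary enrichment

Overlap is ≥ 1 bp on half-open bp intervals (standard BED semantics).
Occupancy counts regions containing at least one peak. Touching domains
get a ± `flank_bins` window (default 1 bin) around the shared edge as
their boundary. Profiles place each peak at its midpoint — the
conventional choice for point marks — and count midpoints in offset bins
around boundary midpoints, averaged over boundaries, with the
domain-midpoint profile as baseline; the window must be a multiple of the
profile bin (with 40 kb profile bins, use e.g. a 480 kb rather than
500 kb half-window).

## Synthetic matrices

The generator is a multiplicative block model with Poisson noise: expected
counts are `background_scale · (1 + d)^(−decay_exponent)` at bin distance
`d`, multiplied by the enrichment factor of every planted domain
containing both bins, so nested children compound their parents' factors.
The upper triangle is drawn and mirrored — matrices are exactly symmetric
and reproducible by seed. Defaults: background scale 15 (counts of order
1–15 over the relevant distances, comparable to corrected mid-range Hi-C
counts at 40 kb), decay exponent 0.8 (sub-quadratic, qualitatively
fractal-globule-like), enrichment 4×. The planted-recovery fixture uses
n = 200 bins with four 40-bin parents at 6× and two 15-bin children per
parent at a further 2× (12× net): a parent-to-child density step large
enough that the two scales separate cleanly in γ, which is the behaviour
under test. What the generator does *not* emulate: bias/mappability
artifacts, A/B compartments, translocations, or the continuous
density gradients of real chromatin — so passing recovery tests shows the
optimizer resolves planted multiplicative hierarchies under Poisson noise,
not that any particular γ is right for real data.

`random_domain_set` draws i.i.d. uniform lengths and distributes the free
space uniformly over gap slots (a stars-and-bars construction), so every
non-overlapping arrangement of the drawn lengths is equally likely.

## Problem sizes in the test suite

Oracle-equivalence tests run hundreds of random instances at `n ≤ 12`
(segmentation), `n ≤ 8` (ranked enumeration), `m ≤ 15` (consensus) and
`L ≤ 200` (VI); recovery and significance tests use single `200 × 200`
matrices with 200 shuffle replicates. These sizes keep the whole suite at
a few seconds while exercising every code path; the algorithms themselves
scale to whole-chromosome matrices (`O(n²)` per resolution).

## Known limitations

- Persistence is exact-match only; a domain that shifts by one bin across
  resolutions counts as two domains.
- The scoring context assumes bias-corrected input; no normalisation is
  applied.
- Binary Hi-C stores (.cool/.hic) are not read natively; matrices enter as
  text (dense grid or sparse triples).
- The hierarchy analysis scores nesting; it does not reconstruct the
  hierarchy tree.
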