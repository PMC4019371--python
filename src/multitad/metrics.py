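"""Comparing domain sets and quantifying their hierarchical organization.

Two domain sets on the same chromosome are compared with the variation of
information between the interval partitions they induce: each set is
completed with its gap (non-domain) intervals so that blocks tile the
chromosome, each block has probability length / L, and

    VI(C, C') = H(C) + H(C') - 2 I(C, C'),

with the joint probability of a block pair given by the length of their
intersection over L. VI is a pseudometric: zero for identical partitions,
symmetric, and satisfying the triangle inequality.

The hierarchy score h of a pool of domains is the fraction of qualifying
domain pairs in which one domain properly contains the other. A pair
qualifies when the two domains share at least one bin and differ in more
than a fraction ``alpha`` of their union (symmetric difference over union),
so that near-identical duplicates arising from pooling similar solutions
carry no vote, and disjoint pairs — which say nothing about nesting — are
not counted. A pool of strictly nested domains scores 1; a pool in which no
domain contains another scores 0. Significance is assessed against a null
that randomly reorders each solution's domain and gap lengths along the
chromosome, preserving both length distributions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .domains import Domain, DomainSet, as_domain
from .exceptions import UndefinedScoreError


# ---------------------------------------------------------------------------
# interval partitions, entropy, mutual information, VI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntervalPartition:
    """Blocks (domain or gap intervals) tiling bins [0, L) exactly."""

    L: int
    blocks: tuple[tuple[int, int, bool], ...]  # (a, b, is_domain), b inclusive

    def __post_init__(self):
        pos = 0
        for a, b, _ in self.blocks:
            if a != pos or b < a:
                raise ValueError("blocks must tile [0, L) without holes or overlap")
            pos = b + 1
        if pos != self.L:
            raise ValueError(f"blocks cover [0, {pos}) but L = {self.L}")

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([(b - a + 1) / self.L for a, b, _ in self.blocks])


def to_partition(ds: DomainSet, L: int) -> IntervalPartition:
    """Complete a domain set with its gap intervals into a tiling of [0, L)."""
    blocks = []
    pos = 0
    for d in ds:
        if d.b >= L:
            raise ValueError(f"domain {d} exceeds chromosome length {L}")
        if d.a > pos:
            blocks.append((pos, d.a - 1, False))
        blocks.append((d.a, d.b, True))
        pos = d.b + 1
    if pos < L:
        blocks.append((pos, L - 1, False))
    return IntervalPartition(L=L, blocks=tuple(blocks))


def entropy(partition: IntervalPartition) -> float:
    """Shannon entropy of block probabilities (natural log)."""
    p = partition.probabilities
    return float(-np.sum(p * np.log(p)))


def mutual_information(P: IntervalPartition, Q: IntervalPartition) -> float:
    """Mutual information between two tilings of the same chromosome.

    Joint probabilities are intersection lengths over L; only block pairs
    with nonzero overlap contribute. Computed by a linear merge of the two
    sorted tilings.
    """
    if P.L != Q.L:
        raise ValueError(f"partition lengths differ: {P.L} != {Q.L}")
    L = float(P.L)
    mi = 0.0
    i = j = 0
    while i < len(P.blocks) and j < len(Q.blocks):
        a1, b1, _ = P.blocks[i]
        a2, b2, _ = Q.blocks[j]
        ov = min(b1, b2) - max(a1, a2) + 1
        if ov > 0:
            pij = ov / L
            pi = (b1 - a1 + 1) / L
            qj = (b2 - a2 + 1) / L
            mi += pij * np.log(pij / (pi * qj))
        if b1 <= b2:
            i += 1
        if b2 <= b1:
            j += 1
    return float(mi)


def variation_of_information(D1: DomainSet, D2: DomainSet, L: int) -> float:
    """VI distance between the partitions induced by two domain sets."""
    P, Q = to_partition(D1, L), to_partition(D2, L)
    vi = entropy(P) + entropy(Q) - 2.0 * mutual_information(P, Q)
    return max(float(vi), 0.0)  # clip tiny negative rounding residue


# ---------------------------------------------------------------------------
# hierarchy score
# ---------------------------------------------------------------------------


@dataclass
class HierarchyResult:
    """Hierarchy score of a domain pool, optionally with its shuffle null."""

    h: float
    pair_count: int
    alpha: float
    null_scores: np.ndarray | None = None
    p_value: float | None = None
    p_adjusted: float | None = None


def _pool_arrays(pool) -> tuple[np.ndarray, np.ndarray]:
    doms = {as_domain(d) for d in pool}
    if len(doms) < 2:
        raise UndefinedScoreError(
            f"hierarchy score needs >= 2 distinct domains, got {len(doms)}"
        )
    arr = np.array(sorted(doms), dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def hierarchy_score(
    pool,
    alpha: float = 0.1,
    max_pairs: int | None = None,
    seed: int | None = None,
) -> HierarchyResult:
    """Fraction of qualifying domain pairs with one properly inside the other.

    ``pool`` is any iterable of domains (duplicates collapse: the pool is a
    set union). A pair qualifies when the domains overlap by at least one
    bin and their symmetric-difference fraction exceeds ``alpha``. When the
    pool has no qualifying pairs and no domain contains another, the score
    is 0 by convention (nothing is nested); if the only containments are
    between alpha-similar near-duplicates the score is undefined.

    ``max_pairs`` caps the number of (unordered) pairs examined by uniform
    subsampling with ``seed``.
    """
    if not 0 <= alpha < 1:
        raise ValueError(f"alpha must be in [0, 1), got {alpha}")
    a, b = _pool_arrays(pool)
    m = len(a)
    n_pairs = m * (m - 1) // 2
    if max_pairs is not None and n_pairs > max_pairs:
        rng = np.random.default_rng(seed)
        flat = rng.choice(n_pairs, size=max_pairs, replace=False)
        # map flat pair index to (i, j), i < j, rows of the upper triangle
        i = (
            m - 2 - np.floor(
                np.sqrt(-8.0 * flat + 4 * m * (m - 1) - 7) / 2.0 - 0.5
            )
        ).astype(np.int64)
        j = (flat + i + 1 - i * (2 * m - i - 1) // 2).astype(np.int64)
    else:
        i, j = np.triu_indices(m, 1)
    inter = np.minimum(b[i], b[j]) - np.maximum(a[i], a[j]) + 1
    np.maximum(inter, 0, out=inter)
    li = b[i] - a[i] + 1
    lj = b[j] - a[j] + 1
    union = li + lj - inter
    different = (union - inter) > alpha * union
    qualifying = (inter > 0) & different
    nested = ((a[i] <= a[j]) & (b[j] <= b[i])) | ((a[j] <= a[i]) & (b[i] <= b[j]))
    n_qual = int(qualifying.sum())
    if n_qual == 0:
        if nested.any():
            raise UndefinedScoreError(
                "no qualifying pairs, but alpha-similar nested pairs exist"
            )
        return HierarchyResult(h=0.0, pair_count=0, alpha=alpha)
    h = float(nested[qualifying].mean())
    return HierarchyResult(h=h, pair_count=n_qual, alpha=alpha)


# ---------------------------------------------------------------------------
# length-preserving shuffle and significance
# ---------------------------------------------------------------------------


def shuffle_domain_set(ds: DomainSet, L: int, seed=None) -> DomainSet:
    """Randomly reorder a domain set's block lengths along the chromosome.

    Domain lengths are permuted among domain slots and gap lengths among
    gap slots, keeping the alternation pattern, so both length multisets
    and total coverage are preserved exactly. ``seed`` may be an int or a
    numpy Generator.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    dom_lens = [d.n_bins for d in ds]
    if not dom_lens:
        return DomainSet((), gamma=ds.gamma, score=ds.score)
    gap_lens = []
    pos = 0
    for d in ds:
        gap_lens.append(d.a - pos)
        pos = d.b + 1
    gap_lens.append(L - pos)  # trailing gap (possibly 0)
    dom_lens = list(rng.permutation(dom_lens))
    gap_lens = list(rng.permutation(gap_lens))
    doms = []
    pos = 0
    for g, dl in zip(gap_lens, dom_lens):
        pos += int(g)
        doms.append(Domain(pos, pos + int(dl) - 1))
        pos += int(dl)
    return DomainSet(tuple(doms), gamma=ds.gamma)


def _pooled_h(solutions, alpha: float) -> float:
    pool = [d for sol in solutions for d in sol]
    return hierarchy_score(pool, alpha=alpha).h


def hierarchy_significance(
    pools_by_chrom: dict,
    L,
    alpha: float = 0.1,
    replicates: int = 1000,
    seed: int | None = None,
) -> dict[str, HierarchyResult]:
    """Per-chromosome hierarchy score with a shuffle null and BH correction.

    ``pools_by_chrom`` maps chromosome label to a sequence of
    :class:`DomainSet` solutions (e.g. top-K solutions across resolutions);
    the observed score pools their domains. Each null replicate shuffles
    every solution independently (preserving its domain and gap length
    distributions) and re-pools. ``L`` is an int or a mapping chrom -> int.

    Empirical p-values use the add-one permutation correction
    ``p = (1 + #{null h >= observed h}) / (1 + replicates)`` and are
    Benjamini-Hochberg adjusted across chromosomes.
    """
    if replicates < 1:
        raise ValueError(f"replicates must be >= 1, got {replicates}")
    rng = np.random.default_rng(seed)
    results: dict[str, HierarchyResult] = {}
    for chrom, solutions in pools_by_chrom.items():
        if not solutions:
            raise ValueError(f"{chrom}: empty solution pool")
        Lc = L[chrom] if isinstance(L, dict) else int(L)
        pool = [d for sol in solutions for d in sol]
        obs = hierarchy_score(pool, alpha=alpha)
        null = np.empty(replicates)
        for r in range(replicates):
            shuffled = [shuffle_domain_set(sol, Lc, rng) for sol in solutions]
            null[r] = _pooled_h(shuffled, alpha)
        p = (1.0 + np.sum(null >= obs.h)) / (1.0 + replicates)
        results[chrom] = HierarchyResult(
            h=obs.h,
            pair_count=obs.pair_count,
            alpha=alpha,
            null_scores=null,
            p_value=float(p),
        )
    chroms = list(results)
    _, p_adj, _, _ = multipletests(
        [results[c].p_value for c in chroms], method="fdr_bh"
    )
    for c, pa in zip(chroms, p_adj):
        results[c].p_adjusted = float(pa)
    return results
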