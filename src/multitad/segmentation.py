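"""Single-resolution segmentation and ranked enumeration of alternatives.

A segmentation tiles the chromosome with positive-quality domains and the
gaps (non-domains) between them. Because gaps contribute nothing to the
objective, two gaps are never allowed to be adjacent — otherwise the same
set of domains would correspond to many equal-scoring tilings. With maximal
gaps, valid segmentations are in bijection with sets of pairwise
non-overlapping positive-quality domains, scored by their total quality.

The optimum is found by dynamic programming over bin boundaries; the K
highest-scoring distinct segmentations are enumerated best-first over the
DP's directed acyclic graph, using exact optimal-completion values as the
search bound so solutions emerge in non-increasing score order.
"""

from __future__ import annotations

import heapq
import itertools

import numpy as np
from sklearn.base import BaseEstimator

from .domains import Domain, DomainSet, RankedSolutions
from .matrix_io import ContactMatrix
from .scoring import ScoringContext, build_scoring_context

#: absolute tolerance for treating two segmentation scores as tied
SCORE_TIE_TOL = 1e-9


def _positive_quality(q: np.ndarray) -> np.ndarray:
    """Replace non-positive and forbidden qualities with -inf."""
    q = q.copy()
    q[~(q > 0)] = -np.inf
    return q


def _backward_values(ctx: ScoringContext, gamma: float):
    """Optimal completion values for every DP state.

    ``BU[i]``: best achievable score for bins ``[i, n)`` when the block
    before boundary ``i`` was a domain (or the chromosome start), so either
    a gap or a domain may come next. ``BV[i]``: the same when a gap came
    before, so a domain must come next (or ``i == n``).
    """
    n = ctx.n
    BU = np.full(n + 1, -np.inf)
    BV = np.full(n + 1, -np.inf)
    SV = np.full(n + 2, -np.inf)  # suffix max of BV
    BU[n] = BV[n] = 0.0
    SV[n] = 0.0
    for i in range(n - 1, -1, -1):
        if i <= n - 2:
            q = _positive_quality(ctx.quality_starting_at(i, gamma))  # l=i+1..n-1
            dom_best = np.max(q + BU[i + 2 :])
        else:
            dom_best = -np.inf
        BV[i] = dom_best
        BU[i] = max(dom_best, SV[i + 1])
        SV[i] = max(SV[i + 1], BV[i])
    return BU, BV


def _enumerate(ctx: ScoringContext, gamma: float, k: int):
    """Yield up to ``k`` distinct segmentations in non-increasing score order."""
    n = ctx.n
    BU, BV = _backward_values(ctx, gamma)
    qrows = {}  # cached positive-quality rows per start position

    def qrow(i):
        if i not in qrows:
            qrows[i] = _positive_quality(ctx.quality_starting_at(i, gamma))
        return qrows[i]

    counter = itertools.count()
    # heap entries: (-bound, n_domains, intervals, tiebreak counter, state, pos, score)
    heap = [(-BU[0], 0, (), next(counter), "u", 0, 0.0)]
    emitted = set()
    results = []
    while heap and len(results) < k:
        neg_bound, ndom, intervals, _, state, pos, acc = heapq.heappop(heap)
        if not np.isfinite(neg_bound):
            break
        if pos == n:
            if intervals not in emitted:
                emitted.add(intervals)
                results.append((acc, intervals))
            continue
        if state == "u":
            # gap [pos, j-1] for every j > pos; after a gap a domain must follow
            for j in range(pos + 1, n + 1):
                bound = acc + BV[j]
                if np.isfinite(bound):
                    heapq.heappush(
                        heap, (-bound, ndom, intervals, next(counter), "v", j, acc)
                    )
        # domain [pos, j-1] for j >= pos + 2, from either state
        if pos <= n - 2:
            q = qrow(pos)  # q[t] is quality of domain [pos, pos+1+t]
            for t in range(len(q)):
                if not np.isfinite(q[t]):
                    continue
                j = pos + 2 + t
                bound = acc + q[t] + BU[j]
                if np.isfinite(bound):
                    heapq.heappush(
                        heap,
                        (
                            -bound,
                            ndom + 1,
                            intervals + ((pos, j - 1),),
                            next(counter),
                            "u",
                            j,
                            acc + q[t],
                        ),
                    )
    return results


def _tie_sort(results):
    """Within runs of (near-)tied scores, prefer fewer domains, then the
    lexicographically smallest interval list."""
    out = []
    i = 0
    while i < len(results):
        j = i
        while j + 1 < len(results) and abs(
            results[j + 1][0] - results[i][0]
        ) <= SCORE_TIE_TOL:
            j += 1
        group = sorted(results[i : j + 1], key=lambda r: (len(r[1]), r[1]))
        out.extend(group)
        i = j + 1
    return out


def solve_topk(ctx: ScoringContext, gamma: float, k: int) -> RankedSolutions:
    """The K highest-scoring distinct segmentations at resolution ``gamma``.

    Fewer than K solutions are returned when fewer distinct valid
    segmentations exist. Ties are broken deterministically: fewer domains
    first, then lexicographically smallest interval list.
    """
    if k < 1:
        raise ValueError(f"K must be >= 1, got {k}")
    if gamma < 0:
        raise ValueError(f"gamma must be >= 0, got {gamma}")
    results = _tie_sort(_enumerate(ctx, gamma, k))
    sols = tuple(
        DomainSet(tuple(Domain(a, b) for a, b in ivs), gamma=gamma, score=sc)
        for sc, ivs in results
    )
    return RankedSolutions(gamma=gamma, solutions=sols)


def solve_optimal(ctx: ScoringContext, gamma: float) -> DomainSet:
    """The optimal segmentation at resolution ``gamma``.

    Equivalent to the first entry of :func:`solve_topk`, so the two share
    one tie-break rule.
    """
    return solve_topk(ctx, gamma, 1).best


def brute_force_segmentation(
    matrix: ContactMatrix | np.ndarray,
    gamma: float,
    min_mean_samples: int = 1,
) -> list[tuple[float, DomainSet]]:
    """Exhaustively enumerate and score every valid segmentation (test oracle).

    Valid segmentations correspond one-to-one to sets of pairwise
    non-overlapping positive-quality domains (gaps taken maximal, so no two
    gaps are adjacent). Limited to n <= 16.
    """
    ctx = build_scoring_context(matrix, min_mean_samples=min_mean_samples)
    n = ctx.n
    if n > 16:
        raise ValueError(f"brute force limited to n <= 16, got n={n}")
    qual = {}
    for a in range(n - 1):
        q = ctx.quality_starting_at(a, gamma)
        for t, val in enumerate(q):
            if val > 0:
                qual[(a, a + 1 + t)] = float(val)

    memo: dict[int, list[tuple[float, tuple]]] = {}

    def suffix(start: int):
        if start in memo:
            return memo[start]
        out = [(0.0, ())]
        for a in range(start, n - 1):
            for b in range(a + 1, n):
                if (a, b) in qual:
                    for sc, tail in suffix(b + 1):
                        out.append((qual[(a, b)] + sc, ((a, b),) + tail))
        memo[start] = out
        return out

    results = sorted(suffix(0), key=lambda r: (-r[0], len(r[1]), r[1]))
    return [
        (sc, DomainSet(tuple(Domain(a, b) for a, b in ivs), gamma=gamma, score=sc))
        for sc, ivs in results
    ]


class DomainSegmenter(BaseEstimator):
    """Call topological domains on a contact matrix at one resolution.

    A scikit-learn style estimator: ``fit`` takes a square symmetric
    contact matrix (a :class:`~multitad.matrix_io.ContactMatrix` or a plain
    2-D array of non-negative frequencies) and segments its bins into
    domains and gaps.

    Parameters
    ----------
    gamma : float, default 0.5
        Resolution parameter; larger values favour smaller domains.
    n_solutions : int, default 1
        Number of top-ranked alternative segmentations to enumerate.
    min_mean_samples : int, default 100
        Minimum number of same-span diagonal windows required to estimate
        the background mean; larger spans are forbidden.

    Attributes
    ----------
    context_ : ScoringContext
        Precomputed interval sums for the fitted matrix.
    solutions_ : RankedSolutions
        The ``n_solutions`` best segmentations, best first.
    domains_ : DomainSet
        The optimal segmentation.
    score_ : float
        Total quality of the optimal segmentation.
    labels_ : ndarray of shape (n_bins,)
        Per-bin domain index, -1 for bins in gaps.
    """

    def __init__(self, gamma: float = 0.5, n_solutions: int = 1,
                 min_mean_samples: int = 100):
        self.gamma = gamma
        self.n_solutions = n_solutions
        self.min_mean_samples = min_mean_samples

    def fit(self, X, y=None):
        self.context_ = build_scoring_context(
            X, min_mean_samples=self.min_mean_samples
        )
        self.solutions_ = solve_topk(self.context_, self.gamma, self.n_solutions)
        self.domains_ = self.solutions_.best
        self.score_ = self.domains_.score
        self.labels_ = self.domains_.labels(self.context_.n)
        self.n_features_in_ = self.context_.n
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
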