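"""Resolution sweeps, domain persistence, and the cross-resolution consensus.

The resolution parameter gamma is swept over a grid {0, step, 2*step, ...};
each grid point contributes its single optimal segmentation. A domain's
persistence is the number of grid points whose optimal segmentation
contains exactly that interval (exact repetition — no fuzzy merging). The
consensus set is the non-overlapping subset of all swept domains that
maximizes total persistence, found by the classic weighted interval
scheduling dynamic program over endpoint-sorted candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.base import BaseEstimator

from .domains import Domain, DomainSet
from .scoring import ScoringContext, build_scoring_context
from .segmentation import solve_optimal


@dataclass(frozen=True)
class ResolutionSweep:
    """Optimal domain set at each resolution of a gamma grid."""

    gammas: tuple[float, ...]
    per_gamma: dict[float, DomainSet]

    def __post_init__(self):
        if len(set(self.gammas)) != len(self.gammas):
            raise ValueError("gamma grid values must be distinct")

    def all_domains(self) -> list[Domain]:
        return [d for g in self.gammas for d in self.per_gamma[g]]


@dataclass(frozen=True)
class PersistenceMap:
    """Distinct domains with their persistence counts across a sweep."""

    entries: dict[Domain, int]
    n_resolutions: int

    @property
    def m(self) -> int:
        return len(self.entries)


def _gamma_grid(gamma_max: float, step: float) -> tuple[float, ...]:
    if gamma_max <= 0 or step <= 0 or step > gamma_max:
        raise ValueError(
            f"need 0 < step <= gamma_max, got step={step}, gamma_max={gamma_max}"
        )
    n_steps = int(round(gamma_max / step))
    grid = [round(i * step, 10) for i in range(n_steps + 1)]
    if abs(grid[-1] - gamma_max) > 1e-9:  # gamma_max not a multiple of step
        grid.append(round(gamma_max, 10))
    return tuple(grid)


def sweep_resolutions(
    ctx: ScoringContext, gamma_max: float, step: float
) -> ResolutionSweep:
    """Optimal segmentation at every gamma in {0, step, ..., gamma_max}."""
    grid = _gamma_grid(gamma_max, step)
    per_gamma = {g: solve_optimal(ctx, g) for g in grid}
    return ResolutionSweep(gammas=grid, per_gamma=per_gamma)


def select_gamma_max(
    ctx: ScoringContext,
    step: float,
    min_median_bins: int = 2,
    cap: float = 2.0,
) -> float:
    """Smallest grid gamma whose optimal set has median domain size (bins)
    above ``min_median_bins``, scanning upward from 0 to ``cap``.

    At 40 kb bins the default threshold of 2 bins corresponds to requiring
    a median domain size above 80 kb, screening out calls dominated by
    trivial two-fragment domains.

    Raises
    ------
    LookupError
        If no gamma at or below the cap satisfies the criterion.
    """
    if step <= 0:
        raise ValueError(f"step must be positive, got {step}")
    g = 0.0
    i = 0
    while g <= cap + 1e-9:
        ds = solve_optimal(ctx, g)
        if len(ds) and ds.median_size() > min_median_bins:
            return g
        i += 1
        g = round(i * step, 10)
    raise LookupError(
        f"no gamma in [0, {cap}] reaches median domain size > {min_median_bins} bins"
    )


def compute_persistence(sweep: ResolutionSweep) -> PersistenceMap:
    """Count, for each distinct interval, the resolutions whose optimal set
    contains exactly that interval."""
    entries: dict[Domain, int] = {}
    for g in sweep.gammas:
        for d in sweep.per_gamma[g]:
            entries[d] = entries.get(d, 0) + 1
    return PersistenceMap(entries=entries, n_resolutions=len(sweep.gammas))


def consensus_domains(pm: PersistenceMap) -> DomainSet:
    """Non-overlapping subset of candidates maximizing total persistence.

    Weighted interval scheduling: candidates sorted by end bin; for each,
    the nearest compatible predecessor is found by binary search; the DP
    chooses inclusion on ties. Domains touching at adjacent bins are
    compatible. Runs in O(m log m).
    """
    if not pm.entries:
        return DomainSet((), score=0.0)
    doms = sorted(pm.entries, key=lambda d: (d.b, d.a))
    w = np.array([pm.entries[d] for d in doms], dtype=float)
    ends = np.array([d.b for d in doms])
    starts = np.array([d.a for d in doms])
    # c[j]: number of candidates (prefix length) compatible with j, i.e.
    # with end bin strictly before start of j
    c = np.searchsorted(ends, starts, side="left")
    m = len(doms)
    opt = np.zeros(m + 1)
    take = np.zeros(m + 1, dtype=bool)
    for j in range(1, m + 1):
        with_j = opt[c[j - 1]] + w[j - 1]
        take[j] = with_j >= opt[j - 1]  # prefer inclusion on ties
        opt[j] = max(opt[j - 1], with_j)
    chosen = []
    j = m
    while j > 0:
        if take[j]:
            chosen.append(doms[j - 1])
            j = c[j - 1]
        else:
            j -= 1
    chosen.sort()
    return DomainSet(tuple(chosen), score=float(opt[m]))


def brute_force_consensus(pm: PersistenceMap) -> DomainSet:
    """Exhaustive maximum-persistence non-overlapping subset (test oracle)."""
    doms = sorted(pm.entries)
    if len(doms) > 20:
        raise ValueError(f"brute force limited to m <= 20, got {len(doms)}")
    best, best_set = 0.0, ()
    for r in range(len(doms) + 1):
        for subset in combinations(doms, r):
            ok = all(
                subset[i + 1].a > subset[i].b for i in range(len(subset) - 1)
            )
            if ok:
                total = float(sum(pm.entries[d] for d in subset))
                if total > best:
                    best, best_set = total, subset
    return DomainSet(tuple(best_set), score=best)


class ConsensusDomainCaller(BaseEstimator):
    """Sweep resolutions and call the consensus set of persistent domains.

    Parameters
    ----------
    gamma_max : float or None, default 0.5
        Upper end of the gamma grid. ``None`` selects it from the data:
        the smallest grid gamma with median domain size above
        ``min_median_bins`` bins.
    step : float, default 0.05
        Gamma grid increment.
    min_mean_samples : int, default 100
        Background-mean sample rule passed to the scoring context.
    min_median_bins : int, default 2
        Median-size threshold used when ``gamma_max`` is selected
        automatically.

    Attributes
    ----------
    context_ : ScoringContext
    gamma_max_ : float
        The gamma grid upper end actually used.
    sweep_ : ResolutionSweep
    persistence_ : PersistenceMap
    consensus_ : DomainSet
        Non-overlapping consensus domains; ``consensus_.score`` is the
        total persistence.
    labels_ : ndarray of shape (n_bins,)
        Per-bin consensus domain index, -1 in gaps.
    """

    def __init__(self, gamma_max: float | None = 0.5, step: float = 0.05,
                 min_mean_samples: int = 100, min_median_bins: int = 2):
        self.gamma_max = gamma_max
        self.step = step
        self.min_mean_samples = min_mean_samples
        self.min_median_bins = min_median_bins

    def fit(self, X, y=None):
        self.context_ = build_scoring_context(
            X, min_mean_samples=self.min_mean_samples
        )
        if self.gamma_max is None:
            self.gamma_max_ = select_gamma_max(
                self.context_, self.step, min_median_bins=self.min_median_bins
            )
        else:
            self.gamma_max_ = self.gamma_max
        if self.gamma_max_ <= 0:
            # degenerate single-resolution grid at gamma = 0
            self.sweep_ = ResolutionSweep(
                (0.0,), {0.0: solve_optimal(self.context_, 0.0)}
            )
        else:
            self.sweep_ = sweep_resolutions(self.context_, self.gamma_max_, self.step)
        self.persistence_ = compute_persistence(self.sweep_)
        self.consensus_ = consensus_domains(self.persistence_)
        self.labels_ = self.consensus_.labels(self.context_.n)
        self.n_features_in_ = self.context_.n
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        return self.fit(X).labels_
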