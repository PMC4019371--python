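"""Scaled-density scoring of candidate domains.

For an interval of bins ``[k, l]`` on a symmetric contact matrix ``A`` the
raw sum is the total contact frequency over the strictly-upper-triangular
pairs within the interval::

    raw(k, l) = sum_{g=k..l} sum_{h=g+1..l} A[g, h]

The scaled density is ``s(k, l, gamma) = raw(k, l) / (l - k)**gamma`` — at
gamma = 1 the weighted subgraph density of the interval, at gamma = 2 half
its internal density. The quality of a domain is the zero-centred density

    q(k, l, gamma) = s(k, l, gamma) - mu_s(l - k),

where ``mu_s(span)`` is the mean of ``s`` over all diagonal windows of the
same span. Intervals with non-positive quality are non-domains. Spans with
fewer than ``min_mean_samples`` windows available for the mean (i.e. spans
above ``n - min_mean_samples``) are forbidden outright, which in practice
only rules out domains hundreds of megabases long.

A 2-D prefix-sum table makes every raw interval sum an O(1) query after
O(n^2) preprocessing; the per-span means are likewise precomputed once.
"""

from __future__ import annotations

import numpy as np

from .exceptions import SpanTooLargeError
from .matrix_io import ContactMatrix


class ScoringContext:
    """Precomputed interval sums and per-span background means for one matrix."""

    def __init__(self, matrix: ContactMatrix | np.ndarray, min_mean_samples: int = 100):
        if isinstance(matrix, ContactMatrix):
            A = matrix.values
            self.matrix = matrix
        else:
            A = np.asarray(matrix, dtype=float)
            self.matrix = None
        n = A.shape[0]
        if A.ndim != 2 or A.shape[1] != n:
            raise ValueError("contact matrix must be square")
        if not 1 <= min_mean_samples <= n - 1:
            raise ValueError(
                f"min_mean_samples must be in [1, n-1]={n - 1}, got {min_mean_samples}"
            )
        self.n = n
        self.min_mean_samples = int(min_mean_samples)
        self.max_span = n - self.min_mean_samples

        # padded 2-D prefix sums and diagonal cumulative sum
        P = np.zeros((n + 1, n + 1))
        P[1:, 1:] = A.cumsum(axis=0).cumsum(axis=1)
        self._P = P
        dc = np.zeros(n + 1)
        dc[1:] = np.cumsum(np.diag(A))
        self._dc = dc

        # mean raw sum per span (gamma-independent); NaN for forbidden spans
        mean_raw = np.full(n, np.nan)
        mean_raw[0] = 0.0
        k = np.arange(n)
        for span in range(1, self.max_span + 1):
            ks = k[: n - span]
            mean_raw[span] = self._raw_vec(ks, ks + span).mean()
        self.mean_raw_sum = mean_raw

    # ---- raw sums -------------------------------------------------------

    def _raw_vec(self, k, l):
        """Vectorized raw sums for parallel arrays of interval ends."""
        P, dc = self._P, self._dc
        block = P[l + 1, l + 1] - P[k, l + 1] - P[l + 1, k] + P[k, k]
        # raw sums are non-negative by construction; clamp cancellation residue
        return np.maximum((block - (dc[l + 1] - dc[k])) / 2.0, 0.0)

    def raw_sum(self, k: int, l: int) -> float:
        """Total contact frequency over pairs strictly within ``[k, l]``."""
        if not 0 <= k <= l <= self.n - 1:
            raise ValueError(f"need 0 <= k <= l <= n-1, got k={k}, l={l}")
        return float(self._raw_vec(np.int64(k), np.int64(l)))

    # ---- scores ---------------------------------------------------------

    def scaled_density(self, k: int, l: int, gamma: float) -> float:
        if k >= l:
            raise ValueError(f"need k < l, got k={k}, l={l}")
        return self.raw_sum(k, l) / float(l - k) ** gamma

    def mean_scaled_density(self, span: int, gamma: float) -> float:
        if not 1 <= span <= self.max_span:
            raise SpanTooLargeError(
                f"span {span} has fewer than {self.min_mean_samples} diagonal "
                f"windows (max allowed span {self.max_span})"
            )
        return self.mean_raw_sum[span] / float(span) ** gamma

    def quality(self, k: int, l: int, gamma: float) -> float:
        if k >= l:
            raise ValueError(f"need k < l, got k={k}, l={l}")
        span = l - k
        return (self.raw_sum(k, l) - self.mean_raw_sum[span]) / float(
            span
        ) ** gamma if span <= self.max_span else self._forbidden(span)

    def _forbidden(self, span):
        raise SpanTooLargeError(
            f"span {span} exceeds max allowed span {self.max_span}"
        )

    # ---- vectorized quality for the segmentation DP ---------------------

    def quality_ending_at(self, l: int, gamma: float) -> np.ndarray:
        """Quality of every domain ``[k, l]`` for k = 0..l-1.

        Forbidden spans get ``-inf`` so callers can treat them uniformly.
        """
        k = np.arange(l)
        span = l - k
        with np.errstate(invalid="ignore"):
            q = (self._raw_vec(k, np.full(l, l)) - self.mean_raw_sum[span]) / (
                span.astype(float) ** gamma
            )
        q[span > self.max_span] = -np.inf
        return q

    def quality_starting_at(self, k: int, gamma: float) -> np.ndarray:
        """Quality of every domain ``[k, l]`` for l = k+1..n-1."""
        l = np.arange(k + 1, self.n)
        span = l - k
        with np.errstate(invalid="ignore"):
            q = (self._raw_vec(np.full(len(l), k), l) - self.mean_raw_sum[span]) / (
                span.astype(float) ** gamma
            )
        q[span > self.max_span] = -np.inf
        return q


def build_scoring_context(
    matrix: ContactMatrix | np.ndarray, min_mean_samples: int = 100
) -> ScoringContext:
    """Precompute interval sums and per-span means for O(1) score queries."""
    return ScoringContext(matrix, min_mean_samples=min_mean_samples)


def scaled_density(ctx: ScoringContext, k: int, l: int, gamma: float) -> float:
    return ctx.scaled_density(k, l, gamma)


def mean_scaled_density(ctx: ScoringContext, span: int, gamma: float) -> float:
    return ctx.mean_scaled_density(span, gamma)


def quality(ctx: ScoringContext, k: int, l: int, gamma: float) -> float:
    return ctx.quality(k, l, gamma)
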