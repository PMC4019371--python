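"""Core interval containers: domains, domain sets, ranked solution lists.

Bins are 0-based. A domain ``[a, b]`` is inclusive of both endpoint bins and
must span at least two bins (``a < b``). Domain sets are sorted and pairwise
non-overlapping; two domains that touch at adjacent bins do not overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .exceptions import DomainValidationError


class Domain(NamedTuple):
    """A chromosome interval in bin coordinates, inclusive at both ends."""

    a: int
    b: int

    @property
    def n_bins(self) -> int:
        return self.b - self.a + 1

    def contains(self, other: "Domain") -> bool:
        """Proper containment: ``other`` strictly inside (not equal to) self."""
        return self.a <= other.a and other.b <= self.b and self != other

    def validate(self) -> None:
        if not (0 <= self.a < self.b):
            raise DomainValidationError(
                f"domain [{self.a}, {self.b}] must satisfy 0 <= a < b"
            )


def as_domain(obj) -> Domain:
    d = obj if isinstance(obj, Domain) else Domain(int(obj[0]), int(obj[1]))
    d.validate()
    return d


@dataclass(frozen=True)
class DomainSet:
    """A sorted, pairwise non-overlapping collection of domains.

    Parameters
    ----------
    domains
        Domains sorted by start bin.
    gamma
        Resolution parameter the set was called at, if any.
    score
        Total quality (sum of member domain qualities) or total persistence
        for consensus sets; ``None`` when unknown (e.g. read from BED).
    """

    domains: tuple[Domain, ...]
    gamma: float | None = None
    score: float | None = None

    def __post_init__(self):
        doms = tuple(as_domain(d) for d in self.domains)
        object.__setattr__(self, "domains", doms)
        for prev, cur in zip(doms, doms[1:]):
            if cur.a <= prev.b:
                raise DomainValidationError(
                    f"domains {prev} and {cur} overlap or are unsorted"
                )

    @classmethod
    def from_intervals(
        cls,
        intervals: Iterable,
        gamma: float | None = None,
        score: float | None = None,
    ) -> "DomainSet":
        doms = sorted(as_domain(d) for d in intervals)
        return cls(tuple(doms), gamma=gamma, score=score)

    def __iter__(self) -> Iterator[Domain]:
        return iter(self.domains)

    def __len__(self) -> int:
        return len(self.domains)

    def __getitem__(self, i) -> Domain:
        return self.domains[i]

    @property
    def sizes(self) -> np.ndarray:
        """Domain sizes in bins."""
        return np.array([d.n_bins for d in self.domains], dtype=int)

    def median_size(self) -> float:
        if not self.domains:
            return float("nan")
        return float(np.median(self.sizes))

    def mean_size(self) -> float:
        if not self.domains:
            return float("nan")
        return float(np.mean(self.sizes))

    def labels(self, n_bins: int) -> np.ndarray:
        """Per-bin labels: domain index for covered bins, -1 for gaps."""
        lab = np.full(n_bins, -1, dtype=int)
        for i, d in enumerate(self.domains):
            if d.b >= n_bins:
                raise DomainValidationError(
                    f"domain {d} exceeds chromosome length {n_bins}"
                )
            lab[d.a : d.b + 1] = i
        return lab


@dataclass(frozen=True)
class RankedSolutions:
    """Distinct segmentations in non-increasing score order."""

    gamma: float
    solutions: tuple[DomainSet, ...] = field(default_factory=tuple)

    def __post_init__(self):
        scores = [s.score for s in self.solutions]
        for hi, lo in zip(scores, scores[1:]):
            if lo > hi + 1e-9:
                raise DomainValidationError("solution scores must be non-increasing")
        seen = set()
        for s in self.solutions:
            key = s.domains
            if key in seen:
                raise DomainValidationError("duplicate segmentation in ranked list")
            seen.add(key)

    def __iter__(self) -> Iterator[DomainSet]:
        return iter(self.solutions)

    def __len__(self) -> int:
        return len(self.solutions)

    def __getitem__(self, i) -> DomainSet:
        return self.solutions[i]

    @property
    def best(self) -> DomainSet:
        return self.solutions[0]
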