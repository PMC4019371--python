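"""Synthetic contact matrices with planted, optionally nested, domains.

The generator draws each contact count from a Poisson distribution whose
mean follows a multiplicative block model on top of genomic distance decay:

    E[A_ij] = background_scale * (1 + |i - j|)**(-decay_exponent)
              * prod(enrichment_factor of every planted domain containing
                     both i and j)

Nested domains therefore compound multiplicatively, giving child blocks a
higher density than their parents — the signature the multiscale caller is
meant to resolve. The upper triangle (including the diagonal) is drawn and
mirrored, so matrices are exactly symmetric and deterministic given a seed.
The default decay exponent of 0.8 is sub-quadratic, qualitatively matching
the shallow power-law decay of real chromatin contact maps. No experimental
artifacts (mappability, compartments, translocations) are emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .domains import Domain, DomainSet, as_domain
from .exceptions import InfeasiblePackingError
from .matrix_io import ContactMatrix


@dataclass(frozen=True)
class PlantedTruth:
    """Ground-truth planted domains (a forest: nesting allowed) and the
    generator parameters that produced the matrix."""

    domains: tuple[Domain, ...]
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        doms = tuple(sorted(as_domain(d) for d in self.domains))
        object.__setattr__(self, "domains", doms)
        # any two domains must be nested or disjoint (a laminar family)
        for i, d in enumerate(doms):
            for e in doms[i + 1 :]:
                if e.a > d.b:
                    break
                # sorted order gives e.a >= d.a; laminar means e inside d,
                # or d inside e (equal starts), never a partial crossing
                if not (e.b <= d.b or e.a == d.a):
                    raise ValueError(f"planted domains {d} and {e} cross")

    def top_level(self) -> tuple[Domain, ...]:
        return tuple(
            d
            for d in self.domains
            if not any(o != d and o.a <= d.a and d.b <= o.b for o in self.domains)
        )

    def leaves(self) -> tuple[Domain, ...]:
        return tuple(
            d
            for d in self.domains
            if not any(o != d and d.a <= o.a and o.b <= d.b for o in self.domains)
        )


def two_level_truth(
    n: int = 200,
    n_parents: int | None = None,
    parent_len: int = 40,
    gap: int = 8,
    child_len: int = 15,
    margin: int = 2,
) -> PlantedTruth:
    """A deterministic two-level layout: evenly spaced parents, each holding
    two children separated inside the parent. When ``n_parents`` is None, as
    many parents as fit in ``n`` bins are planted."""
    domains = []
    start = gap // 2 + 1
    if n_parents is None:
        n_parents = (n - start - parent_len) // (parent_len + gap) + 1
        if n_parents < 1:
            raise ValueError("n too small for even one parent domain")
    for p in range(n_parents):
        a = start + p * (parent_len + gap)
        b = a + parent_len - 1
        if b >= n:
            raise ValueError("layout does not fit: reduce parents or lengths")
        domains.append(Domain(a, b))
        c1 = Domain(a + margin, a + margin + child_len - 1)
        c2 = Domain(b - margin - child_len + 1, b - margin)
        if c2.a <= c1.b:
            raise ValueError("children overlap: shrink child_len or margin")
        domains.extend([c1, c2])
    return PlantedTruth(tuple(domains))


def simulate_hierarchical_matrix(
    truth: PlantedTruth,
    n: int,
    bin_size: int = 40_000,
    background_scale: float = 15.0,
    decay_exponent: float = 0.8,
    enrichment_factor: float = 4.0,
    seed: int | None = None,
    chrom: str = "chrS",
) -> tuple[ContactMatrix, PlantedTruth]:
    """Draw a Poisson contact matrix with the given planted domains.

    ``enrichment_factor`` may be a scalar applied to every planted domain
    or a sequence aligned with ``truth.domains``.
    """
    if n < 8:
        raise ValueError(f"n must be >= 8, got {n}")
    if background_scale <= 0 or decay_exponent < 0:
        raise ValueError("background_scale must be > 0 and decay_exponent >= 0")
    factors = np.broadcast_to(
        np.asarray(enrichment_factor, dtype=float), (len(truth.domains),)
    )
    if np.any(factors <= 0):
        raise ValueError("enrichment factors must be positive")
    if any(d.b >= n for d in truth.domains):
        raise ValueError("planted domain exceeds matrix size")
    idx = np.arange(n)
    dist = np.abs(idx[:, None] - idx[None, :])
    mean = background_scale * (1.0 + dist) ** (-decay_exponent)
    for d, f in zip(truth.domains, factors):
        mean[d.a : d.b + 1, d.a : d.b + 1] *= f
    rng = np.random.default_rng(seed)
    upper = rng.poisson(np.triu(mean)).astype(float)
    A = np.triu(upper, 1) + np.triu(upper, 1).T + np.diag(np.diag(upper))
    params = dict(
        n=n,
        bin_size=bin_size,
        background_scale=background_scale,
        decay_exponent=decay_exponent,
        enrichment_factor=list(map(float, factors)),
        noise_model="poisson",
        seed=seed,
    )
    matrix = ContactMatrix(chrom=chrom, bin_size=bin_size, values=A)
    return matrix, PlantedTruth(truth.domains, params=params)


def random_domain_set(
    L: int,
    num_domains: int,
    min_len: int,
    max_len: int,
    seed=None,
) -> DomainSet:
    """Uniformly placed non-overlapping domains with i.i.d. uniform lengths.

    Lengths are drawn uniformly from ``[min_len, max_len]`` (bins,
    ``min_len >= 2``); placement distributes the free space uniformly over
    the gap slots, so every non-overlapping arrangement of the drawn
    lengths is equally likely. Deterministic given ``seed`` (an int or a
    numpy Generator).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if num_domains == 0:
        return DomainSet(())
    if min_len < 2 or max_len < min_len:
        raise ValueError("need 2 <= min_len <= max_len")
    if num_domains * min_len > L:
        raise InfeasiblePackingError(
            f"{num_domains} domains of length >= {min_len} cannot fit in L={L}"
        )
    lens = rng.integers(min_len, max_len + 1, size=num_domains)
    if lens.sum() > L:
        raise InfeasiblePackingError(
            f"sampled lengths sum to {lens.sum()} > L={L}"
        )
    rng.shuffle(lens)
    free = int(L - lens.sum())
    marks = np.sort(rng.choice(free + num_domains, size=num_domains, replace=False))
    lead = marks - np.arange(num_domains)  # cumulative gap before each domain
    starts = lead + np.concatenate(([0], np.cumsum(lens)[:-1]))
    doms = tuple(Domain(int(s), int(s + ln - 1)) for s, ln in zip(starts, lens))
    return DomainSet(doms)
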