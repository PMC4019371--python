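"""Reading and writing contact matrices, domain calls and peak intervals.

Two plain-text matrix dialects are supported: a dense whitespace-delimited
grid (optionally with a header row and/or a leading label column) and a
sparse 3-column ``i j count`` list of bin pairs. Domain calls and peaks use
BED (0-based, half-open base-pair coordinates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, floor
from pathlib import Path

import numpy as np

from .domains import Domain, DomainSet
from .exceptions import BedFormatError, DomainValidationError, MatrixFormatError

SYMMETRY_RTOL = 1e-6


@dataclass
class ContactMatrix:
    """A symmetric, non-negative n x n matrix of binned contact frequencies."""

    chrom: str
    bin_size: int
    values: np.ndarray

    def __post_init__(self):
        A = np.asarray(self.values, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise MatrixFormatError(f"matrix must be square, got shape {A.shape}")
        if A.shape[0] < 2:
            raise MatrixFormatError("matrix must have at least 2 bins")
        if not np.all(np.isfinite(A)):
            raise ValueError("matrix entries must be finite")
        if np.any(A < 0):
            raise ValueError("matrix entries must be non-negative")
        if not np.allclose(A, A.T, rtol=SYMMETRY_RTOL, atol=1e-8):
            raise ValueError("matrix must be symmetric (relative tolerance 1e-6)")
        self.values = A

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class PeakSet:
    """Sorted half-open base-pair intervals on one chromosome."""

    chrom: str
    intervals: np.ndarray  # shape (m, 2), columns (start_bp, end_bp)

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=np.int64).reshape(-1, 2)
        if iv.size:
            if np.any(iv[:, 0] < 0):
                raise ValueError("peak coordinates must be non-negative")
            if np.any(iv[:, 1] <= iv[:, 0]):
                raise ValueError("peak end must exceed start")
            iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
        self.intervals = iv

    def __len__(self) -> int:
        return len(self.intervals)


def _tokenize(path) -> list[list[str]]:
    rows = []
    with open(path) as fh:
        for line in fh:
            toks = line.split()
            if toks:
                rows.append(toks)
    return rows


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def read_dense_matrix(path, chrom: str, bin_size: int) -> ContactMatrix:
    """Read a whitespace-delimited dense matrix.

    A leading header row and/or a leading column of row labels are detected
    by a non-numeric first token and stripped. Input that is asymmetric
    beyond tolerance is symmetrized as ``(A + A.T) / 2`` with a warning.
    """
    rows = _tokenize(path)
    if not rows:
        raise MatrixFormatError(f"{path}: empty matrix file")
    if not _is_number(rows[0][0]) and all(not _is_number(t) for t in rows[0]):
        rows = rows[1:]  # header row of bin labels
        if not rows:
            raise MatrixFormatError(f"{path}: no data rows after header")
    if rows and not _is_number(rows[0][0]):
        rows = [r[1:] for r in rows]  # leading label column
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise MatrixFormatError(f"{path}: ragged rows (widths {sorted(widths)})")
    try:
        A = np.array([[float(t) for t in r] for r in rows])
    except ValueError as e:
        raise MatrixFormatError(f"{path}: non-numeric matrix entry ({e})") from None
    if A.shape[0] != A.shape[1]:
        raise MatrixFormatError(
            f"{path}: matrix is {A.shape[0]}x{A.shape[1]}, expected square"
        )
    if not np.all(np.isfinite(A)):
        raise ValueError(f"{path}: matrix entries must be finite")
    if np.any(A < 0):
        raise ValueError(f"{path}: matrix entries must be non-negative")
    if not np.allclose(A, A.T, rtol=SYMMETRY_RTOL, atol=1e-8):
        warnings.warn(
            f"{path}: matrix asymmetric beyond tolerance; symmetrizing as (A+A.T)/2",
            stacklevel=2,
        )
        A = (A + A.T) / 2.0
    return ContactMatrix(chrom=chrom, bin_size=bin_size, values=A)


def read_sparse_matrix(
    path, chrom: str, bin_size: int, n: int | None = None
) -> ContactMatrix:
    """Read a sparse ``i j count`` triple list into a dense symmetric matrix.

    Bin indices are 0-based. Entry (i, j) and its mirror (j, i) are both
    set; duplicate rows (including mirrored duplicates) are summed. When
    ``n`` is absent it is inferred as ``1 + max index``.
    """
    triples = []
    rows = _tokenize(path)
    for lineno, toks in enumerate(rows, start=1):
        if len(toks) != 3:
            raise MatrixFormatError(f"{path}:{lineno}: expected 'i j count'")
        try:
            i, j, c = int(toks[0]), int(toks[1]), float(toks[2])
        except ValueError:
            raise MatrixFormatError(
                f"{path}:{lineno}: non-numeric sparse entry"
            ) from None
        if i < 0 or j < 0:
            raise IndexError(f"{path}:{lineno}: negative bin index")
        if c < 0:
            raise ValueError(f"{path}:{lineno}: negative count")
        triples.append((i, j, c))
    if n is None:
        if not triples:
            raise MatrixFormatError(f"{path}: empty sparse file and n not given")
        n = 1 + max(max(i, j) for i, j, _ in triples)
    A = np.zeros((n, n))
    for i, j, c in triples:
        if i >= n or j >= n:
            raise IndexError(f"bin index ({i},{j}) out of range for n={n}")
        A[i, j] += c
        if i != j:
            A[j, i] += c
    return ContactMatrix(chrom=chrom, bin_size=bin_size, values=A)


def write_dense_matrix(matrix: ContactMatrix, path) -> None:
    np.savetxt(path, matrix.values, fmt="%.6g")


def write_domains_bed(domains: DomainSet, chrom: str, bin_size: int, path) -> None:
    """Write domains as BED3: ``chrom  a*bin_size  (b+1)*bin_size``."""
    with open(path, "w") as fh:
        for d in domains:
            fh.write(f"{chrom}\t{d.a * bin_size}\t{(d.b + 1) * bin_size}\n")


def _read_bed3(path) -> list[tuple[str, int, int]]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            toks = line.split()
            if len(toks) < 3:
                raise BedFormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                start, end = int(toks[1]), int(toks[2])
            except ValueError:
                raise BedFormatError(
                    f"{path}:{lineno}: non-integer BED coordinates"
                ) from None
            if end <= start:
                raise BedFormatError(f"{path}:{lineno}: end <= start")
            if start < 0:
                raise BedFormatError(f"{path}:{lineno}: negative coordinate")
            records.append((toks[0], start, end))
    return records


def read_domains_bed(path, bin_size: int) -> DomainSet:
    """Read a BED3+ file of domain calls on the bin grid.

    Coordinates are snapped to bins: floor for starts, ceil - 1 for ends.
    Overlapping records and single-bin records are rejected.
    """
    records = _read_bed3(path)
    doms = []
    for chrom, start, end in records:
        a = floor(start / bin_size)
        b = ceil(end / bin_size) - 1
        if a >= b:
            raise DomainValidationError(
                f"{path}: record {chrom}:{start}-{end} spans fewer than 2 bins"
            )
        doms.append(Domain(a, b))
    doms.sort()
    for prev, cur in zip(doms, doms[1:]):
        if cur.a <= prev.b:
            raise DomainValidationError(f"{path}: overlapping records {prev}, {cur}")
    return DomainSet(tuple(doms))


def read_peaks_bed(path, chrom: str | None = None) -> PeakSet:
    """Read a BED3+ peak file; strand and extra columns are ignored.

    If ``chrom`` is given, only records on that chromosome are kept;
    otherwise all records must share a single chromosome.
    """
    records = _read_bed3(path)
    if chrom is not None:
        records = [r for r in records if r[0] == chrom]
        label = chrom
    else:
        chroms = {r[0] for r in records}
        if len(chroms) > 1:
            raise BedFormatError(
                f"{path}: multiple chromosomes {sorted(chroms)}; pass chrom="
            )
        label = chroms.pop() if chroms else ""
    iv = np.array([(s, e) for _, s, e in records], dtype=np.int64).reshape(-1, 2)
    return PeakSet(chrom=label, intervals=iv)
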