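"""Boundary extraction and peak-occupancy enrichment around domains.

Boundaries are the inter-domain regions between consecutive called domains,
in base-pair coordinates; when two domains touch at adjacent bins the
boundary is a symmetric window of ``flank_bins`` bins around the shared
edge. Occupancy is counted as the fraction of regions containing at least
one peak (>= 1 bp overlap, half-open intervals). Positional profiles count
peak midpoints in fixed-width offset bins around boundary midpoints, with
the analogous profile anchored at domain midpoints as a baseline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .domains import DomainSet
from .exceptions import UndefinedScoreError
from .matrix_io import PeakSet


def extract_boundaries(
    ds: DomainSet, bin_size: int, flank_bins: int = 1
) -> list[tuple[int, int]]:
    """Half-open bp intervals between consecutive domains.

    Chromosome ends are not boundaries; a single domain yields none.
    """
    out = []
    for prev, cur in zip(ds.domains, ds.domains[1:]):
        if cur.a > prev.b + 1:
            out.append(((prev.b + 1) * bin_size, cur.a * bin_size))
        else:  # touching domains: window of +-flank_bins around the edge
            out.append(
                (
                    (prev.b + 1 - flank_bins) * bin_size,
                    (prev.b + 1 + flank_bins) * bin_size,
                )
            )
    return out


def domains_bp(ds: DomainSet, bin_size: int) -> list[tuple[int, int]]:
    """Domains as half-open bp intervals."""
    return [(d.a * bin_size, (d.b + 1) * bin_size) for d in ds]


def fraction_containing_peaks(
    intervals: list[tuple[int, int]], peaks: PeakSet
) -> tuple[int, int, float]:
    """(count, total, fraction) of intervals overlapping >= 1 peak by >= 1 bp."""
    total = len(intervals)
    if total == 0:
        raise UndefinedScoreError("no intervals: fraction undefined")
    if len(peaks) == 0:
        return 0, total, 0.0
    starts = peaks.intervals[:, 0]
    ends_sorted = np.sort(peaks.intervals[:, 1])
    count = 0
    for s, e in intervals:
        # overlap exists iff some peak has start < e and end > s
        n_start_before = np.searchsorted(starts, e, side="left")
        n_end_at_or_before = np.searchsorted(ends_sorted, s, side="right")
        if n_start_before > n_end_at_or_before:
            count += 1
    return count, total, count / total


def enrichment_table(
    ds: DomainSet,
    signals,
    bin_size: int,
    flank_bins: int = 1,
) -> pd.DataFrame:
    """Peak occupancy of domains and boundaries, one row per signal.

    ``signals`` is a mapping name -> PeakSet or an iterable of
    (name, PeakSet) pairs; duplicate names are rejected.
    """
    if isinstance(signals, dict):
        items = list(signals.items())
    else:
        items = list(signals)
        names = [nm for nm, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate signal names")
    dom_iv = domains_bp(ds, bin_size)
    bnd_iv = extract_boundaries(ds, bin_size, flank_bins=flank_bins)
    rows = []
    for name, peaks in items:
        dw, dt, df_ = fraction_containing_peaks(dom_iv, peaks) if dom_iv else (0, 0, np.nan)
        bw, bt, bf = (
            fraction_containing_peaks(bnd_iv, peaks) if bnd_iv else (0, 0, np.nan)
        )
        rows.append(
            {
                "signal": name,
                "domains_with_peak": dw,
                "domains_total": dt,
                "domain_fraction": df_,
                "boundaries_with_peak": bw,
                "boundaries_total": bt,
                "boundary_fraction": bf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "signal",
            "domains_with_peak",
            "domains_total",
            "domain_fraction",
            "boundaries_with_peak",
            "boundaries_total",
            "boundary_fraction",
        ],
    )


def boundary_profile(
    ds: DomainSet,
    peaks: PeakSet,
    bin_size: int,
    window_bp: int = 500_000,
    bin_bp: int = 40_000,
    flank_bins: int = 1,
) -> pd.DataFrame:
    """Mean peak-midpoint counts per offset bin around boundary midpoints.

    Columns: ``offset_bp`` (bin centre offsets from -window to +window),
    ``boundaries`` (mean count anchored at boundary midpoints) and
    ``domains`` (the analogous baseline anchored at domain midpoints).
    Profile length is ``2 * window_bp / bin_bp + 1``.
    """
    if window_bp % bin_bp != 0:
        raise ValueError("window_bp must be a multiple of bin_bp")
    boundaries = extract_boundaries(ds, bin_size, flank_bins=flank_bins)
    if not boundaries:
        raise UndefinedScoreError("no boundaries: profile undefined")
    w = window_bp // bin_bp
    offsets = np.arange(-w, w + 1) * bin_bp
    peak_mids = (
        (peaks.intervals[:, 0] + peaks.intervals[:, 1]) / 2.0
        if len(peaks)
        else np.array([])
    )

    def profile(anchors):
        counts = np.zeros(2 * w + 1)
        for mid in anchors:
            if peak_mids.size == 0:
                continue
            rel = peak_mids - mid
            idx = np.floor(rel / bin_bp + 0.5).astype(int) + w
            ok = (idx >= 0) & (idx <= 2 * w)
            np.add.at(counts, idx[ok], 1)
        return counts / len(anchors)

    bnd_mids = [(s + e) / 2.0 for s, e in boundaries]
    dom_mids = [(s + e) / 2.0 for s, e in domains_bp(ds, bin_size)]
    return pd.DataFrame(
        {
            "offset_bp": offsets,
            "boundaries": profile(bnd_mids),
            "domains": profile(dom_mids) if dom_mids else np.zeros(2 * w + 1),
        }
    )
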