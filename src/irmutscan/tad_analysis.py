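"""Variant accumulation inside vs outside topologically associating domains.

Each TAD, and each *gap* (maximal region not covered by any TAD, including
chromosome ends), is divided into ten equally long portions and variants
are counted per portion.  A variant at VCF position ``p`` inside interval
``[start, end)`` falls into bin ``floor((p - 1 - start) * n_bins / (end -
start))``, so bin widths differ by at most one base pair when the length is
not divisible by the bin count.  TADs and gaps together partition the
chromosome, so the binned counts conserve the chromosome total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .core import GenomicInterval, Variant, normalize_chrom

logger = logging.getLogger("irmutscan")

__all__ = [
    "merge_intervals",
    "complement_gaps",
    "bin_counts",
    "BinnedDomainProfile",
    "bin_domains",
    "inside_outside_ratio",
    "boundary_enrichment",
    "N_BINS",
]

N_BINS = 10


@dataclass
class BinnedDomainProfile:
    """Bin-resolved variant counts for one TAD or gap."""

    domain: GenomicInterval
    location: str  # "inside" (TAD) | "outside" (gap)
    bin_counts: list[int]

    @property
    def total(self) -> int:
        return sum(self.bin_counts)


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals on one chromosome (sorted output)."""
    if not intervals:
        return []
    ivs = sorted(intervals, key=lambda iv: iv.start)
    merged = [ivs[0]]
    overlapped = False
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.start < last.end:
                overlapped = True
            merged[-1] = GenomicInterval(
                last.chrom, last.start, max(last.end, iv.end), last.name
            )
        else:
            merged.append(iv)
    if overlapped:
        logger.warning("merge_intervals: overlapping TADs merged")
    return merged


def complement_gaps(
    tads: Sequence[GenomicInterval], chromosome_length: int, chrom: str = ""
) -> list[GenomicInterval]:
    """Maximal intervals of one chromosome not covered by any TAD.

    TADs extending past the chromosome end are clipped with a warning;
    overlapping TADs are merged first.  The returned gaps together with the
    merged TADs partition ``[0, chromosome_length)``.
    """
    clipped = []
    for iv in tads:
        if iv.end > chromosome_length:
            logger.warning(
                "TAD %s:[%d,%d) exceeds chromosome length %d, clipped",
                iv.chrom,
                iv.start,
                iv.end,
                chromosome_length,
            )
            if iv.start >= chromosome_length:
                continue
            iv = GenomicInterval(iv.chrom, iv.start, chromosome_length, iv.name)
        clipped.append(iv)
    merged = merge_intervals(clipped)
    if not chrom and merged:
        chrom = merged[0].chrom
    gaps = []
    cursor = 0
    for iv in merged:
        if iv.start > cursor:
            gaps.append(GenomicInterval(chrom, cursor, iv.start, "gap"))
        cursor = iv.end
    if cursor < chromosome_length:
        gaps.append(GenomicInterval(chrom, cursor, chromosome_length, "gap"))
    return gaps


def bin_counts(
    variants: Sequence[Variant], interval: GenomicInterval, n_bins: int = N_BINS
) -> list[int]:
    """Count variants of ``interval``'s chromosome per equal-length bin.

    Intervals shorter than ``n_bins`` cannot support distinct bins; they
    fall back to a single bin (returned padded with zeros) with a warning.
    """
    length = len(interval)
    if length < n_bins:
        logger.warning(
            "interval %s:[%d,%d) shorter than %d bins, single-bin fallback",
            interval.chrom,
            interval.start,
            interval.end,
            n_bins,
        )
        total = sum(
            1 for v in variants if interval.contains_vcf_pos(v.chrom, v.pos)
        )
        return [total] + [0] * (n_bins - 1)
    counts = [0] * n_bins
    for v in variants:
        if not interval.contains_vcf_pos(v.chrom, v.pos):
            continue
        b = (v.pos - 1 - interval.start) * n_bins // length
        counts[min(b, n_bins - 1)] += 1
    return counts


def bin_domains(
    variants: Sequence[Variant],
    tads: Sequence[GenomicInterval],
    chromosome_length: int,
    chrom: str,
    n_bins: int = N_BINS,
) -> list[BinnedDomainProfile]:
    """Bin a chromosome's variants over its merged TADs and their gaps."""
    chrom_tads = [
        iv for iv in tads if normalize_chrom(iv.chrom) == normalize_chrom(chrom)
    ]
    merged = merge_intervals(
        [
            GenomicInterval(iv.chrom, iv.start, min(iv.end, chromosome_length), iv.name)
            for iv in chrom_tads
            if iv.start < chromosome_length
        ]
    )
    gaps = complement_gaps(merged, chromosome_length, chrom=chrom)
    chrom_variants = [
        v for v in variants if normalize_chrom(v.chrom) == normalize_chrom(chrom)
    ]
    profiles = [
        BinnedDomainProfile(iv, "inside", bin_counts(chrom_variants, iv, n_bins))
        for iv in merged
    ]
    profiles += [
        BinnedDomainProfile(iv, "outside", bin_counts(chrom_variants, iv, n_bins))
        for iv in gaps
    ]
    profiles.sort(key=lambda p: p.domain.start)
    return profiles


def inside_outside_ratio(
    profiles: Sequence[BinnedDomainProfile],
) -> tuple[Optional[float], Optional[float]]:
    """(raw, length-normalized) inside:outside variant ratio.

    Raw is the plain count ratio; normalized divides each side's per-Mb
    density first, removing the effect of TAD genome coverage.  Either
    value is None when its denominator is zero.
    """
    inside = sum(p.total for p in profiles if p.location == "inside")
    outside = sum(p.total for p in profiles if p.location == "outside")
    len_in = sum(len(p.domain) for p in profiles if p.location == "inside")
    len_out = sum(len(p.domain) for p in profiles if p.location == "outside")
    raw = inside / outside if outside else None
    normalized = None
    if len_in and len_out and outside:
        normalized = (inside / len_in) / (outside / len_out)
    return raw, normalized


def boundary_enrichment(
    profiles: Sequence[BinnedDomainProfile], location: str = "inside"
) -> tuple[list[int], Optional[float]]:
    """Aggregate bin vector across domains and score edge-bin enrichment.

    Returns the element-wise sum of bin counts over all domains at
    ``location`` and the enrichment score mean(first, last bin) /
    mean(interior bins); the score is None when the interior mean is zero.
    """
    selected = [p for p in profiles if p.location == location]
    if not selected:
        return [], None
    n = len(selected[0].bin_counts)
    agg = [sum(p.bin_counts[i] for p in selected) for i in range(n)]
    edge = (agg[0] + agg[-1]) / 2
    interior = sum(agg[1:-1]) / (n - 2)
    score = edge / interior if interior else None
    return agg, score
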