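"""Accumulation profiles, Ti/Tv spectra, SNV:InDel ratios and gene-density
correlation.

Accumulation over a set of intervals (cytogenetic bands, chromosomes) is
length-normalized to variants per megabase:

    V/Mb = 1,000,000 * (variant count in interval) / (interval length in bp)

Transitions are the purine-purine (A<->G) and pyrimidine-pyrimidine
(C<->T) substitutions; the four other unordered base pairs are
transversions, and Ti/Tv is the plain count ratio nTi/nTv.  The human
genome-wide expectation is ~2.1; a depressed ratio (excess transversions)
is a signature of oxidative damage, as produced by ionizing radiation.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from scipy.stats import pearsonr, spearmanr

from .core import GenomicInterval, Variant, normalize_chrom
from .indel_signatures import classify_indel

logger = logging.getLogger("irmutscan")

__all__ = [
    "AccumulationProfile",
    "TiTvSummary",
    "accumulate",
    "titv",
    "is_transition",
    "snv_indel_ratio",
    "gene_density_correlation",
]

_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

#: Pyrimidine-reference collapse for the six substitution classes.
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class AccumulationProfile:
    """Variant counts and per-Mb rates over a set of intervals."""

    rows: list[tuple[GenomicInterval, int, float]]
    variant_type: str = "both"  # SNV | InDel | both
    sample_label: str = ""
    unassigned: int = 0

    @property
    def total(self) -> int:
        return sum(count for _, count, _ in self.rows) + self.unassigned

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                (iv.chrom, iv.start, iv.end, iv.name, count, per_mb)
                for iv, count, per_mb in self.rows
            ],
            columns=["chrom", "start", "end", "name", "count", "per_mb"],
        )


@dataclass
class TiTvSummary:
    ti_count: int
    tv_count: int
    per_type_counts: Counter = field(default_factory=Counter)
    n_excluded: int = 0  # non-SNV records seen in input

    @property
    def ratio(self) -> Optional[float]:
        if self.tv_count == 0:
            return None
        return self.ti_count / self.tv_count


def is_transition(ref: str, alt: str) -> bool:
    return (ref, alt) in _TRANSITIONS


def _pyrimidine_class(ref: str, alt: str) -> str:
    """Collapse a substitution to its pyrimidine-reference class, e.g. C>T."""
    if ref in ("A", "G"):
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{ref}>{alt}"


def accumulate(
    variants: Sequence[Variant],
    intervals: Sequence[GenomicInterval],
    variant_type: str = "both",
    sample_label: str = "",
) -> AccumulationProfile:
    """Count variants per interval and normalize to variants/Mb.

    Each variant is counted in the unique interval containing ``pos - 1``;
    variants outside every interval go to the ``unassigned`` tally.
    Overlapping intervals draw a warning and the first (sorted) match wins.
    """
    by_chrom: dict[str, list[GenomicInterval]] = defaultdict(list)
    for iv in intervals:
        by_chrom[normalize_chrom(iv.chrom)].append(iv)
    starts: dict[str, list[int]] = {}
    for chrom, ivs in by_chrom.items():
        ivs.sort(key=lambda iv: iv.start)
        for prev, cur in zip(ivs, ivs[1:]):
            if cur.start < prev.end:
                logger.warning(
                    "accumulate: overlapping intervals on %s at %d", chrom, cur.start
                )
        starts[chrom] = [iv.start for iv in ivs]

    counts: Counter = Counter()
    unassigned = 0
    for v in variants:
        kind, _ = classify_indel(v)
        if variant_type == "SNV" and kind != "SNV":
            continue
        if variant_type == "InDel" and kind not in ("ins", "del"):
            continue
        chrom = normalize_chrom(v.chrom)
        ivs = by_chrom.get(chrom)
        if not ivs:
            unassigned += 1
            continue
        i = bisect_right(starts[chrom], v.pos - 1) - 1
        if i >= 0 and v.pos - 1 < ivs[i].end:
            counts[ivs[i]] += 1
        else:
            unassigned += 1

    rows = [
        (iv, counts.get(iv, 0), 1_000_000 * counts.get(iv, 0) / len(iv))
        for chrom in sorted(by_chrom)
        for iv in by_chrom[chrom]
    ]
    return AccumulationProfile(
        rows=rows,
        variant_type=variant_type,
        sample_label=sample_label,
        unassigned=unassigned,
    )


def titv(
    variants: Sequence[Variant], grouping: str = "genome"
) -> dict[str, TiTvSummary]:
    """Transition/transversion summary per group.

    ``grouping`` is one of ``genome`` (single group keyed ``"genome"``),
    ``chromosome`` or ``sample``.  Only true SNVs (ref and alt of length 1)
    enter the counts; InDels and multi-nucleotide substitutions are tallied
    under ``n_excluded``.
    """
    if grouping not in ("genome", "chromosome", "sample"):
        raise ValueError(f"unknown grouping {grouping!r}")
    out: dict[str, TiTvSummary] = {}
    for v in variants:
        if grouping == "genome":
            key = "genome"
        elif grouping == "chromosome":
            key = normalize_chrom(v.chrom)
        else:
            key = v.sample
        summary = out.setdefault(key, TiTvSummary(0, 0))
        kind, _ = classify_indel(v)
        if kind != "SNV" or v.ref == "N" or v.alt == "N":
            summary.n_excluded += 1
            continue
        if is_transition(v.ref, v.alt):
            summary.ti_count += 1
        else:
            summary.tv_count += 1
        summary.per_type_counts[_pyrimidine_class(v.ref, v.alt)] += 1
    return out


def snv_indel_ratio(variants: Sequence[Variant]) -> Optional[float]:
    """SNV count divided by InDel count; None when no InDels are present."""
    n_snv = n_indel = 0
    for v in variants:
        kind, _ = classify_indel(v)
        if kind == "SNV":
            n_snv += 1
        elif kind in ("ins", "del"):
            n_indel += 1
    if n_indel == 0:
        return None
    return n_snv / n_indel


def gene_density_correlation(
    per_chrom_rate: Mapping[str, float],
    density_table: Mapping[str, float],
    method: str = "pearson",
) -> Optional[float]:
    """Correlate per-chromosome variant density (V/Mb) with gene density.

    Chromosomes present in both mappings are used; requires at least three.
    Returns None when either vector is constant (correlation undefined).
    """
    chroms = sorted(
        set(map(normalize_chrom, per_chrom_rate)) & set(map(normalize_chrom, density_table)),
        key=lambda c: (c.zfill(4) if c.isdigit() else c),
    )
    if len(chroms) < 3:
        raise ValueError("gene-density correlation needs >= 3 shared chromosomes")
    rate = {normalize_chrom(k): v for k, v in per_chrom_rate.items()}
    dens = {normalize_chrom(k): v for k, v in density_table.items()}
    x = [rate[c] for c in chroms]
    y = [dens[c] for c in chroms]
    if len(set(x)) == 1 or len(set(y)) == 1:
        return None
    if method == "pearson":
        r = pearsonr(x, y).statistic
    elif method == "spearman":
        r = spearmanr(x, y).statistic
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(r)
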