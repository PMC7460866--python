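"""Readers and writers for the external formats the pipeline touches.

Supported formats: VCF v4.x (optionally SnpEff-annotated via the pipe-
delimited ``ANN`` INFO field), BED3/BED4 interval files, UCSC cytoBand
tables, BreakDancer-max tab-delimited structural-variant tables, and a
two-column per-chromosome gene-density TSV.

VCF records are decomposed per alternate allele on read: one
:class:`~irmutscan.core.Variant` per (record, ALT) pair.  FORMAT fields are
taken from the first sample; a missing DP/GQ/AD is carried as ``None``
("absent"), never silently coerced to zero.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .core import (
    GenomicInterval,
    ImpactAnnotation,
    TranslocationCall,
    Variant,
    normalize_chrom,
)

logger = logging.getLogger("irmutscan")

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_intervals",
    "read_translocation_table",
    "write_translocation_table",
    "read_gene_density",
    "parse_ann_field",
    "format_ann_field",
]

# SnpEff ANN sub-field layout (pipe-delimited, 16 fields):
# Allele | Annotation | Impact | Gene_Name | Gene_ID | Feature_Type |
# Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | cDNA | CDS |
# AA | Distance | Errors
_ANN_N_FIELDS = 16

# RefSeq "known" accession prefixes; NM_/NR_ mark curated transcripts,
# which is how RefSeq-known membership travels through a VCF.
_REFSEQ_PREFIXES = ("NM_", "NR_", "NP_")


def parse_ann_field(ann: str) -> tuple[ImpactAnnotation, ...]:
    """Parse a SnpEff ``ANN`` INFO value into annotation entries.

    Entries whose impact is not one of the four SnpEff classes are skipped
    with a warning rather than aborting the read.
    """
    out = []
    for entry in ann.split(","):
        fields = entry.split("|")
        if len(fields) < 7:
            logger.warning("skipping malformed ANN entry: %r", entry)
            continue
        so_term, impact, gene, feature_id = (
            fields[1],
            fields[2],
            fields[3],
            fields[6],
        )
        try:
            out.append(
                ImpactAnnotation(
                    so_term=so_term,
                    impact=impact,
                    gene=gene,
                    transcript_id=feature_id,
                    is_refseq_known=feature_id.startswith(_REFSEQ_PREFIXES),
                )
            )
        except ValueError as exc:
            logger.warning("skipping ANN entry: %s", exc)
    return tuple(out)


def format_ann_field(alt: str, annotations: Iterable[ImpactAnnotation]) -> str:
    entries = []
    for a in annotations:
        fields = [""] * _ANN_N_FIELDS
        fields[0] = alt
        fields[1] = a.so_term
        fields[2] = a.impact
        fields[3] = a.gene
        fields[4] = a.gene
        fields[5] = "transcript"
        fields[6] = a.transcript_id
        fields[7] = "protein_coding"
        entries.append("|".join(fields))
    return ",".join(entries)


def _fmt_int(rec, field: str) -> Optional[int]:
    """First-sample integer FORMAT value, or None when absent/missing."""
    arr = rec.format(field)
    if arr is None:
        return None
    v = np.asarray(arr).ravel()[0]
    if v is None or (np.issubdtype(type(v), np.integer) and v < 0):
        return None  # htslib encodes '.' as a negative sentinel
    return int(v)


def read_vcf(path: str | Path, sample_label: str = "") -> list[Variant]:
    """Read a VCF into per-allele :class:`Variant` records.

    Multi-allelic records are decomposed: one variant per alternate allele,
    with ``alt_count`` taken from the matching AD slot.  Records missing DP
    or GQ are kept and flagged by ``None`` fields; downstream filters decide
    how to treat them.
    """
    variants: list[Variant] = []
    vcf = VCF(str(path))
    n_flagged = 0
    for i, rec in enumerate(vcf):
        try:
            dp = _fmt_int(rec, "DP")
            gq = _fmt_int(rec, "GQ")
            ad = rec.format("AD")
            ann = rec.INFO.get("ANN")
            annotations = parse_ann_field(ann) if ann else ()
            for j, alt in enumerate(rec.ALT):
                alt_count: Optional[int] = None
                if ad is not None:
                    row = np.asarray(ad).ravel()
                    if len(row) > j + 1 and row[j + 1] >= 0:
                        alt_count = int(row[j + 1])
                if alt_count is not None and dp is not None and alt_count > dp:
                    # inconsistent caller output: trust DP, drop the count
                    logger.warning(
                        "%s:%d AD exceeds DP; alt_count dropped", rec.CHROM, rec.POS
                    )
                    alt_count = None
                if dp is None or gq is None:
                    n_flagged += 1
                variants.append(
                    Variant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref=rec.REF,
                        alt=alt,
                        dp=dp,
                        gq=gq,
                        alt_count=alt_count,
                        sample=sample_label,
                        annotations=annotations,
                    )
                )
        except ValueError as exc:
            raise ValueError(f"malformed VCF record #{i + 1} in {path}: {exc}") from exc
    if n_flagged:
        logger.warning("%s: %d records lack DP or GQ", path, n_flagged)
    logger.info("read %d variants from %s", len(variants), path)
    return variants


def write_vcf(
    variants: Sequence[Variant],
    path: str | Path,
    sample_name: str = "SAMPLE",
    contig_lengths: Optional[dict[str, int]] = None,
    add_chr_prefix: bool = True,
) -> None:
    """Write variants as a minimal, sorted VCF v4.2 with GT:DP:GQ:AD.

    Absent DP/GQ/AD values are written as ``.`` so they round-trip as
    absent.  Annotations are serialized back into a SnpEff-style ``ANN``
    INFO field.
    """

    def outname(chrom: str) -> str:
        c = normalize_chrom(chrom)
        return f"chr{c}" if add_chr_prefix else c

    def sort_key(v: Variant):
        c = normalize_chrom(v.chrom)
        return ((0, c.zfill(4)) if c.isdigit() else (1, c), v.pos, v.ref, v.alt)

    lines = [
        "##fileformat=VCFv4.2",
        "##source=irmutscan",
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | "
        "Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | "
        "cDNA.pos / cDNA.length | CDS.pos / CDS.length | AA.pos / AA.length | "
        "Distance | ERRORS / WARNINGS / INFO'\">",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
    ]
    if contig_lengths:
        for chrom, length in contig_lengths.items():
            lines.append(f"##contig=<ID={outname(chrom)},length={length}>")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_name
    )
    for v in sorted(variants, key=sort_key):
        info = format_ann_field(v.alt, v.annotations) if v.annotations else None
        dp = "." if v.dp is None else str(v.dp)
        gq = "." if v.gq is None else str(v.gq)
        if v.alt_count is None:
            ad = "."
        else:
            ref_count = max((v.dp or v.alt_count) - v.alt_count, 0)
            ad = f"{ref_count},{v.alt_count}"
        lines.append(
            "\t".join(
                [
                    outname(v.chrom),
                    str(v.pos),
                    ".",
                    v.ref,
                    v.alt,
                    ".",
                    "PASS",
                    f"ANN={info}" if info else ".",
                    "GT:DP:GQ:AD",
                    f"0/1:{dp}:{gq}:{ad}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
    logger.info("wrote %d variants to %s", len(variants), path)


def read_intervals(path: str | Path, kind: str = "bed") -> list[GenomicInterval]:
    """Read genomic intervals from a BED3/BED4 or UCSC cytoBand table.

    ``kind`` is one of ``cytoband`` (>=4 columns, 4th is the band name),
    ``tad`` or ``bed`` (>=3 columns, optional 4th name column).  Coordinates
    are kept 0-based half-open; records with ``start >= end`` are rejected
    with a warning; output is sorted within each chromosome.  Overlapping
    intervals are kept as-is (a warning is emitted): no silent merging.
    """
    if kind not in ("cytoband", "tad", "bed"):
        raise ValueError(f"unknown interval kind {kind!r}")
    min_cols = 4 if kind == "cytoband" else 3
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype={0: str}
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < min_cols:
        raise ValueError(
            f"{path}: expected >= {min_cols} columns for kind={kind}, "
            f"got {df.shape[1]}"
        )
    intervals: list[GenomicInterval] = []
    for row in df.itertuples(index=False):
        chrom, start, end = str(row[0]), int(row[1]), int(row[2])
        name = str(row[3]) if df.shape[1] > 3 else ("TAD" if kind == "tad" else "")
        if start >= end:
            logger.warning("%s: rejecting interval %s:[%d,%d)", path, chrom, start, end)
            continue
        intervals.append(GenomicInterval(chrom, start, end, name))
    intervals.sort(key=lambda iv: (normalize_chrom(iv.chrom).zfill(4), iv.start))
    prev = None
    for iv in intervals:
        if (
            prev is not None
            and normalize_chrom(prev.chrom) == normalize_chrom(iv.chrom)
            and iv.start < prev.end
        ):
            logger.warning("%s: overlapping intervals at %s:%d", path, iv.chrom, iv.start)
        prev = iv
    return intervals


def read_translocation_table(
    path: str | Path, sample_label: str = ""
) -> list[TranslocationCall]:
    """Read a BreakDancer-max output table, keeping inter-chromosomal (CTX) rows.

    Expected tab-delimited columns (header lines start with ``#``):
    chr1, pos1, orientation1, chr2, pos2, orientation2, type, size, score,
    num_reads, [...].  Breakends are stored in canonical chromosome order.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None, dtype={0: str, 3: str}
        )
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 10:
        raise ValueError(
            f"{path}: expected >= 10 BreakDancer columns, got {df.shape[1]}"
        )
    calls: list[TranslocationCall] = []
    for row in df.itertuples(index=False):
        if str(row[6]) != "CTX":
            continue
        chrom_a, chrom_b = str(row[0]), str(row[3])
        if normalize_chrom(chrom_a) == normalize_chrom(chrom_b):
            logger.warning("%s: intra-chromosomal CTX row skipped", path)
            continue
        calls.append(
            TranslocationCall.make(
                chrom_a,
                int(row[1]),
                chrom_b,
                int(row[4]),
                supporting_reads=int(row[9]),
                confidence=float(row[8]),
                sample=sample_label,
            )
        )
    logger.info("read %d CTX calls from %s", len(calls), path)
    return calls


def write_translocation_table(
    calls: Sequence[TranslocationCall], path: str | Path, add_chr_prefix: bool = True
) -> None:
    """Write calls in the BreakDancer-max tab-delimited dialect."""

    def outname(chrom: str) -> str:
        c = normalize_chrom(chrom)
        return f"chr{c}" if add_chr_prefix else c

    lines = [
        "#Chr1\tPos1\tOrientation1\tChr2\tPos2\tOrientation2\tType\tSize\tScore\tnum_Reads"
    ]
    for c in calls:
        lines.append(
            f"{outname(c.chrom_a)}\t{c.pos_a}\t2+2-\t{outname(c.chrom_b)}\t{c.pos_b}"
            f"\t0+2-\tCTX\t-269\t{c.confidence:g}\t{c.supporting_reads}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_density(path: str | Path) -> dict[str, float]:
    """Read a two-column TSV of chromosome -> genes per Mb."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype={0: str})
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected 2 columns (chrom, genes_per_mb)")
    return {normalize_chrom(str(r[0])): float(r[1]) for r in df.itertuples(index=False)}
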