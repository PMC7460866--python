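"""Core domain types shared by every stage of the pipeline.

Coordinate conventions
----------------------
Variants use the VCF convention (1-based ``pos``); intervals use the BED
convention (0-based, half-open).  Every containment test converts a variant
position to ``pos - 1`` before comparing against an interval, so a variant
at VCF position ``p`` lies in ``[start, end)`` iff ``start <= p - 1 < end``.

Chromosome names are normalized internally by stripping a leading ``chr``
prefix, so UCSC-style band tables and Ensembl-style VCFs interoperate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

__all__ = [
    "Variant",
    "GenomicInterval",
    "TranslocationCall",
    "ImpactAnnotation",
    "normalize_chrom",
    "IMPACT_SEVERITY",
]

#: SnpEff impact classes ordered from most to least severe.
IMPACT_SEVERITY = ("HIGH", "MODERATE", "LOW", "MODIFIER")

_VALID_BASES = frozenset("ACGTN")


def normalize_chrom(chrom: str) -> str:
    """Strip a leading ``chr``/``Chr`` prefix from a chromosome name."""
    if chrom[:3].lower() == "chr":
        return chrom[3:]
    return chrom


@dataclass(frozen=True)
class ImpactAnnotation:
    """One SnpEff ANN entry: a sequence-ontology consequence on one transcript."""

    so_term: str
    impact: str
    gene: str
    transcript_id: str
    is_refseq_known: bool

    def __post_init__(self) -> None:
        if self.impact not in IMPACT_SEVERITY:
            raise ValueError(f"unknown impact class {self.impact!r}")


@dataclass(frozen=True)
class Variant:
    """One small-variant call for a single alternate allele.

    ``dp``/``gq``/``alt_count`` are ``None`` when the originating VCF record
    did not carry the corresponding FORMAT field (absent, not zero).
    """

    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    dp: Optional[int] = None
    gq: Optional[int] = None
    alt_count: Optional[int] = None
    sample: str = ""
    annotations: tuple[ImpactAnnotation, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"VCF position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if not set(self.ref) <= _VALID_BASES or not set(self.alt) <= _VALID_BASES:
            raise ValueError(f"alleles must be over ACGTN: {self.ref}>{self.alt}")
        if self.dp is not None and self.dp < 0:
            raise ValueError("dp must be >= 0")
        if self.gq is not None and self.gq < 0:
            raise ValueError("gq must be >= 0")
        if (
            self.alt_count is not None
            and self.dp is not None
            and self.alt_count > self.dp
        ):
            raise ValueError(f"alt_count {self.alt_count} exceeds dp {self.dp}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used for control-pool matching: (chrom, pos, ref, alt)."""
        return (normalize_chrom(self.chrom), self.pos, self.ref, self.alt)

    def with_sample(self, sample: str) -> "Variant":
        return replace(self, sample=sample)


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval (cytogenetic band, TAD, or gap)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains_vcf_pos(self, chrom: str, pos: int) -> bool:
        """True iff a variant at VCF (1-based) position ``pos`` lies inside."""
        return (
            normalize_chrom(chrom) == normalize_chrom(self.chrom)
            and self.start <= pos - 1 < self.end
        )


@dataclass(frozen=True)
class TranslocationCall:
    """An inter-chromosomal translocation: paired breakends on two chromosomes.

    Breakends are canonically ordered so that ``chrom_a < chrom_b`` under a
    natural sort (numeric chromosomes before X/Y), making unordered-pair
    comparisons trivial.
    """

    chrom_a: str
    pos_a: int
    chrom_b: str
    pos_b: int
    supporting_reads: int = 0
    confidence: float = 0.0
    sample: str = ""

    def __post_init__(self) -> None:
        if normalize_chrom(self.chrom_a) == normalize_chrom(self.chrom_b):
            raise ValueError("translocation calls must be inter-chromosomal")
        if not (0 <= self.confidence <= 100):
            raise ValueError("confidence must lie in [0, 100]")

    @staticmethod
    def _chrom_sort_key(chrom: str) -> tuple[int, str]:
        c = normalize_chrom(chrom)
        return (0, c.zfill(4)) if c.isdigit() else (1, c)

    @classmethod
    def make(
        cls,
        chrom_a: str,
        pos_a: int,
        chrom_b: str,
        pos_b: int,
        supporting_reads: int = 0,
        confidence: float = 0.0,
        sample: str = "",
    ) -> "TranslocationCall":
        """Construct with breakends put into canonical order."""
        if cls._chrom_sort_key(chrom_a) > cls._chrom_sort_key(chrom_b):
            chrom_a, pos_a, chrom_b, pos_b = chrom_b, pos_b, chrom_a, pos_a
        return cls(chrom_a, pos_a, chrom_b, pos_b, supporting_reads, confidence, sample)

    @property
    def chrom_pair(self) -> tuple[str, str]:
        return (normalize_chrom(self.chrom_a), normalize_chrom(self.chrom_b))
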