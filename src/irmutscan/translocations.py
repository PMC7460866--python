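"""Post-processing of inter-chromosomal translocation call tables.

Two calls are *windowed-equal* when they join the same chromosome pair and
both breakends lie within the same 200-nucleotide window.  Treated-sample
calls windowed-equal to any control call are removed (they pre-date the
irradiation), survivors are deduplicated within the sample, and calls must
carry at least 20 supporting read pairs and a confidence score strictly
greater than 80 to be counted.  Counts are reported per unordered
chromosome pair, direction-free.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

from .core import TranslocationCall

logger = logging.getLogger("irmutscan")

__all__ = [
    "windowed_equal",
    "subtract_controls",
    "dedup",
    "quality_filter",
    "pair_matrix",
    "TranslocationMatrix",
    "DEFAULT_WINDOW",
    "DEFAULT_MIN_READS",
    "DEFAULT_MIN_CONFIDENCE",
]

DEFAULT_WINDOW = 200
DEFAULT_MIN_READS = 20
DEFAULT_MIN_CONFIDENCE = 80.0


@dataclass
class TranslocationMatrix:
    """Symmetric per-chromosome-pair translocation counts."""

    counts: Counter = field(default_factory=Counter)
    total: int = 0
    sample_label: str = ""

    def count(self, chrom_a: str, chrom_b: str) -> int:
        key = tuple(sorted((chrom_a, chrom_b)))
        return self.counts.get(key, 0)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [(a, b, n) for (a, b), n in sorted(self.counts.items())],
            columns=["chrom_a", "chrom_b", "count"],
        )


def windowed_equal(
    a: TranslocationCall, b: TranslocationCall, window: int = DEFAULT_WINDOW
) -> bool:
    """True iff both calls join the same chromosome pair with both breakends
    closer than ``window`` nucleotides (strict)."""
    if a.chrom_pair != b.chrom_pair:
        return False
    return abs(a.pos_a - b.pos_a) < window and abs(a.pos_b - b.pos_b) < window


def subtract_controls(
    treated_calls: Sequence[TranslocationCall],
    control_calls: Sequence[TranslocationCall],
    window: int = DEFAULT_WINDOW,
) -> list[TranslocationCall]:
    """Remove treated calls windowed-equal to any control call."""
    kept = [
        t
        for t in treated_calls
        if not any(windowed_equal(t, c, window) for c in control_calls)
    ]
    logger.info(
        "subtract_controls: %d/%d treated calls retained",
        len(kept),
        len(treated_calls),
    )
    return kept


def dedup(
    calls: Sequence[TranslocationCall], window: int = DEFAULT_WINDOW
) -> list[TranslocationCall]:
    """Merge windowed-equal calls within one sample, keeping the
    higher-confidence (then higher-support) call of each cluster."""
    ranked = sorted(
        calls, key=lambda c: (c.confidence, c.supporting_reads), reverse=True
    )
    kept: list[TranslocationCall] = []
    for c in ranked:
        if not any(windowed_equal(c, k, window) for k in kept):
            kept.append(c)
    return kept


def quality_filter(
    calls: Sequence[TranslocationCall],
    min_reads: int = DEFAULT_MIN_READS,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
) -> list[TranslocationCall]:
    """Keep calls with supporting_reads >= min_reads and confidence
    strictly greater than min_confidence."""
    return [
        c
        for c in calls
        if c.supporting_reads >= min_reads and c.confidence > min_confidence
    ]


def pair_matrix(
    calls: Sequence[TranslocationCall], sample_label: str = ""
) -> TranslocationMatrix:
    """Count calls per unordered chromosome pair."""
    counts: Counter = Counter()
    for c in calls:
        counts[tuple(sorted(c.chrom_pair))] += 1
    return TranslocationMatrix(
        counts=counts, total=sum(counts.values()), sample_label=sample_label
    )


def process_sample(
    treated_calls: Sequence[TranslocationCall],
    control_calls: Sequence[TranslocationCall],
    window: int = DEFAULT_WINDOW,
    min_reads: int = DEFAULT_MIN_READS,
    min_confidence: float = DEFAULT_MIN_CONFIDENCE,
    deduplicate: bool = True,
    sample_label: str = "",
) -> tuple[list[TranslocationCall], TranslocationMatrix]:
    """Full translocation post-processing for one treated sample."""
    calls = subtract_controls(treated_calls, control_calls, window)
    if deduplicate:
        calls = dedup(calls, window)
    calls = quality_filter(calls, min_reads, min_confidence)
    return calls, pair_matrix(calls, sample_label)
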