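"""Functional-impact summaries of SnpEff-annotated variants.

SnpEff annotates each variant against every overlapping transcript, so the
same consequence may appear many times per genomic location.  The summary
therefore (1) restricts annotations to transcripts in the curated
("known") RefSeq collection, (2) folds closely related sequence-ontology
terms into combined terms, (3) counts each distinct combined term once per
location, and (4) assigns each location a single impact class — the most
severe among its retained annotations (HIGH > MODERATE > LOW > MODIFIER).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import IMPACT_SEVERITY, GenomicInterval, Variant, normalize_chrom

logger = logging.getLogger("irmutscan")

__all__ = ["combine_so_terms", "tally", "ImpactTally", "SO_TERM_COMBINATIONS"]

#: Fold-in map from raw SnpEff sequence-ontology terms (possibly
#: '&'-joined) to less specific combined terms; unmapped terms pass
#: through unchanged.
SO_TERM_COMBINATIONS: dict[str, str] = {
    "splice_region_variant&intron_variant": "splice_region",
    "splice_region_variant": "splice_region",
    "splice_region_variant&synonymous_variant": "splice_region",
    "splice_region_variant&non_coding_exon_variant": "splice_region",
    "splice_acceptor_variant&intron_variant": "splice_site",
    "splice_donor_variant&intron_variant": "splice_site",
    "splice_acceptor_variant&splice_donor_variant&intron_variant": "splice_site",
    "missense_variant&splice_region_variant": "missense_variant",
    "stop_retained_variant": "synonymous_variant",
    "stop_gained&splice_region_variant": "stop_gained",
    "5_prime_UTR_premature_start_codon_gain_variant": "5_prime_UTR_variant",
}

_SEVERITY_RANK = {impact: i for i, impact in enumerate(IMPACT_SEVERITY)}


def combine_so_terms(so_term: str) -> str:
    """Map a SnpEff SO term (or '&'-joined combination) to its combined term."""
    return SO_TERM_COMBINATIONS.get(so_term, so_term)


@dataclass
class ImpactTally:
    """Impact-class and combined-term counts at a chosen grouping level."""

    per_impact: dict[str, Counter] = field(default_factory=dict)
    per_combined_term: dict[str, Counter] = field(default_factory=dict)
    grouping: str = "genome"
    n_unannotated: int = 0

    def impact_counts(self, group: str = "genome") -> dict[str, int]:
        c = self.per_impact.get(group, Counter())
        return {impact: c.get(impact, 0) for impact in IMPACT_SEVERITY}

    def to_frame(self):
        import pandas as pd

        rows = []
        for group in sorted(self.per_impact):
            rows.append({"group": group, **self.impact_counts(group)})
        return pd.DataFrame(rows)


def _band_lookup(bands: Sequence[GenomicInterval]):
    from bisect import bisect_right
    from collections import defaultdict

    by_chrom = defaultdict(list)
    for iv in bands:
        by_chrom[normalize_chrom(iv.chrom)].append(iv)
    for ivs in by_chrom.values():
        ivs.sort(key=lambda iv: iv.start)

    def lookup(chrom: str, pos: int) -> str:
        ivs = by_chrom.get(normalize_chrom(chrom), [])
        i = bisect_right([iv.start for iv in ivs], pos - 1) - 1
        if i >= 0 and pos - 1 < ivs[i].end:
            return f"{normalize_chrom(chrom)}{ivs[i].name}"
        return "unassigned"

    return lookup


def tally(
    variants: Sequence[Variant],
    grouping: str = "genome",
    bands: Optional[Sequence[GenomicInterval]] = None,
    refseq_known_only: bool = True,
    unannotated_term: str = "unannotated",
) -> ImpactTally:
    """Summarize predicted functional impact per location.

    Per variant location, annotations are first restricted to RefSeq-known
    transcripts; each distinct combined SO term then contributes exactly
    one count regardless of transcript multiplicity, and the location's
    impact class is the most severe among the retained annotations.
    Locations with no retained annotation count as MODIFIER under
    ``unannotated_term``.
    """
    if grouping not in ("genome", "chromosome", "band"):
        raise ValueError(f"unknown grouping {grouping!r}")
    if grouping == "band" and bands is None:
        raise ValueError("band grouping requires band intervals")
    band_of = _band_lookup(bands) if grouping == "band" else None

    tally_ = ImpactTally(grouping=grouping)
    seen: set = set()
    for v in variants:
        if v.key in seen:  # one contribution per location
            continue
        seen.add(v.key)
        if grouping == "genome":
            group = "genome"
        elif grouping == "chromosome":
            group = normalize_chrom(v.chrom)
        else:
            group = band_of(v.chrom, v.pos)  # type: ignore[misc]
        impacts = tally_.per_impact.setdefault(group, Counter())
        terms = tally_.per_combined_term.setdefault(group, Counter())

        anns = [
            a for a in v.annotations if (a.is_refseq_known or not refseq_known_only)
        ]
        if not anns:
            tally_.n_unannotated += 1
            impacts["MODIFIER"] += 1
            terms[unannotated_term] += 1
            continue
        impacts[min(anns, key=lambda a: _SEVERITY_RANK[a.impact]).impact] += 1
        for term in {combine_so_terms(a.so_term) for a in anns}:
            terms[term] += 1
    return tally_
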