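"""Three-stage filter chain isolating radiation-induced variants.

Stage 1 (*sample filter*) removes every treated-sample variant whose
(chrom, pos, ref, alt) identity also occurs in the pooled untreated
controls — these are cell-line-specific or pre-existing variants, not
induced ones.  Stage 2 (*coverage filter*) requires a minimum sequencing
depth (DP >= 3) and genotype quality (GQ >= 20).  Stage 3 (*binomial
filter*) removes calls whose alternate-read support is consistent with the
sequencing error rate alone: with ``X ~ Binomial(DP, error_rate)`` the
one-sided exact tail ``p = P(X >= alt_count)`` must fall below ``alpha``
for the call to survive (default error rate 0.001, alpha 0.001).

The three stage predicates are independent, so the retained set does not
depend on stage order and the chain is idempotent; the per-stage removal
tallies, however, are order-dependent (each stage only sees survivors of
the previous one) and are reported for the canonical order
sample -> coverage -> binomial.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from scipy.stats import binom

from .core import Variant
from .indel_signatures import classify_indel

logger = logging.getLogger("irmutscan")

__all__ = [
    "sample_filter",
    "coverage_filter",
    "binomial_filter",
    "binomial_tail",
    "run_filter_chain",
    "FilterReport",
    "DEFAULT_ERROR_RATE",
    "DEFAULT_ALPHA",
    "DEFAULT_MIN_DP",
    "DEFAULT_MIN_GQ",
]

DEFAULT_MIN_DP = 3
DEFAULT_MIN_GQ = 20
DEFAULT_ERROR_RATE = 0.001
DEFAULT_ALPHA = 0.001

_STAGES = ("sample", "coverage", "binomial")


@dataclass
class FilterReport:
    """Bookkeeping for one pass of the filter chain.

    ``counts_before``/``counts_after`` and the depth sums are broken down
    by variant type (SNV vs InDel, with MNVs under "other");
    ``removed_by_stage`` tallies removals in chain order.
    """

    counts_before: dict[str, int] = field(default_factory=dict)
    counts_after: dict[str, int] = field(default_factory=dict)
    removed_by_stage: dict[str, int] = field(
        default_factory=lambda: {s: 0 for s in _STAGES}
    )
    dp_sums_before: dict[str, int] = field(default_factory=dict)
    dp_sums_after: dict[str, int] = field(default_factory=dict)
    n_missing_quality: int = 0  # kept despite absent DP/GQ
    n_missing_alt_count: int = 0  # binomial stage skipped

    def check(self) -> None:
        """Raise if the tallies do not reconcile."""
        total_before = sum(self.counts_before.values())
        total_after = sum(self.counts_after.values())
        removed = sum(self.removed_by_stage.values())
        if total_before != total_after + removed:
            raise AssertionError(
                f"report does not reconcile: {total_before} != "
                f"{total_after} + {removed}"
            )

    def to_frame(self):
        import pandas as pd

        rows = []
        for typ in sorted(set(self.counts_before) | set(self.counts_after)):
            rows.append(
                {
                    "type": typ,
                    "count_before": self.counts_before.get(typ, 0),
                    "count_after": self.counts_after.get(typ, 0),
                    "dp_sum_before": self.dp_sums_before.get(typ, 0),
                    "dp_sum_after": self.dp_sums_after.get(typ, 0),
                }
            )
        df = pd.DataFrame(rows)
        for stage in _STAGES:
            df[f"removed_{stage}"] = self.removed_by_stage[stage]
        return df


def _type_of(v: Variant) -> str:
    kind, _ = classify_indel(v)
    if kind == "SNV":
        return "SNV"
    if kind in ("ins", "del"):
        return "InDel"
    return "other"


def _tally(variants: Sequence[Variant]) -> tuple[dict[str, int], dict[str, int]]:
    counts: dict[str, int] = {}
    dp_sums: dict[str, int] = {}
    for v in variants:
        t = _type_of(v)
        counts[t] = counts.get(t, 0) + 1
        dp_sums[t] = dp_sums.get(t, 0) + (v.dp or 0)
    return counts, dp_sums


def sample_filter(
    treated: Sequence[Variant], control_pool: Sequence[Variant]
) -> list[Variant]:
    """Drop treated variants present in the pooled controls.

    Matching is on (chrom, pos, ref, alt) only — genotype is ignored, since
    the controls act as a variant pool, not a genotyped cohort.
    """
    if not control_pool:
        logger.warning("sample_filter: empty control pool, all variants pass")
        return list(treated)
    pool_keys = {v.key for v in control_pool}
    return [v for v in treated if v.key not in pool_keys]


def coverage_filter(
    variants: Sequence[Variant],
    min_dp: int = DEFAULT_MIN_DP,
    min_gq: int = DEFAULT_MIN_GQ,
) -> list[Variant]:
    """Keep variants with DP >= min_dp and GQ >= min_gq (inclusive minima).

    Variants lacking DP or GQ are retained with a warning: absence of a
    FORMAT field is a caller artifact, not evidence of low coverage.
    """
    kept, n_missing = [], 0
    for v in variants:
        if v.dp is None or v.gq is None:
            n_missing += 1
            kept.append(v)
        elif v.dp >= min_dp and v.gq >= min_gq:
            kept.append(v)
    if n_missing:
        logger.warning(
            "coverage_filter: %d variants lack DP or GQ, retained", n_missing
        )
    return kept


def binomial_tail(alt_count: int, dp: int, error_rate: float) -> float:
    """Exact one-sided tail P(X >= alt_count), X ~ Binomial(dp, error_rate)."""
    if alt_count > dp:
        raise ValueError(f"alt_count {alt_count} > dp {dp}")
    if alt_count <= 0:
        return 1.0
    return float(binom.sf(alt_count - 1, dp, error_rate))


def binomial_filter(
    variants: Sequence[Variant],
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
) -> list[Variant]:
    """Keep variants whose alternate support exceeds sequencing error.

    A variant survives iff the exact binomial tail probability of seeing at
    least its ``alt_count`` alternate reads among ``dp`` total reads under
    the per-base error rate is below ``alpha``.  Variants without an
    alt_count (no AD field) skip this test and are retained with a warning.
    """
    kept, n_skipped = [], 0
    for v in variants:
        if v.alt_count is None or v.dp is None:
            n_skipped += 1
            kept.append(v)
            continue
        if binomial_tail(v.alt_count, v.dp, error_rate) < alpha:
            kept.append(v)
    if n_skipped:
        logger.warning(
            "binomial_filter: %d variants lack AD/DP, test skipped", n_skipped
        )
    return kept


def run_filter_chain(
    treated: Sequence[Variant],
    control_pool: Sequence[Variant],
    min_dp: int = DEFAULT_MIN_DP,
    min_gq: int = DEFAULT_MIN_GQ,
    error_rate: float = DEFAULT_ERROR_RATE,
    alpha: float = DEFAULT_ALPHA,
) -> tuple[list[Variant], FilterReport]:
    """Apply sample -> coverage -> binomial filtering and report tallies."""
    report = FilterReport()
    report.counts_before, report.dp_sums_before = _tally(treated)

    after_sample = sample_filter(treated, control_pool)
    report.removed_by_stage["sample"] = len(treated) - len(after_sample)

    report.n_missing_quality = sum(
        1 for v in after_sample if v.dp is None or v.gq is None
    )
    after_coverage = coverage_filter(after_sample, min_dp=min_dp, min_gq=min_gq)
    report.removed_by_stage["coverage"] = len(after_sample) - len(after_coverage)

    report.n_missing_alt_count = sum(
        1 for v in after_coverage if v.alt_count is None or v.dp is None
    )
    retained = binomial_filter(after_coverage, error_rate=error_rate, alpha=alpha)
    report.removed_by_stage["binomial"] = len(after_coverage) - len(retained)

    report.counts_after, report.dp_sums_after = _tally(retained)
    report.check()
    logger.info(
        "filter chain: %d -> %d variants (removed %s)",
        len(treated),
        len(retained),
        report.removed_by_stage,
    )
    return retained, report
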