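"""Synthetic input generator with the statistical structure the analysis
assumes.

The generator emulates a whole-genome-sequencing radiation-mutagenesis
experiment without any external data: an untreated control variant pool
plus treated samples that share a configurable fraction (default 98%) of
their variants with that pool, so that control-pool subtraction leaves the
treatment-specific ~2%.  Pre-existing and treatment-specific variants
differ in transition/transversion ratio (default 2.1 vs 1.45) and
SNV:InDel ratio (default 5.2 vs 2.1); treatment-specific variants are
loaded heterogeneously across chromosomes (default weights span a 10x
range, mimicking the contrast between the most and least affected
chromosomes), while control variants are spread far more evenly.
Deletions and insertions are *placed* so as to realize a configured mix of
repeat / microhomology / featureless contexts, and every placement is
validated by the same classifier the analysis uses — the ground-truth
labels written to the manifest are classifier-consistent by construction.

Translocation tables contain a configured fraction of treated events that
are jittered copies (< 200 nt on both breakends) of control events, with
supporting-read counts and confidence scores straddling the 20-read and
80-score thresholds, so control subtraction, windowed deduplication and
quality filtering are all exercised with an exactly known answer.

All outputs are deterministic functions of the seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .core import (
    GenomicInterval,
    ImpactAnnotation,
    TranslocationCall,
    Variant,
    normalize_chrom,
)
from .indel_signatures import classify_context
from . import io_formats

logger = logging.getLogger("irmutscan")

__all__ = [
    "SimulationConfig",
    "ReferenceSet",
    "VariantSets",
    "TranslocationSets",
    "make_reference",
    "make_variant_sets",
    "make_translocations",
    "make_gene_density",
    "simulate",
]

_BASES = np.array(list("ACGT"))
_TI_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV_PARTNERS = {
    "A": ("C", "T"),
    "G": ("C", "T"),
    "C": ("A", "G"),
    "T": ("A", "G"),
}

# SO terms emitted per impact class (SnpEff vocabulary, incl. '&'-joined
# combinations so the term-combination step is exercised).
_TERMS_BY_IMPACT = {
    "HIGH": ["stop_gained", "splice_acceptor_variant&intron_variant"],
    "MODERATE": ["missense_variant", "missense_variant&splice_region_variant"],
    "LOW": [
        "synonymous_variant",
        "splice_region_variant&intron_variant",
        "stop_retained_variant",
    ],
    "MODIFIER": [
        "intron_variant",
        "intergenic_region",
        "upstream_gene_variant",
        "downstream_gene_variant",
    ],
}

_MIN_CHROM_LENGTH = 50_000
_EDGE_MARGIN = 300  # keep variants clear of chromosome ends (flank context)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the emulated study design."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (1_000_000, 1_000_000, 1_000_000, 1_000_000)
    n_bands_per_chromosome: int = 5
    sample_labels: tuple[str, ...] = (
        "16h_0.5Gy",
        "16h_2Gy",
        "16h_10Gy",
        "7d_0.5Gy",
        "7d_2Gy",
        "7d_10Gy",
    )
    n_variants_per_sample: int = 10_000
    control_pool_size: Optional[int] = None  # default: n_variants_per_sample
    shared_fraction: float = 0.98
    pre_titv: float = 2.1
    ir_titv: float = 1.45
    pre_snv_indel_ratio: float = 5.2
    ir_snv_indel_ratio: float = 2.1
    per_chromosome_weights: tuple[float, ...] = (10.0, 4.0, 2.0, 1.0)
    control_weight_flatten: float = 0.3  # control weights = treated ** this
    indel_length_decay: float = 0.5  # geometric p; mono/di-nucleotide dominance
    max_indel_length: int = 20
    context_mix: tuple[float, float, float] = (0.4, 0.3, 0.3)  # rep, mh, none
    triplet_none_boost: float = 1.0  # multiplier for 3-nt featureless deletions
    insertion_fraction: float = 0.5
    n_translocations: int = 40
    control_translocation_fraction: float = 0.5
    dp_mean: float = 60.0
    error_variant_rate: float = 0.01  # artifact variants, fraction of n
    low_quality_rate: float = 0.005  # low-DP/GQ variants, fraction of n
    sequencing_error_rate: float = 0.001
    tad_density_boost: float = 1.0  # inside-TAD density multiplier
    boundary_bin_boost: float = 1.0  # first/last-bin density multiplier
    impact_mix: tuple[float, float, float, float] = (0.0005, 0.006, 0.095, 0.8985)
    refseq_known_fraction: float = 0.8
    gene_density_noise: float = 4.0

    def validate(self) -> None:
        if len(self.chrom_lengths) < 1:
            raise ValueError("need at least one chromosome")
        if any(length < _MIN_CHROM_LENGTH for length in self.chrom_lengths):
            raise ValueError(
                f"chromosomes must be >= {_MIN_CHROM_LENGTH} bp for band/TAD binning"
            )
        if len(self.per_chromosome_weights) != len(self.chrom_lengths):
            raise ValueError("per_chromosome_weights must match chrom_lengths")
        if any(w <= 0 for w in self.per_chromosome_weights):
            raise ValueError("chromosome weights must be positive")
        for name, frac in [
            ("shared_fraction", self.shared_fraction),
            ("control_translocation_fraction", self.control_translocation_fraction),
            ("error_variant_rate", self.error_variant_rate),
            ("low_quality_rate", self.low_quality_rate),
            ("refseq_known_fraction", self.refseq_known_fraction),
            ("insertion_fraction", self.insertion_fraction),
        ]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{name} must lie in [0,1], got {frac}")
        if not math.isclose(sum(self.context_mix), 1.0, abs_tol=1e-9):
            raise ValueError("context_mix must sum to 1")
        if not math.isclose(sum(self.impact_mix), 1.0, abs_tol=1e-9):
            raise ValueError("impact_mix must sum to 1")
        if not 0 < self.indel_length_decay <= 1:
            raise ValueError("indel_length_decay must be a geometric p in (0,1]")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(len(self.chrom_lengths))]


@dataclass
class ReferenceSet:
    """Reference sequences plus the band/TAD scaffolding built on them."""

    sequences: dict[str, str]
    bands: list[GenomicInterval]
    tads: list[GenomicInterval]
    mono_runs: dict[str, list[tuple[int, int, str]]]  # (start0, length, base)

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


@dataclass
class VariantSets:
    control: list[Variant]
    treated: dict[str, list[Variant]]
    truth: dict


@dataclass
class TranslocationSets:
    control: list[TranslocationCall]
    treated: dict[str, list[TranslocationCall]]
    truth: dict


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# ---------------------------------------------------------------------------
# reference, bands, TADs


def _band_name(i: int, n: int) -> str:
    half = n // 2
    return f"p{half - i}" if i < half else f"q{i - half + 1}"


def make_reference(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> ReferenceSet:
    """Build per-chromosome random sequence with implanted repeat tracts.

    Sequence is i.i.d.-uniform A/C/G/T with mononucleotide runs (8-12 bp,
    every ~1.5 kb) and dinucleotide tracts (10-16 bp, every ~3 kb)
    implanted so repeat and microhomology contexts occur at useful rates.
    Bands partition each chromosome into equal parts; TADs cover roughly
    60-80% of each chromosome with gaps in between.
    """
    config.validate()
    if rng is None:
        rng = _rng_streams(config.seed, 4)[0]
    sequences: dict[str, str] = {}
    bands: list[GenomicInterval] = []
    tads: list[GenomicInterval] = []
    mono_runs: dict[str, list[tuple[int, int, str]]] = {}

    for chrom, length in zip(config.chrom_names, config.chrom_lengths):
        arr = rng.integers(0, 4, size=length)
        runs: list[tuple[int, int, str]] = []
        # dinucleotide tandem tracts first, mononucleotide runs second, so
        # the recorded run registry is never overwritten afterwards
        pos = int(rng.integers(1000, 3000))
        while pos < length - 2000:
            unit = rng.integers(0, 4, size=2)
            n_copies = int(rng.integers(5, 9))
            tract = np.tile(unit, n_copies)
            arr[pos : pos + len(tract)] = tract
            pos += int(rng.integers(2000, 4000))
        pos = int(rng.integers(500, 1500))
        while pos < length - 2000:
            run_len = int(rng.integers(8, 13))
            base_idx = int(rng.integers(0, 4))
            arr[pos : pos + run_len] = base_idx
            runs.append((pos, run_len, str(_BASES[base_idx])))
            pos += int(rng.integers(1000, 2000))
        sequences[chrom] = "".join(_BASES[arr])
        mono_runs[chrom] = runs

        n_bands = config.n_bands_per_chromosome
        edges = [round(i * length / n_bands) for i in range(n_bands + 1)]
        for i in range(n_bands):
            bands.append(
                GenomicInterval(chrom, edges[i], edges[i + 1], _band_name(i, n_bands))
            )

        cursor = int(rng.uniform(0.02, 0.05) * length)
        while True:
            tad_len = int(rng.uniform(0.05, 0.12) * length)
            if cursor + tad_len > length - 0.02 * length:
                break
            tads.append(GenomicInterval(chrom, cursor, cursor + tad_len, "TAD"))
            cursor += tad_len + int(rng.uniform(0.02, 0.05) * length)
    return ReferenceSet(sequences, bands, tads, mono_runs)


# ---------------------------------------------------------------------------
# position sampling (TAD/boundary aware)


class _PositionSampler:
    """Draw 1-based variant positions, optionally density-weighted.

    With both boosts at 1 this is uniform over the chromosome interior.
    ``tad_density_boost`` multiplies the density inside TADs relative to
    gaps; ``boundary_bin_boost`` multiplies the density in the first and
    last of the ten bins of every TAD and gap.
    """

    def __init__(self, config: SimulationConfig, reference: ReferenceSet):
        from .tad_analysis import complement_gaps, merge_intervals

        self._rng_cache: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        self.uniform = config.tad_density_boost == 1 and config.boundary_bin_boost == 1
        self.lengths = reference.chrom_lengths
        if self.uniform:
            return
        n_bins = 10
        for chrom, length in self.lengths.items():
            chrom_tads = merge_intervals(
                [t for t in reference.tads if t.chrom == chrom]
            )
            gaps = complement_gaps(chrom_tads, length, chrom=chrom)
            starts, ends, weights = [], [], []
            for iv, inside in [(t, True) for t in chrom_tads] + [
                (g, False) for g in gaps
            ]:
                edges = [
                    iv.start + (len(iv) * i) // n_bins for i in range(n_bins + 1)
                ]
                for b in range(n_bins):
                    w = float(edges[b + 1] - edges[b])
                    if w <= 0:
                        continue
                    if inside:
                        w *= config.tad_density_boost
                    if b in (0, n_bins - 1):
                        w *= config.boundary_bin_boost
                    starts.append(edges[b])
                    ends.append(edges[b + 1])
                    weights.append(w)
            w_arr = np.array(weights)
            self._rng_cache[chrom] = (
                np.array(starts),
                np.array(ends),
                w_arr / w_arr.sum(),
            )

    def draw(self, rng: np.random.Generator, chrom: str) -> int:
        length = self.lengths[chrom]
        while True:
            if self.uniform:
                p0 = int(rng.integers(0, length))
            else:
                starts, ends, probs = self._rng_cache[chrom]
                b = rng.choice(len(probs), p=probs)
                p0 = int(rng.integers(starts[b], ends[b]))
            if _EDGE_MARGIN <= p0 < length - _EDGE_MARGIN:
                return p0 + 1  # 1-based


# ---------------------------------------------------------------------------
# variant construction


def _draw_quality(rng: np.random.Generator, config: SimulationConfig):
    dp = max(int(rng.poisson(config.dp_mean)), 4)
    gq = 99 if rng.random() < 0.9 else int(rng.integers(30, 99))
    vaf = 1.0 if rng.random() < 0.2 else 0.5  # hom / het
    alt = int(np.clip(rng.binomial(dp, vaf), 1, dp))
    return dp, gq, alt


def _draw_annotations(
    rng: np.random.Generator, config: SimulationConfig
) -> tuple[ImpactAnnotation, ...]:
    impact = ("HIGH", "MODERATE", "LOW", "MODIFIER")[
        rng.choice(4, p=list(config.impact_mix))
    ]
    term = _TERMS_BY_IMPACT[impact][rng.integers(0, len(_TERMS_BY_IMPACT[impact]))]
    gene = f"GENE{int(rng.integers(1, 5000))}"
    known = rng.random() < config.refseq_known_fraction
    n_tx = int(rng.integers(1, 4))
    anns = []
    for t in range(n_tx):
        acc = (
            f"NM_{int(rng.integers(1, 999999)):06d}.{t + 1}"
            if known
            else f"ENST{int(rng.integers(1, 999999)):011d}"
        )
        anns.append(ImpactAnnotation(term, impact, gene, acc, known))
    return tuple(anns)


def _draw_indel_length(
    rng: np.random.Generator, config: SimulationConfig, context: str, is_del: bool
) -> int:
    p = config.indel_length_decay
    lmax = config.max_indel_length
    lengths = np.arange(1, lmax + 1)
    pmf = p * (1 - p) ** (lengths - 1)
    if context == "mh":  # microhomology needs len >= 2
        pmf[0] = 0.0
    if is_del and context == "none" and config.triplet_none_boost != 1.0:
        pmf[2] *= config.triplet_none_boost
    pmf /= pmf.sum()
    return int(rng.choice(lengths, p=pmf))


def _place_deletion(
    rng: np.random.Generator,
    config: SimulationConfig,
    reference: ReferenceSet,
    sampler: _PositionSampler,
    chrom: str,
    context: str,
    max_tries: int = 60,
) -> Optional[tuple[int, str, str, str, int]]:
    """Place a deletion realizing ``context``; returns (pos, ref, alt,
    realized_context, sub_length) or None when unplaceable."""
    seq = reference.sequences[chrom]
    length = _draw_indel_length(rng, config, context, is_del=True)
    flank = max(2 * length, 20)
    for _ in range(max_tries):
        pos = sampler.draw(rng, chrom)  # 1-based anchor
        d0 = pos  # 0-based start of deleted bases
        if d0 + length + flank >= len(seq):
            continue
        s = seq[d0 : d0 + length]
        up = seq[max(d0 - flank, 0) : d0]
        down = seq[d0 + length : d0 + length + flank]
        cls, sub = classify_context(s, up, down)
        if cls == context:
            ref = seq[d0 - 1 : d0 + length]
            return pos, ref, ref[0], cls, sub
    if context == "rep":
        # fall back to an implanted mononucleotide run
        runs = [r for r in reference.mono_runs[chrom] if r[1] >= 2 * length]
        if runs:
            start0, run_len, _base = runs[rng.integers(0, len(runs))]
            d0 = start0 + int(rng.integers(0, run_len - 2 * length + 1))
            s = seq[d0 : d0 + length]
            ref = seq[d0 - 1 : d0 + length]
            return d0, ref, ref[0], "rep", length
    return None


def _place_insertion(
    rng: np.random.Generator,
    config: SimulationConfig,
    reference: ReferenceSet,
    sampler: _PositionSampler,
    chrom: str,
    context: str,
) -> tuple[int, str, str, str, int]:
    """Construct an insertion realizing ``context`` (always placeable)."""
    seq = reference.sequences[chrom]
    length = _draw_indel_length(rng, config, context, is_del=False)
    pos = sampler.draw(rng, chrom)  # anchor, 1-based
    down = seq[pos : pos + max(2 * length, 20)]
    up = seq[max(pos - 2 * length - 20, 0) : pos]
    if context == "rep":
        s = down[:length]
    elif context == "mh":
        m = int(rng.integers(1, length))
        mismatch = str(rng.choice([b for b in "ACGT" if b != down[m]]))
        tail = "".join(rng.choice(list("ACGT"), size=length - m - 1))
        s = down[:m] + mismatch + tail
    else:  # none: defeat homology and full copies on both flanks
        if length == 1:
            s = str(rng.choice([b for b in "ACGT" if b not in (down[0], up[-1])]))
        else:
            first = str(rng.choice([b for b in "ACGT" if b != down[0]]))
            last = str(rng.choice([b for b in "ACGT" if b != up[-1]]))
            middle = "".join(rng.choice(list("ACGT"), size=length - 2))
            s = first + middle + last
    cls, sub = classify_context(s, up, down)
    anchor = seq[pos - 1]
    return pos, anchor, anchor + s, cls, sub


def _make_variant(
    rng: np.random.Generator,
    config: SimulationConfig,
    reference: ReferenceSet,
    sampler: _PositionSampler,
    titv: float,
    snv_indel_ratio: float,
    sample: str,
    truth_sink: Optional[dict] = None,
) -> Variant:
    """Draw one genuine variant with the given spectrum parameters."""
    chroms = config.chrom_names
    weights = np.asarray(config.per_chromosome_weights, dtype=float)
    if sample == "control":
        weights = weights ** config.control_weight_flatten
    weights = weights / weights.sum()
    chrom = chroms[rng.choice(len(chroms), p=weights)]
    seq = reference.sequences[chrom]

    is_snv = rng.random() < snv_indel_ratio / (1.0 + snv_indel_ratio)
    dp, gq, alt_count = _draw_quality(rng, config)
    anns = _draw_annotations(rng, config)
    if is_snv:
        pos = sampler.draw(rng, chrom)
        ref = seq[pos - 1]
        if rng.random() < titv / (1.0 + titv):
            alt = _TI_PARTNER[ref]
        else:
            alt = _TV_PARTNERS[ref][rng.integers(0, 2)]
        return Variant(chrom, pos, ref, alt, dp, gq, alt_count, sample, anns)

    context = ("rep", "mh", "none")[rng.choice(3, p=list(config.context_mix))]
    is_ins = rng.random() < config.insertion_fraction
    for _ in range(5):  # resample the context if placement keeps failing
        if is_ins:
            placed = _place_insertion(rng, config, reference, sampler, chrom, context)
        else:
            placed = _place_deletion(rng, config, reference, sampler, chrom, context)
        if placed is not None:
            break
        logger.warning("context %r unplaceable on %s, resampling", context, chrom)
        context = ("rep", "mh", "none")[rng.choice(3, p=list(config.context_mix))]
    else:
        raise RuntimeError("could not place InDel after repeated resampling")
    pos, ref, alt, realized, sub = placed
    if truth_sink is not None:
        key = ("ins" if is_ins else "del", realized)
        truth_sink[key] = truth_sink.get(key, 0) + 1
        if not is_ins and realized == "none":
            lkey = ("del_none_len", len(ref) - 1)
            truth_sink[lkey] = truth_sink.get(lkey, 0) + 1
    return Variant(chrom, pos, ref, alt, dp, gq, alt_count, sample, anns)


def make_variant_sets(
    config: SimulationConfig,
    reference: ReferenceSet,
    rng: Optional[np.random.Generator] = None,
) -> VariantSets:
    """Generate the control pool and all treated samples.

    Each treated sample of ``n`` variants contains a Binomial(n,
    shared_fraction) draw from the control pool (with per-sample depth and
    quality values) plus treatment-specific variants with the
    radiation-spectrum parameters, plus small extra contingents of
    sequencing-error artifacts (alternate support drawn from the error
    model) and low-DP/GQ calls, which the coverage and binomial filters
    are expected to remove.
    """
    config.validate()
    if rng is None:
        rng = _rng_streams(config.seed, 4)[1]
    sampler = _PositionSampler(config, reference)
    n = config.n_variants_per_sample
    pool_size = config.control_pool_size or n

    control = [
        _make_variant(
            rng, config, reference, sampler,
            config.pre_titv, config.pre_snv_indel_ratio, "control",
        )
        for _ in range(pool_size)
    ]
    control_keys = {v.key for v in control}

    treated: dict[str, list[Variant]] = {}
    truth: dict = {"per_sample": {}}
    for label in config.sample_labels:
        n_shared = int(rng.binomial(n, config.shared_fraction))
        n_specific = n - n_shared
        sample_truth: dict = {"context_counts": {}}
        variants: list[Variant] = []

        for idx in rng.choice(pool_size, size=n_shared, replace=False):
            src = control[int(idx)]
            dp, gq, alt_count = _draw_quality(rng, config)
            variants.append(
                Variant(
                    src.chrom, src.pos, src.ref, src.alt,
                    dp, gq, alt_count, label, src.annotations,
                )
            )

        context_sink: dict = {}
        n_placed = 0
        while n_placed < n_specific:
            v = _make_variant(
                rng, config, reference, sampler,
                config.ir_titv, config.ir_snv_indel_ratio, label, context_sink,
            )
            if v.key in control_keys:  # would defeat the sample filter
                continue
            variants.append(v)
            n_placed += 1

        n_artifact = round(n * config.error_variant_rate)
        for _ in range(n_artifact):
            while True:
                chrom = config.chrom_names[
                    rng.integers(0, len(config.chrom_names))
                ]
                pos = sampler.draw(rng, chrom)
                ref = reference.sequences[chrom][pos - 1]
                alt = _TI_PARTNER[ref] if rng.random() < 0.5 else _TV_PARTNERS[ref][0]
                if (normalize_chrom(chrom), pos, ref, alt) not in control_keys:
                    break
            dp = max(int(rng.poisson(config.dp_mean)), 4)
            alt_count = int(rng.binomial(dp, config.sequencing_error_rate))
            variants.append(
                Variant(chrom, pos, ref, alt, dp, 99, min(alt_count, dp), label,
                        _draw_annotations(rng, config))
            )

        n_lowq = round(n * config.low_quality_rate)
        for _ in range(n_lowq):
            while True:
                chrom = config.chrom_names[
                    rng.integers(0, len(config.chrom_names))
                ]
                pos = sampler.draw(rng, chrom)
                ref = reference.sequences[chrom][pos - 1]
                alt = _TI_PARTNER[ref]
                if (normalize_chrom(chrom), pos, ref, alt) not in control_keys:
                    break
            if rng.random() < 0.5:
                dp, gq = int(rng.integers(0, 3)), 99  # fails DP >= 3
            else:
                dp, gq = max(int(rng.poisson(config.dp_mean)), 4), int(
                    rng.integers(0, 20)
                )  # fails GQ >= 20
            alt_count = min(max(dp // 2, 0), dp)
            variants.append(
                Variant(chrom, pos, ref, alt, dp, gq, alt_count, label,
                        _draw_annotations(rng, config))
            )

        sample_truth.update(
            n_shared=n_shared,
            n_specific=n_specific,
            n_artifact=n_artifact,
            n_low_quality=n_lowq,
            n_total=len(variants),
            context_counts={
                f"{k[0]}.{k[1]}": v
                for k, v in context_sink.items()
                if not isinstance(k[1], int)
            },
            del_none_length_counts={
                str(k[1]): v for k, v in context_sink.items() if k[0] == "del_none_len"
            },
        )
        truth["per_sample"][label] = sample_truth
        treated[label] = variants
    truth["control_pool_size"] = pool_size
    return VariantSets(control=control, treated=treated, truth=truth)


# ---------------------------------------------------------------------------
# translocations


def make_translocations(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> TranslocationSets:
    """Generate control and treated translocation tables with known truth.

    Treated samples contain jittered copies of control events (< 200 nt on
    both breakends) plus novel events placed >= 400 nt from every other
    event on the same chromosome pair, so windowed control subtraction has
    an exact expected answer: the novel events passing the read-support
    and confidence thresholds.
    """
    config.validate()
    if len(config.chrom_lengths) < 2:
        raise ValueError("translocations need at least two chromosomes")
    if rng is None:
        rng = _rng_streams(config.seed, 4)[2]
    chroms = config.chrom_names
    lengths = dict(zip(chroms, config.chrom_lengths))

    def draw_quality():
        reads = int(rng.integers(5, 45))
        conf = float(rng.integers(60, 101))
        return reads, conf

    def draw_event(existing: Sequence[TranslocationCall]) -> TranslocationCall:
        while True:
            i, j = rng.choice(len(chroms), size=2, replace=False)
            a, b = chroms[int(i)], chroms[int(j)]
            pos_a = int(rng.integers(1000, lengths[a] - 1000))
            pos_b = int(rng.integers(1000, lengths[b] - 1000))
            reads, conf = draw_quality()
            cand = TranslocationCall.make(a, pos_a, b, pos_b, reads, conf)
            if all(
                cand.chrom_pair != e.chrom_pair
                or max(abs(cand.pos_a - e.pos_a), abs(cand.pos_b - e.pos_b)) >= 400
                for e in existing
            ):
                return cand

    n = config.n_translocations
    control: list[TranslocationCall] = []
    for _ in range(n):
        control.append(draw_event(control))

    treated: dict[str, list[TranslocationCall]] = {}
    truth: dict = {"per_sample": {}}
    for label in config.sample_labels:
        n_shared = round(n * config.control_translocation_fraction)
        calls: list[TranslocationCall] = []
        for idx in rng.choice(len(control), size=n_shared, replace=False):
            src = control[int(idx)]
            jit_a = int(rng.integers(0, 200)) * (1 if rng.random() < 0.5 else -1)
            jit_b = int(rng.integers(0, 200)) * (1 if rng.random() < 0.5 else -1)
            reads, conf = draw_quality()
            calls.append(
                TranslocationCall.make(
                    src.chrom_a, src.pos_a + jit_a, src.chrom_b, src.pos_b + jit_b,
                    reads, conf, label,
                )
            )
        n_novel = n - n_shared
        n_true = 0
        for _ in range(n_novel):
            ev = draw_event(control + calls)
            if ev.supporting_reads >= 20 and ev.confidence > 80:
                n_true += 1
            calls.append(ev)
        order = rng.permutation(len(calls))
        treated[label] = [calls[int(k)] for k in order]
        truth["per_sample"][label] = {
            "n_shared": n_shared,
            "n_novel": n_novel,
            "n_retained_expected": n_true,
        }
    return TranslocationSets(control=control, treated=treated, truth=truth)


# ---------------------------------------------------------------------------
# gene density & top-level driver


def make_gene_density(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> dict[str, float]:
    """Genes/Mb per chromosome: affine in the chromosome variant weight
    plus Gaussian noise, spanning roughly the 2.6-22.5 genes/Mb range of
    the human genome so the density correlation is moderately positive."""
    if rng is None:
        rng = _rng_streams(config.seed, 4)[3]
    w = np.asarray(config.per_chromosome_weights, dtype=float)
    lo, hi = 2.65, 22.53
    scaled = lo + (hi - lo) * (w - w.min()) / max(w.max() - w.min(), 1e-12)
    noisy = np.clip(scaled + rng.normal(0, config.gene_density_noise, len(w)), 0.5, None)
    return dict(zip(config.chrom_names, noisy.round(2)))


def _write_fasta(sequences: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in sequences.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def simulate(config: SimulationConfig, outdir: str | Path) -> dict:
    """Generate and write the full synthetic input set.

    Emits reference.fa, cytobands.tsv, tads.bed, gene_density.tsv, a
    control VCF, one treated VCF and one translocation table per sample
    label, a control translocation table, and manifest.json recording the
    configuration and all ground-truth quantities.  Returns the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    reference = make_reference(config)
    variant_sets = make_variant_sets(config, reference)
    transloc_sets = make_translocations(config)
    density = make_gene_density(config)

    _write_fasta(reference.sequences, outdir / "reference.fa")
    with open(outdir / "cytobands.tsv", "w") as fh:
        for i, iv in enumerate(reference.bands):
            stain = "gneg" if i % 2 == 0 else "gpos50"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{stain}\n")
    with open(outdir / "tads.bed", "w") as fh:
        for iv in reference.tads:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
    with open(outdir / "gene_density.tsv", "w") as fh:
        for chrom, d in density.items():
            fh.write(f"{chrom}\t{d}\n")

    contigs = reference.chrom_lengths
    io_formats.write_vcf(
        variant_sets.control, outdir / "control.vcf", "control", contigs
    )
    for label, variants in variant_sets.treated.items():
        io_formats.write_vcf(
            variants, outdir / f"treated_{label}.vcf", label, contigs
        )
    io_formats.write_translocation_table(
        transloc_sets.control, outdir / "translocations_control.tsv"
    )
    for label, calls in transloc_sets.treated.items():
        io_formats.write_translocation_table(
            calls, outdir / f"translocations_{label}.tsv"
        )

    manifest = {
        "config": asdict(config),
        "variants": variant_sets.truth,
        "translocations": transloc_sets.truth,
        "gene_density": density,
        "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=list)
    logger.info("synthetic dataset written to %s", outdir)
    return manifest
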