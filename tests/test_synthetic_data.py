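"""Generator: determinism, structural validity, parameter realization,
generator-classifier consistency."""

import math

import numpy as np
import pytest

from irmutscan.core import normalize_chrom
from irmutscan.indel_signatures import classify_indel, signature_context
from irmutscan.synthetic_data import (
    SimulationConfig,
    make_gene_density,
    make_reference,
    make_translocations,
    make_variant_sets,
    simulate,
)


class TestConfigValidation:
    def test_short_chromosome_rejected(self):
        with pytest.raises(ValueError, match="bp"):
            SimulationConfig(chrom_lengths=(10_000,), per_chromosome_weights=(1.0,)).validate()

    def test_weight_length_mismatch(self):
        with pytest.raises(ValueError):
            SimulationConfig(per_chromosome_weights=(1.0, 2.0)).validate()

    def test_fraction_out_of_range(self):
        with pytest.raises(ValueError):
            SimulationConfig(shared_fraction=1.5).validate()

    def test_context_mix_must_sum_to_one(self):
        with pytest.raises(ValueError):
            SimulationConfig(context_mix=(0.5, 0.5, 0.5)).validate()

    def test_single_chromosome_translocations_rejected(self):
        cfg = SimulationConfig(
            chrom_lengths=(200_000,), per_chromosome_weights=(1.0,)
        )
        with pytest.raises(ValueError, match="two chromosomes"):
            make_translocations(cfg)


class TestReference:
    def test_bands_partition_each_chromosome(self, small_config, small_reference):
        for chrom, length in small_reference.chrom_lengths.items():
            bands = [b for b in small_reference.bands if b.chrom == chrom]
            assert bands[0].start == 0 and bands[-1].end == length
            for a, b in zip(bands, bands[1:]):
                assert a.end == b.start
            assert sum(len(b) for b in bands) == length

    def test_tads_inside_bounds_with_gaps(self, small_reference):
        for chrom, length in small_reference.chrom_lengths.items():
            tads = [t for t in small_reference.tads if t.chrom == chrom]
            assert tads, "every chromosome has TADs"
            coverage = sum(len(t) for t in tads) / length
            assert 0.4 < coverage < 0.9
            for t in tads:
                assert 0 <= t.start < t.end <= length
            for a, b in zip(tads, tads[1:]):
                assert a.end < b.start  # gaps between TADs

    def test_mono_runs_present_in_sequence(self, small_reference):
        runs = small_reference.mono_runs["chr1"]
        assert len(runs) > 50
        seq = small_reference.sequences["chr1"]
        for start, length, base in runs[:20]:
            assert seq[start : start + length] == base * length

    def test_deterministic_under_seed(self, small_config):
        a = make_reference(small_config)
        b = make_reference(small_config)
        assert a.sequences == b.sequences
        assert a.tads == b.tads and a.bands == b.bands


class TestVariantSets:
    def test_shared_fraction_realized(self, small_config, small_variant_sets):
        label = small_config.sample_labels[0]
        truth = small_variant_sets.truth["per_sample"][label]
        n = small_config.n_variants_per_sample
        sf = small_config.shared_fraction
        se = math.sqrt(n * sf * (1 - sf))
        assert abs(truth["n_shared"] - n * sf) < 3 * se
        control_keys = {v.key for v in small_variant_sets.control}
        shared = sum(
            1 for v in small_variant_sets.treated[label] if v.key in control_keys
        )
        assert shared == truth["n_shared"]

    def test_snv_ref_matches_reference(self, small_reference, small_variant_sets):
        for v in small_variant_sets.control[:500]:
            kind, _ = classify_indel(v)
            if kind == "SNV":
                seq = small_reference.sequences[v.chrom]
                assert seq[v.pos - 1] == v.ref

    def test_generator_classifier_consistency(
        self, small_config, small_reference, small_variant_sets
    ):
        """Every generated InDel receives a classifier label whose class
        totals equal the generator's recorded ground truth."""
        from collections import Counter

        label = small_config.sample_labels[0]
        truth = small_variant_sets.truth["per_sample"][label]["context_counts"]
        control_keys = {v.key for v in small_variant_sets.control}
        specific = [
            v
            for v in small_variant_sets.treated[label]
            if v.key not in control_keys
        ]
        realized = Counter()
        for v in specific:
            kind, _ = classify_indel(v)
            if kind in ("ins", "del"):
                sig = signature_context(v, small_reference.sequences)
                assert sig is not None
                realized[f"{kind}.{sig.context_class}"] += 1
        assert realized == Counter(truth)

    def test_ir_titv_realized(self, small_config, small_reference, small_variant_sets):
        from irmutscan.filtering import run_filter_chain
        from irmutscan.snv_stats import titv

        label = small_config.sample_labels[0]
        kept, _ = run_filter_chain(
            small_variant_sets.treated[label], small_variant_sets.control
        )
        summary = titv(kept)["genome"]
        n = summary.ti_count + summary.tv_count
        p_expected = small_config.ir_titv / (1 + small_config.ir_titv)
        se = math.sqrt(p_expected * (1 - p_expected) / n)
        assert abs(summary.ti_count / n - p_expected) < 3 * se

    def test_deterministic_vcf_output(self, tmp_path):
        cfg = SimulationConfig(
            seed=3,
            chrom_lengths=(200_000, 200_000),
            per_chromosome_weights=(2.0, 1.0),
            n_variants_per_sample=500,
            sample_labels=("16h_2Gy",),
        )
        m1 = simulate(cfg, tmp_path / "a")
        m2 = simulate(cfg, tmp_path / "b")
        for name in ["reference.fa", "control.vcf", "treated_16h_2Gy.vcf",
                     "translocations_16h_2Gy.tsv", "cytobands.tsv", "tads.bed"]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes(), name
        assert m1["variants"] == m2["variants"]


class TestTranslocationGeneration:
    def test_shared_events_jittered_within_window(self, small_translocations):
        label, calls = next(iter(small_translocations.treated.items()))
        truth = small_translocations.truth["per_sample"][label]
        control = small_translocations.control
        n_within = sum(
            1
            for t in calls
            if any(
                t.chrom_pair == c.chrom_pair
                and abs(t.pos_a - c.pos_a) < 200
                and abs(t.pos_b - c.pos_b) < 200
                for c in control
            )
        )
        assert n_within == truth["n_shared"]

    def test_quality_straddles_thresholds(self, small_translocations):
        calls = small_translocations.control
        assert any(c.supporting_reads < 20 for c in calls)
        assert any(c.supporting_reads >= 20 for c in calls)
        assert any(c.confidence <= 80 for c in calls)
        assert any(c.confidence > 80 for c in calls)


def test_gene_density_affine_in_weights():
    cfg = SimulationConfig(gene_density_noise=0.0)
    d = make_gene_density(cfg)
    w = cfg.per_chromosome_weights
    vals = [d[c] for c in cfg.chrom_names]
    # noiseless density is a positive affine map of the weights
    # (values are rounded to two decimals on output)
    assert vals[0] == max(vals) and vals[-1] == min(vals)
    slopes = np.diff(vals) / np.diff(w)
    np.testing.assert_allclose(slopes, slopes[0], rtol=0.02)


def test_simulate_writes_complete_set(tmp_path):
    cfg = SimulationConfig(
        seed=5,
        chrom_lengths=(150_000, 150_000),
        per_chromosome_weights=(3.0, 1.0),
        n_variants_per_sample=300,
        sample_labels=("16h_2Gy", "7d_10Gy"),
    )
    manifest = simulate(cfg, tmp_path)
    expected = {
        "reference.fa", "cytobands.tsv", "tads.bed", "gene_density.tsv",
        "control.vcf", "treated_16h_2Gy.vcf", "treated_7d_10Gy.vcf",
        "translocations_control.tsv", "translocations_16h_2Gy.tsv",
        "translocations_7d_10Gy.tsv",
    }
    assert expected <= set(manifest["files"])
    # files are readable by the package's own readers
    from pyfaidx import Fasta

    from irmutscan.io_formats import read_intervals, read_vcf

    fasta = Fasta(str(tmp_path / "reference.fa"))
    assert {normalize_chrom(k) for k in fasta.keys()} == {"1", "2"}
    assert len(read_vcf(tmp_path / "control.vcf")) == 300
    assert read_intervals(tmp_path / "tads.bed", kind="tad")
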