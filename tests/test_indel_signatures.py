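"""InDel typing, repeat/microhomology context classification, fold changes."""

import math
from collections import Counter

import pytest
from hypothesis import given
from hypothesis import strategies as st

from irmutscan.core import Variant
from irmutscan.indel_signatures import (
    DEFAULT_LENGTH_CAP,
    IndelSignature,
    SignatureSpectrum,
    category_order,
    classify_context,
    classify_indel,
    fold_change,
    signature_context,
    spectrum,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def oracle_classify(u: str, s: str, d: str) -> tuple[str, int]:
    """Independent string-scanning classifier used as ground truth.

    Checks repeat by literal prefix extraction, then collects every
    homology length on either flank and reports the maximum.
    """
    n = len(s)
    if d[: len(s)] == s and len(d) >= n:
        return "rep", n
    if len(u) >= n and u[len(u) - n :] == s:
        return "rep", n
    hits = []
    for m in range(1, n):
        if m <= len(d) and all(s[i] == d[i] for i in range(m)):
            hits.append(m)
        if m <= len(u) and all(s[n - 1 - i] == u[len(u) - 1 - i] for i in range(m)):
            hits.append(m)
    if hits:
        return "mh", max(hits)
    return "none", n


class TestClassifyIndel:
    @pytest.mark.parametrize(
        "ref,alt,kind,length",
        [
            ("ATTT", "A", "del", 3),
            ("A", "ACG", "ins", 2),
            ("A", "G", "SNV", 1),
            ("AT", "GC", "MNV", 2),
            ("ATT", "AT", "del", 1),
        ],
    )
    def test_length_from_allele_difference(self, ref, alt, kind, length):
        v = Variant("chr1", 100, ref, alt, 60, 99, 30)
        assert classify_indel(v) == (kind, length)


class TestSignatureContext:
    def _del(self, seq, pos, length):
        """Deletion of seq[pos:pos+length] (0-based), VCF anchored at pos."""
        return Variant("c", pos, seq[pos - 1 : pos + length], seq[pos - 1], 60, 99, 30)

    def test_repeat_full_downstream_copy(self):
        #        anchor v  deleted    copy
        seq = "TTTTTTTTTG" + "ACG" + "ACG" + "TCTCTCTCTC"
        sig = signature_context(self._del(seq, 10, 3), {"c": seq})
        assert (sig.context_class, sig.sub_length) == ("rep", 3)

    def test_microhomology_prefix_match(self):
        # deleted TAGC, downstream TAGG... -> bimh 3; upstream has no suffix match
        seq = "TTTTTTTTTG" + "TAGC" + "TAGGCCCCCC"
        sig = signature_context(self._del(seq, 10, 4), {"c": seq})
        assert (sig.context_class, sig.sub_length) == ("mh", 3)

    def test_none_context_single_base(self):
        # deleted T, upstream ...A, downstream G...
        seq = "CCCCCCCCCA" + "T" + "GCCCCCCCCC"
        sig = signature_context(self._del(seq, 10, 1), {"c": seq})
        assert (sig.context_class, sig.sub_length) == ("none", 1)

    def test_mononucleotide_run_is_repeat(self):
        seq = "GCGCGCGCGA" + "T" + "TCGCGCGCGC"  # deleting one T of a TT run
        sig = signature_context(self._del(seq, 10, 1), {"c": seq})
        assert (sig.context_class, sig.sub_length) == ("rep", 1)

    def test_insertion_uses_inserted_sequence(self):
        seq = "GGGGGGGGGA" + "CGT" + "AAAAAAAAAA"
        # insert CGT right after the anchor at pos 10: downstream starts CGT
        v = Variant("c", 10, seq[9], seq[9] + "CGT", 60, 99, 30)
        sig = signature_context(v, {"c": seq})
        assert (sig.indel_type, sig.context_class) == ("ins", "rep")

    def test_unresolved_on_missing_chromosome(self):
        v = Variant("nowhere", 10, "AT", "A", 60, 99, 30)
        assert signature_context(v, {"c": "ACGT" * 10}) is None

    def test_snv_rejected(self):
        with pytest.raises(ValueError):
            signature_context(Variant("c", 5, "A", "G", 60, 99, 30), {"c": "A" * 20})

    @given(st.text(alphabet="ACGT", min_size=8, max_size=8), st.data())
    def test_matches_string_scanning_oracle(self, octamer, data):
        length = data.draw(st.integers(1, 3))
        pos = data.draw(st.integers(1, 8 - length))
        v = self._del(octamer, pos, length)
        sig = signature_context(v, {"c": octamer})
        cls, sub = oracle_classify(
            octamer[:pos], octamer[pos : pos + length], octamer[pos + length :]
        )
        assert (sig.context_class, sig.sub_length) == (cls, sub)

    @given(st.text(alphabet="ACGT", min_size=30, max_size=30), st.data())
    def test_reverse_complement_consistency(self, seq, data):
        """Classifying the mirrored locus yields the same context class."""
        length = data.draw(st.integers(1, 4))
        pos = data.draw(st.integers(2, 30 - length - 2))
        fwd = signature_context(self._del(seq, pos, length), {"c": seq})
        rc = revcomp(seq)
        # deleted block [pos, pos+length) maps to [30-pos-length, 30-pos)
        rc_pos = 30 - pos - length
        rev = signature_context(self._del(rc, rc_pos, length), {"c": rc})
        assert fwd.context_class == rev.context_class
        assert fwd.sub_length == rev.sub_length  # bimh from the mirrored side

    @given(st.text(alphabet="ACGT", min_size=12, max_size=12), st.data())
    def test_partition_property(self, seq, data):
        """Every deletion maps to exactly one class; rep and mh exclusive."""
        length = data.draw(st.integers(1, 3))
        pos = data.draw(st.integers(1, 12 - length))
        s = seq[pos : pos + length]
        u, d = seq[:pos], seq[pos + length :]
        cls, _ = classify_context(s, u, d)
        is_rep = (len(d) >= length and d[:length] == s) or (
            len(u) >= length and u[-length:] == s
        )
        if is_rep:
            assert cls == "rep"
        else:
            assert cls in ("mh", "none")


class TestLabels:
    def test_label_roundtrip(self):
        for sig in [
            IndelSignature("del", "mh", 2),
            IndelSignature("ins", "rep", 3),
            IndelSignature("del", "none", 1),
        ]:
            assert IndelSignature.from_label(sig.label()) == sig

    def test_overflow_bucket(self):
        assert IndelSignature("del", "rep", 7).label(cap=5) == "del.rep.len.5+"
        assert IndelSignature("del", "rep", 5).label(cap=5) == "del.rep.len.5+"
        assert IndelSignature("del", "rep", 4).label(cap=5) == "del.rep.len.4"

    def test_canonical_order_shape(self):
        cats = category_order()
        assert cats[0] == "del.rep.len.1"
        assert cats[-1] == "ins.none.len.5+"
        assert len(cats) == 2 * 3 * DEFAULT_LENGTH_CAP

    def test_mh_requires_bimh_below_length(self):
        with pytest.raises(ValueError):
            IndelSignature("del", "mh", 0)


class TestSpectrum:
    def test_empty_input_zero_spectrum(self):
        spec = spectrum([], {"c": "ACGT" * 10})
        assert spec.total == 0 and not spec.counts

    def test_snv_and_mnv_tallied_separately(self):
        ref = {"c": "ACGTACGTACGTACGTACGTACGTACGT"}
        variants = [
            Variant("c", 5, "A", "G", 60, 99, 30),
            Variant("c", 6, "CG", "GC", 60, 99, 30),
            Variant("c", 10, "GT", "G", 60, 99, 30),
        ]
        spec = spectrum(variants, ref)
        assert (spec.n_snv, spec.n_mnv, spec.total) == (1, 1, 1)

    def test_generator_context_mix_recovered(
        self, small_config, small_reference, small_variant_sets
    ):
        """Realized rep/mh/none proportions match configuration within 3 SE."""
        label, treated = next(iter(small_variant_sets.treated.items()))
        spec = spectrum(treated, small_reference.sequences)
        by_class = Counter()
        for cat, n in spec.counts.items():
            by_class[cat.split(".")[1]] += n
        total = sum(by_class.values())
        assert total > 300
        for cls, expected in zip(("rep", "mh", "none"), small_config.context_mix):
            se = math.sqrt(expected * (1 - expected) / total)
            assert abs(by_class[cls] / total - expected) < 3 * se + 0.01


class TestFoldChange:
    def test_identity_gives_zero(self):
        s = SignatureSpectrum(Counter({"del.rep.len.1": 10}), 10)
        fc, _ = fold_change(s, s)
        assert fc["del.rep.len.1"] == 0.0

    def test_log10_scale(self):
        f = SignatureSpectrum(Counter({"del.rep.len.1": 1}), 1)
        u = SignatureSpectrum(Counter({"del.rep.len.1": 100}), 100)
        fc, _ = fold_change(f, u)
        assert fc["del.rep.len.1"] == pytest.approx(-2.0)

    def test_uniform_retention_closed_form(self):
        """Retaining 2% in every category gives log10(0.02) everywhere."""
        cats = category_order()
        u = SignatureSpectrum(Counter({c: 5000 for c in cats}), 5000 * len(cats))
        f = SignatureSpectrum(Counter({c: 100 for c in cats}), 100 * len(cats))
        fc, avg = fold_change(f, u)
        for c in cats:
            assert fc[c] == pytest.approx(math.log10(0.02), abs=1e-12)
        assert avg["ins"] == pytest.approx(math.log10(0.02), abs=1e-12)
        assert avg["del"] == pytest.approx(math.log10(0.02), abs=1e-12)

    def test_zero_cells_use_pseudocount(self):
        f = SignatureSpectrum(Counter({"del.rep.len.1": 0}), 0)
        u = SignatureSpectrum(Counter({"del.rep.len.1": 50}), 50)
        fc, _ = fold_change(f, u, pseudocount=0.5)
        assert fc["del.rep.len.1"] == pytest.approx(math.log10(0.5 / 50))

    def test_category_absent_in_both_omitted(self):
        f = SignatureSpectrum(Counter({"del.rep.len.1": 5}), 5)
        u = SignatureSpectrum(Counter({"del.rep.len.1": 50}), 50)
        fc, _ = fold_change(f, u)
        assert set(fc) == {"del.rep.len.1"}
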