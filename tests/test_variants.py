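"""Variant normalization, haplotype windows, and set algebra."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somaguide.exceptions import UnknownContigError
from somaguide.io import GenomeSequence, SomaticVariant
from somaguide.simulate import apply_variants
from somaguide.variants import (
    build_haplotype_window,
    flag_multi_variant_windows,
    normalize_variant,
    variant_set_difference,
)

from conftest import random_seq


def _apply(seq: str, v: SomaticVariant) -> str:
    return seq[: v.start] + v.alt + seq[v.end :]


def _equivalent_representations(seq: str, v: SomaticVariant):
    """Brute-force oracle: every (pos, ref, alt) producing the same mutated
    sequence, with allele lengths up to 6."""
    target = _apply(seq, v)
    out = []
    for pos in range(len(seq)):
        for lr in range(1, 7):
            ref = seq[pos : pos + lr]
            if len(ref) < lr:
                continue
            # alt is forced by requiring the flanks outside [pos, pos+lr) to match
            alt = target[pos : len(target) - (len(seq) - pos - lr)]
            if not alt or len(alt) > 6 or ref == alt:
                continue
            cand = SomaticVariant(v.contig, pos, ref, alt)
            if _apply(seq, cand) == target:
                out.append(cand)
    return out


class TestNormalize:
    def test_snv_unchanged(self, small_genome):
        seq = small_genome["chr1"]
        pos = 100
        alt = "ACGT".replace(seq[pos], "")[0]
        v = SomaticVariant("chr1", pos, seq[pos], alt)
        assert normalize_variant(v, small_genome) == v

    def test_repeat_deletion_left_aligned(self):
        # deleting one CA from a CACACACA run: all equivalent encodings must
        # collapse onto the leftmost representation
        seq = "GGT" + "T" + "CACACACA" + "TGGATCGA"
        genome = GenomeSequence({"c": seq})
        right_aligned = SomaticVariant("c", 9, "ACA", "A")  # deletes the last CA
        norm = normalize_variant(right_aligned, genome)
        assert (norm.start, norm.ref, norm.alt) == (3, "TCA", "T")
        # oracle: leftmost minimal equivalent representation
        equivalents = _equivalent_representations(seq, right_aligned)
        # minimal (parsimonious) representations first, then leftmost
        leftmost = min(equivalents, key=lambda x: (len(x.ref) + len(x.alt), x.start))
        assert (norm.start, norm.ref, norm.alt) == (
            leftmost.start, leftmost.ref, leftmost.alt,
        )
        # every equivalent representation normalizes to the same id
        assert {normalize_variant(e, genome).id for e in equivalents} == {norm.id}

    def test_insertion_left_aligned_in_repeat(self):
        seq = "TTGA" + "AGAGAGAG" + "CTTACG"
        genome = GenomeSequence({"c": seq})
        # inserting AG at the right end of the AG run == inserting at the left
        right = SomaticVariant("c", 11, "G", "GAG")
        left = SomaticVariant("c", 3, "A", "AAG")
        assert normalize_variant(right, genome).id == normalize_variant(left, genome).id

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.data())
    def test_idempotent_and_sequence_preserving(self, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        seq = random_seq(rng, 300, gc=0.5)
        genome = GenomeSequence({"c": seq})
        pos = data.draw(st.integers(20, 250))
        kind = data.draw(st.sampled_from(["SNV", "INS", "DEL"]))
        if kind == "SNV":
            v = SomaticVariant("c", pos, seq[pos], "ACGT".replace(seq[pos], "")[0])
        elif kind == "INS":
            ins = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=5))
            v = SomaticVariant("c", pos, seq[pos], seq[pos] + ins)
        else:
            n = data.draw(st.integers(1, 5))
            v = SomaticVariant("c", pos, seq[pos : pos + 1 + n], seq[pos])
        n1 = normalize_variant(v, genome)
        assert normalize_variant(n1, genome) == n1
        assert _apply(seq, n1) == _apply(seq, v)


class TestHaplotypeWindow:
    def test_snv_window_geometry(self, small_genome):
        seq = small_genome["chr1"]
        v = SomaticVariant("chr1", 1000, seq[1000], "ACGT".replace(seq[1000], "")[0])
        w = build_haplotype_window(v, small_genome, W=30)
        assert w.window_start == 970
        assert len(w.normal_seq) == 61
        assert w.tumor_seq != w.normal_seq
        diffs = [i for i, (a, b) in enumerate(zip(w.normal_seq, w.tumor_seq)) if a != b]
        assert diffs == [30]
        assert w.altered_span == (30, 31)
        assert not w.clipped

    def test_insertion_span_covers_inserted_bases(self, small_genome):
        seq = small_genome["chr1"]
        v = SomaticVariant("chr1", 500, seq[500], seq[500] + "CCC")
        w = build_haplotype_window(normalize_variant(v, small_genome), small_genome)
        assert len(w.tumor_seq) == len(w.normal_seq) + 3
        s0, s1 = w.altered_span
        assert s1 - s0 == 3
        assert all(w.offset_map[i] is None for i in range(s0, s1))

    def test_deletion_span_is_junction(self):
        #            0123456789...
        seq = "TTAACGGATCTGACCAGTTAGCAATGCCGTAGCTTACCGGTAACGGATTACAGGCCATTA" * 2
        genome = GenomeSequence({"c": seq})
        v = normalize_variant(SomaticVariant("c", 40, seq[40:43], seq[40]), genome)
        w = build_haplotype_window(v, genome)
        voff = w.variant_offset
        # span = anchor base + first base past the junction; containment rule
        assert w.altered_span == (voff, voff + 2)
        assert w.requires_span_containment
        # tumor sequence: deleted bases absent at the junction
        assert w.tumor_seq == w.normal_seq[: voff + 1] + w.normal_seq[voff + 3 :]

    def test_tumor_reconstruction_invariant(self, small_genome):
        rng = np.random.default_rng(5)
        seq = small_genome["chr1"]
        for _ in range(50):
            pos = int(rng.integers(50, 4900))
            v = SomaticVariant("chr1", pos, seq[pos], "ACGT".replace(seq[pos], "")[0])
            w = build_haplotype_window(v, small_genome)
            voff = w.variant_offset
            rebuilt = (
                w.normal_seq[:voff] + v.alt + w.normal_seq[voff + len(v.ref) :]
            )
            assert rebuilt == w.tumor_seq

    def test_edge_clipping_flagged(self, small_genome):
        seq = small_genome["chr1"]
        v = SomaticVariant("chr1", 5, seq[5], "ACGT".replace(seq[5], "")[0])
        w = build_haplotype_window(v, small_genome)
        assert w.clipped
        assert w.window_start == 0

    def test_unknown_contig_and_small_window_error(self, small_genome):
        v = SomaticVariant("chrX", 100, "A", "G")
        with pytest.raises(UnknownContigError):
            build_haplotype_window(v, small_genome)
        v2 = SomaticVariant("chr1", 100, small_genome["chr1"][100],
                            "ACGT".replace(small_genome["chr1"][100], "")[0])
        with pytest.raises(ValueError, match=">= 23"):
            build_haplotype_window(v2, small_genome, W=10)


class TestSetDifference:
    def test_basic_and_identity(self):
        x = SomaticVariant("c", 10, "A", "G")
        y = SomaticVariant("c", 20, "C", "T")
        assert variant_set_difference([x, y], [y]) == {x.id}
        assert variant_set_difference([x, y], [x, y]) == set()
        assert variant_set_difference([], []) == set()

    def test_equivalent_indel_encodings_collapse(self):
        seq = "GGT" + "T" + "CACACACA" + "TGGATCGA"
        genome = GenomeSequence({"c": seq})
        left = SomaticVariant("c", 3, "TCA", "T")
        right = SomaticVariant("c", 9, "ACA", "A")
        assert _apply(seq, left) == _apply(seq, right)
        assert variant_set_difference([left], [right], genome=genome) == set()


def test_flag_multi_variant_windows():
    a = SomaticVariant("c", 100, "A", "G")
    b = SomaticVariant("c", 120, "C", "T")
    far = SomaticVariant("c", 500, "G", "A")
    flagged = flag_multi_variant_windows([a, b, far], window=30)
    assert flagged == {a.id, b.id}
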