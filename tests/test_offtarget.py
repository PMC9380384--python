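"""Off-target search: brute-force oracle, k-mer index, and the reject filter."""

import numpy as np
import pytest

from somaguide.io import GenomeSequence, SomaticVariant, reverse_complement
from somaguide.nomination import nominate_candidates
from somaguide.offtarget import (
    FilterPolicy,
    GenomeIndex,
    find_matches_bruteforce,
    find_matches_indexed,
    genome_specificity_filter,
)
from somaguide.specificity import SpecificityClass, classify_candidate
from somaguide.variants import build_haplotype_window

from conftest import random_seq

GUIDE = "ATGCATGCATGCATGCATGC"


def _plant(rng, length: int, guide: str, pam: str, at: int) -> GenomeSequence:
    seq = list(random_seq(rng, length, gc=0.25))
    seq[at : at + 20] = list(guide)
    seq[at + 20 : at + 23] = list(pam)
    return GenomeSequence({"g": "".join(seq)})


class TestBruteForce:
    def test_planted_guide_exact_hit(self):
        rng = np.random.default_rng(42)
        genome = _plant(rng, 100_000, GUIDE, "TGG", 50_000)
        hits = [h for h in find_matches_bruteforce(GUIDE, genome, 0) if h.mismatches == 0]
        exact_here = [h for h in hits if h.start == 50_000]
        assert exact_here and exact_here[0].strand == "+"
        assert exact_here[0].pam_observed == "TGG"
        assert exact_here[0].pam_class == "NGG"

    def test_invalid_pam_gives_no_hit(self):
        rng = np.random.default_rng(42)
        genome = _plant(rng, 50_000, GUIDE, "TTT", 25_000)
        assert all(h.start != 25_000 for h in find_matches_bruteforce(GUIDE, genome, 0))

    def test_reverse_complement_genome_mirrors_hits(self):
        rng = np.random.default_rng(7)
        genome = _plant(rng, 20_000, GUIDE, "AGG", 9_000)
        L = genome.length("g")
        fwd = find_matches_bruteforce(GUIDE, genome, 2)
        rc = find_matches_bruteforce(GUIDE, genome.reverse_complement(), 2)
        mirrored = {
            (h.contig, L - h.start - 20, {"+": "-", "-": "+"}[h.strand], h.mismatches)
            for h in rc
        }
        assert {(h.contig, h.start, h.strand, h.mismatches) for h in fwd} == mirrored

    def test_nag_pam_only_with_permissive_set(self):
        rng = np.random.default_rng(13)
        genome = _plant(rng, 30_000, GUIDE, "CAG", 12_000)
        ngg_only = find_matches_bruteforce(GUIDE, genome, 0, pam_set={"NGG"})
        both = find_matches_bruteforce(GUIDE, genome, 0, pam_set={"NGG", "NAG"})
        assert all(h.start != 12_000 for h in ngg_only)
        assert any(h.start == 12_000 and h.pam_class == "NAG" for h in both)


class TestIndexedEquivalence:
    @pytest.mark.parametrize("max_mm", [0, 1, 2, 3])
    def test_matches_bruteforce_on_random_guides(self, midsize_genome, max_mm):
        rng = np.random.default_rng(max_mm)
        index = GenomeIndex(midsize_genome)
        seq = midsize_genome["chr1"]
        for _ in range(15):
            pos = int(rng.integers(0, len(seq) - 23))
            guide = seq[pos : pos + 20]
            brute = find_matches_bruteforce(guide, midsize_genome, max_mm)
            indexed = find_matches_indexed(guide, index, max_mm)
            assert brute == indexed

    def test_exact_matches_equal_substring_search(self, midsize_genome):
        rng = np.random.default_rng(8)
        seq = midsize_genome["chr2"]
        pos = int(rng.integers(0, len(seq) - 23))
        guide = seq[pos : pos + 20]
        hits = find_matches_indexed(guide, midsize_genome, 0)
        # oracle: scan both strands for verbatim occurrences with a valid PAM
        expected = set()
        for contig, s in midsize_genome.items():
            start = s.find(guide)
            while start != -1:
                pam = s[start + 20 : start + 23]
                if len(pam) == 3 and pam[1:] in ("GG", "AG"):
                    expected.add((contig, start, "+"))
                start = s.find(guide, start + 1)
            rc = reverse_complement(guide)
            start = s.find(rc)
            while start != -1:
                if start >= 3 and reverse_complement(s[start - 3 : start])[1:] in ("GG", "AG"):
                    expected.add((contig, start, "-"))
                start = s.find(rc, start + 1)
        assert {(h.contig, h.start, h.strand) for h in hits} == expected

    def test_empty_region_genome(self):
        tiny = GenomeSequence({"t": "ACGTACGTACGT"})  # shorter than one frame
        assert find_matches_indexed(GUIDE, tiny, 1) == []
        assert find_matches_bruteforce(GUIDE, tiny, 1) == []

    def test_hit_count_monotone_in_mm_and_pam_set(self, midsize_genome):
        index = GenomeIndex(midsize_genome)
        seq = midsize_genome["chr1"]
        guide = seq[1000:1020]
        prev: set = set()
        for mm in range(4):
            hits = set(find_matches_indexed(guide, index, mm))
            assert prev <= hits
            prev = hits
        ngg = set(find_matches_indexed(guide, index, 2, pam_set={"NGG"}))
        both = set(find_matches_indexed(guide, index, 2, pam_set={"NGG", "NAG"}))
        assert ngg <= both


class TestFilter:
    def _pam_gain_case(self, extra_copy_pam=None):
        """PAM-gain window, optionally with a verbatim protospacer copy
        (with the given PAM) planted elsewhere in the genome."""
        rng = np.random.default_rng(31)
        flank_l = random_seq(rng, 3000, gc=0.25)
        flank_r = random_seq(rng, 96_000, gc=0.25)
        seq = flank_l + GUIDE + "AAG" + flank_r
        pos = 3000 + 21
        if extra_copy_pam is not None:
            seq = seq[:50_000] + GUIDE + extra_copy_pam + seq[50_023:]
        genome = GenomeSequence({"g": seq})
        assert genome["g"][pos] == "A"
        v = SomaticVariant("g", pos, "A", "G")
        w = build_haplotype_window(v, genome)
        cands = [c for c in nominate_candidates(w) if c.strand == "+" and c.pam == "AGG"]
        assert cands
        call = classify_candidate(cands[0], w)
        assert call.specificity_class is SpecificityClass.PAM_GAIN
        return cands[0], call, genome

    def test_unique_guide_passes_with_native_reported_separately(self):
        cand, call, genome = self._pam_gain_case()
        res = genome_specificity_filter(cand, call, genome)
        assert res.passed
        # PAM-gain guide: native reference locus has no NGG, so at most a
        # permissive NAG native hit; never counted as an off-target
        assert all(h.pam_class != "NGG" for h in res.native_hits)
        assert all(h.mismatches > 0 for h in res.hits)

    def test_verbatim_copy_elsewhere_rejects(self):
        cand, call, genome = self._pam_gain_case(extra_copy_pam="AGG")
        res = genome_specificity_filter(cand, call, genome)
        assert not res.passed
        assert any(h.mismatches == 0 and h.start == 50_000 for h in res.hits)

    def test_report_counts_match_bruteforce(self, midsize_genome):
        rng = np.random.default_rng(77)
        seq = midsize_genome["chr1"]
        pos = int(rng.integers(100, 50_000))
        v = SomaticVariant("chr1", pos, seq[pos], "ACGT".replace(seq[pos], "")[0])
        w = build_haplotype_window(v, midsize_genome)
        policy = FilterPolicy(report_mm=3)
        for cand in nominate_candidates(w):
            call = classify_candidate(cand, w)
            res = genome_specificity_filter(cand, call, midsize_genome, policy)
            brute = find_matches_bruteforce(cand.protospacer, midsize_genome, 3)
            brute_far = [
                h for h in brute
                if not (h.contig == "chr1" and abs(h.start - pos) <= 50)
            ]
            assert sorted(res.hits) == sorted(brute_far)

    def test_call_candidate_mismatch_errors(self):
        cand, call, genome = self._pam_gain_case()
        other = call.__class__(
            candidate_id="someone:else|+-1",
            specificity_class=call.specificity_class,
            normal_mismatch_positions=call.normal_mismatch_positions,
            normal_pam_intact=call.normal_pam_intact,
        )
        with pytest.raises(ValueError, match="does not belong"):
            genome_specificity_filter(cand, other, genome)
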