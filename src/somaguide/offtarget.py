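"""Mismatch-tolerant search of the normal genome for guide matches.

Two independent routes return identical hit sets:

* :func:`find_matches_bruteforce` — exhaustive by construction: every
  20-mer frame on both strands is Hamming-compared against the guide
  (vectorized over contig-length windows).
* :func:`find_matches_indexed` — pigeonhole k-mer index: a 20-mer with at
  most ``max_mm`` mismatches against the guide must contain at least one
  exact chunk when the guide is split into ``max_mm + 1`` pieces; chunk
  lookups give candidate loci that are then verified exactly.

Matching is gap-free (Hamming); bulge off-targets are out of scope.  NAG
is accepted as a permissive off-target PAM alongside NGG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .io import GenomeSequence, reverse_complement
from .nomination import FRAME_LEN, PROTOSPACER_LEN, GuideCandidate
from .specificity import SpecificityCall

log = logging.getLogger(__name__)

DEFAULT_PAM_SET = frozenset({"NGG", "NAG"})

_PAM_CLASS = {"GG": "NGG", "AG": "NAG"}
_N = ord("N")
_MAX_CHUNK = 10  # caps k-mer index memory; pigeonhole still holds with extra chunks


@dataclass(frozen=True, order=True)
class OffTargetHit:
    """A genomic locus matching a protospacer within the mismatch budget.

    ``start`` is the 0-based protospacer start on the reference (the
    protospacer occupies ``[start, start + 20)`` regardless of strand);
    ``pam_observed`` is read in hit-strand orientation.
    """

    contig: str
    start: int
    strand: str
    mismatches: int
    pam_observed: str
    pam_class: str


def _pam_class(p2: str, p3: str) -> Optional[str]:
    return _PAM_CLASS.get(p2 + p3)


def _check_query(protospacer: str, max_mm: int) -> None:
    if len(protospacer) != PROTOSPACER_LEN or any(
        c not in "ACGT" for c in protospacer
    ):
        raise ValueError(f"protospacer must be 20 nt over ACGT: {protospacer!r}")
    if not 0 <= max_mm <= 6:
        raise ValueError(f"max_mm must be in 0..6, got {max_mm}")


def _brute_one_strand(
    protospacer: str,
    contig: str,
    seq: str,
    strand: str,
    max_mm: int,
    pam_set: frozenset[str],
) -> list[OffTargetHit]:
    L = len(seq)
    if L < FRAME_LEN:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    q = np.frombuffer(protospacer.encode(), dtype=np.uint8)
    frames = sliding_window_view(arr, FRAME_LEN)
    mm = (frames[:, :PROTOSPACER_LEN] != q).sum(axis=1)
    has_n = (frames == _N).any(axis=1)
    pam_ok = np.zeros(len(frames), dtype=bool)
    if "NGG" in pam_set:
        pam_ok |= (frames[:, 21] == ord("G")) & (frames[:, 22] == ord("G"))
    if "NAG" in pam_set:
        pam_ok |= (frames[:, 21] == ord("A")) & (frames[:, 22] == ord("G"))
    hits = []
    for i in np.nonzero((mm <= max_mm) & pam_ok & ~has_n)[0]:
        i = int(i)
        pam = seq[i + 20 : i + 23]
        start = i if strand == "+" else L - i - PROTOSPACER_LEN
        hits.append(
            OffTargetHit(contig, start, strand, int(mm[i]), pam, _pam_class(pam[1], pam[2]))
        )
    return hits


def find_matches_bruteforce(
    protospacer: str,
    genome: GenomeSequence,
    max_mm: int,
    pam_set: Iterable[str] = DEFAULT_PAM_SET,
) -> list[OffTargetHit]:
    """Exhaustively scan both strands of the genome for guide matches."""
    _check_query(protospacer, max_mm)
    pam_set = frozenset(pam_set)
    hits: list[OffTargetHit] = []
    for contig, seq in genome.items():
        hits.extend(_brute_one_strand(protospacer, contig, seq, "+", max_mm, pam_set))
        hits.extend(
            _brute_one_strand(
                protospacer, contig, reverse_complement(seq), "-", max_mm, pam_set
            )
        )
    return sorted(hits)


def _chunk_layout(max_mm: int) -> list[tuple[int, int]]:
    """(offset, length) chunks of the 20-mer for the pigeonhole lookup."""
    n = max(2, max_mm + 1)
    while PROTOSPACER_LEN // n > _MAX_CHUNK:  # pragma: no cover - n>=2 suffices
        n += 1
    base, extra = divmod(PROTOSPACER_LEN, n)
    layout, off = [], 0
    for i in range(n):
        size = base + (1 if i < extra else 0)
        layout.append((off, size))
        off += size
    return layout


class GenomeIndex:
    """Exact k-mer position index over a genome, built lazily per k.

    Only the forward strand is indexed; minus-strand queries are handled by
    looking up the reverse-complemented protospacer.
    """

    def __init__(self, genome: GenomeSequence):
        self.genome = genome
        self._indexes: dict[int, dict[str, list[tuple[str, int]]]] = {}

    def kmer_positions(self, k: int) -> dict[str, list[tuple[str, int]]]:
        if k not in self._indexes:
            index: dict[str, list[tuple[str, int]]] = {}
            for contig, seq in self.genome.items():
                clean = "N" not in seq
                for i in range(len(seq) - k + 1):
                    km = seq[i : i + k]
                    if not clean and "N" in km:
                        continue
                    index.setdefault(km, []).append((contig, i))
            self._indexes[k] = index
        return self._indexes[k]


def _hamming20(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def find_matches_indexed(
    protospacer: str,
    genome_index: GenomeIndex | GenomeSequence,
    max_mm: int,
    pam_set: Iterable[str] = DEFAULT_PAM_SET,
) -> list[OffTargetHit]:
    """Pigeonhole k-mer search; identical hit set to the brute-force scan."""
    _check_query(protospacer, max_mm)
    pam_set = frozenset(pam_set)
    if isinstance(genome_index, GenomeSequence):
        genome_index = GenomeIndex(genome_index)
    genome = genome_index.genome
    layout = _chunk_layout(max_mm)
    hits: set[OffTargetHit] = set()
    for strand in "+-":
        query = protospacer if strand == "+" else reverse_complement(protospacer)
        candidates: set[tuple[str, int]] = set()
        for off, size in layout:
            positions = genome_index.kmer_positions(size)
            for contig, p in positions.get(query[off : off + size], ()):
                candidates.add((contig, p - off))
        for contig, start in candidates:
            seq = genome[contig]
            if strand == "+":
                if start < 0 or start + FRAME_LEN > len(seq):
                    continue
                frame = seq[start : start + FRAME_LEN]
                pam = frame[20:]
            else:
                if start < 3 or start + PROTOSPACER_LEN > len(seq):
                    continue
                frame = seq[start - 3 : start + PROTOSPACER_LEN]
                pam = reverse_complement(frame[:3])
            if "N" in frame:
                continue
            mm = _hamming20(seq[start : start + PROTOSPACER_LEN], query)
            if mm > max_mm:
                continue
            cls = _pam_class(pam[1], pam[2])
            if cls not in pam_set:
                continue
            hits.add(OffTargetHit(contig, start, strand, mm, pam, cls))
    return sorted(hits)


@dataclass(frozen=True)
class FilterPolicy:
    """Knobs of the normal-genome specificity filter.

    ``reject_mm`` — a hit at or below this many mismatches outside the
    native locus rejects the guide (default 0: only perfect normal-genome
    matches reject).  ``report_mm`` — hits up to this budget are returned
    for ranking.  ``native_exclusion_radius`` — hits within this many bases
    of the variant's own locus are the allele-specificity question, not
    off-targets, and are reported separately.
    """

    reject_mm: int = 0
    report_mm: int = 3
    pam_set: frozenset[str] = DEFAULT_PAM_SET
    native_exclusion_radius: int = 50


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    hits: tuple[OffTargetHit, ...]
    native_hits: tuple[OffTargetHit, ...]

    @property
    def native_hit_excluded(self) -> bool:
        return bool(self.native_hits)


def genome_specificity_filter(
    candidate: GuideCandidate,
    call: SpecificityCall | None,
    genome_index: GenomeIndex | GenomeSequence,
    policy: FilterPolicy = FilterPolicy(),
) -> FilterResult:
    """Search the normal genome for the guide and apply the reject policy.

    The native normal locus (e.g. the 1-mismatch match a seed-SNV guide has
    at its own variant site) is excluded from rejection and returned
    separately.
    """
    if call is not None and call.candidate_id != candidate.guide_id:
        raise ValueError(
            f"specificity call {call.candidate_id} does not belong to "
            f"candidate {candidate.guide_id}"
        )
    search_mm = max(policy.report_mm, policy.reject_mm)
    all_hits = find_matches_indexed(
        candidate.protospacer, genome_index, search_mm, policy.pam_set
    )
    native, rest = [], []
    for h in all_hits:
        is_native = (
            h.contig == candidate.contig
            and abs(h.start - candidate.variant_start)
            <= policy.native_exclusion_radius
        )
        (native if is_native else rest).append(h)
    passed = all(h.mismatches > policy.reject_mm for h in rest)
    reported = tuple(h for h in rest if h.mismatches <= policy.report_mm)
    native_reported = tuple(h for h in native if h.mismatches <= policy.report_mm)
    return FilterResult(passed, reported, native_reported)
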