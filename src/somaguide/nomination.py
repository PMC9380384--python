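"""Enumerate SpCas9 protospacer+PAM candidates overlapping a somatic variant.

Geometry conventions, fixed once here:

* A candidate *frame* is 23 nt of tumor-window sequence: 20-nt protospacer
  plus 3-nt NGG PAM.  Forward frames carry the PAM at the 3' end
  (``frame[20:23]``); reverse frames start with the PAM complement
  (``CCN`` at ``frame[0:3]``) and the protospacer is read off the minus
  strand.
* Protospacer positions are numbered PAM-proximally 1..20 (1 adjacent to
  the PAM), the convention in which Cas9 seed-region rules are stated.
  PAM positions are encoded 21..23 for P1..P3 (P1 = the free N).
* The blunt cut falls between protospacer positions 3 and 4 from the PAM;
  ``genomic_cut_pos`` is the reference base immediately 5' (reference
  orientation) of that cut, so the BED interval is ``[cut, cut + 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .io import reverse_complement
from .variants import HaplotypeWindow

FRAME_LEN = 23
PROTOSPACER_LEN = 20


def pam_proximal_position(rel: int, strand: str) -> int:
    """Map a frame-relative index 0..22 to PAM-proximal numbering.

    Returns 1..20 for protospacer positions and 21..23 for PAM P1..P3.
    """
    if not 0 <= rel < FRAME_LEN:
        raise ValueError(f"frame-relative index out of range: {rel}")
    if strand == "+":
        return PROTOSPACER_LEN - rel if rel < PROTOSPACER_LEN else rel + 1
    return rel - 2 if rel >= 3 else 23 - rel


def format_position(p: int) -> str:
    """Render a PAM-proximal position: ``'7'`` or ``'P2'``."""
    return f"P{p - 20}" if p > PROTOSPACER_LEN else str(p)


@dataclass(frozen=True)
class GuideCandidate:
    """A 20-nt protospacer + NGG PAM on the tumor haplotype of one variant."""

    variant_id: str
    contig: str
    variant_start: int
    protospacer: str
    pam: str
    strand: str
    frame_start: int
    genomic_cut_pos: Optional[int]
    variant_positions: tuple[int, ...]

    @property
    def tumor_offset(self) -> int:
        """0-based start of the protospacer within ``tumor_seq``."""
        return self.frame_start if self.strand == "+" else self.frame_start + 3

    @property
    def within_insertion(self) -> bool:
        """True when the cut falls inside inserted, tumor-only sequence."""
        return self.genomic_cut_pos is None

    @property
    def guide_id(self) -> str:
        return f"{self.variant_id}|{self.strand}{self.tumor_offset}"


def scan_pam_sites(seq: str) -> list[tuple[int, str]]:
    """All 23-nt frames in ``seq`` with a valid SpCas9 PAM, both strands.

    Returns ``(frame_start, strand)`` pairs sorted by frame start then
    strand ('+' before '-').  Forward frames require ``GG`` at frame
    positions 21-22; reverse frames require ``CC`` at positions 0-1.
    Frames containing ``N`` are excluded.
    """
    hits: list[tuple[int, str]] = []
    for s in range(len(seq) - FRAME_LEN + 1):
        frame = seq[s : s + FRAME_LEN]
        if "N" in frame:
            continue
        if frame[21] == "G" and frame[22] == "G":
            hits.append((s, "+"))
        if frame[0] == "C" and frame[1] == "C":
            hits.append((s, "-"))
    return hits


def nominate_candidates(window: HaplotypeWindow) -> list[GuideCandidate]:
    """All candidate frames on the tumor haplotype that overlap the variant.

    A frame overlaps when it intersects the altered span; for deletions it
    must contain the whole junction span (a frame touching only one side of
    the junction reads sequence present in the normal genome).
    """
    span0, span1 = window.altered_span
    tumor = window.tumor_seq
    out: list[GuideCandidate] = []
    for s, strand in scan_pam_sites(tumor):
        e = s + FRAME_LEN
        if window.requires_span_containment:
            if not (s <= span0 and e >= span1):
                continue
        elif not (s < span1 and e > span0):
            continue
        frame = tumor[s:e]
        if strand == "+":
            protospacer, pam = frame[:PROTOSPACER_LEN], frame[PROTOSPACER_LEN:]
            cut_left = s + 16
        else:
            protospacer = reverse_complement(frame[3:])
            pam = reverse_complement(frame[:3])
            cut_left = s + 5
        positions = tuple(
            sorted(
                pam_proximal_position(t - s, strand)
                for t in range(max(s, span0), min(e, span1))
            )
        )
        out.append(
            GuideCandidate(
                variant_id=window.variant.id,
                contig=window.contig,
                variant_start=window.variant.start,
                protospacer=protospacer,
                pam=pam,
                strand=strand,
                frame_start=s,
                genomic_cut_pos=window.offset_map[cut_left],
                variant_positions=positions,
            )
        )
    return out
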