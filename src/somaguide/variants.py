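"""Variant normalization and paired normal/tumor haplotype windows.

Allele-specific guide design works on a local window around each somatic
variant: the normal (reference) sequence and the tumor sequence with the
variant applied, plus an offset map taking tumor-window positions back to
genomic coordinates (or to "inserted" for tumor-only bases).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .exceptions import UnknownContigError
from .io import GenomeSequence, SomaticVariant, check_ref

#: Minimum window half-width: a 20-nt protospacer + 3-nt PAM must fit.
MIN_WINDOW = 23


def normalize_variant(v: SomaticVariant, genome: GenomeSequence) -> SomaticVariant:
    """Left-align and parsimony-trim a variant (VCF normalization).

    Shared trailing bases are removed (extending left through the genome when
    an allele would otherwise empty, which left-aligns indels in repeats),
    then shared leading bases are removed keeping the single VCF anchor base.
    SNVs pass through unchanged; the operation is idempotent and maps every
    equivalent representation of an indel to one canonical form.
    """
    check_ref(v, genome)
    seq = genome[v.contig]
    start, ref, alt = v.start, v.ref, v.alt
    while ref[-1] == alt[-1]:
        if len(ref) == 1 or len(alt) == 1:
            if start == 0:
                break
            start -= 1
            ref = seq[start] + ref
            alt = seq[start] + alt
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        start += 1
    if (start, ref, alt) == (v.start, v.ref, v.alt):
        return v
    return SomaticVariant(v.contig, start, ref, alt)


def variant_set_difference(
    a: Iterable[SomaticVariant],
    b: Iterable[SomaticVariant],
    genome: GenomeSequence | None = None,
) -> set[str]:
    """Canonical ids of variants in ``a`` absent from ``b``.

    When a genome is supplied both sets are normalized first, so equivalent
    indel representations collapse to the same id before the set difference.
    """
    if genome is not None:
        a = (normalize_variant(v, genome) for v in a)
        b = (normalize_variant(v, genome) for v in b)
    ids_b = {v.id for v in b}
    return {v.id for v in a} - ids_b


def flag_multi_variant_windows(
    variants: Sequence[SomaticVariant], window: int = 30
) -> set[str]:
    """Ids of variants with another variant inside their design window.

    Phase is unknown from a plain VCF, so co-occurring nearby variants are
    flagged rather than co-applied; flagged windows still use one variant.
    """
    flagged: set[str] = set()
    by_contig: dict[str, list[SomaticVariant]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)
    for contig_variants in by_contig.values():
        contig_variants.sort(key=lambda v: v.start)
        for prev, cur in zip(contig_variants, contig_variants[1:]):
            if cur.start - prev.end < window:
                flagged.add(prev.id)
                flagged.add(cur.id)
    return flagged


@dataclass(frozen=True)
class CloneVariantSet:
    """The identifier set of mutations carried by one clone/sample."""

    label: str
    ids: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "ids", frozenset(self.ids))

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class HaplotypeWindow:
    """Paired normal/tumor local sequences around one somatic variant.

    ``altered_span`` is a 0-based half-open interval in ``tumor_seq``
    coordinates covering the tumor-specific sequence feature: the substituted
    base(s) for SNV/MNV, the inserted bases for an insertion, and for a
    deletion the two bases flanking the novel junction.  For deletions a
    guide frame must *contain* the whole span (span the junction) to count
    as overlapping; for all other classes intersection suffices.

    ``offset_map[i]`` is the genomic position of tumor base ``i``, or
    ``None`` for bases that exist only on the tumor haplotype (insertions).
    """

    variant: SomaticVariant
    contig: str
    window_start: int
    normal_seq: str
    tumor_seq: str
    altered_span: tuple[int, int]
    offset_map: tuple[Optional[int], ...]
    clipped: bool = False

    @property
    def variant_offset(self) -> int:
        """Index of the first REF base within ``normal_seq``."""
        return self.variant.start - self.window_start

    @property
    def requires_span_containment(self) -> bool:
        """Deletions discriminate only via the junction: frames must span it."""
        return self.variant.vclass == "DEL"


def build_haplotype_window(
    v: SomaticVariant, genome: GenomeSequence, W: int = 30
) -> HaplotypeWindow:
    """Construct the paired normal/tumor window of half-width ``W`` around ``v``.

    ``W`` must be at least 23 so every protospacer+PAM frame overlapping the
    altered span fits inside the window.  Windows are clipped at contig
    edges with ``clipped`` set.
    """
    if W < MIN_WINDOW:
        raise ValueError(f"W must be >= {MIN_WINDOW}, got {W}")
    if v.contig not in genome:
        raise UnknownContigError(f"{v.id}: contig {v.contig!r} not in genome")
    check_ref(v, genome)
    seq = genome[v.contig]
    left = max(0, v.start - W)
    right = min(len(seq), v.end + W)
    clipped = left != v.start - W or right != v.end + W
    normal = seq[left:right]
    voff = v.start - left
    tumor = normal[:voff] + v.alt + normal[voff + len(v.ref) :]

    nref, nalt = len(v.ref), len(v.alt)
    offset_map: list[Optional[int]] = list(range(left, left + voff))
    for i in range(nalt):
        offset_map.append(left + voff + i if i < nref else None)
    offset_map.extend(range(left + voff + nref, right))
    assert len(offset_map) == len(tumor)

    vclass = v.vclass
    if vclass == "SNV":
        span = (voff, voff + 1)
    elif vclass == "MNV":
        span = (voff, voff + nalt)
    elif vclass == "INS":
        span = (voff + nref, voff + nalt)
    else:  # DEL: last anchor base + first base past the junction
        span = (voff + nalt - 1, min(voff + nalt + 1, len(tumor)))

    return HaplotypeWindow(
        variant=v,
        contig=v.contig,
        window_start=left,
        normal_seq=normal,
        tumor_seq=tumor,
        altered_span=span,
        offset_map=tuple(offset_map),
        clipped=clipped,
    )
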