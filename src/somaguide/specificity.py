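"""Classify candidates by predicted tumor-vs-normal allele discrimination.

A guide discriminates when Cas9 should cut the tumor allele but not the
normal allele at the native locus.  Three mechanisms, in order of
mechanistic strength:

* **PAM_GAIN** — the somatic change creates the NGG; the normal allele has
  no PAM at that frame/strand, so Cas9 cannot engage it at all.
* **INDEL_DISRUPTING** — an insertion or deletion shifts the register of
  the protospacer against the normal allele (unbounded mismatches).
* **SEED_DISCRIMINATING** — an SNV/MNV places >=1 mismatch against the
  normal allele within the PAM-proximal seed (positions 1..seed_len),
  where single mismatches most strongly abolish cutting.

Everything else is **NON_DISCRIMINATING**: the guide would cut both
alleles (e.g. a PAM-distal SNV) and is excluded from panels.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional

from .io import reverse_complement
from .nomination import FRAME_LEN, GuideCandidate, pam_proximal_position
from .variants import HaplotypeWindow

DEFAULT_SEED_LEN = 12


class SpecificityClass(str, enum.Enum):
    PAM_GAIN = "PAM_GAIN"
    INDEL_DISRUPTING = "INDEL_DISRUPTING"
    SEED_DISCRIMINATING = "SEED_DISCRIMINATING"
    NON_DISCRIMINATING = "NON_DISCRIMINATING"


#: Classes accepted as allele-discriminating under the default policy.
DISCRIMINATING_CLASSES = frozenset(
    {
        SpecificityClass.PAM_GAIN,
        SpecificityClass.INDEL_DISRUPTING,
        SpecificityClass.SEED_DISCRIMINATING,
    }
)

#: Strict mode keeps only the two mechanistically safest classes.
STRICT_CLASSES = frozenset(
    {SpecificityClass.PAM_GAIN, SpecificityClass.INDEL_DISRUPTING}
)


def accepted_classes(strict: bool = False) -> frozenset[SpecificityClass]:
    return STRICT_CLASSES if strict else DISCRIMINATING_CLASSES


@dataclass(frozen=True)
class NativeAlignment:
    """Gap-free alignment of a guide frame to the normal allele.

    ``mismatch_positions`` lists protospacer positions (PAM-proximal
    numbering) where the guide differs from the normal allele; PAM-level
    differences are carried by ``normal_pam_intact``.  For indels the frame
    is register-shifted against the normal allele and per-position
    mismatches are meaningless: ``mismatch_positions`` is None and
    ``frame_shifted`` is set (an unbounded-mismatch sentinel).
    """

    mismatch_positions: Optional[tuple[int, ...]]
    normal_pam_intact: bool
    frame_shifted: bool

    @property
    def n_mismatches(self) -> float:
        if self.frame_shifted:
            return float("inf")
        return float(len(self.mismatch_positions))


@dataclass(frozen=True)
class SpecificityCall:
    candidate_id: str
    specificity_class: SpecificityClass
    normal_mismatch_positions: Optional[tuple[int, ...]]
    normal_pam_intact: bool


def _check_pairing(candidate: GuideCandidate, window: HaplotypeWindow) -> None:
    if candidate.variant_id != window.variant.id:
        raise ValueError(
            f"candidate {candidate.guide_id} was not nominated from window "
            f"of {window.variant.id}"
        )


def native_locus_mismatches(
    candidate: GuideCandidate, window: HaplotypeWindow
) -> NativeAlignment:
    """Align the guide frame to the normal allele at the native locus.

    The normal-allele PAM is intact iff all three PAM positions map through
    the offset map to consecutive genomic bases carrying GG at P2-P3 (the
    free N never discriminates).  An indel inside the PAM frame therefore
    breaks the PAM.
    """
    _check_pairing(candidate, window)
    s, strand = candidate.frame_start, candidate.strand
    pam_idx = range(s + 20, s + 23) if strand == "+" else range(s, s + 3)
    mapped = [window.offset_map[t] for t in pam_idx]
    intact = (
        all(g is not None for g in mapped)
        and mapped[1] == mapped[0] + 1
        and mapped[2] == mapped[1] + 1
    )
    if intact:
        normal_pam = "".join(
            window.normal_seq[g - window.window_start] for g in mapped
        )
        if strand == "-":
            normal_pam = reverse_complement(normal_pam)
        intact = normal_pam[1:] == "GG"

    if window.variant.vclass in ("INS", "DEL"):
        return NativeAlignment(None, intact, True)

    proto_idx = range(s, s + 20) if strand == "+" else range(s + 3, s + FRAME_LEN)
    mismatches = [
        pam_proximal_position(t - s, strand)
        for t in proto_idx
        if window.tumor_seq[t] != window.normal_seq[t]
    ]
    return NativeAlignment(tuple(sorted(mismatches)), intact, False)


def classify_candidate(
    candidate: GuideCandidate,
    window: HaplotypeWindow,
    seed_len: int = DEFAULT_SEED_LEN,
) -> SpecificityCall:
    """Assign exactly one specificity class to a nominated candidate.

    Precedence: PAM_GAIN > INDEL_DISRUPTING > SEED_DISCRIMINATING >
    NON_DISCRIMINATING.  ``seed_len`` is the PAM-proximal seed length
    (default 12, sensible range 8-12).
    """
    if not 1 <= seed_len <= 20:
        raise ValueError(f"seed_len out of range: {seed_len}")
    _check_pairing(candidate, window)
    native = native_locus_mismatches(candidate, window)
    if not native.normal_pam_intact:
        cls = SpecificityClass.PAM_GAIN
    elif window.variant.vclass in ("INS", "DEL"):
        cls = SpecificityClass.INDEL_DISRUPTING
    elif any(1 <= p <= seed_len for p in candidate.variant_positions):
        cls = SpecificityClass.SEED_DISCRIMINATING
    else:
        cls = SpecificityClass.NON_DISCRIMINATING
    return SpecificityCall(
        candidate_id=candidate.guide_id,
        specificity_class=cls,
        normal_mismatch_positions=native.mismatch_positions,
        normal_pam_intact=native.normal_pam_intact,
    )
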