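"""Score passing candidates and select the final multi-guide panel.

Scoring is deliberately heuristic and ordinal, not a trained efficiency
model: hard sequence filters first (GC window, homopolymers, poly-T, which
terminates Pol III transcription of the sgRNA), then a composite of the
specificity class weight minus an off-target proximity penalty.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .nomination import GuideCandidate
from .offtarget import OffTargetHit
from .specificity import DISCRIMINATING_CLASSES, SpecificityCall, SpecificityClass

log = logging.getLogger(__name__)

CLASS_WEIGHTS = {
    SpecificityClass.PAM_GAIN: 3.0,
    SpecificityClass.INDEL_DISRUPTING: 2.0,
    SpecificityClass.SEED_DISCRIMINATING: 1.0,
}

GC_MIN, GC_MAX = 0.30, 0.80
MAX_HOMOPOLYMER = 4


def gc_fraction(seq: str) -> float:
    return (seq.count("G") + seq.count("C")) / len(seq)


def max_homopolymer(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best


@dataclass(frozen=True)
class GuideScore:
    gc_fraction: float
    homopolymer_max: int
    has_polyT: bool
    offtarget_penalty: float
    class_weight: float
    composite: Optional[float]
    reject_reasons: tuple[str, ...] = ()

    @property
    def passed(self) -> bool:
        return not self.reject_reasons


def score_guide(
    candidate: GuideCandidate,
    call: SpecificityCall,
    hits: Sequence[OffTargetHit],
) -> GuideScore:
    """Hard filters then composite = class weight - sum 1/(1+mm) over hits.

    Rejected guides (GC outside [0.30, 0.80], homopolymer > 4, >=4
    consecutive T) have no composite score.
    """
    proto = candidate.protospacer
    gc = gc_fraction(proto)
    homo = max_homopolymer(proto)
    polyt = "TTTT" in proto
    reasons = []
    if not GC_MIN <= gc <= GC_MAX:
        reasons.append(f"gc_{gc:.2f}")
    if homo > MAX_HOMOPOLYMER:
        reasons.append(f"homopolymer_{homo}")
    if polyt:
        reasons.append("polyT")
    if call.specificity_class not in DISCRIMINATING_CLASSES:
        reasons.append("non_discriminating")
    penalty = sum(1.0 / (1 + h.mismatches) for h in hits)
    weight = CLASS_WEIGHTS.get(call.specificity_class, 0.0)
    composite = None if reasons else weight - penalty
    return GuideScore(gc, homo, polyt, penalty, weight, composite, tuple(reasons))


@dataclass(frozen=True)
class ScoredGuide:
    candidate: GuideCandidate
    call: SpecificityCall
    score: GuideScore
    hits: tuple[OffTargetHit, ...] = ()


@dataclass(frozen=True)
class Panel:
    entries: tuple[ScoredGuide, ...]
    size_requested: int
    constraints_applied: dict = field(default_factory=dict, compare=False)

    @property
    def guide_ids(self) -> list[str]:
        return [e.candidate.guide_id for e in self.entries]

    @property
    def variant_ids(self) -> list[str]:
        return [e.candidate.variant_id for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def _sort_key(g: ScoredGuide):
    c = g.candidate
    position = c.genomic_cut_pos if c.genomic_cut_pos is not None else c.variant_start
    return (
        -g.score.composite,
        len(g.hits),
        c.contig,
        position,
        0 if c.strand == "+" else 1,
        c.guide_id,
    )


def select_panel(
    scored: Sequence[ScoredGuide],
    size: int = 8,
    max_per_contig: int = 2,
) -> Panel:
    """Greedy selection by descending composite with a total tie-break order.

    Constraints: at most one guide per variant (the panel targets distinct
    mutation sites) and at most ``max_per_contig`` guides per contig
    (cutting is spread across chromosomes).  Returns fewer than ``size``
    with a warning when eligible supply is short.
    """
    if size < 1:
        raise ValueError(f"panel size must be >= 1, got {size}")
    eligible = sorted((g for g in scored if g.score.passed), key=_sort_key)
    chosen: list[ScoredGuide] = []
    seen_variants: set[str] = set()
    per_contig: dict[str, int] = {}
    for g in eligible:
        if len(chosen) == size:
            break
        vid, contig = g.candidate.variant_id, g.candidate.contig
        if vid in seen_variants or per_contig.get(contig, 0) >= max_per_contig:
            continue
        chosen.append(g)
        seen_variants.add(vid)
        per_contig[contig] = per_contig.get(contig, 0) + 1
    if len(chosen) < size:
        log.warning(
            "panel short: %d of %d requested guides selected", len(chosen), size
        )
    return Panel(
        entries=tuple(chosen),
        size_requested=size,
        constraints_applied={
            "one_per_variant": True,
            "max_per_contig": max_per_contig,
        },
    )
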