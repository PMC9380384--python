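"""End-to-end guide design: variants in, scored guide table and panel out."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .io import GUIDE_TSV_COLUMNS, GenomeSequence, SomaticVariant
from .nomination import format_position, nominate_candidates
from .offtarget import FilterPolicy, GenomeIndex, genome_specificity_filter
from .panel import Panel, ScoredGuide, score_guide, select_panel
from .specificity import (
    DEFAULT_SEED_LEN,
    accepted_classes,
    classify_candidate,
)
from .variants import (
    build_haplotype_window,
    flag_multi_variant_windows,
    normalize_variant,
)

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class DesignConfig:
    """All knobs of the design pipeline, with documented defaults."""

    window: int = 30
    seed_len: int = DEFAULT_SEED_LEN
    strict: bool = False
    panel_size: int = 8
    max_per_contig: int = 2
    policy: FilterPolicy = field(default_factory=FilterPolicy)


@dataclass
class DesignResult:
    rows: pd.DataFrame
    panel: Panel
    scored: list[ScoredGuide]
    counts: dict
    flagged_variants: set[str]

    @property
    def panel_rows(self) -> pd.DataFrame:
        ids = set(self.panel.guide_ids)
        return self.rows[self.rows["guide_id"].isin(ids)].reset_index(drop=True)


def _guide_row(g: ScoredGuide) -> dict:
    c, call, score = g.candidate, g.call, g.score
    return {
        "guide_id": c.guide_id,
        "contig": c.contig,
        "cut_pos_0based": c.genomic_cut_pos,
        "strand": c.strand,
        "protospacer": c.protospacer,
        "pam": c.pam,
        "variant_id": c.variant_id,
        "specificity_class": call.specificity_class.value,
        "variant_guide_position": ";".join(
            format_position(p) for p in c.variant_positions
        ),
        "n_offtargets_le_M": len(g.hits),
        "gc_fraction": round(score.gc_fraction, 4),
        "score": None if score.composite is None else round(score.composite, 4),
    }


def design_guides(
    genome: GenomeSequence,
    variants: Sequence[SomaticVariant],
    config: DesignConfig = DesignConfig(),
    index: GenomeIndex | None = None,
) -> DesignResult:
    """Run normalize -> window -> nominate -> classify -> filter -> panel.

    The guide table contains every allele-discriminating candidate that was
    evaluated against the normal genome; the panel additionally applies the
    sequence hard filters and the selection constraints.
    """
    if index is None:
        index = GenomeIndex(genome)
    normalized = [normalize_variant(v, genome) for v in variants]
    flagged = flag_multi_variant_windows(normalized, window=config.window)
    if flagged:
        log.warning(
            "%d variant(s) have another variant within their design window; "
            "windows are built per-variant without co-application",
            len(flagged),
        )
    ok_classes = accepted_classes(config.strict)
    scored: list[ScoredGuide] = []
    n_candidates = n_discriminating = n_pass_filter = 0
    for v in normalized:
        window = build_haplotype_window(v, genome, W=config.window)
        for cand in nominate_candidates(window):
            n_candidates += 1
            call = classify_candidate(cand, window, seed_len=config.seed_len)
            if call.specificity_class not in ok_classes:
                continue
            n_discriminating += 1
            result = genome_specificity_filter(cand, call, index, config.policy)
            if not result.passed:
                continue
            n_pass_filter += 1
            score = score_guide(cand, call, result.hits)
            scored.append(ScoredGuide(cand, call, score, result.hits))
    panel = select_panel(
        scored, size=config.panel_size, max_per_contig=config.max_per_contig
    )
    rows = pd.DataFrame(
        [_guide_row(g) for g in scored], columns=GUIDE_TSV_COLUMNS
    )
    counts = {
        "variants_in": len(normalized),
        "variants_flagged_nearby": len(flagged),
        "candidates_nominated": n_candidates,
        "candidates_discriminating": n_discriminating,
        "candidates_passing_genome_filter": n_pass_filter,
        "candidates_scored_pass": sum(1 for g in scored if g.score.passed),
        "panel_selected": len(panel),
    }
    log.info("design counts: %s", counts)
    return DesignResult(rows, panel, scored, counts, flagged)
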