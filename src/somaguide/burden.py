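"""Target-burden estimation and clonal-persistence analysis.

Two questions frame the feasibility of mutation-targeted CRISPR therapy:

* How many somatic mutations in a tumor yield at least one
  allele-discriminating, genome-unique guide?  Estimated by Monte-Carlo:
  sample variants uniformly against a background genome, run the full
  nominate -> classify -> genome-specificity pipeline on each, and scale
  the passing fraction by the mutation burden (mutations/Mb x genome Mb).
* How robust is an N-guide panel to clonal evolution?  Under independent
  per-site retention with probability p, the chance that every target is
  lost is (1-p)^N; the empirical simulator relaxes independence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import binomtest

from .io import GenomeSequence
from .nomination import nominate_candidates
from .offtarget import DEFAULT_PAM_SET, FilterPolicy, GenomeIndex, genome_specificity_filter
from .simulate import DEFAULT_INDEL_FRACTION, sample_somatic_variant
from .specificity import DEFAULT_SEED_LEN, accepted_classes, classify_candidate
from .variants import CloneVariantSet, build_haplotype_window, normalize_variant

__all__ = [
    "BurdenModel",
    "CloneVariantSet",
    "SuitabilityEstimate",
    "EstimatorConfig",
    "ExpectedTargets",
    "estimate_suitable_fraction",
    "expected_targets",
    "clone_overlap",
    "PairwiseOverlap",
    "CloneOverlapReport",
    "panel_survival_probability",
    "panel_survival_empirical",
]


@dataclass(frozen=True)
class BurdenModel:
    """Somatic mutation burden of a tumor or patient cohort."""

    burden_per_mb: float
    genome_mb: float = 3000.0  # callable human genome, order of magnitude
    indel_fraction: float = DEFAULT_INDEL_FRACTION

    def __post_init__(self):
        if self.burden_per_mb < 0 or self.genome_mb < 0:
            raise ValueError("burden and genome size must be non-negative")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")

    @property
    def total_mutations(self) -> float:
        return self.burden_per_mb * self.genome_mb


@dataclass(frozen=True)
class SuitabilityEstimate:
    """P(a random somatic variant yields >=1 passing guide), with 95% CI."""

    fraction: float
    ci_low: float
    ci_high: float
    n_sampled: int
    seed: int

    def __post_init__(self):
        if not 0 <= self.ci_low <= self.fraction <= self.ci_high <= 1:
            raise ValueError("CI must bracket the point estimate within [0, 1]")


@dataclass(frozen=True)
class EstimatorConfig:
    """Pipeline knobs for the Monte-Carlo suitability estimator."""

    window: int = 30
    seed_len: int = DEFAULT_SEED_LEN
    strict: bool = False
    indel_fraction: float = DEFAULT_INDEL_FRACTION
    indel_max_len: int = 10
    indel_geom_p: float = 0.5
    reject_mm: int = 0
    pam_set: frozenset[str] = DEFAULT_PAM_SET
    native_exclusion_radius: int = 50


def variant_is_suitable(
    variant,
    genome: GenomeSequence,
    index: GenomeIndex,
    config: EstimatorConfig,
    policy: FilterPolicy,
) -> bool:
    """Does this variant yield >=1 allele-discriminating, genome-unique guide?"""
    window = build_haplotype_window(variant, genome, W=config.window)
    ok_classes = accepted_classes(config.strict)
    for cand in nominate_candidates(window):
        call = classify_candidate(cand, window, seed_len=config.seed_len)
        if call.specificity_class not in ok_classes:
            continue
        if genome_specificity_filter(cand, call, index, policy).passed:
            return True
    return False


def estimate_suitable_fraction(
    background_genome: GenomeSequence,
    config: EstimatorConfig = EstimatorConfig(),
    n_samples: int = 10_000,
    seed: int = 0,
    index: GenomeIndex | None = None,
) -> SuitabilityEstimate:
    """Monte-Carlo estimate of the fraction of suitable somatic variants.

    Variants (SNVs to uniform non-reference bases; indels per
    ``indel_fraction`` with geometric lengths) are sampled uniformly over
    the background genome; each runs the full design pipeline.  Pass/fail
    only needs the reject threshold, so the filter runs with its report
    budget capped to ``reject_mm``.  Wilson 95% binomial interval.
    """
    if background_genome.total_length < 100_000:
        raise ValueError("background genome must be >= 100 kb")
    if n_samples < 1000:
        raise ValueError("n_samples must be >= 1000")
    rng = np.random.default_rng(seed)
    if index is None:
        index = GenomeIndex(background_genome)
    policy = FilterPolicy(
        reject_mm=config.reject_mm,
        report_mm=config.reject_mm,
        pam_set=config.pam_set,
        native_exclusion_radius=config.native_exclusion_radius,
    )
    successes = 0
    for _ in range(n_samples):
        v = sample_somatic_variant(
            rng,
            background_genome,
            indel_fraction=config.indel_fraction,
            indel_max_len=config.indel_max_len,
            indel_geom_p=config.indel_geom_p,
            margin=max(30, config.window),
        )
        v = normalize_variant(v, background_genome)
        if variant_is_suitable(v, background_genome, index, config, policy):
            successes += 1
    fraction = successes / n_samples
    ci = binomtest(successes, n_samples).proportion_ci(
        confidence_level=0.95, method="wilson"
    )
    return SuitabilityEstimate(
        fraction=fraction,
        ci_low=float(ci.low),
        ci_high=float(ci.high),
        n_sampled=n_samples,
        seed=seed,
    )


@dataclass(frozen=True)
class ExpectedTargets:
    """Expected suitable target sites per tumor/patient, with interval."""

    count: float
    count_low: float
    count_high: float
    model: BurdenModel
    estimate: SuitabilityEstimate


def expected_targets(model: BurdenModel, est: SuitabilityEstimate) -> ExpectedTargets:
    """count = burden/Mb x genome Mb x suitable fraction (linear in both)."""
    total = model.total_mutations
    return ExpectedTargets(
        count=total * est.fraction,
        count_low=total * est.ci_low,
        count_high=total * est.ci_high,
        model=model,
        estimate=est,
    )


@dataclass(frozen=True)
class PairwiseOverlap:
    parent_label: str
    child_label: str
    n_parent: int
    n_child: int
    n_common: int
    n_parent_only: int
    n_child_only: int

    @property
    def retained_fraction(self) -> float:
        """|child ∩ parent| / |parent| (1.0 for an empty parent)."""
        return self.n_common / self.n_parent if self.n_parent else 1.0

    @property
    def unique_fraction(self) -> float:
        """|child \\ parent| / |child| (0.0 for an empty child)."""
        return self.n_child_only / self.n_child if self.n_child else 0.0


@dataclass(frozen=True)
class CloneOverlapReport:
    labels: tuple[str, ...]
    pairwise: tuple[PairwiseOverlap, ...]
    n_global_intersection: int
    n_global_union: int


def clone_overlap(sets: Sequence[CloneVariantSet]) -> CloneOverlapReport:
    """Exact set arithmetic over >=2 clone/sample mutation sets.

    For each ordered-by-input pair the first set acts as parent.  Satisfies
    |A∩B| + |A\\B| = |A| exactly on all inputs.
    """
    if len(sets) < 2:
        raise ValueError("clone_overlap needs >= 2 variant sets")
    pairs = []
    for a, b in combinations(sets, 2):
        common = a.ids & b.ids
        pairs.append(
            PairwiseOverlap(
                parent_label=a.label,
                child_label=b.label,
                n_parent=len(a.ids),
                n_child=len(b.ids),
                n_common=len(common),
                n_parent_only=len(a.ids - b.ids),
                n_child_only=len(b.ids - a.ids),
            )
        )
    inter = frozenset.intersection(*(s.ids for s in sets))
    union = frozenset.union(*(s.ids for s in sets))
    return CloneOverlapReport(
        labels=tuple(s.label for s in sets),
        pairwise=tuple(pairs),
        n_global_intersection=len(inter),
        n_global_union=len(union),
    )


def panel_survival_probability(p_retain: float, n_sites: int) -> tuple[float, float]:
    """(p_all_lost, p_any_retained) for an N-guide panel.

    Assumes independent per-site retention with probability ``p_retain``:
    p_all_lost = (1 - p_retain)^N.
    """
    if not 0.0 <= p_retain <= 1.0:
        raise ValueError(f"p_retain must be in [0, 1], got {p_retain}")
    if n_sites < 1 or int(n_sites) != n_sites:
        raise ValueError(f"n_sites must be a positive integer, got {n_sites}")
    p_all_lost = (1.0 - p_retain) ** int(n_sites)
    return p_all_lost, 1.0 - p_all_lost


def panel_survival_empirical(
    parent_panel_ids: Iterable[str],
    simulated_clones: Sequence[CloneVariantSet],
) -> float:
    """Fraction of simulated clones retaining >=1 panel target.

    Converges to 1 - (1 - p_retain)^N as the clone count grows when site
    gains/losses are independent.  An empty panel survives in no clone.
    """
    panel = frozenset(parent_panel_ids)
    if not simulated_clones:
        raise ValueError("need >= 1 simulated clone")
    if not panel:
        return 0.0
    survived = sum(1 for c in simulated_clones if panel & c.ids)
    return survived / len(simulated_clones)
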