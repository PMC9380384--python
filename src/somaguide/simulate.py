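"""Synthetic study fixtures: random genomes, somatic spike-ins, derived clones.

The generator emulates the shape of the study inputs: a background genome
at human-like GC content, a tumor-private variant set at a stated burden
per megabase with a realistic SNV/indel mix, and single-cell clones derived
from a parental set with an aggregate retention probability plus
per-passage gains.  Every generator is a pure function of (parameters,
seed) and bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io import GenomeSequence, SomaticVariant
from .variants import CloneVariantSet

#: Indel share of somatic calls in a deeply sequenced hypermutated
#: carcinoma line (817,723 indels / 4,803,421 total calls).
DEFAULT_INDEL_FRACTION = 817_723 / 4_803_421

#: Minimum spacing between spiked variants; keeps each design window
#: single-variant (the supported path — see variant_model non-goals).
DEFAULT_MIN_SPACING = 50

_BASES = np.frombuffer(b"GCAT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for a full synthetic fixture."""

    seed: int
    genome_length_bp: int = 1_000_000
    gc_fraction: float = 0.41
    burden_per_mb: float = 1.0
    indel_fraction: float = DEFAULT_INDEL_FRACTION
    clone_p_retain: float = 0.81
    clone_gain_rate: float = 53.0  # new mutations per passage
    passages: int = 60

    def __post_init__(self):
        if self.genome_length_bp < 1000:
            raise ValueError("genome_length_bp must be >= 1000")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0, 1]")
        if self.burden_per_mb < 0:
            raise ValueError("burden_per_mb must be non-negative")
        if not 0.0 <= self.indel_fraction <= 1.0:
            raise ValueError("indel_fraction must be in [0, 1]")
        if not 0.0 <= self.clone_p_retain <= 1.0:
            raise ValueError("clone_p_retain must be in [0, 1]")
        if self.clone_gain_rate < 0 or self.passages < 0:
            raise ValueError("clone_gain_rate and passages must be non-negative")


def simulate_genome(
    length: int, gc_fraction: float = 0.41, seed: int = 0, contig: str = "sim1"
) -> GenomeSequence:
    """I.i.d. random genome: P(G)=P(C)=gc/2, P(A)=P(T)=(1-gc)/2."""
    if length < 1000:
        raise ValueError(f"length must be >= 1000, got {length}")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError(f"gc_fraction must be in [0, 1], got {gc_fraction}")
    rng = np.random.default_rng(seed)
    p = [gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2, (1 - gc_fraction) / 2]
    codes = rng.choice(_BASES, size=length, p=p)
    return GenomeSequence({contig: codes.tobytes().decode()})


def sample_somatic_variant(
    rng: np.random.Generator,
    genome: GenomeSequence,
    indel_fraction: float = DEFAULT_INDEL_FRACTION,
    indel_max_len: int = 10,
    indel_geom_p: float = 0.5,
    margin: int = 30,
    position: Optional[tuple[str, int]] = None,
) -> SomaticVariant:
    """Draw one somatic variant uniformly over the genome.

    SNVs mutate to a uniform non-reference base; indels (insertion or
    deletion with equal probability) have geometric lengths capped at
    ``indel_max_len``.  Positions keep ``margin`` bases clear of contig
    ends so design windows are not clipped in routine fixtures.
    """
    names = genome.names
    lengths = np.array([genome.length(n) for n in names], dtype=float)
    while True:
        if position is not None:
            contig, pos = position
        else:
            contig = names[rng.choice(len(names), p=lengths / lengths.sum())]
            pos = int(rng.integers(margin, genome.length(contig) - margin))
        seq = genome[contig]
        is_indel = rng.random() < indel_fraction
        if not is_indel:
            ref = seq[pos]
            if ref == "N":
                position = None
                continue
            alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
            return SomaticVariant(contig, pos, ref, alt)
        length = min(int(rng.geometric(indel_geom_p)), indel_max_len)
        if rng.random() < 0.5:  # insertion
            ref = seq[pos]
            if ref == "N":
                position = None
                continue
            inserted = "".join("ACGT"[int(i)] for i in rng.integers(4, size=length))
            return SomaticVariant(contig, pos, ref, ref + inserted)
        ref = seq[pos : pos + 1 + length]
        if len(ref) < 1 + length or "N" in ref:
            position = None
            continue
        return SomaticVariant(contig, pos, ref, ref[0])


def apply_variants(
    genome: GenomeSequence, variants: Sequence[SomaticVariant]
) -> GenomeSequence:
    """Apply non-overlapping variants to a genome, yielding the tumor genome."""
    by_contig: dict[str, list[SomaticVariant]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)
    out = {}
    for contig, seq in genome.items():
        vs = sorted(by_contig.get(contig, []), key=lambda v: v.start)
        for prev, cur in zip(vs, vs[1:]):
            if cur.start < prev.end:
                raise ValueError(
                    f"overlapping variants: {prev.id} and {cur.id}"
                )
        pieces, cursor = [], 0
        for v in vs:
            if seq[v.start : v.end] != v.ref:
                raise ValueError(f"{v.id}: REF does not match genome")
            pieces.append(seq[cursor : v.start])
            pieces.append(v.alt)
            cursor = v.end
        pieces.append(seq[cursor:])
        out[contig] = "".join(pieces)
    return GenomeSequence(out)


def spike_somatic_variants(
    genome: GenomeSequence,
    burden_per_mb: float = 1.0,
    indel_fraction: float = DEFAULT_INDEL_FRACTION,
    seed: int = 0,
    min_spacing: int = DEFAULT_MIN_SPACING,
    indel_max_len: int = 10,
    indel_geom_p: float = 0.5,
) -> tuple[list[SomaticVariant], GenomeSequence]:
    """Spike Poisson(burden x Mb) somatic variants into a genome.

    Positions are drawn uniformly with rejection so no two variants fall
    within ``min_spacing`` bases of each other.  Returns the ground-truth
    variant list (sorted) and the tumor genome with all variants applied.
    """
    rng = np.random.default_rng(seed)
    n = int(rng.poisson(burden_per_mb * genome.total_length / 1e6))
    names = genome.names
    lengths = np.array([genome.length(nm) for nm in names], dtype=float)
    taken: dict[str, list[int]] = {nm: [] for nm in names}
    variants: list[SomaticVariant] = []
    attempts = 0
    while len(variants) < n:
        attempts += 1
        if attempts > 1000 * max(n, 1):
            raise RuntimeError(
                "cannot place variants with the requested spacing; "
                "genome too small for this burden"
            )
        contig = names[rng.choice(len(names), p=lengths / lengths.sum())]
        margin = max(30, min_spacing)
        if genome.length(contig) <= 2 * margin:
            continue
        pos = int(rng.integers(margin, genome.length(contig) - margin))
        if any(abs(pos - q) < min_spacing for q in taken[contig]):
            continue
        v = sample_somatic_variant(
            rng,
            genome,
            indel_fraction=indel_fraction,
            indel_max_len=indel_max_len,
            indel_geom_p=indel_geom_p,
            position=(contig, pos),
        )
        taken[contig].append(pos)
        variants.append(v)
    variants.sort(key=lambda v: (v.contig, v.start))
    return variants, apply_variants(genome, variants)


def derive_clone(
    parent_ids,
    p_retain: float = 0.81,
    gain_rate: float = 53.0,
    passages: int = 60,
    genome: GenomeSequence | None = None,
    seed: int = 0,
    label: str = "clone",
) -> CloneVariantSet:
    """Derive a single-cell clone from a parental mutation set.

    Each parental mutation is kept independently with aggregate probability
    ``p_retain`` (endpoint retention, not per-passage); Poisson(gain_rate x
    passages) new SNVs are added at fresh loci of ``genome``.
    """
    if not 0.0 <= p_retain <= 1.0:
        raise ValueError(f"p_retain must be in [0, 1], got {p_retain}")
    if gain_rate < 0 or passages < 0:
        raise ValueError("gain_rate and passages must be non-negative")
    rng = np.random.default_rng(seed)
    parent = sorted(parent_ids)
    keep_mask = rng.random(len(parent)) < p_retain
    kept = {pid for pid, keep in zip(parent, keep_mask) if keep}
    n_new = int(rng.poisson(gain_rate * passages))
    new_ids: set[str] = set()
    if n_new and genome is not None:
        parent_positions = {
            (pid.split(":")[0], int(pid.split(":")[1])) for pid in parent
        }
        guard = 0
        while len(new_ids) < n_new:
            guard += 1
            if guard > 100 * n_new + 1000:
                break
            v = sample_somatic_variant(rng, genome, indel_fraction=0.0)
            if (v.contig, v.pos) in parent_positions or v.id in new_ids:
                continue
            new_ids.add(v.id)
    elif n_new:
        # No genome: synthesize opaque novel ids (set algebra only needs ids).
        new_ids = {f"{label}:novel:{i}" for i in range(n_new)}
    return CloneVariantSet(label, frozenset(kept | new_ids))
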