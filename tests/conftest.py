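"""Shared fixtures and sequence helpers for the somaguide test suite."""

import numpy as np
import pytest

from somaguide.io import GenomeSequence, SomaticVariant
from somaguide.variants import build_haplotype_window, normalize_variant


def random_seq(rng: np.random.Generator, length: int, gc: float = 0.41) -> str:
    p = [gc / 2, gc / 2, (1 - gc) / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("GCAT"), size=length, p=p))


def make_window(seq: str, variant: SomaticVariant, W: int = 30, contig: str = "c1"):
    """Build a haplotype window from a raw contig string."""
    genome = GenomeSequence({contig: seq})
    return build_haplotype_window(normalize_variant(variant, genome), genome, W=W)


@pytest.fixture(scope="session")
def small_genome() -> GenomeSequence:
    """5-kb random single-contig genome (seeded)."""
    rng = np.random.default_rng(1234)
    return GenomeSequence({"chr1": random_seq(rng, 5000)})


@pytest.fixture(scope="session")
def midsize_genome() -> GenomeSequence:
    """100-kb two-contig genome for off-target and estimator tests."""
    rng = np.random.default_rng(4321)
    return GenomeSequence(
        {"chr1": random_seq(rng, 60_000), "chr2": random_seq(rng, 40_000)}
    )
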