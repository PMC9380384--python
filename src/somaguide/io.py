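"""File formats: FASTA genomes, VCF variant sets, guide tables, cut-site BED.

Every coordinate is 0-based half-open internally.  VCF positions are
converted on read (``pos - 1``) and back on write; BED output is natively
0-based half-open.  DNA is normalized once at the boundary: lowercase is
uppercased and any non-ACGT code (IUPAC ambiguity, gaps) becomes ``N``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .exceptions import (
    DuplicateContigError,
    RefMismatchError,
    UnknownContigError,
    VcfFormatError,
)

log = logging.getLogger(__name__)

_RC = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")
_ALLELE_RE = re.compile(r"^[ACGTN]+$")

#: Column order of the guide table TSV (fixed interface).
GUIDE_TSV_COLUMNS = [
    "guide_id",
    "contig",
    "cut_pos_0based",
    "strand",
    "protospacer",
    "pam",
    "variant_id",
    "specificity_class",
    "variant_guide_position",
    "n_offtargets_le_M",
    "gc_fraction",
    "score",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_RC)[::-1]


def normalize_sequence(seq: str) -> str:
    """Uppercase and collapse every non-ACGT code to ``N``."""
    return _NON_ACGTN.sub("N", seq.upper())


class GenomeSequence:
    """An in-memory genome: ordered map of contig name to DNA string.

    Sequences are normalized on construction (uppercase, ambiguity codes
    to ``N``); contig names must be unique and non-empty.
    """

    def __init__(self, contigs: Mapping[str, str]):
        if not contigs:
            raise ValueError("genome must contain at least one contig")
        self._contigs: dict[str, str] = {}
        for name, seq in contigs.items():
            if not name:
                raise ValueError("contig name must be non-empty")
            self._contigs[str(name)] = normalize_sequence(str(seq))

    @property
    def names(self) -> list[str]:
        return list(self._contigs)

    def __getitem__(self, name: str) -> str:
        return self._contigs[name]

    def __contains__(self, name: str) -> bool:
        return name in self._contigs

    def __len__(self) -> int:
        return len(self._contigs)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(self._contigs.items())

    def length(self, name: str) -> int:
        return len(self._contigs[name])

    @property
    def lengths(self) -> dict[str, int]:
        return {n: len(s) for n, s in self._contigs.items()}

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self._contigs.values())

    def reverse_complement(self) -> "GenomeSequence":
        """Genome with every contig reverse-complemented (names kept)."""
        return GenomeSequence(
            {n: reverse_complement(s) for n, s in self._contigs.items()}
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeSequence):
            return NotImplemented
        return self._contigs == other._contigs

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        parts = ", ".join(f"{n}:{len(s)}bp" for n, s in self._contigs.items())
        return f"GenomeSequence({parts})"


@dataclass(frozen=True)
class SomaticVariant:
    """One tumor-private SNV / insertion / deletion / MNV.

    ``start`` is the 0-based position of the first REF base; the canonical
    ``id`` uses the 1-based VCF position so ids match what a VCF reader sees.
    """

    contig: str
    start: int
    ref: str
    alt: str

    def __post_init__(self):
        if self.start < 0:
            raise ValueError(f"negative variant position: {self.start}")
        for label, allele in (("ref", self.ref), ("alt", self.alt)):
            if not allele or not _ALLELE_RE.match(allele):
                raise ValueError(f"invalid {label} allele {allele!r}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.contig}:{self.pos}")

    @property
    def pos(self) -> int:
        """1-based position of the first REF base (VCF convention)."""
        return self.start + 1

    @property
    def end(self) -> int:
        """0-based half-open end of the REF allele on the genome."""
        return self.start + len(self.ref)

    @property
    def vclass(self) -> str:
        """Variant class: SNV, INS, DEL or MNV."""
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "INS"
        if len(self.ref) > len(self.alt):
            return "DEL"
        return "MNV"

    @property
    def id(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}>{self.alt}"


def check_ref(variant: SomaticVariant, genome: GenomeSequence) -> None:
    """Raise unless the variant's REF allele matches the genome."""
    if variant.contig not in genome:
        raise UnknownContigError(
            f"{variant.id}: contig {variant.contig!r} not in genome"
        )
    observed = genome[variant.contig][variant.start : variant.end]
    if observed != variant.ref:
        raise RefMismatchError(
            f"{variant.id}: REF {variant.ref!r} does not match genome "
            f"{observed!r} at {variant.contig}:{variant.pos}"
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> GenomeSequence:
    """Load a (multi-)FASTA into a :class:`GenomeSequence`.

    Raises on a missing/empty file and on duplicate contig names.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"FASTA not found: {p}")
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(p), "fasta"):
        if rec.id in contigs:
            raise DuplicateContigError(f"duplicate contig name {rec.id!r} in {p}")
        contigs[rec.id] = str(rec.seq)
    if not contigs:
        raise ValueError(f"no FASTA records in {p}")
    return GenomeSequence(contigs)


def write_fasta(genome: GenomeSequence, path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VcfReadStats:
    """Reconciliation counts for a VCF read."""

    n_records: int
    n_alt_alleles: int
    n_skipped_symbolic: int


def _is_symbolic(alt: str) -> bool:
    return (
        alt == "*"
        or alt.startswith("<")
        or "[" in alt
        or "]" in alt
        or not _ALLELE_RE.match(alt.upper())
    )


def _prevalidate_vcf(p: Path) -> None:
    """Cheap structural pass so malformed body lines error with a line number.

    htslib tolerates (or silently drops) some malformed bodies; this check in
    front of the real parser keeps the error contract explicit.
    """
    with open(p) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8:
                raise VcfFormatError(
                    f"{p}: line {lineno}: expected >=8 tab-separated fields, "
                    f"got {len(fields)}"
                )
            try:
                int(fields[1])
            except ValueError:
                raise VcfFormatError(
                    f"{p}: line {lineno}: POS {fields[1]!r} is not an integer"
                ) from None


def read_vcf_with_stats(
    path, genome: GenomeSequence | None = None
) -> tuple[list[SomaticVariant], VcfReadStats]:
    """Read a VCF into variants, one per ALT allele, with reconciliation stats.

    Symbolic ALTs (``<DEL>``, breakends, ``*``) are skipped and counted.
    When a genome is supplied, every REF allele is verified against it.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"VCF not found: {p}")
    if p.suffix not in (".gz", ".bgz"):
        _prevalidate_vcf(p)
    variants: list[SomaticVariant] = []
    n_records = n_alts = n_skipped = 0
    for rec in VCF(str(p)):
        n_records += 1
        for alt in rec.ALT:
            n_alts += 1
            if _is_symbolic(alt):
                n_skipped += 1
                continue
            v = SomaticVariant(rec.CHROM, rec.POS - 1, rec.REF.upper(), alt.upper())
            if genome is not None:
                check_ref(v, genome)
            variants.append(v)
    if n_skipped:
        log.info("skipped %d symbolic ALT allele(s) in %s", n_skipped, p)
    return variants, VcfReadStats(n_records, n_alts, n_skipped)


def read_vcf(path, genome: GenomeSequence | None = None) -> list[SomaticVariant]:
    """Read a VCF into a list of :class:`SomaticVariant` (one per ALT)."""
    return read_vcf_with_stats(path, genome)[0]


def write_vcf(
    variants: Iterable[SomaticVariant],
    path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write variants as a minimal sites-only VCF v4.2."""
    rows = sorted(variants, key=lambda v: (v.contig, v.start, v.ref, v.alt))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=somaguide\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in rows:
            fh.write(f"{v.contig}\t{v.pos}\t{v.id}\t{v.ref}\t{v.alt}\t.\t.\t.\n")


# ---------------------------------------------------------------------------
# Guide tables
# ---------------------------------------------------------------------------

def _as_guide_frame(rows) -> pd.DataFrame:
    if isinstance(rows, pd.DataFrame):
        df = rows.copy()
    else:
        df = pd.DataFrame(list(rows), columns=GUIDE_TSV_COLUMNS)
    missing = [c for c in GUIDE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"guide table missing columns: {missing}")
    df = df[GUIDE_TSV_COLUMNS]
    df["cut_pos_0based"] = df["cut_pos_0based"].astype("Int64")
    df["n_offtargets_le_M"] = df["n_offtargets_le_M"].astype("Int64")
    return df


def write_guides_tsv(rows, path) -> None:
    """Write the guide table (columns fixed by :data:`GUIDE_TSV_COLUMNS`).

    ``cut_pos_0based`` is empty for guides that cut within inserted,
    tumor-only sequence.
    """
    _as_guide_frame(rows).to_csv(path, sep="\t", index=False)


def read_guides_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"contig": str, "guide_id": str, "variant_id": str},
    )
    return _as_guide_frame(df)


def write_cutsites_bed(rows, path, genome: GenomeSequence | None = None) -> None:
    """Write BED6 cut-site intervals, one base per blunt cut, sorted.

    The interval ``[cut_pos, cut_pos + 1)`` marks the reference base 5' of the
    blunt cut (between protospacer positions 3 and 4 from the PAM).  Guides
    cutting inside inserted sequence have no reference cut site and are
    skipped with a logged count.  Bounds are validated when a genome is given.
    """
    df = _as_guide_frame(rows)
    n_skipped = int(df["cut_pos_0based"].isna().sum())
    if n_skipped:
        log.info("skipping %d guide(s) cutting within inserted sequence", n_skipped)
    df = df.dropna(subset=["cut_pos_0based"])
    df = df.sort_values(["contig", "cut_pos_0based", "guide_id"], kind="mergesort")
    with open(path, "w") as fh:
        for row in df.itertuples(index=False):
            start = int(row.cut_pos_0based)
            end = start + 1
            if genome is not None:
                clen = genome.length(row.contig)
                if not (0 <= start < end <= clen):
                    raise ValueError(
                        f"cut site {row.guide_id} out of bounds: "
                        f"[{start},{end}) on {row.contig} (len {clen})"
                    )
            fh.write(f"{row.contig}\t{start}\t{end}\t{row.guide_id}\t0\t{row.strand}\n")
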