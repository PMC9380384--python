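# Methods

## Problem and model

`somaguide` designs SpCas9 guides that cut a tumor-private somatic allele
while leaving the normal genome untouched. Two separate specificity
questions are kept distinct throughout:

1. **Allele discrimination at the native locus** — will the guide cut the
   tumor allele but not the normal allele at the same position?
2. **Genome specificity** — does the guide recognize any *other* site in
   the normal genome?

### Coordinates and geometry

All internal coordinates are 0-based half-open; VCF positions are
converted on read (`pos − 1`) and back on write, BED output is natively
0-based. A candidate frame is 23 nt: a 20-nt protospacer plus NGG PAM.
Protospacer positions are numbered PAM-proximally (position 1 adjacent to
the PAM), the convention in which Cas9 seed rules are stated; PAM
positions are P1–P3 with P1 the free N. The blunt cut sits between
protospacer positions 3 and 4 from the PAM; the BED interval is the
single reference base 5' of the cut in reference orientation.

### Variant normalization

Indels are parsimony-trimmed and left-aligned (the vt-style algorithm:
right-trim shared trailing bases, extending left through the reference
when an allele would empty; then left-trim to a single anchor base).
Normalization is idempotent and maps every equivalent indel encoding to
one canonical id, which is what makes clone-set algebra on ids sound.
SNVs pass through unchanged.

### Haplotype windows

Each variant gets a paired normal/tumor window of half-width `W = 30`
(configurable, minimum 23 so every frame overlapping the variant fits).
An offset map takes tumor-window positions to genomic coordinates, with
`None` for inserted tumor-only bases. The altered span is:

* SNV/MNV — the substituted base(s);
* insertion — the inserted bases (guides wholly inside an insertion are
  valid and maximally tumor-specific; they have no reference cut
  coordinate and are flagged `within-insertion`);
* deletion — the two bases flanking the novel junction, with a
  **containment** overlap rule: a frame counts as overlapping only if it
  spans the junction on both sides. A frame touching only one flank reads
  sequence that exists verbatim in the normal genome and would be a false
  positive under plain intersection; this rule is the package's own
  design choice.

Windows are built one variant at a time; a plain VCF carries no phase, so
nearby co-occurring variants are flagged (not co-applied), and the
simulator spaces spike-ins ≥ 50 bp apart so routine fixtures exercise the
supported single-variant path.

### Specificity classes

Classification is total and mutually exclusive, with precedence
`PAM_GAIN > INDEL_DISRUPTING > SEED_DISCRIMINATING > NON_DISCRIMINATING`:

* **PAM_GAIN** — the normal allele lacks an NGG at the candidate's PAM
  frame/strand. Evaluated through the offset map: the normal PAM is
  intact iff all three PAM positions map to consecutive normal-genome
  bases carrying GG at P2–P3 (the N never discriminates). This
  generalizes to indels: an insertion or deletion inside the PAM frame
  breaks the normal PAM and classifies as PAM_GAIN.
* **INDEL_DISRUPTING** — any other nominated frame of an insertion or
  deletion: the protospacer is register-shifted against the normal allele
  (unbounded mismatches).
* **SEED_DISCRIMINATING** — an SNV/MNV with ≥ 1 altered position within
  protospacer positions 1..`seed_len`. Default `seed_len = 12`
  (sensible range 8–12): the PAM-proximal 10–12 nt seed is the accepted
  determinant of Cas9 single-mismatch sensitivity. Lowering `seed_len`
  only shrinks this class (monotone).
* **NON_DISCRIMINATING** — everything else (e.g. PAM-distal SNVs); such
  guides would cut both alleles and never enter panels.

A strict mode restricts panels to PAM_GAIN and INDEL_DISRUPTING for users
who distrust single-seed-mismatch discrimination.

### Off-target search

Matching is gap-free Hamming over the 20-mer with a permissive PAM set
{NGG, NAG} (NAG is tolerated by SpCas9 and included for filtering, never
for nomination); bulge off-targets are out of scope. Two independent
routes return identical hit sets and are tested against each other:

* brute force — vectorized Hamming over every 23-nt frame on both
  strands (exhaustive by construction; the oracle);
* indexed — pigeonhole chunking: a hit with ≤ `max_mm` mismatches must
  contain an exact chunk when the 20-mer is split into `max_mm + 1`
  pieces. Chunks are capped at 10 nt (so even exact search uses ≥ 2
  chunks), keeping the k-mer index memory bounded; extra chunks preserve
  the pigeonhole guarantee. Indexes are built lazily per k and cached per
  genome.

The filter policy rejects a guide iff a hit at ≤ `reject_mm` mismatches
(default 0: perfect matches only) exists outside the native-locus
exclusion window (default ± 50 bp); hits up to `report_mm` (default 3)
are returned as a ranking penalty rather than a hard rejection. The
native normal locus — which a seed-SNV guide matches at exactly 1
mismatch — is the allele-discrimination question, not an off-target, and
is reported separately.

### Scoring and panel selection

Hard filters first: 0.30 ≤ GC ≤ 0.80, longest homopolymer ≤ 4, no
TTTT in the protospacer (Pol III terminator). Surviving guides get an
ordinal composite: class weight (PAM_GAIN 3, INDEL_DISRUPTING 2,
SEED_DISCRIMINATING 1) minus Σ 1/(1 + mismatches) over reported hits.
The weights are heuristics ranking mechanistic safety, not calibrated
cutting efficiencies. Selection is greedy by descending composite with a
total deterministic tie-break (fewer hits, contig, position, strand '+'
first, guide id), at most one guide per variant and `max_per_contig = 2`
by default (panels should distribute damage across chromosomes, so CLI
examples on single-contig fixtures raise the cap explicitly). Greedy
under these two partition constraints carries the usual 1/2 worst-case
guarantee and is near-optimal on random instances; re-runs are
byte-identical.

## Feasibility statistics

`estimate_suitable_fraction` samples `n` variants uniformly over a
background genome (SNVs to a uniform non-reference base; indels at the
configured fraction, insertion/deletion equiprobable, geometric(0.5)
lengths capped at 10), runs nominate → classify → genome-filter on each,
and returns the fraction with ≥ 1 passing guide with a Wilson 95%
interval. The filter runs with its report budget capped to `reject_mm`
here: pass/fail depends only on the reject threshold, and the 3-mismatch
enumeration is a ranking concern. `expected_targets` multiplies the
fraction by burden/Mb × genome Mb (default 3,000 Mb, an
order-of-magnitude callable human genome; the denominator is
configurable because no single value is canonical).

Persistence: `clone_overlap` is exact set arithmetic over canonical
variant ids (|A∩B| + |A\B| = |A| holds identically; printed percentages
in published clone comparisons are not always mutually consistent with
printed counts, so this module reports counts and derives fractions from
them). `panel_survival_probability` assumes independent per-site
retention, `p_all_lost = (1 − p)^N`; the empirical simulator draws
clones and relaxes nothing but finiteness, converging to the closed form
when retention is independent.

## Synthetic data: what it shows and what it does not

The generator emulates the *shape* of the study inputs with defaults
chosen once: background genome 1 Mb at GC 0.41 (human-like); somatic
burden 1.0/Mb (prostate-cancer cohort figure); indel fraction 0.1702
(the share of indels, 817,723 of 4,803,421 calls, in a deeply sequenced
hypermutated HCC line); clone retention 0.81 over ~60 passages with ~53
new mutations per passage (endpoint figures from a passaged single-cell
clone). Retention is applied as a single aggregate probability, not
per-passage, because only endpoint comparisons are emulated.

The background is i.i.d. random sequence: it has human-like GC but no
repeats, segmental duplications, or mutational-signature context. The
suitable fraction (~0.70 at these defaults) is therefore an estimate
under a repeat-free background; on a real genome, repeat-mediated
perfect off-target matches would reject more guides, which is why the
headline feasibility claims are lower bounds ("more than 100 per
patient", "more than 1,000 per hypermutated line") rather than point
values. Passing tests show the pipeline's logic and coordinate handling
are correct and that the feasibility bounds hold comfortably under a
realistic burden; they do not certify per-guide cutting efficiency on
real chromatin.

## Problem sizes and numerical choices

The acceptance computation uses a 1-Mb background with 10,000 sampled
variants for the per-patient estimate and 50,000 for the cell-line
scaling — sizes at which the Wilson interval is a few parts per thousand
wide and the whole script runs in well under a minute. Degenerate inputs
are defined, not special-cased: empty variant lists produce header-only
tables and an exit-0 run; windows clipped at contig edges carry a flag;
frames containing N are never nominated or counted as hits; an empty
panel is a success with a warning. All randomness flows through
`numpy.random.default_rng(seed)`; seeds are mandatory on stochastic CLI
paths and derived sub-seeds stay below 2³¹.

## Known limitations

* Gap-free off-target model; DNA/RNA-bulge off-targets are not searched.
* No trained on-target efficiency model; the composite score is ordinal.
* One variant per window; phased multi-variant haplotypes are not
  constructed.
* Alternative nucleases (Cas12a) and truncated guides are out of scope.
* The empirical off-target landscape of delivered guides (e.g. from
  GUIDE-seq-style assays) is not modeled; the filter is predictive only.
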