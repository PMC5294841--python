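# Methods

`crisprscreen` annotates CRISPR–Cas systems in prokaryotic genomes and — its
central purpose — screens the putative CRISPR arrays for *false-CRISPRs*:
genomic elements (tandem repeats, STAR-like elements, simple/low-complexity
repeats) whose repeat–spacer-like structure fools structure-only CRISPR
detectors. This note describes the models and procedures, the parameters that
matter, the numerical choices, what the synthetic-data generator does and does
not emulate, and the known limitations.

## Array detection

Detection is a CRT-style seed-and-extend scan. An exact seed k-mer
(`seed_kmer = 8`) recurring at admissible spacings — between
`min_repeat_len + min_spacer_len` and `max_repeat_len + max_spacer_len` bp —
is chained into a candidate repeat ladder; chains shorter than
`min_repeat_count = 3` copies are discarded. Repeat boundaries are then
extended in both directions while each column stays near-unanimous (at least
⌈2n/3⌉ of the n copies sharing the modal base), capped so that every implied
spacer keeps at least `min_spacer_len` bp. Because near-unanimity can creep a
few columns into flanking sequence when spacer prefixes agree by chance, a
refinement pass trims terminal columns that are not strictly unanimous, down
to `min_repeat_len` at most. Copies whose mismatch fraction against the array
consensus exceeds `max_repeat_mismatch_frac = 0.2` are trimmed from the array
ends. Chains are evaluated from every seed offset and candidates deduplicated
by span; overlapping candidates are resolved by most repeats, then longest
span, then smallest start.

Defaults: repeats 21–47 bp (the canonical direct-repeat length range),
spacers 18–72 bp, ≥3 copies, ≤20 % mismatch per copy. The repeat bounds are
biological; the spacer bounds and mismatch tolerance are detector choices and
configurable.

Two post-passes follow:

* **Partial terminal repeats.** If a prefix (3′) or suffix (5′) of the
  consensus — at least `partial_min_match = 0.5` of its length — matches
  immediately beyond a terminal spacer-sized gap at the array-level mismatch
  tolerance, the array is extended over the partial repeat and flagged. Among
  qualifying (gap, length) combinations the scan maximizes matched bases
  minus 4× mismatches, so a clean truncation is preferred over a longer
  fragment padded with accidental flank matches. The 0.5 threshold is a
  design choice (no published value exists); it is configurable.
* **Array merging.** Arrays separated by at most `merge_gap_bp = 200` bp
  whose consensus repeats match at ≥ `repeat_cluster_identity = 0.90` are
  unioned (transitive closure): a long array split by degenerate repeats or
  long spacers is one locus. The inter-array gap becomes a spacer when its
  length fits the spacer bounds, otherwise it is recorded as an insertion.
  Merging is idempotent.

**Consensus.** Per-column majority over the repeat copies, aligned
end-gap-free to the first copy of modal length; copies deviating more than
20 % from the modal length do not vote; ties go to the base occurring first
in scan order; N never votes.

**Distance convention.** All inter-interval distances are
`start₂ − end₁` in 1-based inclusive coordinates (0 on overlap) — the
convention that makes an array at [100, 500] and a gene at [679, 1500] lie
179 bp apart. The merge gap and the locus-grouping gap use the same measure.

## Sequence identity and clustering

Identity between two repeats (or spacers) is the number of identical columns
in a global alignment divided by the length of the shorter sequence — the
CD-HIT convention. The alignment uses affine gap costs (match +1, mismatch
−1, open −2, extend −0.5) with free end gaps, so a shorter sequence is
scored against its best containment in the longer one and interior gaps stay
contiguous. A minimum-edit alignment is deliberately *not* used here: when
lengths differ substantially its mandatory gaps scatter and accumulate
coincidental matches (a random 25-mer can reach "0.9 identity" against a
random 47-mer), which a banded clustering aligner can never produce. N
counts as a mismatch against everything, including another N.

Consensus repeats from all genomes are clustered greedily (CD-HIT-EST
style): longest first, each sequence joins the first existing cluster whose
representative it matches at ≥ 0.90, otherwise it founds a cluster. The
procedure is deterministic; ties follow input order. A *cluster* has ≥2
members; a *singleton* is alone. Reverse-complement matching is off by
default — repeats on opposite strands are distinct clusters — and can be
enabled with `both_strands`.

## Spacer diversity

Spacers of an active array are acquired independently and are nearly all
distinct. Spacers of one array are clustered at 0.70 identity with the same
greedy scheme; writing n for the spacer count and k for the cluster count,
an array is

* **DIVERSE** when k ≥ ⌈n/2⌉ **and** k ≥ 2,
* otherwise **SHORT** when n ≤ 2 (too little signal to call the array dead),
* otherwise **NOT_DIVERSE**.

The k ≥ 2 clause is required for coherence at n = 2: two identical spacers
give k = 1 = ⌈2/2⌉, yet a pair of identical spacers is the canonical
*short* CRISPR, not a diverse one. A pair at exactly 70 % identity clusters
together (the clustering joins at ≥ threshold) and therefore counts against
diversity. `redundant_spacers = n − k`.

## Cas loci, typing and co-location

Cas gene annotations are consumed as a table (TSV/GFF3) or adapted from
hmmscan `--domtblout` output with a protein-to-coordinate companion table,
keeping the best-scoring family per gene. Consecutive hits with intergenic
gap ≤ `locus_gap_bp = 1000` bp form a candidate locus (the grouping gap is a
design choice; nothing in the underlying procedure pins it). A valid locus
has ≥3 cas genes including ≥1 of the adaptation pair cas1/cas2 or the core
interference components (cas5, cas7, cas8, cas9, cas10, csf1, cpf1);
subtype-suffixed names (cas8c) match their base family.

Typing counts type-signature genes from an editable shipped table
(cas3 → I, cas9 → II, cas10 → III, csf1 → IV, cpf1 → V, plus type-specific
effector subunits such as cse1/cse2, csm2–5, cmr1–6, csn2, csf2–4). The
candidate type is the one with the most signature genes; a call is
*confident* with ≥3 type-consistent signature genes. Type V is the
exception: a single cpf1 makes the locus a confident type V. Ties yield
UNTYPED with an ambiguity flag. The table is configuration, not hard-coded
truth; subtype rows can be added.

An array and a locus within `window_bp = 10,000` bp are **co-located** (a
CRISPR–Cas locus). An element whose partner exists in the genome but beyond
the window is **isolated-remote**; with no partner anywhere in the genome it
is an **orphan**. "Genome" means the assembly: in draft-genome mode contigs
are grouped by assembly id, so a partner on another contig counts as present
but remote. Distances are computed on the linear sequence; circular
replicons are not wrapped by default.

The adaptation-module census tabulates, per type, {CRISPR ±} × {nearby
cas1–cas2 pair, remote pair, absent}; the remote pair is only evaluated when
the locus itself lacks the pair (conditional-check rule), so each locus lands
in exactly one cell and row sums equal the locus count. Distance
distributions between types are compared with two-sided Mann–Whitney
rank-sum tests.

## Real vs false, and the false-element cascade

The screen operates on repeat clusters:

1. A cluster with ≥1 member co-located with a valid cas locus is **real**,
   and every member inherits the label — an isolated array whose repeat
   matches cas-associated arrays elsewhere is a real CRISPR.
2. A remaining candidate is **rescued** as real when its consensus repeat is
   within `rescue_mismatch_limit = 5` mismatches of any real-cluster
   representative. Mismatches are counted as global edit distance
   (substitutions + indels, so length difference counts); the choice of
   alignment-with-gaps over Hamming distance is ours, as the underlying rule
   does not specify one.
3. Everything else is a false-CRISPR and enters the classification cascade.
   Spacer diversity is reported as evidence throughout but does not veto
   REAL-ness by default; `strict_diversity` additionally demotes cas-absent,
   non-diverse rescues.

**Tandem detector.** A from-scratch scorer with the classic tandem-repeat
weights: the region is locally aligned against a tiled candidate unit with
match +2, mismatch −7, indel −7; a call is positive at score ≥ 50, aligned
coverage ≥ 0.8 of the region, and ≥ 2 unit copies. Candidate units are
per-period majority consensuses; for regions ≤ 250 bp every period up to
half the region length is tried, longer regions propose periods from a
k-mer distance histogram (plus all periods ≤ 6 for the simple-repeat
check). The best-scoring call wins, smaller periods on ties. The local
alignment against a tiled unit is mathematically equivalent to wraparound
dynamic programming for linear gap costs, and admits an independent oracle
(exhaustive periods scored with Biopython's aligner) used in the tests.
Note that the best-scoring period may be a multiple of the fundamental one:
two long 95 %-identical copies can outscore many short mutated copies.

**STAR detector.** The *S. aureus* repeat signature
`T[G/A/T]TGTTG[G/T]GGCCC[C/A]` (12 concrete instantiations) is scanned with
overlap on both strands, over the array region and its consensus repeat; one
hit is a positive call.

**Simple/low-complexity detector.** Positive when (a) a tandem call with
unit ≤ `simple_max_unit = 6` bp covers ≥ 0.8 of the region, or (b) one
nucleotide's frequency is ≥ `mono_frac = 0.40`, or (c) mononucleotide
Shannon entropy is ≤ 1.5 bits; the triggering criterion is recorded.
`simple_max_unit` is 6 rather than 5: the canonical worked example of a
simple repeat (GCCGTT × 12) has a 6 bp unit even though simple repeats are
usually described as 1–5 bp.

**Cascade order.** STAR → TANDEM → SIMPLE → UNKNOWN (configurable). STAR
precedes TANDEM because a STAR element — identical motif-bearing repeats
head-to-tail — *is* structurally a tandem repeat; tested after TANDEM the
class would be unreachable, contradicting both the recoverability of planted
STAR elements and the observed dominance of STAR calls among *S. aureus*
false-CRISPRs. The TANDEM stage additionally defers to SIMPLE when a ≤6 bp
unit already explains the region (a homopolymer scores as a tandem at
almost any period). SIMPLE is evaluated after both, consistent with
describing an A-rich region as "not STAR-like and not tandem".

Every putative array receives exactly one label, evidence fields are always
populated, and adding a cas locus near any cluster member can only move
labels toward REAL.

**Collection comparison.** A query repeat matching a known false-CRISPR
repeat at ≥ 0.90 identity over ≥ 0.90 of the query length (best local
alignment) is flagged as a potential false-CRISPR.

## Synthetic genomes

The generator plants elements in i.i.d. background (configurable GC; high-GC
and high-AT presets exist because composition bias is a known source of
unexplained false-CRISPRs) with full coordinate truth:

* **CRISPR arrays**: random repeat (21–47 bp), spacers of repeat length ±5 bp
  (clamped at 18), per-copy substitution rate; spacer regimes *diverse*
  (i.i.d.), *duplicated* (one spacer repeated), *constant* (all equal).
* **Cas loci**: coordinate stubs with family labels — 900 bp genes, 100 bp
  apart — carrying the default family sets per type (≥3 type-consistent
  signature genes for types I–IV; type V carries cpf1). Genes have no
  sequence signal; the pipeline consumes annotations, not proteins.
* **Tandem repeats**: exact head-to-tail copies of a random unit; the
  pipeline-level default (60 bp × 6) sits in the range where a repeat
  detector mistakes the unit for repeat + short spacer.
* **STAR elements**: identical units embedding one uniformly drawn motif
  instantiation (either strand) separated by identical linkers.
* **Simple repeats**: mononucleotide runs with 5 % substitution noise.

Elements are separated by random background of at least twice the longest
element length, and — when cas loci are planted — at least 12 kb, so no
false element sits inside the 10 kb co-location window of a planted locus
(it would otherwise be real by definition). Everything is reproducible from
the seed.

What the generator does *not* emulate: real genomic repeat families and
mobile elements, GC-skew structure within elements, protospacer provenance
of spacers, gene sequences for cas loci, degenerate or partially deleted
arrays beyond simple terminal truncation. Passing the planted-recovery
tests therefore demonstrates that the rules are implemented and separable
under their own model assumptions — not field performance on real genomes,
where repeat families are more diverse and annotations noisier.

## Problem sizes in tests and acceptance

The bundled checks run the detector against a brute-force fixed-period
enumerator on 100 random sequences of 2–5 kb plus 10 planted arrays; the
tandem scorer against the exhaustive oracle on regions ≤ 200 bp; the full
pipeline on 50 synthetic genomes (~65 kb each, one real type II system plus
one tandem, STAR and simple element); the diversity rule on all 494
multisets of ≤8 spacers from a 4-member pool; and the STAR motif on all 24
instantiations (forward + reverse-complement) plus 1,000 random 14-mers.
These sizes keep a full run under a few minutes while every rule boundary
(200 bp merge gap, 10 kb window, 0.90/0.70 identities, 5-mismatch rescue,
single-gene cpf1 typing) is exercised exactly.

## Known limitations

* Arrays whose copies lack a shared exact 8-mer at a common offset (heavily
  mutated repeats) can be missed; CRT-family detectors share this property.
* With exactly 3 copies, boundary wobble of 1–2 bp occurs when flank columns
  agree by chance; the planted-recovery contract is ±2 bp.
* The tandem detector reports one best call, which may be a period multiple;
  it does not decompose nested periodicities.
* Array orientation, leader-sequence identification and
  spacer-to-protospacer mapping are out of scope.
* `n_spacer_clusters` uses greedy clustering, so cluster counts can depend on
  processing order for borderline identity values, exactly as in CD-HIT.
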