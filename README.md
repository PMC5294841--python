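# crisprscreen

CRISPR–Cas annotation for bacterial and archaeal genomes with an integrated
screen for **false-CRISPRs** — genomic elements whose repeat–spacer-like
structure fools structure-based CRISPR detectors.

CRISPR arrays (near-identical 21–47 bp direct repeats separated by unique
spacers) are usually found by looking for exactly that structure. But tandem
repeats, *Staphylococcus aureus* repeat (STAR)-like elements and simple
low-complexity repeats mimic it, and structure-only detectors annotate them
as CRISPRs. `crisprscreen` is for anyone annotating CRISPR–Cas systems who
wants those impostors identified rather than silently included: it detects
arrays, types cas loci, quantifies CRISPR/cas co-location, and labels every
putative array as REAL, TANDEM, STAR, SIMPLE or UNKNOWN.

## The screen

Arrays are detected CRT-style (seed k-mer chaining, column-wise extension,
partial terminal repeats annexed, neighbouring arrays within 200 bp with
≥90 %-identical repeats merged) and their consensus repeats clustered across
genomes at 90 % identity (greedy, CD-HIT-EST-like; identity = matches over
the shorter length). Cas gene annotations are grouped into loci (≥3 genes,
≥1 of cas1/cas2 or a core interference gene) and typed by signature genes —
cas3 → I, cas9 → II, cas10 → III, csf1 → IV, cpf1 → V — with a confident call
at ≥3 type-consistent signature genes, or a single *cpf1* for type V.

A repeat cluster is **real** when at least one member array lies within
10 kb of a valid cas locus; all members inherit the label, and a candidate
whose consensus repeat is within 5 mismatches of a real repeat is rescued.
Everything else is a false-CRISPR and is classified by cascade:

| label  | evidence                                                                  |
|--------|---------------------------------------------------------------------------|
| STAR   | signature motif `T[G/A/T]TGTTG[G/T]GGCCC[C/A]`, both strands              |
| TANDEM | local alignment vs a tiled unit (match +2, mismatch −7, indel −7) ≥ 50, coverage ≥ 0.8 |
| SIMPLE | ≤6 bp-unit tandem covering the region, ≥40 % one base, or entropy ≤ 1.5 bits |
| UNKNOWN| none of the above                                                         |

Spacer diversity (spacers clustered at 70 % identity; diverse iff at least
half fall into distinct clusters) is reported as evidence alongside the
cas-near / cas-far / cas-absent status of every array.

See `docs/methods.md` for the full model description, parameter rationale
and limitations.

## Worked example

Generate a synthetic genome carrying one real type II CRISPR–Cas system,
one tandem repeat, one STAR element and one poly-A run, then screen it:

```sh
$ crispr-screen simulate --seed 11 --out demo
synthetic1: 66403 bp, 5 planted element(s)

$ crispr-screen run --fasta demo.fasta --cas-table demo.cas.tsv --out out
1 genome(s): 4 array(s), 0 cluster(s) + 4 singleton(s); classifications: {'REAL': 1, 'TANDEM': 1, 'STAR': 1, 'SIMPLE': 1}
  gff3: out/annotations.gff3
  arrays_tsv: out/arrays.tsv
  summary_json: out/summary.json
```

All four planted elements are detected as putative arrays — that is the
point: they all look like CRISPRs structurally. The per-array table
separates them:

```
array_id                start  end    n_repeats  n_spacers  diversity_status  classification  cas_evidence  rescue_distance  distance_to_nearest_cas
synthetic1:12001-12334  12001  12334  7          6          DIVERSE           REAL            cas-near      0                200
synthetic1:29433-29774  29433  29774  6          5          NOT_DIVERSE       TANDEM          cas-far       23               12000
```

The real array sits 200 bp from its cas locus (cas-near, rescue distance 0
to its own real cluster) and has diverse spacers; the tandem repeat is far
from any cas gene, has no spacer diversity, and its "repeat" is 23
mismatches away from the nearest real repeat. The JSON summary aggregates
the same table into cluster/singleton counts, loci by type
(`{'II_confident': 1}` here), co-location counts and the evidence matrix.

The same screen runs on real data: `--fasta` takes any genome FASTA and
`--cas-table` a TSV/GFF3 of cas gene coordinates and families (or
`--hmmscan` output plus `--gene-coords`). `crispr-screen compare` checks
repeats against a collection of known false-CRISPR repeats (90 % identity
over 90 % of the query length).

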