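"""Synthetic genomes with planted elements and exact ground truth.

The generator emulates the element families the screen must separate:

* repeat-spacer arrays (21-47 bp near-identical repeats, spacers of similar
  size, with diverse / duplicated / constant spacer regimes),
* tandem repeats (head-to-tail copies of a random unit; units in the
  40-100 bp range mimic the CRISPR-confusable tandems),
* STAR-like elements (identical motif-bearing units separated by identical
  linkers, the head-to-tail organisation reported for the family),
* mononucleotide/low-complexity runs (5 % substitution noise),
* cas loci as coordinate stubs with family labels (genes carry no sequence
  signal; the pipeline consumes annotations, not proteins).

Planted elements are separated by at least twice the longest element length of
i.i.d. background (configurable GC, with high-GC / high-AT presets available
for composition-bias stress tests), so detections can be attributed
unambiguously.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .formats import CasGeneHit, GenomeRecord

__all__ = [
    "CrisprSpec",
    "TandemSpec",
    "StarSpec",
    "SimpleSpec",
    "CasLocusSpec",
    "GenomeSpec",
    "PlantedElement",
    "SyntheticTruth",
    "generate_genome",
    "plant_crispr",
    "plant_star",
    "plant_tandem",
    "plant_simple",
]

BASES = np.array(list("ACGT"))

#: Default gene families planted per CRISPR-Cas type (>= 3 type-consistent
#: signature genes for I/II/III/IV so planted loci type confidently; a single
#: cpf1 suffices for type V).
TYPE_FAMILIES: dict[str, list[str]] = {
    "I": ["cas3", "cse1", "cse2", "cas7", "cas5", "cas1", "cas2"],
    "II": ["cas9", "csn2", "cas4", "cas1", "cas2"],
    "III": ["cas10", "csm2", "csm3", "csm4", "cas1", "cas2"],
    "IV": ["csf1", "csf2", "csf3"],
    "V": ["cpf1", "cas4", "cas1", "cas2"],
}


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(rng.choice(BASES, size=length, p=p))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [b for b in "ACGT" if b != out[i]]
            out[i] = choices[rng.integers(3)]
    return "".join(out)


# ---------------------------------------------------------------------------
# element specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CrisprSpec:
    repeat_len: int = 25
    n_spacers: int = 6
    diversity_mode: str = "diverse"  # diverse | duplicated | constant
    mutation_rate: float = 0.0
    spacer_len: Optional[int] = None  # default: repeat_len +/- 5 per spacer
    cas_type: Optional[str] = None  # plant a cas locus of this type nearby
    cas_distance: int = 200
    cas_families: Optional[tuple[str, ...]] = None


@dataclass(frozen=True)
class TandemSpec:
    unit_len: int = 60
    copies: int = 6
    mutation_rate: float = 0.0


@dataclass(frozen=True)
class StarSpec:
    n_copies: int = 5
    unit_len: int = 40
    linker_len: int = 30


@dataclass(frozen=True)
class SimpleSpec:
    base: str = "A"
    length: int = 290
    noise: float = 0.05


@dataclass(frozen=True)
class CasLocusSpec:
    """A standalone cas locus (no companion CRISPR): orphan/isolated scenarios."""

    cas_type: str = "I"
    families: Optional[tuple[str, ...]] = None


@dataclass
class GenomeSpec:
    genome_id: str = "synthetic1"
    gc: float = 0.5
    crisprs: list[CrisprSpec] = field(default_factory=list)
    tandems: list[TandemSpec] = field(default_factory=list)
    stars: list[StarSpec] = field(default_factory=list)
    simples: list[SimpleSpec] = field(default_factory=list)
    cas_loci: list[CasLocusSpec] = field(default_factory=list)
    min_separation: Optional[int] = None  # default: 2x the longest element


@dataclass
class PlantedElement:
    kind: str  # CRISPR | TANDEM | STAR | SIMPLE | CAS_LOCUS
    start: int  # 1-based inclusive
    end: int
    repeat: Optional[str] = None
    spacers: list[str] = field(default_factory=list)
    diversity_mode: Optional[str] = None
    unit: Optional[str] = None
    families: list[str] = field(default_factory=list)
    cas_type: Optional[str] = None


@dataclass
class SyntheticTruth:
    genome_id: str
    elements: list[PlantedElement] = field(default_factory=list)

    def of_kind(self, kind: str) -> list[PlantedElement]:
        return [e for e in self.elements if e.kind == kind]


# ---------------------------------------------------------------------------
# element builders (sequence fragments, coordinates assigned at assembly)
# ---------------------------------------------------------------------------


def plant_crispr(
    rng: np.random.Generator, spec: CrisprSpec
) -> tuple[str, str, list[str]]:
    """Build a repeat-spacer array fragment: returns (sequence, repeat, spacers)."""
    if not (21 <= spec.repeat_len <= 47):
        raise ValueError("repeat_len must be within 21-47")
    if spec.diversity_mode not in {"diverse", "duplicated", "constant"}:
        raise ValueError(f"unknown diversity_mode {spec.diversity_mode!r}")
    repeat = random_dna(rng, spec.repeat_len)

    def spacer_length() -> int:
        if spec.spacer_len is not None:
            return spec.spacer_len
        return max(18, spec.repeat_len + int(rng.integers(-5, 6)))

    spacers: list[str] = []
    for i in range(spec.n_spacers):
        if spec.diversity_mode == "constant" and spacers:
            spacers.append(spacers[0])
        elif spec.diversity_mode == "duplicated" and i == 1:
            spacers.append(spacers[0])
        else:
            spacers.append(random_dna(rng, spacer_length()))
    parts = []
    for sp in spacers:
        parts.append(_mutate(rng, repeat, spec.mutation_rate))
        parts.append(sp)
    parts.append(_mutate(rng, repeat, spec.mutation_rate))
    return "".join(parts), repeat, spacers


def plant_star(rng: np.random.Generator, spec: StarSpec) -> tuple[str, str]:
    """Motif-bearing unit copies separated by identical linkers: (sequence, unit)."""
    from .false_crispr import STAR_MOTIF, expand_motif

    instances = expand_motif(STAR_MOTIF)
    motif = instances[rng.integers(len(instances))]
    if rng.random() < 0.5:
        from .repeat_cluster import reverse_complement

        motif = reverse_complement(motif)
    if spec.unit_len < len(motif):
        raise ValueError("unit_len shorter than the signature motif")
    offset = int(rng.integers(spec.unit_len - len(motif) + 1))
    unit = random_dna(rng, spec.unit_len)
    unit = unit[:offset] + motif + unit[offset + len(motif) :]
    linker = random_dna(rng, spec.linker_len)
    parts = []
    for i in range(spec.n_copies):
        if i:
            parts.append(linker)
        parts.append(unit)
    return "".join(parts), unit


def plant_tandem(rng: np.random.Generator, spec: TandemSpec) -> tuple[str, str]:
    """Head-to-tail unit copies: (sequence, unit)."""
    if spec.unit_len < 1 or spec.copies < 2:
        raise ValueError("tandem needs unit_len >= 1 and copies >= 2")
    unit = random_dna(rng, spec.unit_len)
    seq = "".join(_mutate(rng, unit, spec.mutation_rate) for _ in range(spec.copies))
    return seq, unit


def plant_simple(rng: np.random.Generator, spec: SimpleSpec) -> str:
    """Mononucleotide run with substitution noise."""
    if spec.base not in "ACGT":
        raise ValueError("base must be one of A/C/G/T")
    return _mutate(rng, spec.base * spec.length, spec.noise)


def _cas_locus_genes(
    cas_type: str, families: Optional[Sequence[str]]
) -> list[str]:
    fams = list(families) if families else TYPE_FAMILIES[cas_type]
    return fams


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

_GENE_LEN = 900
_GENE_GAP = 100


def generate_genome(
    spec: GenomeSpec, seed: int
) -> tuple[GenomeRecord, SyntheticTruth, list[CasGeneHit]]:
    """Assemble a genome with all planted elements, truth and cas annotations.

    Elements are placed in spec order, separated by random background of at
    least twice the longest element length; a CRISPR with a ``cas_type``
    carries its cas locus immediately downstream at ``cas_distance``.
    Byte-identical output for a fixed (spec, seed).
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth(genome_id=spec.genome_id)
    cas_hits: list[CasGeneHit] = []

    # build all fragments first so the separation rule can use the true max
    fragments: list[tuple[str, PlantedElement, Optional[list[str]], int]] = []
    # (sequence, element-proto, cas families or None, cas distance)
    for cs in spec.crisprs:
        seq, repeat, spacers = plant_crispr(rng, cs)
        el = PlantedElement(
            kind="CRISPR", start=0, end=0, repeat=repeat, spacers=spacers,
            diversity_mode=cs.diversity_mode, cas_type=cs.cas_type,
        )
        fams = (
            _cas_locus_genes(cs.cas_type, cs.cas_families) if cs.cas_type else None
        )
        fragments.append((seq, el, fams, cs.cas_distance))
    for ts in spec.tandems:
        seq, unit = plant_tandem(rng, ts)
        fragments.append((seq, PlantedElement(kind="TANDEM", start=0, end=0, unit=unit), None, 0))
    for ss in spec.stars:
        seq, unit = plant_star(rng, ss)
        fragments.append((seq, PlantedElement(kind="STAR", start=0, end=0, unit=unit), None, 0))
    for ps in spec.simples:
        seq = plant_simple(rng, ps)
        fragments.append((seq, PlantedElement(kind="SIMPLE", start=0, end=0, unit=ps.base), None, 0))
    for ls in spec.cas_loci:
        fams = _cas_locus_genes(ls.cas_type, ls.families)
        el = PlantedElement(kind="CAS_LOCUS", start=0, end=0, families=fams, cas_type=ls.cas_type)
        fragments.append(("", el, fams, -1))  # standalone locus, no element sequence

    longest = max(
        [len(s) for s, _, _, _ in fragments]
        + [len(f or []) * (_GENE_LEN + _GENE_GAP) for _, _, f, _ in fragments]
        + [1]
    )
    if spec.min_separation is not None:
        sep = spec.min_separation
    else:
        sep = 2 * longest
        # planted false elements must sit beyond the 10 kb co-location window
        # of any planted cas locus, else they are real by definition
        if any(f or el.kind == "CAS_LOCUS" for _, el, f, _ in fragments):
            sep = max(sep, 12_000)

    chunks: list[str] = []
    pos = 0  # 0-based length so far

    def _append_background(length: int) -> None:
        nonlocal pos
        chunks.append(random_dna(rng, length, spec.gc))
        pos += length

    def _append_cas_locus(families: Sequence[str], cas_type: Optional[str]) -> PlantedElement:
        nonlocal pos
        locus_start = pos + 1
        for i, fam in enumerate(families):
            if i:
                _append_background(_GENE_GAP)
            gstart = pos + 1
            _append_background(_GENE_LEN)
            cas_hits.append(
                CasGeneHit(spec.genome_id, gstart, pos, "+", fam, 100.0, source="table")
            )
        el = PlantedElement(
            kind="CAS_LOCUS", start=locus_start, end=pos,
            families=list(families), cas_type=cas_type,
        )
        truth.elements.append(el)
        return el

    for seq, el, fams, cas_distance in fragments:
        _append_background(sep)
        if seq:
            el.start = pos + 1
            chunks.append(seq)
            pos += len(seq)
            el.end = pos
            truth.elements.append(el)
            if fams:  # companion cas locus downstream of the CRISPR
                _append_background(cas_distance - 1)
                _append_cas_locus(fams, el.cas_type)
        else:  # standalone cas locus
            _append_cas_locus(fams or [], el.cas_type)
    _append_background(sep)

    genome = GenomeRecord(spec.genome_id, "".join(chunks))
    for e in truth.elements:
        assert 1 <= e.start <= e.end <= genome.length
    return genome, truth, cas_hits


def write_truth_gff(truth: SyntheticTruth, path) -> None:
    """Ground-truth coordinates as GFF3 for external inspection."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, e in enumerate(truth.elements, start=1):
            attrs = f"ID=planted{i};kind={e.kind}"
            if e.cas_type:
                attrs += f";cas_type={e.cas_type}"
            fh.write(
                f"{truth.genome_id}\tcrisprscreen-sim\tplanted_element\t{e.start}\t{e.end}\t.\t+\t.\t{attrs}\n"
            )


def write_cas_tsv(hits: Sequence[CasGeneHit], path) -> None:
    with open(path, "w") as fh:
        fh.write("genome_id\tstart\tend\tstrand\tfamily\tscore\n")
        for h in hits:
            fh.write(
                f"{h.genome_id}\t{h.gene_start}\t{h.gene_end}\t{h.strand}\t{h.family}\t{h.score}\n"
            )
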