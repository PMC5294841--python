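"""Cas-locus assembly, validation, typing, and CRISPR/cas co-location.

Cas gene hits are chained into candidate loci (intergenic gap <= 1 kb by
default), validated (>= 3 cas genes, at least one from the adaptation pair
cas1/cas2 or the core interference components), and typed by counting
type-signature genes: a call is confident with >= 3 type-consistent signature
genes, except type V, whose single signature gene cpf1 suffices on its own.

Co-location uses the 10 kb window: a CRISPR and a cas locus within the window
form a CRISPR-Cas locus; a partner present in the genome but beyond the window
makes the element isolated-remote; a partner absent from the whole genome
makes it an orphan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from itertools import combinations
from statistics import median
from typing import Iterable, Mapping, Optional, Sequence

from scipy.stats import mannwhitneyu

from .array_detect import CrisprArray
from .formats import CasGeneHit, Config

__all__ = [
    "CORE_GENES",
    "SignatureTable",
    "CasLocus",
    "LocusRejection",
    "SystemAnnotation",
    "group_cas_genes",
    "validate_locus",
    "assign_type",
    "crispr_cas_distance",
    "interval_distance",
    "classify_colocation",
    "adaptation_matrix",
    "compare_distance_distributions",
]

#: Universal adaptation genes plus main interference-module components; a
#: valid locus must contain at least one of these.
CORE_GENES = frozenset(
    {"cas1", "cas2", "cas5", "cas7", "cas8", "cas9", "cas10", "csf1", "cpf1"}
)

MAIN_TYPES = ("I", "II", "III", "IV", "V")

_CAS_BASE_RE = re.compile(r"^(cas\d+)")


def _base_family(family: str) -> str:
    """cas8c -> cas8, Cas1 -> cas1; non-casN names pass through lower-cased."""
    fam = family.strip().lower()
    m = _CAS_BASE_RE.match(fam)
    return m.group(1) if m else fam


class SignatureTable:
    """Mapping from cas family label to the set of types it is a signature of."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self.mapping: dict[str, frozenset[str]] = {}
        for fam, types in mapping.items():
            types = frozenset(types)
            if not types:
                raise ValueError(f"family {fam!r} maps to no type")
            self.mapping[fam.strip().lower()] = types
        if self.mapping.get("cpf1", frozenset({"V"})) != frozenset({"V"}):
            raise ValueError("cpf1 must map to type V only")

    def types_of(self, family: str) -> frozenset[str]:
        return self.mapping.get(family.strip().lower(), frozenset())

    @classmethod
    def from_tsv(cls, path) -> "SignatureTable":
        mapping = {}
        with open(path) as fh:
            for ln in fh:
                ln = ln.strip()
                if not ln or ln.startswith("#") or ln.startswith("family\t"):
                    continue
                fam, types = ln.split("\t")
                mapping[fam] = [t.strip() for t in types.split(",")]
        return cls(mapping)

    @classmethod
    def default(cls) -> "SignatureTable":
        ref = resources.files("crisprscreen.data") / "signature_table.tsv"
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclass
class CasLocus:
    """A validated cluster of cas genes with a type call."""

    genome_id: str
    start: int
    end: int
    genes: list[CasGeneHit]
    type_call: str = "UNTYPED"
    confident: bool = False
    ambiguous: bool = False

    @property
    def families(self) -> list[str]:
        return [g.family for g in self.genes]

    @property
    def has_cas1_cas2(self) -> bool:
        bases = {_base_family(f) for f in self.families}
        return "cas1" in bases and "cas2" in bases

    @property
    def locus_id(self) -> str:
        return f"{self.genome_id}:{self.start}-{self.end}"


@dataclass(frozen=True)
class LocusRejection:
    genes: tuple[CasGeneHit, ...]
    reason: str


def group_cas_genes(hits: Sequence[CasGeneHit], gap_bp: int = 1_000) -> list[list[CasGeneHit]]:
    """Chain consecutive cas hits of one genome with intergenic gap <= gap_bp."""
    genomes = {h.genome_id for h in hits}
    if len(genomes) > 1:
        raise ValueError(f"group_cas_genes expects hits from one genome, got {sorted(genomes)}")
    hits = sorted(hits, key=lambda h: (h.gene_start, h.gene_end))
    groups: list[list[CasGeneHit]] = []
    for h in hits:
        if groups and h.gene_start - max(g.gene_end for g in groups[-1]) <= gap_bp:
            groups[-1].append(h)
        else:
            groups.append([h])
    return groups


def validate_locus(
    candidate: Sequence[CasGeneHit], config: Config | None = None
) -> CasLocus | LocusRejection:
    """Accept a candidate iff it has >= min_locus_genes genes and >= 1 core gene."""
    config = config or Config()
    genes = sorted(candidate, key=lambda h: (h.gene_start, h.gene_end))
    if len(genes) < config.min_locus_genes:
        return LocusRejection(tuple(genes), f"fewer than {config.min_locus_genes} cas genes")
    if not any(_base_family(g.family) in CORE_GENES for g in genes):
        return LocusRejection(tuple(genes), "no adaptation/core interference gene")
    return CasLocus(
        genome_id=genes[0].genome_id,
        start=min(g.gene_start for g in genes),
        end=max(g.gene_end for g in genes),
        genes=list(genes),
    )


def assign_type(
    locus: CasLocus, table: SignatureTable | None = None, min_signature_genes: int = 3
) -> tuple[str, bool]:
    """Type call and confidence for a validated locus (mutates the locus fields).

    The candidate type is the one with the most signature genes present;
    confident iff that count >= min_signature_genes.  A single cpf1 makes the
    locus a confident type V regardless of other counts; no signature genes
    give UNTYPED; a tie gives UNTYPED with the ambiguity flag set.
    """
    table = table or SignatureTable.default()
    if any(g.family.strip().lower() == "cpf1" for g in locus.genes):
        locus.type_call, locus.confident, locus.ambiguous = "V", True, False
        return "V", True
    counts = {t: 0 for t in MAIN_TYPES}
    for g in locus.genes:
        for t in table.types_of(g.family):
            if t in counts:
                counts[t] += 1
    best = max(counts.values())
    if best == 0:
        locus.type_call, locus.confident, locus.ambiguous = "UNTYPED", False, False
        return "UNTYPED", False
    winners = [t for t in MAIN_TYPES if counts[t] == best]
    if len(winners) > 1:
        locus.type_call, locus.confident, locus.ambiguous = "UNTYPED", False, True
        return "UNTYPED", False
    locus.type_call = winners[0]
    locus.confident = best >= min_signature_genes
    locus.ambiguous = False
    return locus.type_call, locus.confident


# ---------------------------------------------------------------------------
# distances and co-location
# ---------------------------------------------------------------------------


def interval_distance(start1: int, end1: int, start2: int, end2: int) -> int:
    """Distance between two 1-based inclusive intervals: start2 - end1 for the
    closer ordering, 0 on overlap (matches the convention used throughout)."""
    if start1 > start2:
        start1, end1, start2, end2 = start2, end2, start1, end1
    if start2 <= end1:
        return 0
    return start2 - end1


def crispr_cas_distance(array: CrisprArray, locus: CasLocus) -> int:
    """Distance from an array to the nearest gene of a cas locus (bp)."""
    if array.genome_id != locus.genome_id:
        raise ValueError(
            f"array on {array.genome_id!r} vs locus on {locus.genome_id!r}: "
            "distance undefined across genomes"
        )
    return min(
        interval_distance(array.start, array.end, g.gene_start, g.gene_end)
        for g in locus.genes
    )


CO_LOCATED = "CO_LOCATED"
ISOLATED_REMOTE = "ISOLATED_REMOTE"
ORPHAN = "ORPHAN"


@dataclass
class SystemAnnotation:
    """CRISPR/cas co-location annotation for one genome (assembly)."""

    genome_id: str
    arrays: list[CrisprArray]
    loci: list[CasLocus]
    array_labels: list[str] = field(default_factory=list)
    locus_labels: list[str] = field(default_factory=list)
    # per (array index, locus index) on the same record
    distances: dict[tuple[int, int], int] = field(default_factory=dict)
    nearest_cas_distance: list[Optional[int]] = field(default_factory=list)


def classify_colocation(
    arrays: Sequence[CrisprArray],
    loci: Sequence[CasLocus],
    config: Config | None = None,
    genome_id: str = "",
) -> SystemAnnotation:
    """Label every array and locus CO_LOCATED / ISOLATED_REMOTE / ORPHAN.

    All elements are assumed to belong to one genome (assembly); elements may
    sit on different records, in which case a partner on another record counts
    as present-but-remote.  Distances are recorded for same-record pairs.
    """
    config = config or Config()
    ann = SystemAnnotation(genome_id=genome_id, arrays=list(arrays), loci=list(loci))
    for ai, arr in enumerate(ann.arrays):
        dists = []
        for li, loc in enumerate(ann.loci):
            if arr.genome_id == loc.genome_id:
                d = crispr_cas_distance(arr, loc)
                ann.distances[(ai, li)] = d
                dists.append(d)
        if not ann.loci:
            label = ORPHAN
        elif dists and min(dists) <= config.window_bp:
            label = CO_LOCATED
        else:
            label = ISOLATED_REMOTE
        ann.array_labels.append(label)
        ann.nearest_cas_distance.append(min(dists) if dists else None)
    for li, loc in enumerate(ann.loci):
        dists = [ann.distances[(ai, li)] for ai in range(len(ann.arrays)) if (ai, li) in ann.distances]
        if not ann.arrays:
            label = ORPHAN
        elif dists and min(dists) <= config.window_bp:
            label = CO_LOCATED
        else:
            label = ISOLATED_REMOTE
        ann.locus_labels.append(label)
    return ann


# ---------------------------------------------------------------------------
# adaptation-module census
# ---------------------------------------------------------------------------


def _has_remote_pair(
    locus: CasLocus, all_hits: Sequence[CasGeneHit], gap_bp: int
) -> bool:
    """True when a cas1-cas2 gene pair exists in the genome outside this locus."""
    outside = [
        h
        for h in all_hits
        if not (
            h.genome_id == locus.genome_id
            and h.gene_start >= locus.start
            and h.gene_end <= locus.end
        )
    ]
    by_genome: dict[str, list[CasGeneHit]] = {}
    for h in outside:
        by_genome.setdefault(h.genome_id, []).append(h)
    for hits in by_genome.values():
        for group in group_cas_genes(hits, gap_bp):
            bases = {_base_family(g.family) for g in group}
            if "cas1" in bases and "cas2" in bases:
                return True
    return False


def adaptation_matrix(
    annotations: Sequence[SystemAnnotation],
    cas_hits_by_genome: Mapping[str, Sequence[CasGeneHit]],
    config: Config | None = None,
    types: Sequence[str] = ("I", "II", "III"),
) -> dict[str, dict[str, int]]:
    """Census of cas1-cas2 presence per typed locus, split by CRISPR co-location.

    Rows are the six categories {CRISPR +/-} x {nearby pair, remote pair,
    absent}; the remote pair is only evaluated when no nearby cas1-cas2 pair
    exists (conditional-check rule), so a locus with a nearby pair lands in
    the ``*_nearby`` row regardless of remote copies.  Row counts per type sum
    to the number of classified loci of that type.
    """
    config = config or Config()
    rows = [
        "crispr+_nearby+",
        "crispr+_remote+",
        "crispr+_remote-",
        "crispr-_nearby+",
        "crispr-_remote+",
        "crispr-_remote-",
    ]
    matrix = {t: {r: 0 for r in rows} for t in types}
    for ann in annotations:
        hits = cas_hits_by_genome.get(ann.genome_id, [])
        for locus, label in zip(ann.loci, ann.locus_labels):
            t = locus.type_call
            if t not in matrix:
                continue
            crispr = "+" if label == CO_LOCATED else "-"
            if locus.has_cas1_cas2:
                row = f"crispr{crispr}_nearby+"
            elif _has_remote_pair(locus, hits, config.locus_gap_bp):
                row = f"crispr{crispr}_remote+"
            else:
                row = f"crispr{crispr}_remote-"
            matrix[t][row] += 1
    return matrix


def compare_distance_distributions(
    dist_lists: Mapping[str, Sequence[float]],
) -> dict:
    """Pairwise two-sided Mann-Whitney rank-sum tests plus per-list medians."""
    if len(dist_lists) < 2:
        raise ValueError("need at least two distance lists")
    for name, values in dist_lists.items():
        if len(values) == 0:
            raise ValueError(f"distance list {name!r} is empty")
    out = {
        "medians": {name: float(median(vals)) for name, vals in dist_lists.items()},
        "pairs": {},
    }
    for a, b in combinations(dist_lists, 2):
        stat, p = mannwhitneyu(dist_lists[a], dist_lists[b], alternative="two-sided")
        out["pairs"][f"{a}_vs_{b}"] = {"U": float(stat), "p_value": float(p)}
    return out
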