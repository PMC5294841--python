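"""External representations and core domain types.

Everything downstream of this module works on in-memory domain objects
(:class:`GenomeRecord`, :class:`CasGeneHit`, ...); all file parsing and
report writing is concentrated here.  Coordinates are 1-based inclusive in
every external file and in every domain type.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field, fields
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised for malformed input files; message names the offending record/line."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeRecord:
    """A single replicon/contig: identifier plus upper-case A/C/G/T/N sequence."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)} in sequence"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def slice(self, start: int, end: int) -> str:
        """Return the sequence between 1-based inclusive coordinates."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(
                f"coordinates [{start},{end}] outside record {self.id!r} "
                f"of length {self.length}"
            )
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class CasGeneHit:
    """An annotated cas gene on a genome (1-based inclusive coordinates)."""

    genome_id: str
    gene_start: int
    gene_end: int
    strand: str
    family: str
    score: float
    source: str = "table"

    def __post_init__(self) -> None:
        if self.gene_start > self.gene_end:
            raise FormatError(
                f"cas hit {self.family} on {self.genome_id}: "
                f"start {self.gene_start} > end {self.gene_end}"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"cas hit {self.family}: bad strand {self.strand!r}")
        if not self.family:
            raise FormatError("cas hit with empty family label")


@dataclass
class Config:
    """All pipeline thresholds, with the screening defaults.

    The co-location window (10 kb), the 200 bp array-merge gap, the 90 % / 70 %
    repeat- and spacer-clustering identities, the >=3-gene locus rule, the
    5-mismatch rescue and the 90 %/90 % collection-comparison rule are the
    normative defaults of the screening procedure; everything is overridable
    from YAML.
    """

    window_bp: int = 10_000
    merge_gap_bp: int = 200
    repeat_cluster_identity: float = 0.90
    spacer_cluster_identity: float = 0.70
    min_locus_genes: int = 3
    min_signature_genes: int = 3
    rescue_mismatch_limit: int = 5
    collection_identity: float = 0.90
    collection_coverage: float = 0.90
    locus_gap_bp: int = 1_000
    n_policy: str = "reject"  # or "map": map non-ACGTN characters to N
    strict_diversity: bool = False
    both_strands: bool = False
    circular: bool = False
    # detector / classifier sub-parameter blocks (dataclasses defined in their
    # own modules; stored here as plain dicts when loaded from YAML)
    detector: "object" = None
    classifier: "object" = None

    def __post_init__(self) -> None:
        for name in (
            "repeat_cluster_identity",
            "spacer_cluster_identity",
            "collection_identity",
            "collection_coverage",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name in (
            "window_bp",
            "merge_gap_bp",
            "min_locus_genes",
            "min_signature_genes",
            "rescue_mismatch_limit",
            "locus_gap_bp",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_policy not in {"reject", "map"}:
            raise ValueError(f"n_policy must be 'reject' or 'map', got {self.n_policy!r}")
        if self.detector is None:
            from .array_detect import DetectorParams

            self.detector = DetectorParams()
        if self.classifier is None:
            from .false_crispr import ClassifierParams

            self.classifier = ClassifierParams()

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "Config":
        from .array_detect import DetectorParams
        from .false_crispr import ClassifierParams

        raw = dict(raw)
        det = raw.pop("detector", None)
        clf = raw.pop("classifier", None)
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        if det is not None:
            cfg.detector = DetectorParams(**det) if isinstance(det, Mapping) else det
        if clf is not None:
            cfg.classifier = ClassifierParams(**clf) if isinstance(clf, Mapping) else clf
        return cfg

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["detector"] = asdict(self.detector)
        d["classifier"] = asdict(self.classifier)
        return d


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _clean_sequence(record_id: str, seq: str, n_policy: str) -> str:
    seq = seq.upper().replace("U", "T")
    if not seq:
        raise FormatError(f"record {record_id!r} has an empty sequence")
    bad = set(seq) - VALID_BASES
    if bad:
        if n_policy == "map":
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        else:
            raise FormatError(
                f"record {record_id!r}: invalid characters {sorted(bad)} "
                "(set n_policy to 'map' to replace them with N)"
            )
    return seq


def read_fasta(path: str | os.PathLike, n_policy: str = "reject") -> list[GenomeRecord]:
    """Read a (multi-)FASTA file into :class:`GenomeRecord` objects, in file order."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        records.append(GenomeRecord(rec.id, _clean_sequence(rec.id, str(rec.seq), n_policy)))
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | os.PathLike) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


_CAS_TSV_COLUMNS = ["genome_id", "start", "end", "strand", "family", "score"]


def _parse_gff_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_cas_table(path: str | os.PathLike) -> list[CasGeneHit]:
    """Read cas-gene annotations from TSV or GFF3.

    TSV needs columns genome_id/start/end/strand/family/score (header optional
    if in that order); GFF3 needs a ``cas_family`` (or ``family``/``gene``)
    attribute.  Hits are returned sorted by (genome_id, gene_start).
    """
    hits: list[CasGeneHit] = []
    with open(path) as fh:
        lines = fh.readlines()
    is_gff = any(ln.startswith("##gff-version") for ln in lines[:5]) or str(path).endswith(
        (".gff", ".gff3")
    )
    for lineno, ln in enumerate(lines, start=1):
        ln = ln.rstrip("\n")
        if not ln or ln.startswith("#"):
            continue
        cols = ln.split("\t")
        try:
            if is_gff:
                if len(cols) < 9:
                    raise FormatError("GFF3 line with fewer than 9 columns")
                attrs = _parse_gff_attributes(cols[8])
                family = attrs.get("cas_family") or attrs.get("family") or attrs.get("gene")
                if not family:
                    raise FormatError("no cas_family/family/gene attribute")
                score = 0.0 if cols[5] in {".", ""} else float(cols[5])
                hit = CasGeneHit(cols[0], int(cols[3]), int(cols[4]), cols[6], family, score)
            else:
                if cols[0] == "genome_id":  # header row
                    missing = [c for c in _CAS_TSV_COLUMNS if c not in cols]
                    if missing:
                        raise FormatError(f"missing columns {missing}")
                    continue
                if len(cols) < 6:
                    raise FormatError("TSV row with fewer than 6 columns")
                hit = CasGeneHit(
                    cols[0], int(cols[1]), int(cols[2]), cols[3], cols[4], float(cols[5])
                )
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        hits.append(hit)
    hits.sort(key=lambda h: (h.genome_id, h.gene_start, h.gene_end))
    return hits


def read_gene_coords(path: str | os.PathLike) -> dict[str, tuple[str, int, int, str]]:
    """Protein-id -> (genome_id, start, end, strand) companion table for hmmscan input."""
    table = {}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, start=1):
            ln = ln.rstrip("\n")
            if not ln or ln.startswith("#"):
                continue
            cols = ln.split("\t")
            if cols[0] == "protein_id":
                continue
            if len(cols) < 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            table[cols[0]] = (cols[1], int(cols[2]), int(cols[3]), cols[4])
    return table


def read_hmmscan_tbl(
    path: str | os.PathLike,
    gene_coords: Mapping[str, tuple[str, int, int, str]],
    min_score: float | None = None,
) -> list[CasGeneHit]:
    """Parse hmmscan ``--domtblout`` output into cas hits.

    Keeps the single best-scoring family per gene (full-sequence score,
    column 8); hits under ``min_score`` are dropped.  Proteins missing from
    ``gene_coords`` are skipped with one summary warning.
    """
    best: dict[str, tuple[float, str]] = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            cols = ln.split()
            if len(cols) < 8:
                raise FormatError(f"{path}: malformed domtblout line: {ln.strip()[:60]}")
            family, gene, score = cols[0], cols[3], float(cols[7])
            if min_score is not None and score < min_score:
                continue
            if gene not in best or score > best[gene][0]:
                best[gene] = (score, family)
    hits, skipped = [], []
    for gene, (score, family) in best.items():
        if gene not in gene_coords:
            skipped.append(gene)
            continue
        genome_id, start, end, strand = gene_coords[gene]
        hits.append(CasGeneHit(genome_id, start, end, strand, family, score, source="hmmscan"))
    if skipped:
        warnings.warn(
            f"read_hmmscan_tbl: skipped {len(skipped)} hit(s) with no coordinate "
            f"mapping (e.g. {skipped[0]!r})",
            stacklevel=2,
        )
    hits.sort(key=lambda h: (h.genome_id, h.gene_start, h.gene_end))
    return hits


# ---------------------------------------------------------------------------
# report writing
# ---------------------------------------------------------------------------

ARRAY_TSV_COLUMNS = [
    "array_id",
    "genome_id",
    "start",
    "end",
    "n_repeats",
    "n_spacers",
    "consensus_repeat",
    "diversity_status",
    "n_spacer_clusters",
    "cluster_id",
    "classification",
    "cas_evidence",
    "rescue_distance",
    "distance_to_nearest_cas",
]


def _gff_escape(value: str) -> str:
    return str(value).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def write_report(results, out_dir: str | os.PathLike) -> dict[str, str]:
    """Write GFF3 + per-array TSV + JSON summary for a pipeline result.

    ``results`` is a :class:`crisprscreen.pipeline.PipelineResult` (duck-typed:
    needs ``array_table`` DataFrame, ``cas_locus_rows``, ``gff_rows`` and
    ``summary``).  Returns the mapping of report kind -> written path.
    """
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "gff3": os.path.join(out_dir, "annotations.gff3"),
        "arrays_tsv": os.path.join(out_dir, "arrays.tsv"),
        "summary_json": os.path.join(out_dir, "summary.json"),
    }

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for row in results.gff_rows:
            seqid, source, ftype, start, end, score, strand, attrs = row
            attr_str = ";".join(f"{k}={_gff_escape(v)}" for k, v in attrs.items())
            fh.write(
                f"{seqid}\t{source}\t{ftype}\t{start}\t{end}\t{score}\t{strand}\t.\t{attr_str}\n"
            )

    table: pd.DataFrame = results.array_table
    table.to_csv(paths["arrays_tsv"], sep="\t", index=False, columns=ARRAY_TSV_COLUMNS)

    def _default(obj):
        if isinstance(obj, float) and math.isinf(obj):
            return None
        raise TypeError(type(obj).__name__)

    with open(paths["summary_json"], "w") as fh:
        json.dump(results.summary, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")
    return paths


def parse_report_gff(path: str | os.PathLike) -> list[tuple]:
    """Re-parse a report GFF3 (for round-trip checks): (seqid, type, start, end, attrs)."""
    rows = []
    with open(path) as fh:
        for ln in fh:
            if ln.startswith("#") or not ln.strip():
                continue
            cols = ln.rstrip("\n").split("\t")
            rows.append((cols[0], cols[2], int(cols[3]), int(cols[4]), _parse_gff_attributes(cols[8])))
    return rows
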