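"""End-to-end orchestration: detect -> merge -> cluster -> diversity ->
cas typing -> co-location -> real/false classification -> reports.

``run`` is deterministic for fixed inputs and configuration.  Summaries are
derived from the per-array table (never tallied independently), so every
summary count reconciles with the TSV rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import __version__
from .array_detect import CrisprArray, extend_partial_repeats, find_arrays, merge_arrays
from .cas_loci import (
    CO_LOCATED,
    CasLocus,
    SignatureTable,
    adaptation_matrix,
    assign_type,
    classify_colocation,
    group_cas_genes,
    validate_locus,
)
from .diversity import is_diverse
from .false_crispr import classify_element, find_real_clusters
from .formats import CasGeneHit, Config, GenomeRecord, write_report
from .repeat_cluster import cluster_repeats

logger = logging.getLogger("crisprscreen")

__all__ = ["PipelineResult", "run"]


@dataclass
class PipelineResult:
    config: Config
    arrays: list[CrisprArray]
    loci: list[CasLocus]
    annotations: list  # SystemAnnotation per genome
    clusters: list
    classifications: dict  # array_id -> ElementClassification
    array_table: pd.DataFrame = field(default=None)
    gff_rows: list = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    def write(self, out_dir) -> dict[str, str]:
        return write_report(self, out_dir)


def _assembly_of(record_id: str, assembly_map: Optional[Mapping[str, str]]) -> str:
    if assembly_map and record_id in assembly_map:
        return assembly_map[record_id]
    return record_id


def run(
    genomes: Sequence[GenomeRecord],
    cas_hits: Sequence[CasGeneHit] = (),
    config: Config | None = None,
    signature_table: SignatureTable | None = None,
    assembly_map: Optional[Mapping[str, str]] = None,
) -> PipelineResult:
    """Run the full screen over a set of genome records.

    ``cas_hits`` may be empty, in which case every cluster is evaluated under
    the cas-absent branch.  ``assembly_map`` groups draft-genome contigs into
    assemblies (record id -> assembly id) so that a remote partner on another
    contig of the same assembly still counts as present in the genome.
    """
    config = config or Config()
    table = signature_table or SignatureTable.default()
    records = {g.id: g for g in genomes}
    logger.debug("config: %s", config.to_dict())

    # --- per-record array detection ------------------------------------
    arrays_by_record: dict[str, list[CrisprArray]] = {}
    for rec in genomes:
        arrs = find_arrays(rec, config.detector)
        arrs = [extend_partial_repeats(a, rec, config.detector) for a in arrs]
        arrs = merge_arrays(arrs, rec, config)
        arrays_by_record[rec.id] = arrs
        logger.debug("%s: %d array(s)", rec.id, len(arrs))

    # --- per-record cas loci -------------------------------------------
    hits_by_record: dict[str, list[CasGeneHit]] = {}
    for h in cas_hits:
        hits_by_record.setdefault(h.genome_id, []).append(h)
    loci_by_record: dict[str, list[CasLocus]] = {rid: [] for rid in records}
    for rid, hits in hits_by_record.items():
        if rid not in records:
            raise ValueError(f"cas hits reference unknown genome record {rid!r}")
        for h in hits:
            if h.gene_end > records[rid].length:
                raise ValueError(
                    f"cas hit {h.family} [{h.gene_start},{h.gene_end}] exceeds "
                    f"record {rid!r} length {records[rid].length}"
                )
        for cand in group_cas_genes(hits, config.locus_gap_bp):
            locus = validate_locus(cand, config)
            if isinstance(locus, CasLocus):
                assign_type(locus, table, config.min_signature_genes)
                loci_by_record[rid].append(locus)
            else:
                logger.debug("%s: rejected candidate locus (%s)", rid, locus.reason)

    # --- co-location per assembly --------------------------------------
    assemblies: dict[str, list[str]] = {}
    for rid in records:
        assemblies.setdefault(_assembly_of(rid, assembly_map), []).append(rid)
    annotations = []
    colocation_by_array: dict[str, str] = {}
    nearest_by_array: dict[str, Optional[int]] = {}
    diversity_by_array: dict[str, object] = {}
    all_arrays: list[CrisprArray] = []
    all_loci: list[CasLocus] = []
    for asm_id, rids in assemblies.items():
        arrs = [a for rid in rids for a in arrays_by_record[rid]]
        loci = [l for rid in rids for l in loci_by_record[rid]]
        ann = classify_colocation(arrs, loci, config, genome_id=asm_id)
        annotations.append(ann)
        for arr, label, nd in zip(ann.arrays, ann.array_labels, ann.nearest_cas_distance):
            colocation_by_array[arr.array_id] = label
            nearest_by_array[arr.array_id] = nd
            diversity_by_array[arr.array_id] = is_diverse(arr, config.spacer_cluster_identity)
        all_arrays.extend(arrs)
        all_loci.extend(loci)

    # --- cross-genome repeat clustering and real/false partition -------
    clusters = cluster_repeats(
        [(a.array_id, a.consensus_repeat) for a in all_arrays],
        threshold=config.repeat_cluster_identity,
        both_strands=config.both_strands,
    )
    cluster_of_array = {k: cl.cluster_id for cl in clusters for k in cl.member_keys}
    real_ids, false_ids = find_real_clusters(clusters, colocation_by_array)
    real_repeats = [
        cl.representative for cl in clusters if cl.cluster_id in real_ids
    ]

    classifications = {}
    arrays_by_id = {a.array_id: a for a in all_arrays}
    for arr in all_arrays:
        rec = records[arr.genome_id]
        flank = config.classifier.flank
        rstart = max(1, arr.start - flank)
        rend = min(rec.length, arr.end + flank)
        div = diversity_by_array[arr.array_id]
        cls = classify_element(
            array_id=arr.array_id,
            region_sequence=rec.slice(rstart, rend),
            consensus_repeat=arr.consensus_repeat,
            cluster_id=cluster_of_array[arr.array_id],
            cluster_is_real=cluster_of_array[arr.array_id] in real_ids,
            colocation_label=colocation_by_array[arr.array_id],
            diversity_status=div.status,
            real_repeats=real_repeats,
            params=config.classifier,
            rescue_mismatch_limit=config.rescue_mismatch_limit,
            strict_diversity=config.strict_diversity,
        )
        classifications[arr.array_id] = cls
        logger.debug("%s -> %s", arr.array_id, cls.label)

    # --- per-array table (single source of truth for summaries) --------
    rows = []
    for arr in all_arrays:
        div = diversity_by_array[arr.array_id]
        cls = classifications[arr.array_id]
        ev = cls.evidence
        cas_evidence = (
            "cas-near" if ev.cas_near else "cas-far" if ev.cas_far_in_genome else "cas-absent"
        )
        nd = nearest_by_array[arr.array_id]
        rows.append(
            {
                "array_id": arr.array_id,
                "genome_id": arr.genome_id,
                "start": arr.start,
                "end": arr.end,
                "n_repeats": arr.n_repeats,
                "n_spacers": arr.n_spacers,
                "consensus_repeat": arr.consensus_repeat,
                "diversity_status": div.status,
                "n_spacer_clusters": div.n_spacer_clusters,
                "cluster_id": cls.cluster_id,
                "classification": cls.label,
                "cas_evidence": cas_evidence,
                "rescue_distance": (
                    "" if ev.rescue_distance == float("inf") else int(ev.rescue_distance)
                ),
                "distance_to_nearest_cas": "" if nd is None else nd,
            }
        )
    array_table = pd.DataFrame(
        rows,
        columns=[
            "array_id", "genome_id", "start", "end", "n_repeats", "n_spacers",
            "consensus_repeat", "diversity_status", "n_spacer_clusters",
            "cluster_id", "classification", "cas_evidence", "rescue_distance",
            "distance_to_nearest_cas",
        ],
    )

    result = PipelineResult(
        config=config,
        arrays=all_arrays,
        loci=all_loci,
        annotations=annotations,
        clusters=clusters,
        classifications=classifications,
        array_table=array_table,
    )
    hits_by_assembly = {
        asm_id: [h for rid in rids for h in hits_by_record.get(rid, [])]
        for asm_id, rids in assemblies.items()
    }
    result.gff_rows = _gff_rows(result)
    result.summary = _summarize(result, cluster_of_array, hits_by_assembly, config)
    return result


def _gff_rows(result: PipelineResult) -> list:
    rows = []
    for arr in result.arrays:
        cls = result.classifications[arr.array_id]
        rows.append(
            (
                arr.genome_id, "crisprscreen", "repeat_spacer_array",
                arr.start, arr.end, ".", "+",
                {
                    "ID": arr.array_id,
                    "consensus_repeat": arr.consensus_repeat,
                    "n_repeats": arr.n_repeats,
                    "n_spacers": arr.n_spacers,
                    "classification": cls.label,
                },
            )
        )
    for locus in result.loci:
        rows.append(
            (
                locus.genome_id, "crisprscreen", "cas_locus",
                locus.start, locus.end, ".", "+",
                {
                    "ID": locus.locus_id,
                    "type_call": locus.type_call,
                    "confident": str(locus.confident).lower(),
                    "families": ",".join(locus.families),
                },
            )
        )
        for g in locus.genes:
            rows.append(
                (
                    g.genome_id, "crisprscreen", "cas_gene",
                    g.gene_start, g.gene_end, g.score, g.strand,
                    {"family": g.family, "locus": locus.locus_id},
                )
            )
    return rows


def _summarize(
    result: PipelineResult,
    cluster_of_array: Mapping[str, str],
    hits_by_record: Mapping[str, Sequence[CasGeneHit]],
    config: Config,
) -> dict:
    t = result.array_table
    by_cluster: dict[str, list[str]] = {}
    for cl in result.clusters:
        by_cluster[cl.cluster_id] = list(cl.member_keys)

    # Table-2-style evidence matrix, derived from the per-array table: rows
    # cluster/singleton, columns cas evidence x diversity status.
    evidence_matrix: dict[str, dict[str, int]] = {}
    for cl in result.clusters:
        sub = t[t.cluster_id == cl.cluster_id]
        if (sub.cas_evidence == "cas-near").any():
            cas_col = "cas-near"
        elif (sub.cas_evidence == "cas-far").any():
            cas_col = "cas-far"
        else:
            cas_col = "cas-absent"
        row = "singleton" if cl.is_singleton else "cluster"
        for status, count in sub.diversity_status.value_counts().items():
            dcol = {"DIVERSE": "d+", "NOT_DIVERSE": "d-", "SHORT": "short"}[status]
            key = f"{cas_col}_{dcol}"
            evidence_matrix.setdefault(row, {}).setdefault(key, 0)
            evidence_matrix[row][key] += int(count)

    locus_types = {}
    for locus in result.loci:
        key = locus.type_call + ("_confident" if locus.confident else "_putative")
        locus_types[key] = locus_types.get(key, 0) + 1

    colocation_counts: dict[str, int] = {}
    for ann in result.annotations:
        for label in ann.locus_labels:
            colocation_counts[f"locus_{label}"] = colocation_counts.get(f"locus_{label}", 0) + 1
        for label in ann.array_labels:
            colocation_counts[f"array_{label}"] = colocation_counts.get(f"array_{label}", 0) + 1

    return {
        "tool": "crisprscreen",
        "version": __version__,
        "config": config.to_dict(),
        "n_genomes": len({g for g in hits_by_record} | set(t.genome_id)),
        "n_arrays": int(len(t)),
        "n_clusters": sum(1 for cl in result.clusters if not cl.is_singleton),
        "n_singletons": sum(1 for cl in result.clusters if cl.is_singleton),
        "loci_by_type": locus_types,
        "colocation": colocation_counts,
        "classification_counts": t.classification.value_counts().to_dict(),
        "diversity_counts": t.diversity_status.value_counts().to_dict(),
        "evidence_matrix": evidence_matrix,
        "adaptation_matrix": adaptation_matrix(result.annotations, hits_by_record, config),
    }
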