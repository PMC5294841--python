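"""Greedy clustering of consensus repeats and comparison against collections.

Consensus repeats from different arrays (and different genomes) are grouped at
90 % identity with a CD-HIT-EST-like greedy incremental scheme: sequences are
taken longest-first and each joins the first existing cluster whose
representative it matches at or above the threshold, otherwise it founds a new
cluster.  Identity is computed over the best global alignment with the shorter
sequence as denominator (the CD-HIT convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Optional, Sequence

from Bio import Align

__all__ = [
    "RepeatCluster",
    "CollectionHit",
    "pairwise_identity",
    "alignment_matches",
    "cluster_repeats",
    "compare_to_collection",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _mask_ambiguous(a: str, b: str) -> tuple[str, str]:
    # N never matches anything, including another N: give the two sides
    # distinct sentinel characters before aligning.
    return a.replace("N", "!"), b.replace("N", "?")


def _identity_aligner() -> Align.PairwiseAligner:
    # global alignment with affine interior gaps and free end gaps: interior
    # gaps stay contiguous (a minimum-edit alignment of two very different
    # lengths scatters its mandatory gaps and accumulates coincidental
    # matches), and a shorter sequence is compared against its best
    # containment in the longer one, as CD-HIT's banded alignment does
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -0.5
    aligner.end_insertion_score = 0
    aligner.end_deletion_score = 0
    return aligner


def alignment_matches(a: str, b: str) -> int:
    """Number of identical columns in the best end-gap-free global alignment."""
    x, y = _mask_ambiguous(a.upper(), b.upper())
    aln = _identity_aligner().align(x, y)[0]
    matches = 0
    for (xs, xe), (ys, _) in zip(*aln.aligned):
        matches += sum(1 for i in range(xe - xs) if x[xs + i] == y[ys + i])
    return matches


def pairwise_identity(a: str, b: str) -> float:
    """Alignment identity with the shorter sequence as denominator.

    Symmetric by construction (the pair is put in canonical order before
    aligning) and in [0, 1].
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires two non-empty sequences")
    x, y = sorted((a.upper(), b.upper()))
    return alignment_matches(x, y) / min(len(a), len(b))


@dataclass
class RepeatCluster:
    """A group of arrays whose consensus repeats match the representative at >= threshold."""

    cluster_id: str
    representative: str
    members: list = field(default_factory=list)  # list of (key, sequence)

    @property
    def is_singleton(self) -> bool:
        return len(self.members) == 1

    @property
    def member_keys(self) -> list:
        return [k for k, _ in self.members]


def cluster_repeats(
    items: Sequence[tuple[Hashable, str]],
    threshold: float = 0.90,
    both_strands: bool = False,
) -> list[RepeatCluster]:
    """Greedy incremental clustering of (key, sequence) pairs.

    Sequences are processed longest-first (ties by input order); each joins the
    first cluster (in founding order) whose representative it matches at
    >= ``threshold`` identity, else founds a new cluster.  Deterministic.
    With ``both_strands`` the reverse complement is also tried; by default two
    repeats on opposite strands form distinct clusters.
    """
    order = sorted(range(len(items)), key=lambda i: (-len(items[i][1]), i))
    clusters: list[RepeatCluster] = []
    for idx in order:
        key, seq = items[idx]
        placed = False
        for cl in clusters:
            ident = pairwise_identity(seq, cl.representative)
            if both_strands:
                ident = max(ident, pairwise_identity(reverse_complement(seq), cl.representative))
            if ident >= threshold:
                cl.members.append((key, seq))
                placed = True
                break
        if not placed:
            clusters.append(
                RepeatCluster(cluster_id=f"C{len(clusters) + 1}", representative=seq, members=[(key, seq)])
            )
    return clusters


@dataclass(frozen=True)
class CollectionHit:
    """Best hit of a query repeat against an external repeat collection."""

    member_index: int
    member_id: str
    identity: float
    coverage: float


def _local_identity_coverage(query: str, member: str) -> tuple[float, float]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    q, m = _mask_ambiguous(query.upper(), member.upper())
    alignments = aligner.align(q, m)
    try:
        aln = alignments[0]
    except IndexError:
        return 0.0, 0.0
    qblocks, mblocks = aln.aligned
    matches = 0
    columns = 0
    for (qs, qe), (ms, me) in zip(qblocks, mblocks):
        columns += qe - qs
        matches += sum(1 for i in range(qe - qs) if q[qs + i] == m[ms + i])
    # gap columns between aligned blocks also count against identity
    if len(qblocks):
        span_q = qblocks[-1][1] - qblocks[0][0]
        span_m = mblocks[-1][1] - mblocks[0][0]
        columns += max(span_q, span_m) - columns
        coverage = span_q / len(query)
    else:
        coverage = 0.0
    identity = matches / columns if columns else 0.0
    return identity, coverage


def compare_to_collection(
    query_repeat: str,
    collection: Sequence[tuple[str, str]] | Sequence[str],
    identity_threshold: float = 0.90,
    coverage_threshold: float = 0.90,
) -> Optional[CollectionHit]:
    """First collection member matching the query at >= identity over >= coverage.

    ``collection`` is a sequence of sequences or of (id, sequence) pairs.
    Coverage is the aligned fraction of the *query* length; identity is
    matches over aligned columns of the best local alignment.  Returns None
    when no member qualifies.
    """
    if not query_repeat:
        raise ValueError("empty query repeat")
    for idx, entry in enumerate(collection):
        member_id, seq = entry if isinstance(entry, tuple) else (f"member{idx + 1}", entry)
        ident, cov = _local_identity_coverage(query_repeat, seq)
        if ident >= identity_threshold and cov >= coverage_threshold:
            return CollectionHit(idx, member_id, ident, cov)
    return None
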