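"""Separation of real CRISPRs from false-CRISPR elements, and annotation of
the false ones.

Many genomic elements mimic the repeat-spacer structure that array detectors
look for.  The screen works at the level of repeat clusters: a cluster of
putative arrays is *real* when at least one member co-locates with a valid
cas locus (all members inherit the label), and an individual candidate is
rescued as real when its consensus repeat is within 5 mismatches of any real
CRISPR repeat.  Everything else is a false-CRISPR and is classified as a
tandem repeat, a STAR-like element (carrying the signature motif
T[G/A/T]TGTTG[G/T]GGCCC[C/A]), a simple/low-complexity repeat, or unknown.

The tandem detector is a from-scratch scorer using the classic tandem-repeat
weights (match +2, mismatch -7, indel -7, minimum score 50): the region is
locally aligned against a tiled candidate unit for each candidate period.
For short regions every admissible period is tried; longer regions use a
k-mer distance histogram to propose periods.  Short-unit periodicity
(unit <= 6 bp) and skewed mononucleotide composition are the domain of the
simple-repeat detector, so the tandem stage of the classification cascade
defers to it for such regions.
"""

from __future__ import annotations

import math
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cas_loci import CO_LOCATED, ISOLATED_REMOTE, ORPHAN
from .repeat_cluster import RepeatCluster, reverse_complement

__all__ = [
    "ClassifierParams",
    "TandemCall",
    "SimpleCall",
    "ElementEvidence",
    "ElementClassification",
    "STAR_MOTIF",
    "find_real_clusters",
    "rescue_distance",
    "detect_tandem",
    "match_star",
    "detect_simple",
    "classify_element",
]

REAL, TANDEM, STAR, SIMPLE, UNKNOWN = "REAL", "TANDEM", "STAR", "SIMPLE", "UNKNOWN"


@dataclass(frozen=True)
class ClassifierParams:
    match_score: int = 2
    mismatch_score: int = -7
    gap_score: int = -7
    min_score: int = 50
    min_coverage: float = 0.8
    min_copies: float = 2.0
    simple_max_unit: int = 6
    mono_frac: float = 0.40
    entropy_max: float = 1.5  # bits
    flank: int = 0
    exhaustive_len: int = 250  # up to this region length every period is tried
    precedence: tuple[str, ...] = (STAR, TANDEM, SIMPLE)

    def __post_init__(self) -> None:
        if set(self.precedence) != {TANDEM, STAR, SIMPLE}:
            raise ValueError("precedence must order TANDEM, STAR, SIMPLE")


# ---------------------------------------------------------------------------
# STAR signature motif
# ---------------------------------------------------------------------------

#: Degenerate signature of the S. aureus repeat (STAR) element.
STAR_MOTIF = "T[GAT]TGTTG[GT]GGCCC[CA]"

_MOTIF_TOKEN_RE = re.compile(r"\[[A-Z]+\]|[A-Z]")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _motif_tokens(motif: str) -> list[str]:
    return _MOTIF_TOKEN_RE.findall(motif)


def _reverse_complement_motif(motif: str) -> str:
    out = []
    for tok in reversed(_motif_tokens(motif)):
        bases = tok.strip("[]")
        comp = "".join(_COMP[b] for b in bases)
        out.append(comp if len(comp) == 1 else f"[{comp}]")
    return "".join(out)


def expand_motif(motif: str = STAR_MOTIF) -> list[str]:
    """All concrete instantiations of a degenerate bracket motif."""
    seqs = [""]
    for tok in _motif_tokens(motif):
        bases = tok.strip("[]")
        seqs = [s + b for s in seqs for b in bases]
    return seqs


def match_star(sequence: str, motif: str = STAR_MOTIF) -> list[tuple[int, str]]:
    """All (1-based position, strand) matches of the signature on both strands.

    Overlapping occurrences are reported; a reverse-strand hit is reported at
    the forward-strand position where the reverse-complemented motif begins.
    """
    seq = sequence.upper()
    hits = []
    for strand, pat in (("+", motif), ("-", _reverse_complement_motif(motif))):
        for m in re.finditer(f"(?=({pat}))", seq):
            hits.append((m.start() + 1, strand))
    hits.sort()
    return hits


# ---------------------------------------------------------------------------
# tandem repeats
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TandemCall:
    period: int
    unit: str
    copies: float
    coverage: float
    score: int


def _local_align(region: str, target: str, params: ClassifierParams) -> tuple[int, int, int]:
    """Best local-alignment score of region vs target with linear gap costs.

    Returns (score, region_start, region_end) of the optimal path, 0-based
    half-open on the region.  Vectorized Smith-Waterman: rows iterate over the
    region, the in-row (horizontal gap) relaxation is an exact prefix-max with
    linear decay.
    """
    m_sc, x_sc, g_sc = params.match_score, params.mismatch_score, params.gap_score
    r = np.frombuffer(region.encode(), dtype=np.uint8)
    t = np.frombuffer(target.encode(), dtype=np.uint8)
    n, m = len(r), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    decay = -g_sc * np.arange(m + 1, dtype=np.int32)
    nmask = np.uint8(ord("N"))
    for i in range(1, n + 1):
        sub = np.where((t == r[i - 1]) & (t != nmask) & (r[i - 1] != nmask), m_sc, x_sc)
        cand = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + g_sc)
        row = np.empty(m + 1, dtype=np.int32)
        row[0] = 0
        row[1:] = np.maximum(cand, 0)
        # horizontal relaxation: row[j] = max_k<=j (row[k] - g*(j-k))
        row = np.maximum.accumulate(row + decay) - decay
        np.maximum(row, 0, out=row)
        H[i] = row
    score = int(H.max())
    if score == 0:
        return 0, 0, 0
    i, j = np.unravel_index(int(H.argmax()), H.shape)
    end_i = int(i)
    # traceback for the region span only
    while H[i, j] > 0:
        h = H[i, j]
        if i > 0 and j > 0 and h == H[i - 1, j - 1] + (
            m_sc if (r[i - 1] == t[j - 1] and r[i - 1] != nmask) else x_sc
        ):
            i, j = i - 1, j - 1
        elif i > 0 and h == H[i - 1, j] + g_sc:
            i -= 1
        elif j > 0 and h == H[i, j - 1] + g_sc:
            j -= 1
        else:  # pragma: no cover - defensive
            break
    return score, int(i), end_i


def _consensus_unit(region: str, period: int) -> str:
    """Majority base per phase column (ties -> first occurrence in scan order)."""
    cols: list[list[str]] = [[] for _ in range(period)]
    for i, c in enumerate(region):
        cols[i % period].append(c)
    out = []
    for col in cols:
        informative = [c for c in col if c != "N"]
        if not informative:
            out.append("N")
            continue
        counts = Counter(informative)
        top = max(counts.values())
        out.append(next(c for c in informative if counts[c] == top))
    return "".join(out)


def _candidate_periods(
    region: str, min_period: int, max_period: int, params: ClassifierParams, k: int = 3
) -> list[int]:
    n = len(region)
    if n <= params.exhaustive_len:
        return list(range(min_period, max_period + 1))
    counts: Counter[int] = Counter()
    last: dict[str, int] = {}
    for i in range(n - k + 1):
        kmer = region[i : i + k]
        if kmer in last:
            d = i - last[kmer]
            if min_period <= d <= max_period:
                counts[d] += 1
        last[kmer] = i
    top = [d for d, _ in counts.most_common(12)]
    always = [p for p in range(min_period, min(params.simple_max_unit, max_period) + 1)]
    return sorted(set(top) | set(always))


def detect_tandem(
    region_sequence: str,
    params: ClassifierParams | None = None,
    min_period: int = 1,
    max_period: int | None = None,
) -> Optional[TandemCall]:
    """Best tandem-repeat call for a region, or None.

    For each candidate period the region is locally aligned against a tiled
    majority-consensus unit (match +2, mismatch -7, indel -7).  A call is
    positive when the best score reaches ``min_score`` (50), the aligned span
    covers at least ``min_coverage`` (0.8) of the region and spans at least
    two unit copies.  The best-scoring positive call is returned.
    """
    params = params or ClassifierParams()
    region = region_sequence.upper()
    n = len(region)
    if n < 2:
        return None
    max_period = min(max_period or n // 2, n // 2)
    if max_period < min_period:
        return None
    best: Optional[TandemCall] = None
    for p in _candidate_periods(region, min_period, max_period, params):
        unit = _consensus_unit(region, p)
        tiled = unit * (math.ceil(n / p) + 2)
        score, i0, i1 = _local_align(region, tiled, params)
        span = i1 - i0
        coverage = span / n
        copies = span / p
        if score >= params.min_score and coverage >= params.min_coverage and copies >= params.min_copies:
            call = TandemCall(period=p, unit=unit, copies=round(copies, 2), coverage=round(coverage, 3), score=score)
            if best is None or (call.score, -call.period) > (best.score, -best.period):
                best = call
    return best


def best_tandem_score(
    region_sequence: str, params: ClassifierParams | None = None
) -> int:
    """Best tandem alignment score over all candidate periods, call criteria aside."""
    params = params or ClassifierParams()
    region = region_sequence.upper()
    n = len(region)
    best = 0
    for p in _candidate_periods(region, 1, max(1, n // 2), params):
        unit = _consensus_unit(region, p)
        tiled = unit * (math.ceil(n / p) + 2)
        score, _, _ = _local_align(region, tiled, params)
        best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# simple / low-complexity repeats
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimpleCall:
    trigger: str  # short_unit_tandem | mono_frac | entropy
    unit: Optional[str] = None
    copies: Optional[float] = None
    mono_base: Optional[str] = None
    mono_fraction: Optional[float] = None
    entropy_bits: Optional[float] = None


def shannon_entropy(sequence: str) -> float:
    """Mononucleotide Shannon entropy in bits (N excluded)."""
    seq = [c for c in sequence.upper() if c != "N"]
    if not seq:
        return 0.0
    counts = Counter(seq)
    n = len(seq)
    return -sum((c / n) * math.log2(c / n) for c in counts.values())


def detect_simple(
    region_sequence: str, params: ClassifierParams | None = None
) -> Optional[SimpleCall]:
    """Simple/low-complexity call: short-unit tandem, mononucleotide skew, or
    low entropy; the triggering criterion is recorded."""
    params = params or ClassifierParams()
    region = region_sequence.upper()
    if not region:
        return None
    call = detect_tandem(region, params, min_period=1, max_period=params.simple_max_unit)
    if call is not None and call.coverage >= params.min_coverage:
        return SimpleCall(trigger="short_unit_tandem", unit=call.unit, copies=call.copies)
    counts = Counter(c for c in region if c != "N")
    total = sum(counts.values())
    if total:
        base, cnt = counts.most_common(1)[0]
        frac = cnt / total
        if frac >= params.mono_frac:
            return SimpleCall(trigger="mono_frac", mono_base=base, mono_fraction=round(frac, 3))
    ent = shannon_entropy(region)
    if ent <= params.entropy_max:
        return SimpleCall(trigger="entropy", entropy_bits=round(ent, 3))
    return None


# ---------------------------------------------------------------------------
# real / false partition and final labels
# ---------------------------------------------------------------------------


def find_real_clusters(
    clusters: Sequence[RepeatCluster],
    colocation_by_array: Mapping,
) -> tuple[set[str], set[str]]:
    """Partition cluster ids into (real, candidate-false).

    ``colocation_by_array`` maps a member key to its co-location label; a
    cluster is real iff any member is CO_LOCATED with a valid cas locus and
    every member inherits the cluster's label.
    """
    real, false = set(), set()
    for cl in clusters:
        if any(colocation_by_array.get(k) == CO_LOCATED for k in cl.member_keys):
            real.add(cl.cluster_id)
        else:
            false.add(cl.cluster_id)
    return real, false


def rescue_distance(candidate_repeat: str, real_repeats: Sequence[str]) -> float:
    """Minimum mismatch count (substitutions + indels in the best global
    alignment) between a candidate consensus repeat and any real CRISPR
    repeat; +inf when the real set is empty."""
    import edlib

    if not real_repeats:
        return math.inf
    cand = candidate_repeat.upper().replace("N", "!")
    best = math.inf
    for rep in real_repeats:
        res = edlib.align(cand, rep.upper().replace("N", "?"), mode="NW", task="distance")
        best = min(best, res["editDistance"])
    return best


@dataclass
class ElementEvidence:
    cas_near: bool = False
    cas_far_in_genome: bool = False
    cas_absent: bool = False
    diversity_status: str = ""
    rescue_distance: float = math.inf
    tandem_call: Optional[TandemCall] = None
    star_hits: list = field(default_factory=list)
    simple_call: Optional[SimpleCall] = None


@dataclass
class ElementClassification:
    array_id: str
    cluster_id: str
    label: str
    evidence: ElementEvidence


def classify_element(
    array_id: str,
    region_sequence: str,
    consensus_repeat: str,
    cluster_id: str,
    cluster_is_real: bool,
    colocation_label: str,
    diversity_status: str,
    real_repeats: Sequence[str],
    params: ClassifierParams | None = None,
    rescue_mismatch_limit: int = 5,
    strict_diversity: bool = False,
) -> ElementClassification:
    """Final label for one putative array.

    REAL by cluster co-location inheritance or by the mismatch rescue
    (< rescue_mismatch_limit mismatches to any real repeat); otherwise the
    false-element cascade runs in the configured precedence.  Evidence fields
    are always populated so downstream tables can reproduce the full decision.
    """
    params = params or ClassifierParams()
    ev = ElementEvidence(
        cas_near=colocation_label == CO_LOCATED,
        cas_far_in_genome=colocation_label == ISOLATED_REMOTE,
        cas_absent=colocation_label == ORPHAN,
        diversity_status=diversity_status,
    )
    ev.rescue_distance = rescue_distance(consensus_repeat, real_repeats)

    rescued = ev.rescue_distance < rescue_mismatch_limit
    if strict_diversity and ev.cas_absent and diversity_status != "DIVERSE":
        rescued = False
    is_real = cluster_is_real or rescued

    region = region_sequence.upper()
    ev.tandem_call = detect_tandem(region, params)
    ev.star_hits = match_star(region) or match_star(consensus_repeat)
    ev.simple_call = detect_simple(region, params)

    if is_real:
        return ElementClassification(array_id, cluster_id, REAL, ev)

    # a short-unit repeat scores as a tandem at many periods (every multiple of
    # the unit, and any period at all for a homopolymer), so when a <=6 bp unit
    # already explains the region the tandem stage defers to the simple class
    short_unit = ev.simple_call is not None and ev.simple_call.trigger == "short_unit_tandem"
    for stage in params.precedence:
        if (
            stage == TANDEM
            and ev.tandem_call is not None
            and ev.tandem_call.period > params.simple_max_unit
            and not short_unit
        ):
            return ElementClassification(array_id, cluster_id, TANDEM, ev)
        if stage == STAR and ev.star_hits:
            return ElementClassification(array_id, cluster_id, STAR, ev)
        if stage == SIMPLE and ev.simple_call is not None:
            return ElementClassification(array_id, cluster_id, SIMPLE, ev)
    return ElementClassification(array_id, cluster_id, UNKNOWN, ev)
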