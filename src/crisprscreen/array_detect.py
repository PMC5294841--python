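"""CRT-style detection of CRISPR-like repeat-spacer arrays.

The detector scans for an exact seed k-mer recurring at admissible spacings
(repeat + spacer bounds), chains the recurrences, then extends the repeat
boundaries left and right across all copies while the columns stay
near-unanimous.  Terminal copies whose mismatch fraction against the array
consensus exceeds the tolerance are trimmed.  Two post-passes mirror the
modifications made for metagenomic use of CRT: partial terminal repeats beyond
the outermost spacers are annexed, and neighbouring arrays that share a
near-identical consensus repeat and sit within the merge gap are unioned into
one locus.

Repeat-length bounds default to the canonical 21-47 bp of direct repeats;
spacer bounds, seed size and the per-repeat mismatch tolerance are detector
choices and configurable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from math import ceil, floor
from typing import Optional, Sequence

from .formats import GenomeRecord
from .repeat_cluster import pairwise_identity

__all__ = [
    "DetectorParams",
    "CrisprArray",
    "find_arrays",
    "extend_partial_repeats",
    "merge_arrays",
    "consensus_repeat",
]


@dataclass(frozen=True)
class DetectorParams:
    min_repeat_len: int = 21
    max_repeat_len: int = 47
    min_spacer_len: int = 18
    max_spacer_len: int = 72
    min_repeat_count: int = 3
    seed_kmer: int = 8
    max_repeat_mismatch_frac: float = 0.2
    partial_min_match: float = 0.5  # fraction of consensus required of a partial terminal repeat

    def __post_init__(self) -> None:
        if self.min_repeat_len > self.max_repeat_len:
            raise ValueError("min_repeat_len > max_repeat_len")
        if self.min_spacer_len > self.max_spacer_len:
            raise ValueError("min_spacer_len > max_spacer_len")
        if self.seed_kmer >= self.min_repeat_len:
            raise ValueError("seed_kmer must be smaller than min_repeat_len")
        if not (0 <= self.max_repeat_mismatch_frac < 1):
            raise ValueError("max_repeat_mismatch_frac must be in [0, 1)")

    @property
    def min_period(self) -> int:
        return self.min_repeat_len + self.min_spacer_len

    @property
    def max_period(self) -> int:
        return self.max_repeat_len + self.max_spacer_len

    @property
    def min_footprint(self) -> int:
        """Smallest genomic span a qualifying array can occupy."""
        return (
            self.min_repeat_count * self.min_repeat_len
            + (self.min_repeat_count - 1) * self.min_spacer_len
        )


Interval = tuple[int, int, str]  # (start, end, sequence), 1-based inclusive


@dataclass
class CrisprArray:
    """An ordered repeat-spacer array with 1-based inclusive genomic coordinates."""

    genome_id: str
    start: int
    end: int
    repeats: list[Interval]
    spacers: list[Interval]
    consensus_repeat: str
    partial_5p: bool = False
    partial_3p: bool = False
    insertions: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_repeats(self) -> int:
        return len(self.repeats)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    @property
    def array_id(self) -> str:
        return f"{self.genome_id}:{self.start}-{self.end}"

    def spacer_seqs(self) -> list[str]:
        return [s for _, _, s in self.spacers]

    def repeat_seqs(self) -> list[str]:
        return [s for _, _, s in self.repeats]


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------


def consensus_repeat(repeats: Sequence[str]) -> str:
    """Per-column majority consensus over length-aligned repeat copies.

    Repeats are aligned end-gap-free against the first copy of modal length;
    copies deviating more than 20 % from the modal length do not vote.  Ties
    are broken by the base occurring first (scanning the voting copies in
    order at that column).  N never votes.
    """
    repeats = [r.upper() for r in repeats if r]
    if not repeats:
        raise ValueError("consensus_repeat requires at least one repeat")
    lengths = Counter(len(r) for r in repeats)
    modal_len = max(lengths, key=lambda L: (lengths[L], -L))
    template = next(r for r in repeats if len(r) == modal_len)

    def _align(r: str) -> Optional[str]:
        if abs(len(r) - modal_len) / modal_len > 0.2:
            return None
        if len(r) == modal_len:
            return r
        if len(r) < modal_len:
            best, best_m = 0, -1
            for off in range(modal_len - len(r) + 1):
                m = sum(1 for i, c in enumerate(r) if c == template[off + i])
                if m > best_m:
                    best, best_m = off, m
            return "-" * best + r + "-" * (modal_len - len(r) - best)
        best, best_m = 0, -1
        for off in range(len(r) - modal_len + 1):
            m = sum(1 for i in range(modal_len) if r[off + i] == template[i])
            if m > best_m:
                best, best_m = off, m
        return r[best : best + modal_len]

    aligned = [a for a in (_align(r) for r in repeats) if a is not None]
    out = []
    for col in range(modal_len):
        column = [a[col] for a in aligned if a[col] not in "-N"]
        if not column:
            out.append(template[col])
            continue
        counts = Counter(column)
        top = max(counts.values())
        # first-occurring base among the tied candidates
        out.append(next(c for c in column if counts[c] == top))
    return "".join(out)


# ---------------------------------------------------------------------------
# detection
# ---------------------------------------------------------------------------


def _mismatches(a: str, b: str) -> int:
    # equal-length comparison; N counts as a mismatch against anything
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def _column_ok(seq: str, positions: list[int], offset: int, n: int) -> bool:
    """True when the column at seed+offset is near-unanimous across copies."""
    chars = []
    for p in positions:
        i = p + offset
        if i < 0 or i >= n:
            return False
        chars.append(seq[i])
    informative = [c for c in chars if c != "N"]
    if not informative:
        return False
    top = Counter(informative).most_common(1)[0][1]
    return top >= -(-2 * len(chars) // 3)  # ceil(2/3 of copies)


def _build_arrays_from_chain(
    seq: str, genome_id: str, seeds: list[int], params: DetectorParams
) -> list[CrisprArray]:
    n = len(seq)
    k = params.seed_kmer
    gaps = [b - a for a, b in zip(seeds, seeds[1:])]
    cap = min(params.max_repeat_len, min(gaps) - params.min_spacer_len)
    if cap < params.min_repeat_len:
        return []

    # extend right from the seed k-mer, then left, while columns agree
    right = k
    while right < cap and _column_ok(seq, seeds, right, n):
        right += 1
    left = 0
    while left + right < cap and _column_ok(seq, seeds, -left - 1, n):
        left += 1
    replen = left + right
    if replen < params.min_repeat_len:
        return []

    starts = [p - left for p in seeds]
    if starts[0] < 0 or starts[-1] + replen > n:
        return []

    # split the chain wherever the implied spacer violates the spacer bounds
    segments: list[list[int]] = [[starts[0]]]
    for prev, cur in zip(starts, starts[1:]):
        spacer_len = cur - (prev + replen)
        if params.min_spacer_len <= spacer_len <= params.max_spacer_len:
            segments[-1].append(cur)
        else:
            segments.append([cur])

    arrays = []
    for seg in segments:
        if len(seg) < params.min_repeat_count:
            continue
        arr = _finalize_segment(seq, genome_id, seg, replen, params)
        if arr is not None:
            arrays.append(arr)
    return arrays


def _finalize_segment(
    seq: str, genome_id: str, starts: list[int], replen: int, params: DetectorParams
) -> Optional[CrisprArray]:
    # boundary refinement: the near-unanimity extension rule can creep a few
    # columns into the flanks when spacer prefixes agree by chance; trim
    # terminal columns that are not unanimous across copies
    def _unanimous(off: int) -> bool:
        chars = {seq[p + off] for p in starts}
        return len(chars) == 1 and "N" not in chars

    lt, rt = 0, 0
    while replen - lt - rt > params.min_repeat_len and not _unanimous(lt):
        lt += 1
    while replen - lt - rt > params.min_repeat_len and not _unanimous(replen - 1 - rt):
        rt += 1
    starts = [p + lt for p in starts]
    replen -= lt + rt

    copies = [seq[p : p + replen] for p in starts]
    cons = consensus_repeat(copies)
    limit = floor(params.max_repeat_mismatch_frac * replen)
    # trim terminal copies exceeding the mismatch tolerance
    lo, hi = 0, len(starts)
    while lo < hi and _mismatches(copies[lo], cons) > limit:
        lo += 1
    while hi > lo and _mismatches(copies[hi - 1], cons) > limit:
        hi -= 1
    starts, copies = starts[lo:hi], copies[lo:hi]
    if len(starts) < params.min_repeat_count:
        return None
    cons = consensus_repeat(copies)

    repeats: list[Interval] = [
        (p + 1, p + replen, seq[p : p + replen]) for p in starts
    ]
    spacers: list[Interval] = []
    for (s1, e1, _), (s2, _, _) in zip(repeats, repeats[1:]):
        spacers.append((e1 + 1, s2 - 1, seq[e1 : s2 - 1]))
    return CrisprArray(
        genome_id=genome_id,
        start=repeats[0][0],
        end=repeats[-1][1],
        repeats=repeats,
        spacers=spacers,
        consensus_repeat=cons,
    )


def _resolve_overlaps(arrays: list[CrisprArray]) -> list[CrisprArray]:
    """Among overlapping candidates keep more repeats, then longer span, then smaller start."""
    arrays = sorted(arrays, key=lambda a: (a.start, a.end))
    kept: list[CrisprArray] = []
    for arr in arrays:
        if kept and arr.start <= kept[-1].end:
            prev = kept[-1]
            best = max(
                (prev, arr),
                key=lambda a: (a.n_repeats, a.span, -a.start),
            )
            kept[-1] = best
        else:
            kept.append(arr)
    return kept


def find_arrays(genome: GenomeRecord, params: DetectorParams | None = None) -> list[CrisprArray]:
    """Detect repeat-spacer arrays in one genome record.

    Deterministic for a fixed input and parameter set; returns arrays sorted
    by start, non-overlapping, each satisfying the array invariants.  Short
    sequences (below the minimum array footprint) yield an empty list.
    """
    params = params or DetectorParams()
    seq = genome.seq
    n = len(seq)
    if n < params.min_footprint:
        return []
    k = params.seed_kmer
    candidates: dict[tuple[int, int], CrisprArray] = {}
    seen_chains: set[tuple[int, ...]] = set()
    for i in range(n - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        j = seq.find(kmer, i + params.min_period, i + params.max_period + k)
        if j < 0:
            continue
        seeds = [i, j]
        while True:
            nxt = seq.find(kmer, seeds[-1] + params.min_period, seeds[-1] + params.max_period + k)
            if nxt < 0:
                break
            seeds.append(nxt)
        if len(seeds) < params.min_repeat_count:
            continue
        # chains seeded at different offsets inside the same repeats converge
        # on one (start, end) after extension; keep each span once
        if tuple(seeds) in seen_chains:
            continue
        seen_chains.add(tuple(seeds))
        for arr in _build_arrays_from_chain(seq, genome.id, seeds, params):
            candidates.setdefault((arr.start, arr.end), arr)
    return _resolve_overlaps(list(candidates.values()))


# ---------------------------------------------------------------------------
# partial terminal repeats
# ---------------------------------------------------------------------------


def _scan_partial(
    seq: str,
    cons: str,
    anchor: int,
    side: str,
    params: DetectorParams,
) -> Optional[tuple[int, int, int]]:
    """Best (gap, partial_len, mismatches) beyond one array terminus, or None.

    ``anchor`` is the 0-based position just past the array (3') or the array's
    0-based start (5').  The partial repeat must cover at least
    ``partial_min_match`` of the consensus at the array's mismatch tolerance,
    separated from the terminus by a spacer-length gap.
    """
    L = len(cons)
    n = len(seq)
    min_len = ceil(params.partial_min_match * L)
    best_key: Optional[tuple[int, int, int]] = None  # (score, plen, -gap)
    result: Optional[tuple[int, int, int]] = None
    for gap in range(params.min_spacer_len, params.max_spacer_len + 1):
        for plen in range(L - 1, min_len - 1, -1):
            if side == "3p":
                s0 = anchor + gap
                frag = seq[s0 : s0 + plen]
                ref = cons[:plen]
            else:
                s0 = anchor - gap - plen
                if s0 < 0:
                    continue
                frag = seq[s0 : s0 + plen]
                ref = cons[L - plen :]
            if len(frag) < plen:
                continue
            mism = _mismatches(frag, ref)
            if mism > floor(params.max_repeat_mismatch_frac * plen):
                continue
            # favour matched bases over raw length so a clean truncation is not
            # padded with accidental flank matches
            key = (plen - 4 * mism, plen, -gap)
            if best_key is None or key > best_key:
                best_key = key
                result = (gap, plen, mism)
    return result


def extend_partial_repeats(
    array: CrisprArray, genome: GenomeRecord, params: DetectorParams | None = None
) -> CrisprArray:
    """Annex partial terminal repeats beyond either outermost repeat.

    If at least ``partial_min_match`` of the consensus matches immediately
    beyond a terminal spacer-length gap (at the array-level mismatch rate),
    the boundary is extended over the partial repeat and the corresponding
    flag set; otherwise the array is returned unchanged.
    """
    params = params or DetectorParams()
    seq = genome.seq
    cons = array.consensus_repeat
    L = len(cons)
    repeats = list(array.repeats)
    spacers = list(array.spacers)
    partial_5p, partial_3p = array.partial_5p, array.partial_3p

    if not partial_3p:
        found = _scan_partial(seq, cons, array.end, "3p", params)
        if found:
            gap, plen, _ = found
            sp_start = array.end + 1
            sp_end = array.end + gap
            rep_start = sp_end + 1
            rep_end = rep_start + plen - 1
            if rep_end <= len(seq):
                spacers.append((sp_start, sp_end, seq[sp_start - 1 : sp_end]))
                repeats.append((rep_start, rep_end, seq[rep_start - 1 : rep_end]))
                partial_3p = True

    if not partial_5p:
        found = _scan_partial(seq, cons, array.start - 1, "5p", params)
        if found:
            gap, plen, _ = found
            sp_end = array.start - 1
            sp_start = sp_end - gap + 1
            rep_end = sp_start - 1
            rep_start = rep_end - plen + 1
            if rep_start >= 1:
                spacers.insert(0, (sp_start, sp_end, seq[sp_start - 1 : sp_end]))
                repeats.insert(0, (rep_start, rep_end, seq[rep_start - 1 : rep_end]))
                partial_5p = True

    if partial_5p == array.partial_5p and partial_3p == array.partial_3p:
        return array
    return replace(
        array,
        start=repeats[0][0],
        end=repeats[-1][1],
        repeats=repeats,
        spacers=spacers,
        partial_5p=partial_5p,
        partial_3p=partial_3p,
    )


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def merge_arrays(arrays: Sequence[CrisprArray], genome: GenomeRecord, config) -> list[CrisprArray]:
    """Union arrays that sit within the merge gap and share near-identical repeats.

    A long array split by mutated repeats or long spacers reappears as
    neighbouring fragments; any two arrays separated by at most
    ``config.merge_gap_bp`` whose consensus repeats match at
    ``config.repeat_cluster_identity`` are considered one locus (transitive
    closure).  The inter-array gap becomes a spacer when its length fits the
    spacer bounds, otherwise it is recorded as an insertion.  Idempotent.
    """
    arrays = sorted(arrays, key=lambda a: (a.start, a.end))
    if len(arrays) < 2:
        return list(arrays)
    params: DetectorParams = getattr(config, "detector", None) or DetectorParams()

    parent = list(range(len(arrays)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            gap = arrays[j].start - arrays[i].end
            if gap > config.merge_gap_bp:
                break
            if gap >= 0 and pairwise_identity(
                arrays[i].consensus_repeat, arrays[j].consensus_repeat
            ) >= config.repeat_cluster_identity:
                parent[find(j)] = find(i)

    groups: dict[int, list[CrisprArray]] = {}
    for idx, arr in enumerate(arrays):
        groups.setdefault(find(idx), []).append(arr)

    merged: list[CrisprArray] = []
    for members in groups.values():
        members.sort(key=lambda a: a.start)
        if len(members) == 1:
            merged.append(members[0])
            continue
        repeats: list[Interval] = []
        spacers: list[Interval] = []
        insertions: list[tuple[int, int]] = []
        for m, arr in enumerate(members):
            if m > 0:
                prev = members[m - 1]
                gstart, gend = prev.end + 1, arr.start - 1
                glen = gend - gstart + 1
                if params.min_spacer_len <= glen <= params.max_spacer_len:
                    spacers.append((gstart, gend, genome.slice(gstart, gend)))
                elif glen > 0:
                    insertions.append((gstart, gend))
            repeats.extend(arr.repeats)
            spacers.extend(arr.spacers)
            insertions.extend(arr.insertions)
        repeats.sort(key=lambda r: r[0])
        spacers.sort(key=lambda s: s[0])
        merged.append(
            CrisprArray(
                genome_id=members[0].genome_id,
                start=members[0].start,
                end=members[-1].end,
                repeats=repeats,
                spacers=spacers,
                consensus_repeat=consensus_repeat([r for _, _, r in repeats]),
                partial_5p=members[0].partial_5p,
                partial_3p=members[-1].partial_3p,
                insertions=sorted(insertions),
            )
        )
    merged.sort(key=lambda a: (a.start, a.end))
    return merged
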