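"""Independent reference implementations used to cross-check the package.

These deliberately avoid the package's own algorithms: the array oracle is a
fixed-period numpy enumerator over (period, phase, repeat-length); the tandem
oracle scores with Biopython's PairwiseAligner; clustering and identity
oracles are plain-loop re-implementations.
"""

from __future__ import annotations

from collections import Counter
from math import ceil, floor

import numpy as np
from Bio import Align


# ---------------------------------------------------------------------------
# brute-force repeat-triple enumeration
# ---------------------------------------------------------------------------


def bruteforce_array_candidates(seq: str, params) -> list[tuple[int, int, int]]:
    """All (start0, period, repeat_len) fixed-period repeat triples that satisfy
    the detector parameters.

    A triple qualifies when three copies at positions i, i+d, i+2d of length L
    each match the per-column majority consensus (ties to the first copy) with
    at most floor(max_repeat_mismatch_frac * L) mismatches, the implied spacer
    d - L lies within the spacer bounds, L within the repeat bounds, and the
    copies share an exact seed k-mer at a common offset.
    """
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(s)
    k = params.seed_kmer
    out: list[tuple[int, int, int]] = []
    for d in range(params.min_period, params.max_period + 1):
        if 2 * d >= n:
            break
        w = n - 2 * d  # candidate phase positions
        c0, c1, c2 = s[:w], s[d : d + w], s[2 * d : 2 * d + w]
        m01 = c0 == c1
        m12 = c1 == c2
        m02 = c0 == c2
        match0 = m01 | m02 | ~m12
        match1 = m01 | m12
        match2 = m02 | m12
        exact = m01 & m02  # all three copies identical at this column
        idx = np.arange(w)
        last_false = np.maximum.accumulate(np.where(~exact, idx, -1))
        run = np.where(exact, idx - last_false, 0)
        seed_ok = run >= k
        cm0 = np.concatenate([[0], np.cumsum(~match0)])
        cm1 = np.concatenate([[0], np.cumsum(~match1)])
        cm2 = np.concatenate([[0], np.cumsum(~match2)])
        cseed = np.concatenate([[0], np.cumsum(seed_ok)])
        lo_L = max(params.min_repeat_len, d - params.max_spacer_len)
        hi_L = min(params.max_repeat_len, d - params.min_spacer_len)
        for L in range(lo_L, hi_L + 1):
            if L > w:
                continue
            limit = floor(params.max_repeat_mismatch_frac * L)
            nwin = w - L + 1
            i0 = np.arange(nwin)
            ok = (
                (cm0[i0 + L] - cm0[i0] <= limit)
                & (cm1[i0 + L] - cm1[i0] <= limit)
                & (cm2[i0 + L] - cm2[i0] <= limit)
            )
            # an exact shared k-mer fully inside the window: some j in
            # [i+k-1, i+L-1] with run[j] >= k and run start >= i
            has_seed = (cseed[i0 + L] - cseed[i0 + k - 1]) > 0
            for i in np.nonzero(ok & has_seed)[0]:
                out.append((int(i), d, L))
    return out


def bruteforce_has_array(seq: str, params) -> bool:
    return bool(bruteforce_array_candidates(seq, params))


# ---------------------------------------------------------------------------
# tandem scoring oracle
# ---------------------------------------------------------------------------


def _majority_unit(region: str, period: int) -> str:
    cols: list[list[str]] = [[] for _ in range(period)]
    for i, c in enumerate(region):
        cols[i % period].append(c)
    out = []
    for col in cols:
        counts = Counter(col)
        top = max(counts.values())
        out.append(next(c for c in col if counts[c] == top))
    return "".join(out)


def oracle_tandem_score(region: str, match: int = 2, mismatch: int = -7, gap: int = -7) -> int:
    """Exhaustive best local score of the region against a tiled majority unit,
    over every period up to half the region length (PairwiseAligner engine)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    n = len(region)
    best = 0
    for p in range(1, n // 2 + 1):
        unit = _majority_unit(region, p)
        tiled = unit * (ceil(n / p) + 2)
        best = max(best, int(aligner.score(region, tiled)))
    return best


# ---------------------------------------------------------------------------
# clustering oracle
# ---------------------------------------------------------------------------


def oracle_identity(a: str, b: str) -> float:
    """Needleman-Wunsch with unit costs via explicit DP, matches / shorter length."""
    a, b = sorted((a.upper(), b.upper()))
    la, lb = len(a), len(b)
    INF = 10**9
    # dp over edit distance, then recover matches along one optimal path
    dist = [[0] * (lb + 1) for _ in range(la + 1)]
    for i in range(la + 1):
        dist[i][0] = i
    for j in range(lb + 1):
        dist[0][j] = j
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            sub = 0 if (a[i - 1] == b[j - 1] and a[i - 1] != "N") else 1
            dist[i][j] = min(
                dist[i - 1][j - 1] + sub, dist[i - 1][j] + 1, dist[i][j - 1] + 1
            )
    # maximize matches among minimum-edit alignments
    best = [[-INF] * (lb + 1) for _ in range(la + 1)]
    best[0][0] = 0
    for i in range(la + 1):
        for j in range(lb + 1):
            if i == j == 0:
                continue
            cands = []
            if i and j:
                sub = 1 if (a[i - 1] != b[j - 1] or a[i - 1] == "N") else 0
                if dist[i][j] == dist[i - 1][j - 1] + sub:
                    cands.append(best[i - 1][j - 1] + (1 - sub))
            if i and dist[i][j] == dist[i - 1][j] + 1:
                cands.append(best[i - 1][j])
            if j and dist[i][j] == dist[i][j - 1] + 1:
                cands.append(best[i][j - 1])
            best[i][j] = max(cands) if cands else -INF
    return best[la][lb] / min(la, lb)


def oracle_greedy_clusters(seqs: list[str], threshold: float, identity_fn) -> list[list[int]]:
    """Plain-loop greedy clustering (longest first, join first qualifying
    representative) returning member index lists in founding order."""
    order = sorted(range(len(seqs)), key=lambda i: (-len(seqs[i]), i))
    reps: list[int] = []
    members: list[list[int]] = []
    for idx in order:
        for ci, r in enumerate(reps):
            if identity_fn(seqs[idx], seqs[r]) >= threshold:
                members[ci].append(idx)
                break
        else:
            reps.append(idx)
            members.append([idx])
    return members
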