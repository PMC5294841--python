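"""Spacer-diversity statistic and the diverse / non-diverse / short trichotomy.

Spacers of an active CRISPR are acquired independently and are therefore
nearly all distinct; conversely, repeated "spacers" are a hallmark of
tandem-repeat-like impostors.  An array is called *diverse* when, after greedy
clustering of its spacers at 70 % identity, at least half of them fall into
distinct clusters (and there are at least two clusters).  Arrays with at most
two spacers that fail the criterion are *short* rather than non-diverse: two
spacers carry too little signal to call an array dead.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil
from typing import Sequence

from .array_detect import CrisprArray
from .repeat_cluster import RepeatCluster, cluster_repeats

__all__ = ["DiversityCall", "cluster_spacers", "is_diverse", "diversity_of_spacers"]


@dataclass(frozen=True)
class DiversityCall:
    n_spacers: int
    n_spacer_clusters: int
    status: str  # DIVERSE | NOT_DIVERSE | SHORT
    redundant_spacers: int


def cluster_spacers(spacers: Sequence[str], threshold: float = 0.70) -> list[RepeatCluster]:
    """Greedy clustering of one array's spacers (same scheme as repeat clustering)."""
    return cluster_repeats([(i, s) for i, s in enumerate(spacers)], threshold=threshold)


def diversity_of_spacers(spacers: Sequence[str], threshold: float = 0.70) -> DiversityCall:
    """Apply the diversity trichotomy to a spacer list.

    DIVERSE   iff n_clusters >= ceil(n/2) and n_clusters >= 2;
    otherwise SHORT when n <= 2, NOT_DIVERSE when n >= 3.
    """
    n = len(spacers)
    if n == 0:
        return DiversityCall(0, 0, "SHORT", 0)
    clusters = cluster_spacers(spacers, threshold)
    k = len(clusters)
    diverse = k >= ceil(n / 2) and k >= 2
    if diverse:
        status = "DIVERSE"
    else:
        status = "SHORT" if n <= 2 else "NOT_DIVERSE"
    return DiversityCall(n, k, status, n - k)


def is_diverse(array: CrisprArray, threshold: float = 0.70) -> DiversityCall:
    """Diversity call for a detected array."""
    return diversity_of_spacers(array.spacer_seqs(), threshold)
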