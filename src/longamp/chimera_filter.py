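"""Elimination of in-vitro recombinant (chimeric) template clusters.

A PCR template switch joins the 5' part of one template to the 3' part of
another, so the product carries a novel combination of end tags: its forward
tag belongs to one real template and its reverse tag to another.  Because
recombinants arise later in the reaction they are expected at lower abundance
than their parents, a cluster is therefore discarded when one (or both) of
its consensus tags also occurs in a *strictly more abundant* cluster.
Equal-abundance tag sharers are all kept — there is no "more abundant"
cluster to dominate them.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import List, Optional, Sequence

from .tag_cluster import TagCluster

TAG_F_SHARED = "tag_f_shared"
TAG_R_SHARED = "tag_r_shared"
BOTH_SHARED = "both_shared"


@dataclass
class DiscardRecord:
    cluster: TagCluster
    reason: str
    dominator_id: str


@dataclass
class FilterResult:
    kept: List[TagCluster]
    discarded: List[DiscardRecord]


def filter_recombinants(clusters: Sequence[TagCluster]) -> FilterResult:
    """Discard every cluster sharing a consensus tag (either end, exact
    match) with a different, strictly more abundant cluster.

    The result is order-invariant: dominance depends only on the abundance
    ranking, and the recorded dominator is the most abundant sharer
    (ties broken by cluster_id).
    """
    by_f = defaultdict(list)
    by_r = defaultdict(list)
    for c in clusters:
        by_f[c.consensus_tag_f].append(c)
        by_r[c.consensus_tag_r].append(c)

    kept: List[TagCluster] = []
    discarded: List[DiscardRecord] = []
    for c in clusters:
        dom_f = [o for o in by_f[c.consensus_tag_f]
                 if o is not c and o.abundance > c.abundance]
        dom_r = [o for o in by_r[c.consensus_tag_r]
                 if o is not c and o.abundance > c.abundance]
        if not dom_f and not dom_r:
            kept.append(c)
            continue
        if dom_f and dom_r:
            reason = BOTH_SHARED
        elif dom_f:
            reason = TAG_F_SHARED
        else:
            reason = TAG_R_SHARED
        dominator = min(dom_f + dom_r, key=lambda o: (-o.abundance, o.cluster_id))
        discarded.append(DiscardRecord(c, reason, dominator.cluster_id))
    return FilterResult(kept, discarded)


@dataclass
class RecombinationStats:
    discarded_reads: int
    total_end_end_reads: int
    rate: float                       # percent of end+end reads
    n_clusters: int
    n_discarded_clusters: int
    discarded_cluster_fraction: float
    parental_ratio: Optional[float]   # mean dominator/discarded abundance ratio


def recombination_stats(result: FilterResult, total_end_end_reads: int
                        ) -> RecombinationStats:
    """Read-level recombination rate: discarded cluster abundance summed over
    the end+end read pool, plus the mean parent:recombinant abundance ratio."""
    if total_end_end_reads <= 0:
        raise ValueError("total_end_end_reads must be positive")
    abundance_by_id = {c.cluster_id: c.abundance
                       for c in result.kept + [d.cluster for d in result.discarded]}
    discarded_reads = sum(d.cluster.abundance for d in result.discarded)
    n = len(result.kept) + len(result.discarded)
    ratios = [abundance_by_id[d.dominator_id] / d.cluster.abundance
              for d in result.discarded]
    return RecombinationStats(
        discarded_reads=discarded_reads,
        total_end_end_reads=total_end_end_reads,
        rate=100.0 * discarded_reads / total_end_end_reads,
        n_clusters=n,
        n_discarded_clusters=len(result.discarded),
        discarded_cluster_fraction=(len(result.discarded) / n) if n else 0.0,
        parental_ratio=(sum(ratios) / len(ratios)) if ratios else None,
    )
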