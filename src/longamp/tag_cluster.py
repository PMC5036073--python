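"""Dual-tag signature construction and greedy centroid clustering.

Reads from the same progenitor template carry the same pair of 10-nt random
tags up to sequencing error.  To recover the template set, every valid
end+end pair is reduced to a fixed-length 64-nt composite signature::

    tag_f(10) + tag_r(10) + bc_f(8) + bc_r(8) + gene_prefix_f(14) + gene_prefix_r(14)

and the composites are clustered greedily at a Hamming-identity threshold
(default > 0.89, i.e. at most 7 of 64 positions differ).  Centroid order is
abundance-sorted then lexicographic, which makes the procedure deterministic
and independent of input order.  Identity is alignment-free: every component
has fixed length, so indels cannot arise from the synthetic layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence

import numpy as np

from .demux import END_END, INVALID_COMBINATION, ClassifiedPair

_N_CODE = 4
_ENCODE = bytes(
    {65: 0, 67: 1, 71: 2, 84: 3}.get(i, _N_CODE) for i in range(256)
)  # A C G T -> 0..3, everything else -> N
_DECODE = "ACGTN"


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii").translate(_ENCODE), dtype=np.uint8)


def _decode(arr: np.ndarray) -> str:
    return "".join(_DECODE[c] for c in arr)


@dataclass(frozen=True)
class TagSignature:
    composite: str
    pair_id: str
    sample: str


@dataclass
class TagCluster:
    cluster_id: str
    consensus: str
    consensus_tag_f: str
    consensus_tag_r: str
    sample: str
    member_pair_ids: list = field(default_factory=list)

    @property
    def abundance(self) -> int:
        return len(self.member_pair_ids)


def build_signature(cp: ClassifiedPair, design=None) -> TagSignature:
    """Composite dual-tag signature of a valid end+end pair (observed
    sequence content, not error-corrected: clustering absorbs the errors)."""
    if cp.fragment_class != END_END:
        raise ValueError("signatures are defined only for END_END pairs")
    if cp.sample is None or cp.sample == INVALID_COMBINATION:
        raise ValueError("signatures require a valid sample assignment")
    f, r = cp.forward_parse, cp.reverse_parse
    composite = (f.tag + r.tag + f.barcode_observed + r.barcode_observed
                 + f.gene_prefix + r.gene_prefix)
    return TagSignature(composite, cp.pair.pair_id, cp.sample)


def cluster_consensus(members: Sequence[str]) -> str:
    """Per-position plurality base; ties break by fixed order A<C<G<T and an
    N can only win a position where it strictly outnumbers every real base."""
    if not members:
        raise ValueError("consensus of an empty member set")
    mat = np.stack([_encode(m) for m in members])
    if mat.shape[1] == 0 or any(len(m) != mat.shape[1] for m in members):
        raise ValueError("consensus members must share a non-zero length")
    votes = np.zeros((mat.shape[1], 5), dtype=np.int64)
    for row in mat:
        votes[np.arange(mat.shape[1]), row] += 1
    best_base = votes[:, :4].argmax(axis=1)          # first max: A<C<G<T tie-break
    base_max = votes[:, :4].max(axis=1)
    winner = np.where(votes[:, _N_CODE] > base_max, _N_CODE, best_base)
    return _decode(winner)


def _weighted_consensus(unique: np.ndarray, counts: Sequence[int],
                        member_rows: Sequence[int]) -> np.ndarray:
    L = unique.shape[1]
    votes = np.zeros((L, 5), dtype=np.int64)
    idx = np.arange(L)
    for row in member_rows:
        votes[idx, unique[row]] += counts[row]
    best_base = votes[:, :4].argmax(axis=1)
    base_max = votes[:, :4].max(axis=1)
    return np.where(votes[:, _N_CODE] > base_max, _N_CODE, best_base).astype(np.uint8)


def _first_match(matrix: np.ndarray, n: int, v: np.ndarray, min_matches: int) -> int:
    """Index of the first of the n matrix rows whose Hamming-match count with
    v reaches min_matches, else -1.  N positions never match."""
    if n == 0:
        return -1
    m = matrix[:n]
    matches = ((m == v) & (m != _N_CODE) & (v != _N_CODE)).sum(axis=1)
    hits = np.nonzero(matches >= min_matches)[0]
    return int(hits[0]) if hits.size else -1


def greedy_cluster(signatures: Sequence[TagSignature], threshold: float = 0.89,
                   design=None) -> List[TagCluster]:
    """Greedy centroid clustering of equal-length composites.

    Unique composites are processed in canonical order (duplicate count
    descending, then lexicographic).  Pass 1 founds clusters with the first
    centroid whose identity reaches the threshold; pass 2 recomputes each
    cluster's plurality consensus and reassigns every composite once against
    the consensus list (new clusters may be founded during reassignment).
    """
    if not signatures:
        return []
    L = len(signatures[0].composite)
    if any(len(s.composite) != L for s in signatures):
        raise ValueError("all composites must have equal length")
    # identity >= threshold  <=>  matches >= ceil(threshold * L)
    min_matches = int(np.ceil(threshold * L - 1e-9))

    groups: dict = {}
    for s in signatures:
        groups.setdefault(s.composite, []).append(s)
    order = sorted(groups, key=lambda c: (-len(groups[c]), c))
    unique = np.stack([_encode(c) for c in order])
    counts = [len(groups[c]) for c in order]
    n_unique = len(order)

    # pass 1: greedy founding against centroids (founder composites)
    centroids = np.empty((n_unique, L), dtype=np.uint8)
    assign1: list = []
    n_clusters = 0
    for i in range(n_unique):
        j = _first_match(centroids, n_clusters, unique[i], min_matches)
        if j < 0:
            centroids[n_clusters] = unique[i]
            j = n_clusters
            n_clusters += 1
        assign1.append(j)

    # plurality consensus of pass-1 clusters
    members1: list = [[] for _ in range(n_clusters)]
    for i, j in enumerate(assign1):
        members1[j].append(i)
    consensus = np.empty((2 * n_unique, L), dtype=np.uint8)
    for j in range(n_clusters):
        consensus[j] = _weighted_consensus(unique, counts, members1[j])

    # pass 2: one reassignment sweep against consensuses (list may grow)
    n_cons = n_clusters
    assign2: list = []
    for i in range(n_unique):
        j = _first_match(consensus, n_cons, unique[i], min_matches)
        if j < 0:
            consensus[n_cons] = unique[i]
            j = n_cons
            n_cons += 1
        assign2.append(j)

    members2: list = [[] for _ in range(n_cons)]
    for i, j in enumerate(assign2):
        members2[j].append(i)

    clusters: List[TagCluster] = []
    serial = 0
    for j in range(n_cons):
        rows = members2[j]
        if not rows:
            continue  # cluster emptied by reassignment
        final = _decode(_weighted_consensus(unique, counts, rows))
        sigs = [s for r in rows for s in groups[order[r]]]
        sample_votes: dict = {}
        for s in sigs:
            sample_votes[s.sample] = sample_votes.get(s.sample, 0) + 1
        sample = max(sorted(sample_votes), key=lambda k: sample_votes[k])
        serial += 1
        clusters.append(TagCluster(
            cluster_id=f"c{serial:06d}",
            consensus=final,
            consensus_tag_f=final[0:10],
            consensus_tag_r=final[10:20],
            sample=sample,
            member_pair_ids=[s.pair_id for s in sigs],
        ))
    return clusters
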