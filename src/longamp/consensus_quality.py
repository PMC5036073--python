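"""Map-back consensus calling with per-base PHRED quality estimates.

Bin reads are mapped onto the kept contigs by shared-k-mer anchoring plus a
band-0 (substitutions-only) comparison — adequate because each bin contains
reads from a single template, so true indels are absent.  The consensus
quality model is additive: at each column

    Q = min(93, max(0, sum of qualities agreeing with the consensus base
                        - sum of qualities disagreeing))

which grows with concordant coverage and is capped at the FASTQ '~' limit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .assembly import Contig, Read
from .io_model import MAX_PHRED

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


@dataclass
class Pileup:
    """Per-position base/quality columns over one contig."""

    contig: Contig
    columns: list  # list of list[(base, qual)]
    n_mapped: int
    n_unmapped: int


@dataclass
class ConsensusSequence:
    cluster_id: str
    sequence: str
    quality: Tuple[int, ...]
    coverage: Tuple[int, ...]
    sample: str

    def __post_init__(self):
        if not (len(self.sequence) == len(self.quality) == len(self.coverage)):
            raise ValueError("consensus field lengths differ")


def _anchor_offset(seq: str, index: Dict[str, int], anchor_k: int,
                   stride: int = 4) -> Optional[int]:
    votes: Dict[int, int] = {}
    for j in range(0, len(seq) - anchor_k + 1, stride):
        p = index.get(seq[j:j + anchor_k])
        if p is not None:
            off = p - j
            votes[off] = votes.get(off, 0) + 1
    if not votes:
        return None
    return min(votes, key=lambda o: (-votes[o], o))


def map_reads(contig: Contig, reads: Sequence[Read], anchor_k: int = 15,
              min_identity: float = 0.90) -> Pileup:
    """Anchor each read by its best shared k-mer offset and record
    substitution-only alignment columns; reads below the identity threshold
    over their overlap are left unmapped."""
    L = len(contig.sequence)
    index: Dict[str, int] = {}
    for i in range(L - anchor_k + 1):
        index.setdefault(contig.sequence[i:i + anchor_k], i)
    columns: List[list] = [[] for _ in range(L)]
    n_mapped = n_unmapped = 0
    for _, seq, quals in reads:
        off = _anchor_offset(seq, index, anchor_k)
        if off is None:
            n_unmapped += 1
            continue
        c_lo, c_hi = max(0, off), min(L, off + len(seq))
        if c_hi - c_lo < anchor_k:
            n_unmapped += 1
            continue
        r_lo = c_lo - off
        window = seq[r_lo:r_lo + (c_hi - c_lo)]
        ref = contig.sequence[c_lo:c_hi]
        matches = sum(1 for a, b in zip(window, ref) if a == b and a != "N")
        if matches / (c_hi - c_lo) < min_identity:
            n_unmapped += 1
            continue
        n_mapped += 1
        for i, (base, q) in enumerate(zip(window, quals[r_lo:r_lo + (c_hi - c_lo)])):
            columns[c_lo + i].append((base, q))
    return Pileup(contig, columns, n_mapped, n_unmapped)


def call_consensus(pileup: Pileup, cluster_id: str = "", sample: str = ""
                   ) -> ConsensusSequence:
    """Quality-weighted plurality consensus with the additive capped PHRED
    model.  Columns with no mapped reads fall back to the contig base at
    quality 0."""
    if not any(pileup.columns):
        raise ValueError("empty pileup")
    seq_out = []
    qual_out = []
    cov_out = []
    for pos, column in enumerate(pileup.columns):
        if not column:
            seq_out.append(pileup.contig.sequence[pos])
            qual_out.append(0)
            cov_out.append(0)
            continue
        weights = [0.0] * 4
        counts = [0] * 4
        total = 0.0
        for base, q in column:
            total += q
            if base in _BASE_IDX:
                weights[_BASE_IDX[base]] += q
                counts[_BASE_IDX[base]] += 1
        # quality-weighted plurality; count then base order break ties
        best = max(range(4), key=lambda i: (weights[i], counts[i], -i))
        agree = weights[best]
        q = int(min(MAX_PHRED, max(0, round(agree - (total - agree)))))
        seq_out.append(_BASES[best])
        qual_out.append(q)
        cov_out.append(len(column))
    return ConsensusSequence(cluster_id, "".join(seq_out), tuple(qual_out),
                             tuple(cov_out), sample)


def consensus_for_bin(result_contigs: Sequence[Contig], reads: Sequence[Read],
                      cluster_id: str, sample: str, anchor_k: int = 15,
                      min_identity: float = 0.90) -> List[ConsensusSequence]:
    """Consensus for every kept contig of a bin.  Each read is attributed to
    the contig where it anchors best (first contig wins ties), so no read is
    piled up twice."""
    if not result_contigs:
        return []
    if len(result_contigs) == 1:
        assignment = {0: list(reads)}
    else:
        indexes = []
        for c in result_contigs:
            idx: Dict[str, int] = {}
            for i in range(len(c.sequence) - anchor_k + 1):
                idx.setdefault(c.sequence[i:i + anchor_k], i)
            indexes.append(idx)
        assignment = {i: [] for i in range(len(result_contigs))}
        for read in reads:
            _, seq, _ = read
            best_ci, best_votes = None, 0
            for ci, idx in enumerate(indexes):
                votes = sum(1 for j in range(0, len(seq) - anchor_k + 1, 4)
                            if seq[j:j + anchor_k] in idx)
                if votes > best_votes:
                    best_ci, best_votes = ci, votes
            if best_ci is not None:
                assignment[best_ci].append(read)
    out = []
    for ci, contig in enumerate(result_contigs):
        pile = map_reads(contig, assignment.get(ci, []), anchor_k, min_identity)
        if not any(pile.columns):
            continue
        suffix = "" if len(result_contigs) == 1 else f".{ci + 1}"
        out.append(call_consensus(pile, cluster_id=f"{cluster_id}{suffix}",
                                  sample=sample))
    return out


def quality_profile(consensuses: Sequence[ConsensusSequence]) -> pd.DataFrame:
    """Per-position summary across consensuses: median/mean quality and
    median coverage at each 1-based position index, over the consensuses
    long enough to reach it."""
    if not consensuses:
        return pd.DataFrame(columns=["position", "n", "mean_quality",
                                     "median_quality", "median_coverage"])
    max_len = max(len(c.sequence) for c in consensuses)
    rows = []
    quals = [np.asarray(c.quality, dtype=float) for c in consensuses]
    covs = [np.asarray(c.coverage, dtype=float) for c in consensuses]
    for pos in range(max_len):
        qs = [q[pos] for q in quals if len(q) > pos]
        cs = [c[pos] for c in covs if len(c) > pos]
        rows.append({
            "position": pos + 1,
            "n": len(qs),
            "mean_quality": float(np.mean(qs)),
            "median_quality": float(np.median(qs)),
            "median_coverage": float(np.median(cs)),
        })
    return pd.DataFrame(rows)
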