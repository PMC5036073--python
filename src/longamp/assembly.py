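"""Per-bin micro-assembly: synthetic-sequence trimming, quality trimming,
k-mer spectrum error correction, de Bruijn contig assembly and the 10-fold
coverage contig filter.

Each bin holds reads from (with high probability) a single ~1.4 kb template,
so a small deterministic de Bruijn assembler with k=31 is adequate: the
amplicon has essentially no repeats at that k.  Reads are first oriented to
the forward strand of the template (the 27F -> 1391R direction) using the
parsed tagged ends as anchors, which keeps the whole graph single-stranded.

Contigs at much lower coverage than the dominant contig within a bin are the
signature of contaminating reads from recombinant fragments that happen to
carry the bin's tag; they are removed by a strict fold rule (default 10x).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .binning import ROLE_END_END, ROLE_INTERNAL_F, ROLE_INTERNAL_R, TemplateBin
from .demux import EndParse
from .io_model import RunConfig, reverse_complement

#: an oriented, trimmed read ready for assembly
Read = Tuple[str, str, Tuple[int, ...]]  # (read_id, seq, quals)


@dataclass
class Contig:
    sequence: str
    per_base_coverage: np.ndarray
    supporting_reads: list = field(default_factory=list)

    @property
    def mean_coverage(self) -> float:
        return float(np.mean(self.per_base_coverage))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AssemblyResult:
    cluster_id: str
    contigs_before: List[Contig]
    contigs_after: List[Contig]

    @property
    def reconstructed_length(self) -> int:
        return sum(len(c) for c in self.contigs_after)

    def is_full_length(self, threshold: int = 1300) -> bool:
        return self.reconstructed_length >= threshold


# ---------------------------------------------------------------------------
# read preparation


def trim_synthetic(seq: str, quals: Sequence[int], parse: Optional[EndParse],
                   adapter_stubs: Sequence[str] = ()) -> Tuple[str, Tuple[int, ...]]:
    """Remove synthetic sequence from a read without ever discarding it.

    For a parsed tagged end the phaser+barcode+tag+primer prefix is cut
    (the biological insert starts at ``parse.insert_start``); any read is
    additionally truncated at 3' read-through into a configured adapter stub
    (leftmost exact occurrence, then leftmost occurrence with one mismatch;
    overlaps shorter than 8 nt are ignored as spurious).
    """
    quals = tuple(quals)
    if parse is not None:
        seq, quals = seq[parse.insert_start:], quals[parse.insert_start:]
    cut = len(seq)
    for stub in adapter_stubs:
        pos = seq.find(stub)
        if 0 <= pos < cut:
            cut = pos
    if cut == len(seq) and adapter_stubs:
        for stub in adapter_stubs:
            w = len(stub)
            for pos in range(0, len(seq) - 7):
                window = seq[pos:pos + w]
                ov = len(window)
                if ov < 8:
                    break
                mm = sum(1 for a, b in zip(window, stub) if a != b)
                if mm <= 1:
                    cut = min(cut, pos)
                    break
    return seq[:cut], quals[:cut]


def quality_trim(seq: str, quals: Sequence[int], q_threshold: int = 20
                 ) -> Tuple[str, Tuple[int, ...]]:
    """3' quality trim by running sum of (q_threshold - q), BWA style: scan
    from the 3' end, cut at the position maximising the running sum; stop
    once the sum goes negative."""
    s = 0
    best = 0
    cut = len(seq)
    for i in range(len(seq) - 1, -1, -1):
        s += q_threshold - quals[i]
        if s < 0:
            break
        if s > best:
            best = s
            cut = i
    return seq[:cut], tuple(quals[:cut])


def oriented_bin_reads(bin_: TemplateBin, config: RunConfig) -> List[Read]:
    """Trim and orient every member read of a bin to the template forward
    strand; reads shorter than 2k after trimming are dropped."""
    k = config.assembler_k
    out: List[Read] = []

    def emit(read_id, seq, quals, parse, flip):
        seq, quals = trim_synthetic(seq, quals, parse, config.adapter_stubs)
        seq, quals = quality_trim(seq, quals, config.quality_trim_q)
        if flip:
            seq = reverse_complement(seq)
            quals = quals[::-1]
        if len(seq) >= 2 * k:
            out.append((read_id, seq, quals))

    for cp, role in bin_.members:
        pair = cp.pair
        mates = {1: (pair.seq1, pair.qual1), 2: (pair.seq2, pair.qual2)}
        if role == ROLE_END_END:
            fs, fq = mates[cp.forward_mate]
            rs, rq = mates[cp.reverse_mate]
            emit(f"{pair.pair_id}/F", fs, fq, cp.forward_parse, flip=False)
            emit(f"{pair.pair_id}/R", rs, rq, cp.reverse_parse, flip=True)
        elif role == ROLE_INTERNAL_F:
            ts, tq = mates[cp.forward_mate]
            is_, iq = mates[cp.internal_mate_index]
            emit(f"{pair.pair_id}/F", ts, tq, cp.forward_parse, flip=False)
            # the internal mate reads back toward the tagged forward end
            emit(f"{pair.pair_id}/I", is_, iq, None, flip=True)
        elif role == ROLE_INTERNAL_R:
            ts, tq = mates[cp.reverse_mate]
            is_, iq = mates[cp.internal_mate_index]
            emit(f"{pair.pair_id}/R", ts, tq, cp.reverse_parse, flip=True)
            emit(f"{pair.pair_id}/I", is_, iq, None, flip=False)
    return out


# ---------------------------------------------------------------------------
# k-mer error correction


def _kmer_counts(reads: Sequence[Read], k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for _, seq, _ in reads:
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            if "N" not in km:
                counts[km] = counts.get(km, 0) + 1
    return counts


def correct_errors(reads: Sequence[Read], k: int = 31, min_count: int = 3,
                   min_reads: int = 3, max_corrections: int = 2) -> List[Read]:
    """Spectrum-based single-base correction.

    A base is suspect when every k-mer covering it is weak (count below
    ``min_count``); it is corrected iff exactly one substitution lifts all
    its covering k-mers to solid, with at most ``max_corrections`` edits per
    read.  Ambiguous cases are left untouched.  Bins with fewer than
    ``min_reads`` reads are returned unchanged (no usable spectrum).
    """
    if len(reads) < min_reads:
        return list(reads)
    counts = _kmer_counts(reads, k)

    def covering_solid(seq: str, i: int) -> bool:
        lo = max(0, i - k + 1)
        hi = min(i, len(seq) - k)
        if hi < lo:
            return True  # base not covered by any full k-mer: leave alone
        return any(counts.get(seq[j:j + k], 0) >= min_count
                   for j in range(lo, hi + 1))

    def all_covering_solid(seq: str, i: int) -> bool:
        lo = max(0, i - k + 1)
        hi = min(i, len(seq) - k)
        if hi < lo:
            return False
        return all(counts.get(seq[j:j + k], 0) >= min_count
                   for j in range(lo, hi + 1))

    out: List[Read] = []
    for read_id, seq, quals in reads:
        n_weak_kmers = sum(1 for i in range(len(seq) - k + 1)
                           if counts.get(seq[i:i + k], 0) < min_count)
        if n_weak_kmers == 0:
            out.append((read_id, seq, quals))
            continue
        edits = 0
        i = 0
        while i < len(seq) and edits < max_corrections:
            if not covering_solid(seq, i):
                fixes = []
                for b in "ACGT":
                    if b == seq[i]:
                        continue
                    cand = seq[:i] + b + seq[i + 1:]
                    if all_covering_solid(cand, i):
                        fixes.append(cand)
                if len(fixes) == 1:
                    seq = fixes[0]
                    edits += 1
            i += 1
        out.append((read_id, seq, quals))
    return out


# ---------------------------------------------------------------------------
# de Bruijn assembly


def _unitigs(kmers: set, k: int) -> List[str]:
    """Maximal unambiguous paths through the k-mer graph, deterministically
    ordered.  Cycles (rare in this setting) are emitted from their smallest
    k-mer."""

    def succs(km):
        suf = km[1:]
        return [suf + b for b in "ACGT" if suf + b in kmers]

    def preds(km):
        pre = km[:-1]
        return [b + pre for b in "ACGT" if b + pre in kmers]

    starts = []
    for km in kmers:
        p = preds(km)
        if len(p) != 1 or len(succs(p[0])) != 1:
            starts.append(km)
    visited = set()
    unitigs = []
    for km in sorted(starts):
        if km in visited:
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            nxt = succs(cur)
            if len(nxt) != 1:
                break
            nx = nxt[0]
            if len(preds(nx)) != 1 or nx in visited:
                break
            path.append(nx)
            visited.add(nx)
            cur = nx
        unitigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    # leftovers are pure cycles
    leftover = sorted(kmers - visited)
    for km in leftover:
        if km in visited:
            continue
        path = [km]
        visited.add(km)
        cur = km
        while True:
            nxt = [x for x in succs(cur) if x not in visited]
            if not nxt:
                break
            cur = sorted(nxt)[0]
            path.append(cur)
            visited.add(cur)
        unitigs.append(path[0] + "".join(p[-1] for p in path[1:]))
    return sorted(unitigs, key=lambda u: (-len(u), u))


def assemble_bin(reads: Sequence[Read], k: int = 31) -> List[Contig]:
    """Assemble one bin into contigs.

    The base solid-k-mer floor is 2 (1 for bins with < 10 reads).  Because
    coverage is U-shaped (tagged ends are read by every pair) a second,
    depth-adaptive floor — a tenth of the count-weighted median k-mer count,
    which is what separates coincident-error and contaminating-chimera
    k-mers from the template in deep bins — is also tried, and the attempt
    yielding the fewest contigs (ties: the longest total reconstruction)
    wins.  Tips and low-coverage bubble arms are pruned in bounded rounds;
    maximal unambiguous paths become contigs with per-base coverage taken
    from the k-mer counts.
    """
    counts = _kmer_counts(reads, k)
    if not counts:
        return []
    base_floor = 2 if len(reads) >= 10 else 1
    arr = np.sort(np.fromiter(counts.values(), dtype=np.int64))
    cum = np.cumsum(arr)
    depth_proxy = int(arr[np.searchsorted(cum, cum[-1] / 2)])
    floors = sorted({base_floor, max(base_floor, depth_proxy // 10)})
    best: List[Contig] = []
    for floor in floors:
        attempt = _assemble_with_floor(reads, counts, k, floor)
        if not best or _assembly_rank(attempt) < _assembly_rank(best):
            best = attempt
    return best


def _assembly_rank(contigs: List[Contig]) -> tuple:
    if not contigs:  # an empty assembly never beats a non-empty one
        return (float("inf"), 0)
    return (len(contigs), -sum(len(c) for c in contigs))


def _assemble_with_floor(reads: Sequence[Read], counts: Dict[str, int],
                         k: int, floor: int) -> List[Contig]:
    solid = {km for km, c in counts.items() if c >= floor}
    if not solid:
        return []

    unitigs = _unitigs(solid, k)
    max_tip = max(2 * k, max((len(s) for _, s, _ in reads), default=0) + k)
    for _ in range(3):  # bounded pruning rounds
        if len(unitigs) <= 1:
            break

        def preds(km):
            return [b + km[:-1] for b in "ACGT" if b + km[:-1] in solid]

        def succs(km):
            return [km[1:] + b for b in "ACGT" if km[1:] + b in solid]

        def mean_count(u):
            return (sum(counts[u[i:i + k]] for i in range(len(u) - k + 1))
                    / (len(u) - k + 1))

        pruned = set()
        # low-coverage bubble arms (coincident errors surviving correction):
        # parallel short unitigs sharing both junction (k-1)-mers
        arms: Dict[tuple, list] = {}
        for u in unitigs:
            if len(u) < 2 * k:
                arms.setdefault((u[:k - 1], u[-(k - 1):]), []).append(u)
        for group in arms.values():
            if len(group) < 2:
                continue
            best = max(mean_count(u) for u in group)
            for u in group:
                if mean_count(u) < best:
                    pruned.update(u[i:i + k] for i in range(len(u) - k + 1))
        # tips: very short ones unconditionally; read-length-scale ones only
        # when a clearly better-supported continuation exists at their
        # junction (the signature of contaminating chimeric fragments)
        for u in unitigs:
            if len(u) >= max_tip:
                continue
            first, last = u[:k], u[len(u) - k:]
            dead_start, dead_end = not preds(first), not succs(last)
            if dead_start == dead_end:  # isolated or internal: not a tip
                continue
            if len(u) < 2 * k:
                pruned.update(u[i:i + k] for i in range(len(u) - k + 1))
                continue
            junction = preds(first) if dead_end else succs(last)
            anchor = first if dead_end else last
            sibling = 0
            for q in junction:
                for s in (succs(q) if dead_end else preds(q)):
                    if s != anchor:
                        sibling = max(sibling, counts[s])
            if sibling >= 3 * mean_count(u):
                pruned.update(u[i:i + k] for i in range(len(u) - k + 1))
        if not pruned or pruned == solid:
            break
        solid -= pruned
        unitigs = _unitigs(solid, k)

    contigs = []
    for u in unitigs:
        ncov = len(u) - k + 1
        cov = np.empty(len(u), dtype=float)
        for i in range(ncov):
            cov[i] = counts.get(u[i:i + k], 0)
        cov[ncov:] = cov[ncov - 1]
        contigs.append(Contig(u, cov))

    # attribute supporting reads by shared solid k-mers
    kmer_to_contig: Dict[str, int] = {}
    for ci, c in enumerate(contigs):
        for i in range(len(c.sequence) - k + 1):
            kmer_to_contig.setdefault(c.sequence[i:i + k], ci)
    for read_id, seq, _ in reads:
        hit = set()
        for i in range(0, len(seq) - k + 1, k):
            ci = kmer_to_contig.get(seq[i:i + k])
            if ci is not None:
                hit.add(ci)
        for ci in hit:
            contigs[ci].supporting_reads.append(read_id)
    return contigs


def filter_contigs(contigs: Sequence[Contig], fold: float = 10.0) -> List[Contig]:
    """Drop contigs whose mean coverage is more than ``fold`` times lower
    than the best-covered contig (strict rule: exactly ``fold``-fold lower
    is kept).  Order is preserved; idempotent and scale-invariant."""
    if not contigs:
        return []
    m = max(c.mean_coverage for c in contigs)
    return [c for c in contigs if not (c.mean_coverage * fold < m)]


def assemble_template_bin(bin_: TemplateBin, config: RunConfig) -> AssemblyResult:
    """Full per-bin pipeline: orient/trim -> correct -> assemble -> filter."""
    reads = oriented_bin_reads(bin_, config)
    reads = correct_errors(reads, k=config.assembler_k,
                           min_count=config.correction_min_count,
                           min_reads=config.min_reads_for_correction)
    before = assemble_bin(reads, k=config.assembler_k)
    after = filter_contigs(before, fold=config.contig_fold_threshold)
    return AssemblyResult(bin_.cluster_id, before, after)
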