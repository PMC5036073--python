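"""Demultiplexing: decode each read end's phaser/barcode/tag/primer layout,
classify read pairs as end+end or end+internal, and assign samples.

A tagged amplicon end reads as::

    [phaser 0-3 nt][barcode 8 nt][random tag 10 nt][gene primer][16S sequence ...]

The sample barcode is matched against the known set with up to one mismatch;
because internal 16S sequence can spuriously match a barcode, a candidate
parse must also show the gene-primer annealing sequence immediately after the
tag.  Pairs where exactly one mate parses are presumed to come from
tagmentation (end+internal) fragments.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

from .io_model import (EndDesign, ReadPair, RunConfig, SampleSheet, hamming,
                       iupac_mismatches)

FORWARD = "FORWARD"
REVERSE = "REVERSE"
END_END = "END_END"
END_INTERNAL = "END_INTERNAL"
UNASSIGNED = "UNASSIGNED"
INVALID_COMBINATION = "INVALID_COMBINATION"


@dataclass
class EndParse:
    """Decoded layout of one tagged amplicon end."""

    end_label: str
    phaser_len: int
    barcode_observed: str
    barcode_assigned: Optional[str]
    barcode_mismatches: int
    tag: str
    primer_mismatches: int
    gene_prefix: str
    insert_start: int


@dataclass
class ClassifiedPair:
    pair: ReadPair
    fragment_class: str
    forward_parse: Optional[EndParse] = None
    reverse_parse: Optional[EndParse] = None
    forward_mate: Optional[int] = None     # 1 or 2: which mate carries the forward end
    reverse_mate: Optional[int] = None
    internal_mate_index: Optional[int] = None
    sample: Optional[str] = None
    anomaly: Optional[str] = None


def parse_end(seq: str, design: EndDesign, barcode_set: Sequence[str],
              primer_tolerance: int = 2, barcode_mismatch_budget: int = 1,
              ) -> Optional[EndParse]:
    """Try to decode a tagged end at each allowed phaser offset (ascending;
    first satisfying offset wins).

    At offset ``p`` the barcode window must match exactly one known barcode
    within the mismatch budget AND the gene primer must be present (within
    ``primer_tolerance`` mismatches, IUPAC-aware) right after the tag.
    Returns ``None`` when no offset satisfies both conditions — absence is a
    valid outcome, not an error.
    """
    bl, tl = design.barcode_length, design.tag_length
    plen = len(design.gene_primer)
    for p in sorted(design.phaser_lengths):
        need = p + bl + tl + plen + design.gene_prefix_length
        if need > len(seq):
            continue
        window = seq[p:p + bl]
        hits = []
        for bc in barcode_set:
            d = hamming(window, bc)
            if d <= barcode_mismatch_budget:
                hits.append((d, bc))
        if len(hits) != 1:
            # no hit, or ambiguous (>= 2 barcodes within budget): reject offset
            continue
        bc_mm, bc = hits[0]
        primer_start = p + bl + tl
        pm = iupac_mismatches(seq[primer_start:primer_start + plen], design.gene_primer)
        if pm > primer_tolerance:
            continue
        ins = primer_start + plen
        return EndParse(
            end_label=design.end_label,
            phaser_len=p,
            barcode_observed=window,
            barcode_assigned=bc,
            barcode_mismatches=bc_mm,
            tag=seq[p + bl:p + bl + tl],
            primer_mismatches=pm,
            gene_prefix=seq[ins:ins + design.gene_prefix_length],
            insert_start=ins,
        )
    return None


def assign_sample(bc_f: str, bc_r: str, sheet: SampleSheet) -> str:
    """Return the sample for a valid ordered barcode pair, else the
    INVALID_COMBINATION sentinel (the in-vitro recombination signal)."""
    return sheet.valid_combinations.get((bc_f, bc_r), INVALID_COMBINATION)


def classify_pair(pair: ReadPair, config: RunConfig, sheet: SampleSheet
                  ) -> ClassifiedPair:
    """Classify one read pair as END_END, END_INTERNAL or UNASSIGNED.

    Each mate is tested against both end designs.  One forward and one
    reverse parse make an end+end pair (sample assigned from the barcode
    combination); a single parse makes an end+internal pair; two parses with
    the same end label are anomalous and excluded rather than guessed.
    """
    tol = config.primer_mismatch_tolerance
    parses = []  # (mate_index, EndParse)
    for idx, seq in ((1, pair.seq1), (2, pair.seq2)):
        pf = parse_end(seq, config.forward_design, sheet.forward_set, tol)
        pr = parse_end(seq, config.reverse_design, sheet.reverse_set, tol)
        if pf is not None and pr is not None:
            # one mate matching both designs cannot be resolved
            return ClassifiedPair(pair, UNASSIGNED, anomaly="mate_matches_both_designs")
        if pf is not None:
            parses.append((idx, pf))
        elif pr is not None:
            parses.append((idx, pr))

    if len(parses) == 2:
        labels = {p.end_label for _, p in parses}
        if labels != {FORWARD, REVERSE}:
            return ClassifiedPair(pair, UNASSIGNED, anomaly="same_end_twice")
        (i1, p1), (i2, p2) = parses
        if p1.end_label == FORWARD:
            fmate, fp, rmate, rp = i1, p1, i2, p2
        else:
            fmate, fp, rmate, rp = i2, p2, i1, p1
        sample = assign_sample(fp.barcode_assigned, rp.barcode_assigned, sheet)
        return ClassifiedPair(pair, END_END, forward_parse=fp, reverse_parse=rp,
                              forward_mate=fmate, reverse_mate=rmate, sample=sample)
    if len(parses) == 1:
        idx, p = parses[0]
        other = 2 if idx == 1 else 1
        if p.end_label == FORWARD:
            return ClassifiedPair(pair, END_INTERNAL, forward_parse=p,
                                  forward_mate=idx, internal_mate_index=other)
        return ClassifiedPair(pair, END_INTERNAL, reverse_parse=p,
                              reverse_mate=idx, internal_mate_index=other)
    return ClassifiedPair(pair, UNASSIGNED)


def classify_pairs(pairs: Iterable[ReadPair], config: RunConfig,
                   sheet: SampleSheet) -> Iterator[ClassifiedPair]:
    for pair in pairs:
        yield classify_pair(pair, config, sheet)


@dataclass
class RateStat:
    invalid: int
    total: int
    rate: float  # percent


def invalid_combination_rate(pairs: Iterable[ClassifiedPair], total: int
                             ) -> RateStat:
    """Percentage of all read pairs that are end+end with a barcode
    combination never assigned to a sample — a lower bound on the in-vitro
    recombination rate."""
    if total <= 0:
        raise ValueError("total must be positive")
    invalid = sum(1 for cp in pairs
                  if cp.fragment_class == END_END and cp.sample == INVALID_COMBINATION)
    return RateStat(invalid, total, 100.0 * invalid / total)


def demux_stats(classified: Sequence[ClassifiedPair]) -> dict:
    """Per-class counts plus the invalid-combination rate, JSON-ready."""
    counts = Counter(cp.fragment_class for cp in classified)
    anomalies = Counter(cp.anomaly for cp in classified if cp.anomaly)
    per_sample = Counter(cp.sample for cp in classified
                         if cp.fragment_class == END_END and cp.sample)
    total = len(classified)
    stats = {
        "total_pairs": total,
        "end_end": counts.get(END_END, 0),
        "end_internal": counts.get(END_INTERNAL, 0),
        "unassigned": counts.get(UNASSIGNED, 0),
        "anomalies": dict(anomalies),
        "per_sample_end_end": dict(per_sample),
    }
    if total:
        rs = invalid_combination_rate(classified, total)
        stats["invalid_combination"] = rs.invalid
        stats["invalid_combination_rate_pct"] = rs.rate
    return stats
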