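"""Core domain types, sequence utilities and file I/O shared by all stages.

Conventions used throughout the package:

* all coordinates are 0-based, half-open;
* qualities are PHRED integers (0-93) serialized as PHRED+33, never PHRED+64;
* an ``N`` base never counts as a match in any Hamming comparison.
"""

from __future__ import annotations

import csv
import gzip
import io
import itertools
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Iterable, Iterator, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33
MAX_PHRED = 93

#: Standard bacterial 16S primer annealing sequences (27F and 1391R).
PRIMER_27F = "AGAGTTTGATCMTGGCTCAG"
PRIMER_1391R = "GACGGGCGGTGTGTRCA"

#: IUPAC degenerate nucleotide expansions.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVNacgtryswkmbdhvn",
                            "TGCAYRSWMKVHDBNtgcayrswmkvhdbn")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance where ``N`` (either side) always counts as a mismatch."""
    if len(a) != len(b):
        raise ValueError(f"hamming on unequal lengths: {len(a)} vs {len(b)}")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N" or y == "N")


def hamming_identity(a: str, b: str) -> float:
    """Fraction of positions that match (N never matches)."""
    if len(a) != len(b):
        raise ValueError("identity on unequal lengths")
    if not a:
        raise ValueError("identity of empty sequences")
    return 1.0 - hamming(a, b) / len(a)


def iupac_mismatches(observed: str, pattern: str) -> int:
    """Mismatch count of an observed read window against a possibly degenerate
    pattern.  A read base matches when it is inside the IUPAC expansion of the
    pattern base; an ``N`` in the read never matches."""
    if len(observed) != len(pattern):
        raise ValueError("iupac_mismatches on unequal lengths")
    mm = 0
    for obs, pat in zip(observed, pattern):
        if obs == "N" or obs not in IUPAC.get(pat, pat):
            mm += 1
    return mm


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ReadPair:
    """One paired-end record; qualities are PHRED integer tuples."""

    pair_id: str
    seq1: str
    qual1: tuple
    seq2: str
    qual2: tuple

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.pair_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class EndDesign:
    """Layout of one synthetic amplicon end:
    phaser (0-3 nt) + sample barcode (8 nt) + random tag (10 nt) + gene primer."""

    end_label: str  # FORWARD or REVERSE
    gene_primer: str
    phaser_lengths: tuple = (0, 1, 2, 3)
    barcode_length: int = 8
    tag_length: int = 10
    gene_prefix_length: int = 14

    def __post_init__(self):
        if self.barcode_length <= 0 or self.tag_length <= 0:
            raise ValueError("barcode_length and tag_length must be positive")
        if not self.gene_primer:
            raise ValueError("gene_primer must be non-empty")

    def insert_start(self, phaser_len: int) -> int:
        return phaser_len + self.barcode_length + self.tag_length + len(self.gene_primer)


DEFAULT_FORWARD_DESIGN = EndDesign("FORWARD", PRIMER_27F)
DEFAULT_REVERSE_DESIGN = EndDesign("REVERSE", PRIMER_1391R)


@dataclass
class SampleSheet:
    """Sample -> (forward barcode, reverse barcode) with validated barcode sets."""

    samples: dict  # name -> (bc_f, bc_r)
    barcode_length: int = 8
    min_pairwise_distance: int = 3

    def __post_init__(self):
        self.valid_combinations = {}
        for name, (bf, br) in self.samples.items():
            key = (bf, br)
            if key in self.valid_combinations:
                raise ValueError(f"duplicate barcode combination {key}")
            self.valid_combinations[key] = name
        self.forward_set = sorted({bf for bf, _ in self.samples.values()})
        self.reverse_set = sorted({br for _, br in self.samples.values()})
        for side, bcs in (("forward", self.forward_set), ("reverse", self.reverse_set)):
            for bc in bcs:
                if len(bc) != self.barcode_length:
                    raise ValueError(
                        f"{side} barcode {bc} has length {len(bc)}, "
                        f"expected {self.barcode_length}")
                if set(bc) - set("ACGT"):
                    raise ValueError(f"{side} barcode {bc} has non-ACGT characters")
            # pairwise Hamming >= 3 guarantees unambiguous 1-mismatch decoding
            for a, b in itertools.combinations(bcs, 2):
                d = hamming(a, b)
                if d < self.min_pairwise_distance:
                    raise ValueError(
                        f"{side} barcodes {a} and {b} are at Hamming distance "
                        f"{d} < {self.min_pairwise_distance}")


@dataclass
class RunConfig:
    """All pipeline thresholds in one place; documented defaults mirror the
    protocol description (see docs/methods.md)."""

    forward_design: EndDesign = field(default_factory=lambda: DEFAULT_FORWARD_DESIGN)
    reverse_design: EndDesign = field(default_factory=lambda: DEFAULT_REVERSE_DESIGN)
    sample_sheet_path: str | None = None
    identity_threshold: float = 0.89     # dual-tag composite clustering
    tag_mismatch_budget: int = 1         # read-to-cluster tag binning
    primer_mismatch_tolerance: int = 2   # primer annealing screen
    contig_fold_threshold: float = 10.0  # coverage-based chimeric contig removal
    assembler_k: int = 31
    quality_trim_q: int = 20
    anchor_k: int = 15                   # map-back seed k-mer
    map_min_identity: float = 0.90
    full_length_threshold: int = 1300
    correction_min_count: int = 3
    min_reads_for_correction: int = 3
    adapter_stubs: tuple = ()
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if not (0.0 < self.identity_threshold <= 1.0):
            raise ValueError("identity threshold must be in (0, 1]")
        if self.contig_fold_threshold <= 1:
            raise ValueError("contig fold threshold must be > 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in ("forward_design", "reverse_design"):
            d[key]["phaser_lengths"] = list(d[key]["phaser_lengths"])
        d["adapter_stubs"] = list(self.adapter_stubs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key in ("forward_design", "reverse_design"):
            if key in d and isinstance(d[key], dict):
                dd = dict(d[key])
                if "phaser_lengths" in dd:
                    dd["phaser_lengths"] = tuple(dd["phaser_lengths"])
                d[key] = EndDesign(**dd)
        if "adapter_stubs" in d:
            d["adapter_stubs"] = tuple(d["adapter_stubs"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


# ---------------------------------------------------------------------------
# readers / writers


def _open_text(path) -> IO[str]:
    path = str(path)
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def _strip_mate_suffix(title: str) -> str:
    name = title.split()[0]
    if name.endswith("/1") or name.endswith("/2"):
        name = name[:-2]
    return name


def _decode_quals(qual_str: str) -> tuple:
    return tuple(ord(c) - PHRED_OFFSET for c in qual_str)


def read_fastq_pairs(path_r1, path_r2) -> Iterator[ReadPair]:
    """Stream mate-reconciled read pairs from two PHRED+33 FASTQ files
    (plain or gzip).  Raises on mismatched record counts or IDs."""
    with _open_text(path_r1) as h1, _open_text(path_r2) as h2:
        it1 = FastqGeneralIterator(h1)
        it2 = FastqGeneralIterator(h2)
        for i, (rec1, rec2) in enumerate(itertools.zip_longest(it1, it2), start=1):
            if rec1 is None or rec2 is None:
                short = path_r1 if rec1 is None else path_r2
                raise ValueError(
                    f"FASTQ files have different record counts: {short} "
                    f"ends before record {i}")
            t1, s1, q1 = rec1
            t2, s2, q2 = rec2
            id1, id2 = _strip_mate_suffix(t1), _strip_mate_suffix(t2)
            if id1 != id2:
                raise ValueError(
                    f"mate ID mismatch at record {i}: {id1!r} vs {id2!r}")
            yield ReadPair(id1, s1.upper(), _decode_quals(q1),
                           s2.upper(), _decode_quals(q2))


def write_fastq_pairs(pairs: Iterable[ReadPair], path_r1, path_r2) -> None:
    op = gzip.open if str(path_r1).endswith(".gz") else open
    with op(path_r1, "wt") as h1, op(path_r2, "wt") as h2:
        for p in pairs:
            q1 = "".join(chr(q + PHRED_OFFSET) for q in p.qual1)
            q2 = "".join(chr(q + PHRED_OFFSET) for q in p.qual2)
            h1.write(f"@{p.pair_id}/1\n{p.seq1}\n+\n{q1}\n")
            h2.write(f"@{p.pair_id}/2\n{p.seq2}\n+\n{q2}\n")


def load_sample_sheet(path, design: EndDesign | None = None) -> SampleSheet:
    """Read a TSV/CSV sample sheet (sample, forward barcode, reverse barcode).

    A header row is detected by non-ACGT content in the barcode columns.
    Barcodes are upper-cased; the sheet is validated (lengths, duplicates,
    minimum pairwise Hamming distance 3 within each barcode set).
    """
    bc_len = design.barcode_length if design else 8
    text = Path(path).read_text()
    delim = "\t" if "\t" in text.splitlines()[0] else ","
    samples: dict = {}
    for row in csv.reader(io.StringIO(text), delimiter=delim):
        if not row or all(not c.strip() for c in row):
            continue
        if len(row) < 3:
            raise ValueError(f"sample sheet row has fewer than 3 columns: {row}")
        name, bf, br = row[0].strip(), row[1].strip().upper(), row[2].strip().upper()
        if set(bf + br) - set("ACGTN"):  # header row
            continue
        if name in samples:
            raise ValueError(f"duplicate sample name {name!r}")
        samples[name] = (bf, br)
    if not samples:
        raise ValueError(f"no samples parsed from {path}")
    return SampleSheet(samples, barcode_length=bc_len)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    with open(path, "wt") as h:
        h.write("sample\tforward_barcode\treverse_barcode\n")
        for name, (bf, br) in sheet.samples.items():
            h.write(f"{name}\t{bf}\t{br}\n")


def write_fasta_with_quality(records: Sequence, fasta_path, fastq_path) -> None:
    """Write consensus records (objects with ``cluster_id``, ``sample``,
    ``sequence`` and ``quality`` attributes) as paired FASTA + FASTQ files.

    Record IDs encode sample, cluster and length; qualities are capped at 93
    (FASTQ ``~``); values outside 0-93 raise.
    """
    fa_records, fq_records = [], []
    for rec in records:
        if len(rec.sequence) != len(rec.quality):
            raise ValueError(f"{rec.cluster_id}: sequence/quality length mismatch")
        quals = list(rec.quality)
        if any(q < 0 or q > MAX_PHRED for q in quals):
            raise ValueError(f"{rec.cluster_id}: quality outside 0-{MAX_PHRED}")
        rid = f"{rec.sample}|{rec.cluster_id}|len={len(rec.sequence)}"
        sr = SeqRecord(Seq(rec.sequence), id=rid, description="")
        fa_records.append(sr)
        fq = SeqRecord(Seq(rec.sequence), id=rid, description="")
        fq.letter_annotations["phred_quality"] = quals
        fq_records.append(fq)
    SeqIO.write(fa_records, str(fasta_path), "fasta")
    SeqIO.write(fq_records, str(fastq_path), "fastq")


def read_fasta(path) -> list:
    """Return [(id, sequence)] from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
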