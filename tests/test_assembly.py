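"""Trimming, error correction, de Bruijn assembly, coverage contig filter."""

import random

import numpy as np
import pytest

from longamp.assembly import (Contig, assemble_bin, correct_errors,
                              filter_contigs, quality_trim, trim_synthetic)
from longamp.demux import EndParse


def _rand_seq(rnd, n):
    return "".join(rnd.choice("ACGT") for _ in range(n))


def _tile_reads(template, read_len=120, step=40, copies=1):
    reads = []
    serial = 0
    for c in range(copies):
        for start in range(0, max(1, len(template) - read_len + 1), step):
            seq = template[start:start + read_len]
            reads.append((f"r{serial}", seq, tuple([35] * len(seq))))
            serial += 1
        tail = template[-read_len:]
        reads.append((f"r{serial}", tail, tuple([35] * len(tail))))
        serial += 1
    return reads


class TestTrimSynthetic:
    def test_parsed_prefix_removed(self):
        parse = EndParse("FORWARD", 2, "A" * 8, "A" * 8, 0, "C" * 10, 0,
                         "G" * 14, 40)
        seq = "X" * 40 + "ACGTACGT"
        trimmed, quals = trim_synthetic(seq.replace("X", "T"),
                                        [30] * 48, parse)
        assert trimmed == "ACGTACGT"
        assert len(quals) == 8

    def test_adapter_stub_removed_exact_and_one_mismatch(self):
        stub = "CTGTCTCTTATACACATCTG"  # 20-nt stub at the 3' end
        seq = "ACGT" * 20 + stub
        trimmed, _ = trim_synthetic(seq, [30] * len(seq), None, (stub,))
        assert trimmed == "ACGT" * 20
        fuzzy = stub[:5] + "A" + stub[6:]
        seq2 = "ACGT" * 20 + fuzzy
        trimmed2, _ = trim_synthetic(seq2, [30] * len(seq2), None, (stub,))
        assert trimmed2 == "ACGT" * 20

    def test_clean_read_unchanged(self):
        seq = "ACGTACGTACGT"
        trimmed, quals = trim_synthetic(seq, [30] * 12, None, ("TTTTGGGGCCCC",))
        assert trimmed == seq and len(quals) == 12


class TestQualityTrim:
    def test_high_quality_unchanged(self):
        seq, quals = quality_trim("ACGT" * 10, [40] * 40, 20)
        assert len(seq) == 40

    def test_low_quality_tail_removed(self):
        # running-sum trace: ten Q2 bases at the 3' end accumulate +18 each
        seq, quals = quality_trim("A" * 30 + "C" * 10, [38] * 30 + [2] * 10, 20)
        assert seq == "A" * 30
        assert len(quals) == 30

    def test_all_low_quality_fully_trimmed(self):
        seq, _ = quality_trim("ACGT" * 5, [2] * 20, 20)
        assert seq == ""

    def test_interior_dip_kept(self):
        # one bad base inside a good read must not truncate the 3' end
        quals = [38] * 10 + [2] + [38] * 10
        seq, _ = quality_trim("A" * 21, quals, 20)
        assert len(seq) == 21


class TestCorrectErrors:
    def test_clean_reads_unchanged(self):
        rnd = random.Random(0)
        template = _rand_seq(rnd, 200)
        reads = [(f"r{i}", template, tuple([35] * 200)) for i in range(30)]
        assert correct_errors(reads, k=31) == reads

    def test_single_substitution_reverted(self):
        rnd = random.Random(1)
        template = _rand_seq(rnd, 200)
        good = [(f"r{i}", template, tuple([35] * 200)) for i in range(29)]
        bad_seq = template[:100] + ("A" if template[100] != "A" else "C") \
            + template[101:]
        reads = good + [("bad", bad_seq, tuple([35] * 200))]
        corrected = correct_errors(reads, k=31)
        assert corrected[-1][1] == template

    def test_ambiguous_correction_left_unchanged(self):
        # two haplotypes at equal depth: a third variant base between them
        # has two equally solid fixes and must stay untouched
        rnd = random.Random(2)
        left, right = _rand_seq(rnd, 100), _rand_seq(rnd, 100)
        hap_a = left + "A" + right
        hap_c = left + "C" + right
        reads = [(f"a{i}", hap_a, tuple([35] * 201)) for i in range(10)]
        reads += [(f"c{i}", hap_c, tuple([35] * 201)) for i in range(10)]
        odd = left + "G" + right
        reads.append(("odd", odd, tuple([35] * 201)))
        corrected = correct_errors(reads, k=31)
        assert corrected[-1][1] == odd

    def test_tiny_bins_skipped(self):
        reads = [("a", "ACGT" * 20, tuple([35] * 80))]
        assert correct_errors(reads, k=31, min_reads=3) == reads


class TestAssembleBin:
    def test_lossless_reconstruction(self):
        rnd = random.Random(3)
        template = _rand_seq(rnd, 1365)
        reads = _tile_reads(template, read_len=250, step=60, copies=5)
        contigs = assemble_bin(reads, k=31)
        assert len(contigs) == 1
        assert contigs[0].sequence == template

    def test_coverage_gap_splits_contigs(self):
        rnd = random.Random(4)
        template = _rand_seq(rnd, 1000)
        # tile the two halves only, leaving a > k gap in the middle
        reads = _tile_reads(template[:400], copies=3) + \
            _tile_reads(template[600:], copies=3)
        contigs = assemble_bin(reads, k=31)
        assert len(contigs) == 2
        assert {c.sequence for c in contigs} == {template[:400], template[600:]}

    def test_no_solid_kmers_empty(self):
        assert assemble_bin([], k=31) == []

    def test_coverage_tracks_kmer_counts(self):
        rnd = random.Random(5)
        template = _rand_seq(rnd, 300)
        reads = [(f"r{i}", template, tuple([35] * 300)) for i in range(7)]
        contigs = assemble_bin(reads, k=31)
        assert len(contigs) == 1
        assert np.all(contigs[0].per_base_coverage == 7)
        assert contigs[0].mean_coverage == 7.0

    def test_error_read_corrected_roundtrip(self):
        """1% error at ~30x: correction + assembly recover the template."""
        rnd = random.Random(6)
        template = _rand_seq(rnd, 800)
        reads = []
        serial = 0
        for c in range(7):
            for start in range(0, 800 - 250 + 1, 55):
                seq = list(template[start:start + 250])
                for i in range(len(seq)):
                    if rnd.random() < 0.01:
                        seq[i] = rnd.choice([b for b in "ACGT" if b != seq[i]])
                reads.append((f"r{serial}", "".join(seq), tuple([35] * 250)))
                serial += 1
            tail = template[-250:]
            reads.append((f"r{serial}", tail, tuple([35] * 250)))
            serial += 1
        corrected = correct_errors(reads, k=31)
        contigs = filter_contigs(assemble_bin(corrected, k=31))
        assert len(contigs) == 1
        assert contigs[0].sequence == template


def _contig(cov, n=100):
    return Contig("A" * n, np.full(n, float(cov)))


class TestFilterContigs:
    def test_strict_boundary(self):
        # 9 * 10 < 100 -> dropped; 10 * 10 == 100 -> kept (not strict)
        kept = filter_contigs([_contig(100), _contig(9)], fold=10)
        assert [c.mean_coverage for c in kept] == [100.0]
        kept = filter_contigs([_contig(100), _contig(10)], fold=10)
        assert [c.mean_coverage for c in kept] == [100.0, 10.0]

    def test_single_contig_kept(self):
        assert len(filter_contigs([_contig(1)])) == 1

    def test_empty_input(self):
        assert filter_contigs([]) == []

    @pytest.mark.parametrize("scale", [1.0, 3.5, 1000.0])
    def test_idempotent_and_scale_invariant(self, scale):
        contigs = [_contig(c * scale) for c in (100, 55, 12, 10, 9.9, 1)]
        once = filter_contigs(contigs)
        assert filter_contigs(once) == once
        unscaled = filter_contigs([_contig(c) for c in (100, 55, 12, 10, 9.9, 1)])
        assert [c.mean_coverage / scale for c in once] == \
            pytest.approx([c.mean_coverage for c in unscaled])
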