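"""Demultiplexing: layout parsing, pair classification, sample assignment."""

import itertools

import pytest

from longamp.demux import (END_END, END_INTERNAL, INVALID_COMBINATION,
                           UNASSIGNED, classify_pair, assign_sample,
                           invalid_combination_rate, parse_end)
from longamp.io_model import (EndDesign, ReadPair, RunConfig, SampleSheet,
                              reverse_complement)

PRIMER = "AGAGTTTGATCMTGGCTCAG"
DESIGN = EndDesign("FORWARD", PRIMER)
BC = "ACACACAC"
BC_SET = [BC, "GTGTGTGT", "TTTTCCCC"]
TAG = "AAGGTTCCAA"
GENE = "ATCGATCGATCGATCGATCGATCGATCGATCG"
PRIMER_REAL = PRIMER.replace("M", "A")


def _layout(phaser="", bc=BC, tag=TAG, primer=PRIMER_REAL, gene=GENE):
    return phaser + bc + tag + primer + gene


class TestParseEnd:
    def test_exact_layout_phaser_zero(self):
        p = parse_end(_layout(), DESIGN, BC_SET)
        assert p is not None
        assert (p.phaser_len, p.barcode_mismatches, p.tag) == (0, 0, TAG)
        assert p.barcode_assigned == BC
        assert p.insert_start == 0 + 8 + 10 + len(PRIMER)
        assert p.gene_prefix == GENE[:14]

    def test_phaser_and_one_barcode_mismatch(self):
        bad_bc = "ACACACAT"  # one mismatch from BC, distance >=2 from others
        p = parse_end(_layout(phaser="GG", bc=bad_bc), DESIGN, BC_SET)
        assert p is not None
        assert (p.phaser_len, p.barcode_mismatches) == (2, 1)
        assert p.barcode_assigned == BC

    def test_two_barcode_mismatches_rejected(self):
        p = parse_end(_layout(bc="ACACACTT"), DESIGN, BC_SET)
        assert p is None

    def test_primer_mismatches_over_tolerance_rejected(self):
        bad_primer = "TTTGTTTGATCATGGCTCAG"  # 3 mismatches vs 27F
        assert parse_end(_layout(primer=bad_primer), DESIGN, BC_SET) is None
        two_off = "TTAGTTTGATCATGGCTCAG"     # 2 mismatches: tolerated
        assert parse_end(_layout(primer=two_off), DESIGN, BC_SET) is not None

    def test_degenerate_primer_base_matches_both_expansions(self):
        for m in "AC":  # M = A or C
            p = parse_end(_layout(primer=PRIMER.replace("M", m)), DESIGN, BC_SET)
            assert p is not None and p.primer_mismatches == 0

    def test_smallest_phaser_wins(self):
        # barcode present both at offset 0 and (artificially) later; the
        # ascending scan must report phaser 0
        p = parse_end(_layout(), DESIGN, BC_SET)
        assert p.phaser_len == 0

    def test_too_short_sequence(self):
        assert parse_end(BC + TAG, DESIGN, BC_SET) is None

    def test_one_error_decoding_never_misassigns(self):
        """Exhaustive 1-error corruption: with min pairwise distance >= 3,
        1-mismatch decoding can never pick the wrong barcode."""
        for bc in BC_SET:
            for i, b in itertools.product(range(8), "ACGT"):
                corrupted = bc[:i] + b + bc[i + 1:]
                p = parse_end(_layout(bc=corrupted), DESIGN, BC_SET)
                assert p is not None
                assert p.barcode_assigned == bc


def _sheet():
    return SampleSheet({"S1": ("ACACACAC", "TGCATGCA"),
                        "S2": ("GTGTGTGT", "CCAACCAA")})


def _pair(seq1, seq2):
    return ReadPair("p1", seq1, tuple([35] * len(seq1)),
                    seq2, tuple([35] * len(seq2)))


class TestClassifyPair:
    CFG = RunConfig()

    def fwd_read(self, bc="ACACACAC"):
        from longamp.io_model import PRIMER_27F
        return bc + TAG + PRIMER_27F.replace("M", "C") + GENE

    def rev_read(self, bc="TGCATGCA"):
        from longamp.io_model import PRIMER_1391R
        return bc + "TTCCGGAATT" + PRIMER_1391R.replace("R", "G") + GENE

    def test_end_end(self):
        cp = classify_pair(_pair(self.fwd_read(), self.rev_read()), self.CFG,
                           _sheet())
        assert cp.fragment_class == END_END
        assert (cp.forward_mate, cp.reverse_mate) == (1, 2)
        assert cp.sample == "S1"

    def test_end_end_swapped_mates(self):
        cp = classify_pair(_pair(self.rev_read(), self.fwd_read()), self.CFG,
                           _sheet())
        assert cp.fragment_class == END_END
        assert (cp.forward_mate, cp.reverse_mate) == (2, 1)

    def test_end_internal(self):
        cp = classify_pair(_pair(self.rev_read(), GENE * 8), self.CFG, _sheet())
        assert cp.fragment_class == END_INTERNAL
        assert cp.reverse_parse is not None and cp.forward_parse is None
        assert cp.internal_mate_index == 2

    def test_unassigned(self):
        cp = classify_pair(_pair(GENE * 8, GENE * 8), self.CFG, _sheet())
        assert cp.fragment_class == UNASSIGNED

    def test_same_end_twice_is_anomaly(self):
        cp = classify_pair(_pair(self.fwd_read("ACACACAC"),
                                 self.fwd_read("GTGTGTGT")), self.CFG, _sheet())
        assert cp.fragment_class == UNASSIGNED
        assert cp.anomaly == "same_end_twice"

    def test_cross_combination_flagged_invalid(self):
        cp = classify_pair(_pair(self.fwd_read("ACACACAC"),
                                 self.rev_read("CCAACCAA")), self.CFG, _sheet())
        assert cp.fragment_class == END_END
        assert cp.sample == INVALID_COMBINATION


class TestAssignSample:
    def test_valid_and_cross_pairs(self):
        sheet = _sheet()
        assert assign_sample("ACACACAC", "TGCATGCA", sheet) == "S1"
        assert assign_sample("GTGTGTGT", "CCAACCAA", sheet) == "S2"
        assert assign_sample("ACACACAC", "CCAACCAA", sheet) == INVALID_COMBINATION


class TestInvalidCombinationRate:
    @pytest.mark.parametrize("invalid,total,expected",
                             [(11240, 296864, 3.8), (0, 100, 0.0),
                              (10, 40, 25.0)])
    def test_rates(self, invalid, total, expected):
        class FakeCP:
            def __init__(self):
                self.fragment_class = END_END
                self.sample = INVALID_COMBINATION

        pairs = [FakeCP() for _ in range(invalid)]
        rs = invalid_combination_rate(pairs, total)
        assert round(rs.rate, 1) == expected

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            invalid_combination_rate([], 0)


class TestOnSimulation:
    def test_error_free_full_length_all_end_end(self, clean_small_run):
        """Zero error, zero chimeras: every full-length fragment classifies
        END_END and the sample matches truth."""
        d = clean_small_run
        run = d["run"]
        truth = {r.pair_id: r for r in run.truth.reads}
        mol = run.truth.molecule_by_id()
        by_id = {cp.pair.pair_id: cp for cp in d["classified"]}
        for rt in run.truth.reads:
            cp = by_id[rt.pair_id]
            if rt.fragment_class == "end_end":
                assert cp.fragment_class == END_END
                assert cp.sample == mol[rt.molecule_id].sample_f
            else:
                assert cp.fragment_class == END_INTERNAL

    def test_classification_deterministic(self, clean_small_run):
        from longamp.demux import classify_pair as clf
        d = clean_small_run
        run = d["run"]
        again = [clf(p, run.run_config, run.sample_sheet)
                 for p in run.read_pairs[:200]]
        for a, b in zip(again, d["classified"][:200]):
            assert (a.fragment_class, a.sample) == (b.fragment_class, b.sample)
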