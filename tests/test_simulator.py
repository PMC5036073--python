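"""Protocol simulator: determinism, truth bookkeeping, distributional checks."""

import math

import numpy as np
import pytest

from longamp.io_model import PRIMER_1391R, PRIMER_27F, iupac_mismatches
from longamp.simulator import (SimConfig, generate_barcode_set,
                               make_sample_sheet, simulate_amplification,
                               simulate_fragments_and_reads, simulate_run,
                               simulate_templates)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestBarcodes:
    def test_set_obeys_min_distance(self):
        from longamp.io_model import hamming
        bcs = generate_barcode_set(25, rng=_rng(1))
        assert len(bcs) == 25
        for i, a in enumerate(bcs):
            for b in bcs[i + 1:]:
                assert hamming(a, b) >= 3

    def test_combinatorial_design(self):
        """25 barcodes per side allow 625 sample combinations; 10-nt tags
        give ~1 million distinct labels per end."""
        fwd = generate_barcode_set(25, rng=_rng(2))
        rev = generate_barcode_set(25, rng=_rng(3))
        assert len(fwd) * len(rev) == 625
        assert 4 ** 10 >= 10 ** 6


class TestTemplates:
    def test_counts_and_truth(self):
        cfg = SimConfig(n_templates=100, seed=5)
        tmpl = simulate_templates(cfg, _rng(5))
        assert len(tmpl) == 100
        assert len({t.template_id for t in tmpl}) == 100
        for t in tmpl[:10]:
            assert len(t.sequence) == cfg.template_length
            assert len(t.tag_f) == len(t.tag_r) == 10
            # primer-compatible termini
            assert iupac_mismatches(t.sequence[:20], PRIMER_27F) == 0

    def test_determinism(self):
        cfg = SimConfig(n_templates=30, seed=9)
        a = simulate_templates(cfg, _rng(9))
        b = simulate_templates(cfg, _rng(9))
        assert [(t.sequence, t.tag_f, t.tag_r) for t in a] == \
            [(t.sequence, t.tag_f, t.tag_r) for t in b]

    def test_tag_collisions_follow_birthday_bound(self):
        """5,000 uniform draws from 4^10 tags: collisions within 3 SD of the
        birthday expectation."""
        cfg = SimConfig(n_templates=5000, seed=13)
        tmpl = simulate_templates(cfg, _rng(13))
        space = 4 ** 10
        n = 5000
        expected = n * (n - 1) / 2 / space  # expected colliding pairs
        sd = math.sqrt(expected)            # ~Poisson
        for tags in ([t.tag_f for t in tmpl], [t.tag_r for t in tmpl]):
            pairs = sum(c * (c - 1) // 2
                        for c in np.unique(tags, return_counts=True)[1])
            assert abs(pairs - expected) <= 3 * sd + 1

    def test_unique_tags_option(self):
        cfg = SimConfig(n_templates=2000, seed=14, unique_tags=True)
        tmpl = simulate_templates(cfg, _rng(14))
        assert len({t.tag_f for t in tmpl}) == 2000
        assert len({t.tag_r for t in tmpl}) == 2000


class TestAmplification:
    def _templates(self, n=200, seed=21):
        return simulate_templates(SimConfig(n_templates=n, seed=seed),
                                  _rng(seed))

    def test_no_chimeras_at_rate_zero(self):
        mols = simulate_amplification(self._templates(), 1.0, 0.0, 4, _rng(1))
        assert not any(m.is_chimera for m in mols)

    def test_chimera_fraction_within_binomial_interval(self):
        mols = simulate_amplification(self._templates(500, 22), 1.27, 0.10,
                                      4, _rng(2))
        n = len(mols)
        frac = sum(m.is_chimera for m in mols) / n
        half = 2.576 * math.sqrt(0.1 * 0.9 / n)
        assert abs(frac - 0.10) <= half

    def test_chimeras_have_two_distinct_parents_and_mixed_tags(self):
        tmpl = self._templates(100, 23)
        by_id = {t.template_id: t for t in tmpl}
        mols = simulate_amplification(tmpl, 1.0, 0.3, 4, _rng(3))
        for m in mols:
            if m.is_chimera:
                assert m.parent_f != m.parent_r
                assert m.tag_f == by_id[m.parent_f].tag_f
                assert m.tag_r == by_id[m.parent_r].tag_r
                assert 0 < m.breakpoint < len(m.sequence)

    def test_sigma_zero_uniform_copies(self):
        mols = simulate_amplification(self._templates(50, 24), 0.0, 0.0, 6,
                                      _rng(4))
        counts = {}
        for m in mols:
            counts[m.parent_f] = counts.get(m.parent_f, 0) + 1
        assert set(counts.values()) == {6}


@pytest.fixture(scope="module")
def small_pool():
    cfg = SimConfig(n_templates=40, seed=31, tagmented_ratio=7.0)
    rng = np.random.default_rng(cfg.seed)
    sheet = make_sample_sheet(cfg, rng)
    tmpl = simulate_templates(cfg, rng)
    mols = simulate_amplification(tmpl, cfg.sigma, 0.0, cfg.depth, rng)
    pairs, truth = simulate_fragments_and_reads(mols, cfg, sheet, rng)
    return cfg, mols, pairs, truth


class TestFragmentsAndReads:
    def test_ratio_near_seven_to_one(self, small_pool):
        cfg, mols, pairs, truth = small_pool
        n_ee = sum(1 for t in truth if t.fragment_class == "end_end")
        n_ti = len(truth) - n_ee
        assert n_ee == len(mols)
        assert abs(n_ti / n_ee - cfg.tagmented_ratio) / cfg.tagmented_ratio \
            <= 0.05

    def test_truth_bijection(self, small_pool):
        _, _, pairs, truth = small_pool
        assert {p.pair_id for p in pairs} == {t.pair_id for t in truth}
        assert len(pairs) == len(truth)

    def test_read_lengths(self, small_pool):
        cfg, _, pairs, _ = small_pool
        for p in pairs[:500]:
            assert len(p.seq1) == len(p.seq2) == cfg.read_length
            assert all(2 <= q <= 40 for q in p.qual1)

    def test_fragment_size_selection(self):
        """Tagmented fragments honour the 400-1,500 size window: every
        internal breakpoint leaves at least frag_min - prefix of template."""
        cfg = SimConfig(n_templates=10, seed=33, tagmented_ratio=4.0,
                        error_rate=0.0)
        rng = np.random.default_rng(cfg.seed)
        sheet = make_sample_sheet(cfg, rng)
        tmpl = simulate_templates(cfg, rng)
        mols = simulate_amplification(tmpl, 0.0, 0.0, 3, rng)
        by_id = {m.molecule_id: m for m in mols}
        pairs, truth = simulate_fragments_and_reads(mols, cfg, sheet, rng)
        by_pid = {p.pair_id: p for p in pairs}
        for t in truth:
            if t.fragment_class == "end_end":
                continue
            p = by_pid[t.pair_id]
            mol = by_id[t.molecule_id]
            # internal mate must be entirely template sequence
            internal = p.seq2 if t.fragment_class == "end_internal_f" else p.seq1
            from longamp.io_model import reverse_complement
            if t.fragment_class == "end_internal_f":
                assert reverse_complement(internal) in mol.sequence
            else:
                assert internal in mol.sequence


class TestSimulateRun:
    def test_same_seed_byte_identical(self, tmp_path):
        from longamp.simulator import write_sim_run
        cfg = SimConfig(n_templates=15, seed=41, tagmented_ratio=2.0)
        p1 = write_sim_run(simulate_run(cfg), tmp_path / "a")
        p2 = write_sim_run(simulate_run(cfg), tmp_path / "b")
        for key in ("r1", "r2", "templates", "molecules", "reads"):
            a = open(p1[key], "rb").read()
            b = open(p2[key], "rb").read()
            assert a == b

    def test_chimera_rate_validation(self):
        with pytest.raises(ValueError):
            SimConfig(chimera_rate=1.5)
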