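"""Synthetic tagged-amplicon run generator with full ground truth.

The generator emulates the wet-lab protocol end to end so every pipeline
stage is testable without external data:

* templates: ~1.4 kb amplicons with fixed 27F/1391R-compatible termini,
  one sample barcode pair and two independent uniform-random 10-nt tags
  per template (duplicate tag draws allowed by default — collision realism);
* amplification: per-template copy number ``max(1, round(depth * LogNormal(0, sigma)))``,
  reproducing the heavy-tailed abundance spread seen in real runs;
* chimeras: with probability ``chimera_rate`` a copy is replaced by a
  single-breakpoint template switch joining the prefix of one template to
  the suffix of another, inheriting the forward tag from the prefix parent
  and the reverse tag from the suffix parent;
* library: every full-length molecule yields one end+end read pair; a
  tagmentation pool of one-tagged-end fragments (uniform breakpoints,
  retained in the 400-1,500 bp size range) is mixed in at a 7:1 read-pair
  ratio; reads are 2 x 250 nt with the synthetic phaser/barcode/tag/primer
  layout serialized on tagged ends;
* errors: per-base substitutions at a constant rate, with a deterministic
  position-decaying quality curve plus integer jitter (qualities are
  serialized faithfully but do not drive error placement).

Same config + seed => byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from .io_model import (DEFAULT_FORWARD_DESIGN, DEFAULT_REVERSE_DESIGN,
                       IUPAC, PRIMER_1391R, PRIMER_27F, ReadPair,
                       RunConfig, SampleSheet, hamming, reverse_complement,
                       write_fastq_pairs, write_sample_sheet)

_BASES = "ACGT"


@dataclass
class SimConfig:
    """Study conditions for a synthetic run (defaults follow the protocol
    description; see docs/methods.md for the rationale of each value)."""

    n_templates: int = 1000
    template_length: int = 1365
    n_samples: int = 12
    n_barcodes: int = 25           # per barcode set; up to 25 x 25 combinations
    barcode_length: int = 8
    tag_length: int = 10
    sigma: float = 1.27            # lognormal bias; CV = sqrt(e^{sigma^2}-1) ~ 2
    chimera_rate: float = 0.10     # per amplified copy
    depth: float = 4.0             # copy number scale; mean abundance = depth*e^{sigma^2/2}
    frag_min: int = 400
    frag_max: int = 1500
    tagmented_ratio: float = 7.0   # tagmented : full-length read pairs
    read_length: int = 250
    error_rate: float = 0.005
    q_start: int = 38
    q_end: int = 28
    q_noise: int = 2
    seed: int = 0
    unique_tags: bool = False      # draw tags without replacement
    reference_fasta: Optional[str] = None

    def __post_init__(self):
        if not (0.0 <= self.chimera_rate <= 1.0):
            raise ValueError("chimera_rate must be in [0, 1]")
        if self.frag_min >= self.frag_max:
            raise ValueError("fragment size range is empty")


@dataclass
class TemplateTruth:
    template_id: str
    sample: str
    tag_f: str
    tag_r: str
    sequence: str


@dataclass
class Molecule:
    molecule_id: str
    sequence: str
    tag_f: str
    tag_r: str
    sample_f: str     # sample whose barcode sits on the forward end
    sample_r: str
    is_chimera: bool
    parent_f: str     # template contributing the prefix (and tag_f)
    parent_r: str
    breakpoint: Optional[int]


@dataclass
class ReadTruth:
    pair_id: str
    molecule_id: str
    fragment_class: str   # end_end | end_internal_f | end_internal_r
    is_chimera: bool
    breakpoint: Optional[int]


@dataclass
class SimTruth:
    templates: List[TemplateTruth]
    molecules: List[Molecule]
    reads: List[ReadTruth]

    def template_by_id(self) -> Dict[str, TemplateTruth]:
        return {t.template_id: t for t in self.templates}

    def molecule_by_id(self) -> Dict[str, Molecule]:
        return {m.molecule_id: m for m in self.molecules}


@dataclass
class SimRun:
    config: SimConfig
    run_config: RunConfig
    sample_sheet: SampleSheet
    read_pairs: List[ReadPair]
    truth: SimTruth


# ---------------------------------------------------------------------------
# building blocks


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve IUPAC degeneracies to a concrete template-compatible base."""
    out = []
    for b in primer:
        exp = IUPAC[b]
        out.append(exp if len(exp) == 1 else exp[rng.integers(0, len(exp))])
    return "".join(out)


def generate_barcode_set(n: int, length: int = 8, min_dist: int = 3,
                         rng: Optional[np.random.Generator] = None,
                         max_tries: int = 100000) -> List[str]:
    """Greedy random barcode design with a minimum pairwise Hamming distance
    (3 by default, the requirement for unambiguous 1-mismatch decoding)."""
    rng = rng or np.random.default_rng(0)
    chosen: List[str] = []
    tries = 0
    while len(chosen) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not build barcode set; relax constraints")
        cand = _random_seq(rng, length)
        if all(hamming(cand, c) >= min_dist for c in chosen):
            chosen.append(cand)
    return chosen


def make_sample_sheet(cfg: SimConfig, rng: np.random.Generator) -> SampleSheet:
    """One forward + one reverse barcode per sample (diagonal design), drawn
    from two independently generated barcode sets; cross combinations are
    therefore always invalid, which is what flags cross-sample chimeras."""
    fwd = generate_barcode_set(cfg.n_barcodes, cfg.barcode_length, rng=rng)
    rev = generate_barcode_set(cfg.n_barcodes, cfg.barcode_length, rng=rng)
    if cfg.n_samples > cfg.n_barcodes:
        raise ValueError("more samples than barcodes")
    samples = {f"S{i + 1:02d}": (fwd[i], rev[i]) for i in range(cfg.n_samples)}
    return SampleSheet(samples, barcode_length=cfg.barcode_length)


# ---------------------------------------------------------------------------
# stage 1: templates


def simulate_templates(cfg: SimConfig, rng: np.random.Generator
                       ) -> List[TemplateTruth]:
    """Template sequences (reference FASTA or random with primer-compatible
    termini), each with a sample and an independent random tag per end."""
    if cfg.reference_fasta:
        from .io_model import read_fasta
        refs = read_fasta(cfg.reference_fasta)
        if not refs:
            raise ValueError(f"no sequences in {cfg.reference_fasta}")
        seqs = [refs[i % len(refs)][1] for i in range(cfg.n_templates)]
    else:
        seqs = []
        core_len = (cfg.template_length - len(PRIMER_27F) - len(PRIMER_1391R))
        if core_len <= 0:
            raise ValueError("template_length shorter than the two primers")
        for _ in range(cfg.n_templates):
            left = _realize_primer(PRIMER_27F, rng)
            right = reverse_complement(_realize_primer(PRIMER_1391R, rng))
            seqs.append(left + _random_seq(rng, core_len) + right)

    samples = [f"S{(i % cfg.n_samples) + 1:02d}" for i in range(cfg.n_templates)]
    if cfg.unique_tags:
        used_f: set = set()
        used_r: set = set()
        tags_f, tags_r = [], []
        while len(tags_f) < cfg.n_templates:
            t = _random_seq(rng, cfg.tag_length)
            if t not in used_f:
                used_f.add(t)
                tags_f.append(t)
        while len(tags_r) < cfg.n_templates:
            t = _random_seq(rng, cfg.tag_length)
            if t not in used_r:
                used_r.add(t)
                tags_r.append(t)
    else:
        tags_f = [_random_seq(rng, cfg.tag_length) for _ in range(cfg.n_templates)]
        tags_r = [_random_seq(rng, cfg.tag_length) for _ in range(cfg.n_templates)]
    return [TemplateTruth(f"t{i:05d}", samples[i], tags_f[i], tags_r[i], seqs[i])
            for i in range(cfg.n_templates)]


# ---------------------------------------------------------------------------
# stage 2: biased amplification with template switching


def simulate_amplification(templates: Sequence[TemplateTruth], sigma: float,
                           chimera_rate: float, depth: float,
                           rng: np.random.Generator) -> List[Molecule]:
    """Copy each template ``max(1, round(depth * LogNormal(0, sigma)))``
    times; each copy independently becomes a chimera with probability
    ``chimera_rate``, joining the prefix of one random template to the
    suffix of another (distinct) template at a uniform interior breakpoint."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    n = len(templates)
    factors = rng.lognormal(mean=0.0, sigma=sigma, size=n) if sigma > 0 \
        else np.ones(n)
    copies = np.maximum(1, np.rint(depth * factors)).astype(int)
    molecules: List[Molecule] = []
    serial = 0
    for ti, t in enumerate(templates):
        for _ in range(copies[ti]):
            serial += 1
            mid = f"m{serial:07d}"
            if chimera_rate > 0 and rng.random() < chimera_rate:
                i = int(rng.integers(0, n))
                j = int(rng.integers(0, n - 1))
                if j >= i:
                    j += 1
                a, b = templates[i], templates[j]
                lim = min(len(a.sequence), len(b.sequence))
                bp = int(rng.integers(1, lim))
                molecules.append(Molecule(
                    mid, a.sequence[:bp] + b.sequence[bp:],
                    tag_f=a.tag_f, tag_r=b.tag_r,
                    sample_f=a.sample, sample_r=b.sample,
                    is_chimera=True, parent_f=a.template_id,
                    parent_r=b.template_id, breakpoint=bp))
            else:
                molecules.append(Molecule(
                    mid, t.sequence, tag_f=t.tag_f, tag_r=t.tag_r,
                    sample_f=t.sample, sample_r=t.sample,
                    is_chimera=False, parent_f=t.template_id,
                    parent_r=t.template_id, breakpoint=None))
    return molecules


# ---------------------------------------------------------------------------
# stage 3: fragments, reads, errors


def _quality_string(n: int, cfg: SimConfig, rng: np.random.Generator
                    ) -> Tuple[int, ...]:
    pos = np.arange(n)
    base = cfg.q_start - (cfg.q_start - cfg.q_end) * pos / max(1, cfg.read_length - 1)
    if cfg.q_noise > 0:
        base = base + rng.integers(-cfg.q_noise, cfg.q_noise + 1, size=n)
    return tuple(int(q) for q in np.clip(np.rint(base), 2, 40))


def _with_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    positions = rng.choice(len(seq), size=n_err, replace=False)
    out = list(seq)
    for p in positions:
        alternatives = [b for b in _BASES if b != out[p]]
        out[p] = alternatives[rng.integers(0, 3)]
    return "".join(out)


def _tagged_prefix(barcode: str, tag: str, cfg: SimConfig,
                   rng: np.random.Generator) -> str:
    phaser_len = int(rng.integers(0, 4))
    return _random_seq(rng, phaser_len) + barcode + tag


def _make_read(payload: str, cfg: SimConfig, rng: np.random.Generator
               ) -> Tuple[str, Tuple[int, ...]]:
    seq = payload[:cfg.read_length]
    seq = _with_errors(seq, cfg.error_rate, rng)
    return seq, _quality_string(len(seq), cfg, rng)


def simulate_fragments_and_reads(molecules: Sequence[Molecule], cfg: SimConfig,
                                 sheet: SampleSheet, rng: np.random.Generator
                                 ) -> Tuple[List[ReadPair], List[ReadTruth]]:
    """Emit one end+end pair per molecule plus a tagmentation pool of
    one-tagged-end fragments at the configured read-pair ratio."""
    pairs: List[ReadPair] = []
    truth: List[ReadTruth] = []
    serial = 0

    def next_id() -> str:
        nonlocal serial
        serial += 1
        return f"sim{serial:07d}"

    bc = sheet.samples  # sample -> (bc_f, bc_r)

    # full-length (end+end) pool
    for mol in molecules:
        pid = next_id()
        pre_f = _tagged_prefix(bc[mol.sample_f][0], mol.tag_f, cfg, rng)
        pre_r = _tagged_prefix(bc[mol.sample_r][1], mol.tag_r, cfg, rng)
        s1, q1 = _make_read(pre_f + mol.sequence, cfg, rng)
        s2, q2 = _make_read(pre_r + reverse_complement(mol.sequence), cfg, rng)
        pairs.append(ReadPair(pid, s1, q1, s2, q2))
        truth.append(ReadTruth(pid, mol.molecule_id, "end_end",
                               mol.is_chimera, mol.breakpoint))

    # tagmentation pool, sampled from the molecule pool (i.e. proportional
    # to copy number) with uniform breakpoints, size-selected
    target = int(round(cfg.tagmented_ratio * len(molecules)))
    guard = 0
    max_guard = 200 * max(1, target)
    while len(pairs) - len(molecules) < target:
        guard += 1
        if guard > max_guard:
            raise RuntimeError("fragment size selection rejected too many draws")
        mol = molecules[int(rng.integers(0, len(molecules)))]
        L = len(mol.sequence)
        left_end = bool(rng.integers(0, 2))
        if left_end:
            pre = _tagged_prefix(bc[mol.sample_f][0], mol.tag_f, cfg, rng)
            b = int(rng.integers(1, L))
            frag_len = len(pre) + b
            if not (cfg.frag_min <= frag_len <= cfg.frag_max):
                continue
            tagged = pre + mol.sequence[:b]
            internal = reverse_complement(mol.sequence[:b])
            pid = next_id()
            s1, q1 = _make_read(tagged, cfg, rng)
            s2, q2 = _make_read(internal, cfg, rng)
            pairs.append(ReadPair(pid, s1, q1, s2, q2))
            truth.append(ReadTruth(pid, mol.molecule_id, "end_internal_f",
                                   mol.is_chimera, mol.breakpoint))
        else:
            pre = _tagged_prefix(bc[mol.sample_r][1], mol.tag_r, cfg, rng)
            b = int(rng.integers(1, L))
            frag_len = len(pre) + (L - b)
            if not (cfg.frag_min <= frag_len <= cfg.frag_max):
                continue
            tagged = pre + reverse_complement(mol.sequence[b:])
            internal = mol.sequence[b:]
            pid = next_id()
            # the tagged (reverse) end is read 2 in the real library layout
            s1, q1 = _make_read(internal, cfg, rng)
            s2, q2 = _make_read(tagged, cfg, rng)
            pairs.append(ReadPair(pid, s1, q1, s2, q2))
            truth.append(ReadTruth(pid, mol.molecule_id, "end_internal_r",
                                   mol.is_chimera, mol.breakpoint))
    return pairs, truth


# ---------------------------------------------------------------------------
# orchestration


def simulate_run(cfg: SimConfig) -> SimRun:
    """Full synthetic run: templates -> amplification -> reads, with the
    matching sample sheet and pipeline run configuration."""
    rng = np.random.default_rng(cfg.seed)
    sheet = make_sample_sheet(cfg, rng)
    templates = simulate_templates(cfg, rng)
    molecules = simulate_amplification(templates, cfg.sigma, cfg.chimera_rate,
                                       cfg.depth, rng)
    pairs, read_truth = simulate_fragments_and_reads(molecules, cfg, sheet, rng)
    run_config = RunConfig(
        forward_design=DEFAULT_FORWARD_DESIGN,
        reverse_design=DEFAULT_REVERSE_DESIGN,
        seed=cfg.seed,
    )
    return SimRun(cfg, run_config, sheet, pairs,
                  SimTruth(templates, molecules, read_truth))


def write_sim_run(run: SimRun, out_dir) -> dict:
    """Serialize a simulated run: R1/R2 FASTQ, truth tables (TSV), sample
    sheet and config; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "r1": out / "reads_R1.fastq",
        "r2": out / "reads_R2.fastq",
        "sample_sheet": out / "sample_sheet.tsv",
        "templates": out / "truth_templates.tsv",
        "molecules": out / "truth_molecules.tsv",
        "reads": out / "truth_reads.tsv",
        "sim_config": out / "sim_config.yaml",
    }
    write_fastq_pairs(run.read_pairs, paths["r1"], paths["r2"])
    write_sample_sheet(run.sample_sheet, paths["sample_sheet"])
    with open(paths["templates"], "wt") as h:
        h.write("template_id\tsample\ttag_f\ttag_r\tsequence\n")
        for t in run.truth.templates:
            h.write(f"{t.template_id}\t{t.sample}\t{t.tag_f}\t{t.tag_r}\t{t.sequence}\n")
    with open(paths["molecules"], "wt") as h:
        h.write("molecule_id\tis_chimera\tparent_f\tparent_r\tbreakpoint"
                "\ttag_f\ttag_r\tsample_f\tsample_r\n")
        for m in run.truth.molecules:
            bp = "" if m.breakpoint is None else m.breakpoint
            h.write(f"{m.molecule_id}\t{int(m.is_chimera)}\t{m.parent_f}\t"
                    f"{m.parent_r}\t{bp}\t{m.tag_f}\t{m.tag_r}\t{m.sample_f}\t"
                    f"{m.sample_r}\n")
    with open(paths["reads"], "wt") as h:
        h.write("pair_id\tmolecule_id\tfragment_class\tis_chimera\tbreakpoint\n")
        for r in run.truth.reads:
            bp = "" if r.breakpoint is None else r.breakpoint
            h.write(f"{r.pair_id}\t{r.molecule_id}\t{r.fragment_class}\t"
                    f"{int(r.is_chimera)}\t{bp}\n")
    paths["sim_config"].write_text(yaml.safe_dump(asdict(run.config)))
    return {k: str(v) for k, v in paths.items()}
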