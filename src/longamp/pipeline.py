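"""File-based pipeline orchestration: simulate -> demux -> cluster ->
chimera-filter -> bin -> assemble -> consensus -> report.

Every stage reads its inputs from files and writes its outputs plus a
checksum manifest; a stage is skipped on rerun when its inputs, parameters
and outputs all match the recorded checksums (corrupted or missing outputs
trigger recomputation).  All stage functions are also usable directly as a
library API.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import binning as binning_mod
from . import run_stats
from .assembly import assemble_template_bin, oriented_bin_reads
from .chimera_filter import filter_recombinants, recombination_stats
from .consensus_quality import consensus_for_bin, quality_profile
from .demux import (END_END, INVALID_COMBINATION, ClassifiedPair,
                    EndParse, classify_pair, demux_stats)
from .io_model import (ReadPair, RunConfig, load_sample_sheet, read_fastq_pairs,
                       write_fasta_with_quality)
from .simulator import SimConfig, simulate_run, write_sim_run
from .tag_cluster import TagCluster, build_signature, greedy_cluster

log = logging.getLogger("longamp")

_PARSE_FIELDS = ["phaser_len", "barcode_observed", "barcode_assigned",
                 "barcode_mismatches", "tag", "primer_mismatches",
                 "gene_prefix", "insert_start"]


# ---------------------------------------------------------------------------
# manifests


def _md5(path: Path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _params_hash(params: dict) -> str:
    return hashlib.md5(json.dumps(params, sort_keys=True, default=str)
                       .encode()).hexdigest()


@dataclass
class StageManifest:
    stage: str
    inputs: dict
    params_hash: str
    outputs: dict


def run_stage(out_dir: Path, stage: str, inputs: Sequence[Path], params: dict,
              outputs: Sequence[Path], compute, force: bool = False) -> bool:
    """Run ``compute()`` unless the stage manifest shows identical inputs,
    parameters and intact outputs.  Returns True when recomputed."""
    out_dir = Path(out_dir)
    mdir = out_dir / "manifests"
    mdir.mkdir(parents=True, exist_ok=True)
    mpath = mdir / f"{stage}.json"
    in_sums = {str(p): _md5(Path(p)) for p in inputs}
    phash = _params_hash(params)
    if not force and mpath.exists():
        try:
            old = json.loads(mpath.read_text())
            if (old.get("inputs") == in_sums and old.get("params_hash") == phash
                    and all(Path(p).exists() and _md5(Path(p)) == s
                            for p, s in old.get("outputs", {}).items())):
                log.info("stage %s: up to date, skipped", stage)
                return False
        except (json.JSONDecodeError, OSError):
            pass
    log.info("stage %s: running", stage)
    compute()
    out_sums = {str(p): _md5(Path(p)) for p in outputs if Path(p).exists()}
    mpath.write_text(json.dumps(asdict(StageManifest(stage, in_sums, phash,
                                                     out_sums)), indent=2))
    return True


# ---------------------------------------------------------------------------
# classification table serialization


def write_classification(classified: Sequence[ClassifiedPair], path) -> None:
    cols = (["pair_id", "fragment_class", "sample", "anomaly", "forward_mate",
             "reverse_mate", "internal_mate_index"]
            + [f"f_{f}" for f in _PARSE_FIELDS] + [f"r_{f}" for f in _PARSE_FIELDS])
    with open(path, "wt", newline="") as h:
        w = csv.writer(h, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for cp in classified:
            row = [cp.pair.pair_id, cp.fragment_class, cp.sample or "",
                   cp.anomaly or "", cp.forward_mate or "", cp.reverse_mate or "",
                   cp.internal_mate_index or ""]
            for parse in (cp.forward_parse, cp.reverse_parse):
                if parse is None:
                    row.extend([""] * len(_PARSE_FIELDS))
                else:
                    row.extend(getattr(parse, f) for f in _PARSE_FIELDS)
            w.writerow(row)


def read_classification(path, pairs: Optional[Dict[str, ReadPair]] = None
                        ) -> List[ClassifiedPair]:
    """Rebuild ClassifiedPair records from the TSV; if ``pairs`` (pair_id ->
    ReadPair) is given, full reads are attached, otherwise empty stubs."""
    out: List[ClassifiedPair] = []
    with open(path, "rt", newline="") as h:
        reader = csv.DictReader(h, delimiter="\t")
        for row in reader:
            pid = row["pair_id"]
            pair = pairs[pid] if pairs is not None else ReadPair(pid, "", (), "", ())

            def parse_of(prefix, label):
                if not row[f"{prefix}_tag"]:
                    return None
                return EndParse(
                    end_label=label,
                    phaser_len=int(row[f"{prefix}_phaser_len"]),
                    barcode_observed=row[f"{prefix}_barcode_observed"],
                    barcode_assigned=row[f"{prefix}_barcode_assigned"] or None,
                    barcode_mismatches=int(row[f"{prefix}_barcode_mismatches"]),
                    tag=row[f"{prefix}_tag"],
                    primer_mismatches=int(row[f"{prefix}_primer_mismatches"]),
                    gene_prefix=row[f"{prefix}_gene_prefix"],
                    insert_start=int(row[f"{prefix}_insert_start"]),
                )

            out.append(ClassifiedPair(
                pair=pair,
                fragment_class=row["fragment_class"],
                forward_parse=parse_of("f", "FORWARD"),
                reverse_parse=parse_of("r", "REVERSE"),
                forward_mate=int(row["forward_mate"]) if row["forward_mate"] else None,
                reverse_mate=int(row["reverse_mate"]) if row["reverse_mate"] else None,
                internal_mate_index=(int(row["internal_mate_index"])
                                     if row["internal_mate_index"] else None),
                sample=row["sample"] or None,
                anomaly=row["anomaly"] or None,
            ))
    return out


def write_clusters(clusters: Sequence[TagCluster], path) -> None:
    with open(path, "wt", newline="") as h:
        w = csv.writer(h, delimiter="\t", lineterminator="\n")
        w.writerow(["cluster_id", "sample", "abundance", "consensus",
                    "tag_f", "tag_r", "member_pair_ids"])
        for c in clusters:
            w.writerow([c.cluster_id, c.sample, c.abundance, c.consensus,
                        c.consensus_tag_f, c.consensus_tag_r,
                        ",".join(c.member_pair_ids)])


def read_clusters(path) -> List[TagCluster]:
    out = []
    with open(path, "rt", newline="") as h:
        for row in csv.DictReader(h, delimiter="\t"):
            out.append(TagCluster(
                cluster_id=row["cluster_id"],
                consensus=row["consensus"],
                consensus_tag_f=row["tag_f"],
                consensus_tag_r=row["tag_r"],
                sample=row["sample"],
                member_pair_ids=(row["member_pair_ids"].split(",")
                                 if row["member_pair_ids"] else []),
            ))
    return out


# ---------------------------------------------------------------------------
# stages


def stage_demux(r1, r2, sheet_path, config: RunConfig, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sheet = load_sample_sheet(sheet_path, config.forward_design)
    classified = [classify_pair(p, config, sheet)
                  for p in read_fastq_pairs(r1, r2)]
    write_classification(classified, out / "classification.tsv")
    stats = demux_stats(classified)
    (out / "demux_stats.json").write_text(json.dumps(stats, indent=2))
    return {"classification": str(out / "classification.tsv"),
            "stats": str(out / "demux_stats.json")}


def stage_cluster(classification_tsv, config: RunConfig, out_dir) -> dict:
    out = Path(out_dir)
    classified = read_classification(classification_tsv)
    signatures = [build_signature(cp) for cp in classified
                  if cp.fragment_class == END_END
                  and cp.sample not in (None, INVALID_COMBINATION)]
    clusters = greedy_cluster(signatures, threshold=config.identity_threshold)
    write_clusters(clusters, out / "clusters.tsv")
    stats = {"n_signatures": len(signatures), "n_clusters": len(clusters)}
    (out / "cluster_stats.json").write_text(json.dumps(stats, indent=2))
    return {"clusters": str(out / "clusters.tsv")}


def stage_chimera_filter(clusters_tsv, demux_stats_json, out_dir) -> dict:
    out = Path(out_dir)
    clusters = read_clusters(clusters_tsv)
    result = filter_recombinants(clusters)
    write_clusters(result.kept, out / "clusters_kept.tsv")
    with open(out / "clusters_discarded.tsv", "wt", newline="") as h:
        w = csv.writer(h, delimiter="\t", lineterminator="\n")
        w.writerow(["cluster_id", "sample", "abundance", "tag_f", "tag_r",
                    "reason", "dominator_id"])
        for d in result.discarded:
            c = d.cluster
            w.writerow([c.cluster_id, c.sample, c.abundance, c.consensus_tag_f,
                        c.consensus_tag_r, d.reason, d.dominator_id])
    dstats = json.loads(Path(demux_stats_json).read_text())
    total_ee = dstats.get("end_end", 0)
    stats: dict = {"n_kept": len(result.kept),
                   "n_discarded": len(result.discarded)}
    if total_ee > 0:
        rs = recombination_stats(result, total_ee)
        stats.update({
            "total_end_end_reads": rs.total_end_end_reads,
            "discarded_reads": rs.discarded_reads,
            "recombination_rate_pct": rs.rate,
            "discarded_cluster_fraction": rs.discarded_cluster_fraction,
            "parental_ratio": rs.parental_ratio,
            "combined_recombination_rate_pct":
                run_stats.combined_recombination_estimate(
                    dstats.get("invalid_combination", 0),
                    rs.discarded_reads, total_ee),
        })
    (out / "chimera_stats.json").write_text(json.dumps(stats, indent=2))
    return {"kept": str(out / "clusters_kept.tsv"),
            "discarded": str(out / "clusters_discarded.tsv"),
            "stats": str(out / "chimera_stats.json")}


def stage_bin(classification_tsv, kept_tsv, config: RunConfig, out_dir,
              r1=None, r2=None, write_fastq: bool = False) -> dict:
    out = Path(out_dir)
    classified = read_classification(classification_tsv)
    kept = read_clusters(kept_tsv)
    bins = binning_mod.bin_reads(classified, kept,
                                 budget=config.tag_mismatch_budget)
    with open(out / "bin_manifest.tsv", "wt", newline="") as h:
        w = csv.writer(h, delimiter="\t", lineterminator="\n")
        w.writerow(["cluster_id", "sample", "pair_id", "role"])
        for cid in sorted(bins):
            for cp, role in bins[cid].members:
                w.writerow([cid, bins[cid].sample, cp.pair.pair_id, role])
    if write_fastq:
        if r1 is None or r2 is None:
            raise ValueError("per-bin FASTQ output needs the input FASTQ paths")
        pairs = {p.pair_id: p for p in read_fastq_pairs(r1, r2)}
        from .io_model import write_fastq_pairs as _wfp
        bdir = out / "bins"
        bdir.mkdir(exist_ok=True)
        for cid in sorted(bins):
            if not bins[cid].members:
                continue
            d = bdir / cid
            d.mkdir(exist_ok=True)
            members = [pairs[cp.pair.pair_id] for cp, _ in bins[cid].members]
            _wfp(members, d / "r1.fastq", d / "r2.fastq")
    stats = {
        "n_bins": len(bins),
        "binned_end_end": sum(b.end_end_count for b in bins.values()),
        "binned_internal": sum(b.internal_count for b in bins.values()),
        "tag_collisions": len(binning_mod.TagIndex(
            kept, budget=config.tag_mismatch_budget).collisions),
    }
    (out / "binning_stats.json").write_text(json.dumps(stats, indent=2))
    return {"manifest": str(out / "bin_manifest.tsv")}


def load_bins(bin_manifest, classification_tsv, kept_tsv, r1, r2
              ) -> Dict[str, binning_mod.TemplateBin]:
    """Rebuild TemplateBins with full reads attached, from stage outputs."""
    pairs = {p.pair_id: p for p in read_fastq_pairs(r1, r2)}
    classified = {cp.pair.pair_id: cp
                  for cp in read_classification(classification_tsv, pairs)}
    kept = {c.cluster_id: c for c in read_clusters(kept_tsv)}
    bins: Dict[str, binning_mod.TemplateBin] = {}
    with open(bin_manifest, "rt", newline="") as h:
        for row in csv.DictReader(h, delimiter="\t"):
            cid = row["cluster_id"]
            if cid not in bins:
                bins[cid] = binning_mod.TemplateBin(cid, kept[cid].sample)
            bins[cid].members.append((classified[row["pair_id"]], row["role"]))
    return bins


def stage_assemble(bin_manifest, classification_tsv, kept_tsv, r1, r2,
                   config: RunConfig, out_dir) -> dict:
    out = Path(out_dir)
    bins = load_bins(bin_manifest, classification_tsv, kept_tsv, r1, r2)
    results = {}
    with open(out / "contigs.fasta", "wt") as fa, \
            open(out / "assemblies.tsv", "wt", newline="") as h:
        w = csv.writer(h, delimiter="\t", lineterminator="\n")
        w.writerow(["cluster_id", "n_contigs_before", "n_contigs_after",
                    "reconstructed_length", "mean_coverage", "full_length"])
        for cid in sorted(bins):
            res = assemble_template_bin(bins[cid], config)
            results[cid] = res
            for i, c in enumerate(res.contigs_after, 1):
                fa.write(f">{cid}.ctg{i} mean_coverage={c.mean_coverage:.2f}\n"
                         f"{c.sequence}\n")
            mean_cov = (sum(c.mean_coverage for c in res.contigs_after)
                        / len(res.contigs_after)) if res.contigs_after else 0.0
            w.writerow([cid, len(res.contigs_before), len(res.contigs_after),
                        res.reconstructed_length, f"{mean_cov:.2f}",
                        int(res.is_full_length(config.full_length_threshold))])
    lengths = [r.reconstructed_length for r in results.values()
               if r.contigs_after]
    summary = run_stats.length_summary(
        lengths, threshold=config.full_length_threshold)
    (out / "assembly_stats.json").write_text(json.dumps({
        "n_bins_assembled": sum(1 for r in results.values() if r.contigs_after),
        "length_summary": asdict(summary),
    }, indent=2))
    return {"contigs": str(out / "contigs.fasta"),
            "assemblies": str(out / "assemblies.tsv")}


def stage_consensus(bin_manifest, classification_tsv, kept_tsv, contigs_fasta,
                    r1, r2, config: RunConfig, out_dir) -> dict:
    from .assembly import Contig
    import numpy as np
    out = Path(out_dir)
    bins = load_bins(bin_manifest, classification_tsv, kept_tsv, r1, r2)
    per_bin_contigs: Dict[str, list] = {}
    from Bio import SeqIO
    for rec in SeqIO.parse(str(contigs_fasta), "fasta"):
        cid = rec.id.rsplit(".ctg", 1)[0]
        per_bin_contigs.setdefault(cid, []).append(
            Contig(str(rec.seq), np.ones(len(rec.seq))))
    consensuses = []
    for cid in sorted(per_bin_contigs):
        if cid not in bins:
            continue
        reads = oriented_bin_reads(bins[cid], config)
        consensuses.extend(consensus_for_bin(
            per_bin_contigs[cid], reads, cid, bins[cid].sample,
            anchor_k=config.anchor_k, min_identity=config.map_min_identity))
    write_fasta_with_quality(consensuses, out / "consensus.fasta",
                             out / "consensus.fastq")
    profile = quality_profile(consensuses)
    profile.to_csv(out / "quality_profile.tsv", sep="\t", index=False)
    lengths = [len(c.sequence) for c in consensuses]
    summary = run_stats.length_summary(lengths,
                                       threshold=config.full_length_threshold)
    (out / "consensus_stats.json").write_text(json.dumps({
        "n_consensus_sequences": len(consensuses),
        "length_summary": asdict(summary),
        "median_quality": (float(np.median([q for c in consensuses
                                            for q in c.quality]))
                           if consensuses else None),
    }, indent=2))
    return {"fasta": str(out / "consensus.fasta"),
            "fastq": str(out / "consensus.fastq"),
            "profile": str(out / "quality_profile.tsv")}


def stage_report(out_dir, kept_tsv=None) -> dict:
    out = Path(out_dir)
    stats: Dict[str, dict] = {}
    for stage, fname in [("demux", "demux_stats.json"),
                         ("cluster", "cluster_stats.json"),
                         ("chimera_filter", "chimera_stats.json"),
                         ("binning", "binning_stats.json"),
                         ("assembly", "assembly_stats.json"),
                         ("consensus", "consensus_stats.json")]:
        p = out / fname
        if p.exists():
            stats[stage] = json.loads(p.read_text())
    kept_path = Path(kept_tsv) if kept_tsv else out / "clusters_kept.tsv"
    if kept_path.exists():
        kept = read_clusters(kept_path)
        abundances = [c.abundance for c in kept]
        if len(abundances) >= 2:
            bias = run_stats.bias_estimate(abundances)
            entry = {"n_clusters": bias.n_clusters,
                     "mean_abundance": bias.mean_abundance,
                     "sd_abundance": bias.sd_abundance,
                     "relative_mean_error": bias.relative_mean_error}
            if sum(1 for a in abundances if a > 1) >= 2:
                bias_ns = run_stats.bias_estimate(abundances,
                                                  exclude_singletons=True)
                entry["relative_mean_error_no_singletons"] = \
                    bias_ns.relative_mean_error
            stats["bias"] = entry
            # figure-style backing table: relative cluster abundances
            with open(out / "bias_distribution.tsv", "wt") as h:
                h.write("cluster_id\tabundance\trelative_abundance\n")
                mean = bias.mean_abundance
                for c in kept:
                    h.write(f"{c.cluster_id}\t{c.abundance}\t"
                            f"{c.abundance / mean:.4f}\n")
    return run_stats.write_report(stats, out / "report.json")


# ---------------------------------------------------------------------------
# run-all


def run_all(config: RunConfig, out_dir, r1=None, r2=None, sheet_path=None,
            sim_config: Optional[SimConfig] = None, force: bool = False,
            stop_after: Optional[str] = None, write_bin_fastq: bool = False
            ) -> dict:
    """Execute the full pipeline; any stage failure propagates with the
    stage name.  Returns the final report dict (or partial stats)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_path = out / "run_config.yaml"
    config.to_yaml(cfg_path)

    if sim_config is not None:
        sim_dir = out / "sim"

        def _sim():
            write_sim_run(simulate_run(sim_config), sim_dir)

        run_stage(out, "simulate", [], asdict(sim_config),
                  [sim_dir / "reads_R1.fastq", sim_dir / "reads_R2.fastq",
                   sim_dir / "sample_sheet.tsv"], _sim, force)
        r1, r2 = sim_dir / "reads_R1.fastq", sim_dir / "reads_R2.fastq"
        sheet_path = sim_dir / "sample_sheet.tsv"
    if r1 is None or r2 is None or sheet_path is None:
        raise ValueError("need input FASTQ pair and sample sheet "
                         "(or a simulation config)")

    params = config.to_dict()
    stages = []

    def add(name, inputs, outputs, fn):
        stages.append((name, inputs, outputs, fn))

    cls_tsv = out / "classification.tsv"
    add("demux", [r1, r2, sheet_path],
        [cls_tsv, out / "demux_stats.json"],
        lambda: stage_demux(r1, r2, sheet_path, config, out))
    add("cluster", [cls_tsv], [out / "clusters.tsv"],
        lambda: stage_cluster(cls_tsv, config, out))
    add("chimera_filter", [out / "clusters.tsv", out / "demux_stats.json"],
        [out / "clusters_kept.tsv", out / "clusters_discarded.tsv",
         out / "chimera_stats.json"],
        lambda: stage_chimera_filter(out / "clusters.tsv",
                                     out / "demux_stats.json", out))
    add("bin", [cls_tsv, out / "clusters_kept.tsv"],
        [out / "bin_manifest.tsv"],
        lambda: stage_bin(cls_tsv, out / "clusters_kept.tsv", config, out,
                          r1=r1, r2=r2, write_fastq=write_bin_fastq))
    add("assemble", [out / "bin_manifest.tsv", cls_tsv,
                     out / "clusters_kept.tsv"],
        [out / "contigs.fasta", out / "assemblies.tsv"],
        lambda: stage_assemble(out / "bin_manifest.tsv", cls_tsv,
                               out / "clusters_kept.tsv", r1, r2, config, out))
    add("consensus", [out / "bin_manifest.tsv", out / "contigs.fasta"],
        [out / "consensus.fasta", out / "consensus.fastq",
         out / "quality_profile.tsv"],
        lambda: stage_consensus(out / "bin_manifest.tsv", cls_tsv,
                                out / "clusters_kept.tsv",
                                out / "contigs.fasta", r1, r2, config, out))

    for name, inputs, outputs, fn in stages:
        try:
            run_stage(out, name, inputs, params, outputs, fn, force)
        except Exception as exc:
            raise RuntimeError(f"stage {name} failed: {exc}") from exc
        if stop_after == name:
            return stage_report(out)
    return stage_report(out)
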