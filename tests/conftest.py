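"""Shared fixtures: small synthetic runs and an in-memory pipeline driver."""

from __future__ import annotations

import pytest

from longamp.binning import bin_reads
from longamp.chimera_filter import filter_recombinants, recombination_stats
from longamp.demux import (END_END, INVALID_COMBINATION, classify_pair,
                           demux_stats)
from longamp.simulator import SimConfig, simulate_run
from longamp.tag_cluster import build_signature, greedy_cluster


def run_pipeline_memory(sim_cfg: SimConfig) -> dict:
    """Simulate and run demux -> cluster -> chimera-filter -> bin in memory;
    returns every intermediate for truth-based assertions."""
    run = simulate_run(sim_cfg)
    classified = [classify_pair(p, run.run_config, run.sample_sheet)
                  for p in run.read_pairs]
    stats = demux_stats(classified)
    signatures = [build_signature(cp) for cp in classified
                  if cp.fragment_class == END_END
                  and cp.sample not in (None, INVALID_COMBINATION)]
    clusters = greedy_cluster(signatures,
                              threshold=run.run_config.identity_threshold)
    filt = filter_recombinants(clusters)
    bins = bin_reads(classified, filt.kept,
                     budget=run.run_config.tag_mismatch_budget)
    rec = (recombination_stats(filt, stats["end_end"])
           if stats["end_end"] else None)
    return {"run": run, "classified": classified, "stats": stats,
            "signatures": signatures, "clusters": clusters, "filter": filt,
            "kept": filt.kept, "bins": bins, "recombination": rec}


@pytest.fixture(scope="session")
def clean_small_run():
    """20 error-free, bias-free, chimera-free templates with full coverage:
    the lossless path every stage must handle perfectly."""
    cfg = SimConfig(n_templates=20, n_samples=4, seed=3, sigma=0.0,
                    chimera_rate=0.0, error_rate=0.0, depth=20,
                    unique_tags=True)
    return run_pipeline_memory(cfg)


@pytest.fixture(scope="session")
def noisy_run():
    """Study-like conditions at reduced scale: sequencing error, PCR bias
    and 10% template switching."""
    cfg = SimConfig(n_templates=120, seed=7, tagmented_ratio=2.0,
                    unique_tags=True)
    return run_pipeline_memory(cfg)
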