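"""Run-level summaries: length distribution, full-length counts, PCR
amplification-bias estimation from cluster abundances, and report writing.

Under dual molecular tagging every tagged template starts as a single copy,
so with unbiased amplification every end+end cluster would have the same
abundance.  The spread of observed abundances therefore measures PCR bias;
it is summarised as the *relative mean error* — the coefficient of
variation, sample SD over mean — of cluster abundances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np


@dataclass
class LengthSummary:
    count: int
    minimum: Optional[int]
    maximum: Optional[int]
    histogram: dict          # bin lower edge -> count
    n_above_threshold: int   # strictly greater than threshold
    pct_above_threshold: float
    threshold: int


def length_summary(lengths: Sequence[int], threshold: int = 1300,
                   bin_width: int = 100) -> LengthSummary:
    """Sequence-length distribution with the strictly-greater-than-threshold
    full-length count (percentage rounded to 1 decimal)."""
    lengths = list(lengths)
    if not lengths:
        return LengthSummary(0, None, None, {}, 0, 0.0, threshold)
    arr = np.asarray(lengths)
    edges = np.arange((arr.min() // bin_width) * bin_width,
                      arr.max() + bin_width, bin_width)
    hist, _ = np.histogram(arr, bins=np.append(edges, edges[-1] + bin_width))
    n_above = int((arr > threshold).sum())
    return LengthSummary(
        count=len(lengths),
        minimum=int(arr.min()),
        maximum=int(arr.max()),
        histogram={int(e): int(h) for e, h in zip(edges, hist)},
        n_above_threshold=n_above,
        pct_above_threshold=round(100.0 * n_above / len(lengths), 1),
        threshold=threshold,
    )


@dataclass
class BiasEstimate:
    n_clusters: int
    mean_abundance: float
    sd_abundance: float
    relative_mean_error: float       # CV = sd / mean
    relative_abundances: np.ndarray  # abundance / mean, per cluster
    singletons_excluded: bool


def bias_estimate(abundances: Sequence[int], exclude_singletons: bool = False,
                  ddof: int = 1) -> BiasEstimate:
    """Coefficient of variation of end+end cluster abundances (sample SD by
    default; ``ddof=0`` for the population SD)."""
    arr = np.asarray([a for a in abundances
                      if not (exclude_singletons and a <= 1)], dtype=float)
    if arr.size < 2:
        raise ValueError("bias estimation needs at least 2 clusters after exclusion")
    mean = float(arr.mean())
    sd = float(arr.std(ddof=ddof))
    return BiasEstimate(
        n_clusters=int(arr.size),
        mean_abundance=mean,
        sd_abundance=sd,
        relative_mean_error=sd / mean,
        relative_abundances=arr / mean,
        singletons_excluded=exclude_singletons,
    )


def combined_recombination_estimate(invalid_end_end_reads: int,
                                    discarded_reads: int,
                                    total_end_end_reads: int) -> float:
    """Overall percentage of end+end reads attributed to in-vitro
    recombination, combining both detection signals: barcode combinations
    never assigned to a sample (cross-sample recombinants, caught at demux)
    and clusters discarded by the dual-tag abundance rule (within-sample
    recombinants)."""
    if total_end_end_reads <= 0:
        raise ValueError("total_end_end_reads must be positive")
    return 100.0 * (invalid_end_end_reads + discarded_reads) / total_end_end_reads


def write_report(stats: Dict[str, dict], path) -> dict:
    """Assemble the per-stage statistics blocks into one JSON report.

    ``stats`` maps stage name (demux, cluster, chimera_filter, binning,
    assembly, consensus, bias) to its summary dict; stages not yet run are
    recorded as absent so a partial run still yields a valid report.
    """
    expected = ["demux", "cluster", "chimera_filter", "binning",
                "assembly", "consensus", "bias"]
    report = {"stages_present": [s for s in expected if s in stats],
              "stages_absent": [s for s in expected if s not in stats]}
    for name in expected:
        if name in stats:
            report[name] = stats[name]
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True,
                                     default=_json_default))
    return report


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
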