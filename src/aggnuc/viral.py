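"""Viral-sequence screening by coverage, contiguity and read-count thresholds.

Non-host reads aligned to a viral genome are summarized by three metrics —
mean coverage depth over covered positions, longest contiguous covered run,
and read count — and screened at two stages: a loose *retrieval* stage
(depth >= 5x, run >= 75 nt, reads >= 50) used to form group read ratios,
and a strict *positive identification* stage (depth >= 5x, run >= 100 nt,
reads >= 400).  All comparisons are inclusive (>=).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import Config, GenomicInterval


@dataclass
class ViralSummary:
    virus_id: str
    reads: int
    mean_depth: float
    longest_run: int
    group_label: str = ""
    molecule: str = ""

    def __post_init__(self) -> None:
        if self.reads < 0 or self.mean_depth < 0 or self.longest_run < 0:
            raise ValueError("viral summary metrics must be >= 0")


@dataclass
class ViralVerdict:
    summary: ViralSummary
    pass_depth: bool
    pass_run: bool
    pass_reads: bool
    stage: str

    @property
    def positive(self) -> bool:
        return self.pass_depth and self.pass_run and self.pass_reads


def summarize_coverage(
    intervals: Sequence[GenomicInterval], genome_length: int, virus_id: str = "",
    group_label: str = "", molecule: str = "",
) -> ViralSummary:
    """Coverage summary of read intervals on one viral genome.

    mean_depth averages depth over covered positions only; longest_run is
    the longest stretch of consecutive positions with depth >= 1.  An empty
    read set gives (0, 0, 0).
    """
    if not intervals:
        return ViralSummary(virus_id, 0, 0.0, 0, group_label, molecule)
    diff = np.zeros(genome_length + 2, dtype=np.int64)
    for iv in intervals:
        if iv.start < 1 or iv.end > genome_length:
            raise ValueError(f"read {iv} outside [1, {genome_length}]")
        diff[iv.start] += 1
        diff[iv.end + 1] -= 1
    cov = np.cumsum(diff)[1 : genome_length + 1]
    covered = cov > 0
    n_covered = int(covered.sum())
    mean_depth = float(cov[covered].sum() / n_covered) if n_covered else 0.0
    if n_covered:
        edges = np.flatnonzero(np.diff(np.concatenate(([False], covered, [False]))))
        longest = int((edges[1::2] - edges[::2]).max())
    else:
        longest = 0
    return ViralSummary(
        virus_id, len(intervals), mean_depth, longest, group_label, molecule
    )


def apply_thresholds(
    summary: ViralSummary, stage: str = "positive_id", config: Config | None = None
) -> ViralVerdict:
    """Screen one viral summary at the named stage's thresholds."""
    config = config or Config()
    if stage == "retrieval":
        min_depth, min_run, min_reads = config.viral_retrieval
    elif stage == "positive_id":
        min_depth, min_run, min_reads = config.viral_positive_id
    else:
        raise ValueError(f"unknown stage {stage!r}")
    return ViralVerdict(
        summary=summary,
        pass_depth=summary.mean_depth >= min_depth,
        pass_run=summary.longest_run >= min_run,
        pass_reads=summary.reads >= min_reads,
        stage=stage,
    )


def viral_fraction(viral_reads: int, total_reads: int, decimals: int = 2) -> float:
    """Viral reads as a percentage of the raw library, e.g.
    124803/132252624 -> 0.09 (%)."""
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if viral_reads > total_reads:
        raise ValueError("viral_reads cannot exceed total_reads")
    return round(100.0 * viral_reads / total_reads, decimals)


def _safe_ratio(num: float, den: float) -> Optional[float]:
    if den == 0:
        return None
    return round(num / den, 2)


def ratio_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-virus ratio columns from a counts table.

    Input columns: virus_id, amc_rna, ad_rna, amc_dna, ad_dna.  Output adds
    RNA/DNA ratios per group and AD/AMC ratios per molecule, each rounded
    to 2 decimals; a zero denominator yields a missing (flagged) cell.
    """
    out = table.copy()
    out["amc_rna_dna"] = [
        _safe_ratio(r, d) for r, d in zip(table["amc_rna"], table["amc_dna"])
    ]
    out["ad_rna_dna"] = [
        _safe_ratio(r, d) for r, d in zip(table["ad_rna"], table["ad_dna"])
    ]
    out["rna_ad_amc"] = [
        _safe_ratio(a, c) for a, c in zip(table["ad_rna"], table["amc_rna"])
    ]
    out["dna_ad_amc"] = [
        _safe_ratio(a, c) for a, c in zip(table["ad_dna"], table["amc_dna"])
    ]
    return out


def count_positive_viruses(table: pd.DataFrame, min_reads: int = 400) -> int:
    """Viruses whose read count meets the positive-ID threshold in at least
    one group/molecule sample.

    Table-level census over the count columns (amc_rna, ad_rna, amc_dna,
    ad_dna); the per-sample depth/contiguity screens are applied upstream
    by ``apply_thresholds`` where coverage detail is available.
    """
    cols = ["amc_rna", "ad_rna", "amc_dna", "ad_dna"]
    counts = table[cols].to_numpy()
    return int((counts >= min_reads).any(axis=1).sum())
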