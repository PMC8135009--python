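"""Fragment pile-up peak calling against a uniform genomic null.

The null model: if N library reads of width w each landed uniformly on a
genome of G bp, the number overlapping any fixed w-bp window would be
Binomial(N, w/G).  A candidate window containing k reads is scored with the
upper tail P(X >= k); the E-value multiplies that tail by the number of
candidate windows tested genome-wide.

Candidate windows are read-defined, not tiled.  In the sparse regime
(mean coverage < ~0.5x) they are maximal clusters of overlapping reads,
which matches the variable, read-defined widths of observed fragment
contigs.  In dense regimes cluster merging degenerates (the whole genome
fuses into one cluster), so candidate windows become maximal runs of
coverage above a Poisson upper quantile of the genome-wide mean coverage.

Analytic cluster p-values are *scores*, not calibrated tail probabilities:
under the null every singleton cluster has the same deterministic p, so the
distribution over windows is far from uniform.  ``calibrate_null`` builds
an empirical null score distribution by simulating the same read regime,
and ``empirical_pvalues`` converts scores to rank-based p-values that are
uniform under the null by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .model import Config, GeneRecord, GenomicInterval, ReadSet


@dataclass
class PeakCall:
    """A scored fragment pile-up window."""

    interval: GenomicInterval
    reads_per_group: dict[str, int]
    pvalue_per_group: dict[str, Optional[float]]
    evalue_per_group: dict[str, Optional[float]] = field(default_factory=dict)
    empirical_p_per_group: dict[str, Optional[float]] = field(default_factory=dict)


@dataclass
class PeakAnnotation:
    """Nearest-gene annotation of one peak.

    Distances are gap sizes in bp; 0 means the gene overlaps (or abuts)
    the peak.  ``gene_mapped`` is true iff either distance is 0.
    """

    peak: PeakCall
    gene_5p: Optional[GeneRecord]
    dist_5p: Optional[int]
    gene_3p: Optional[GeneRecord]
    dist_3p: Optional[int]

    @property
    def gene_mapped(self) -> bool:
        return self.dist_5p == 0 or self.dist_3p == 0


def peak_pvalue(k: int, N: int, w: int, G: int, method: str = "exact") -> float:
    """Upper-tail probability that >= k of N uniform reads hit a w-bp window.

    P(X >= k) with X ~ Binomial(N, w/G), evaluated exactly by default;
    method="poisson" uses the Poisson(N*w/G) approximation.  Monotone
    non-increasing in k; k = 0 gives exactly 1.
    """
    if not (0 <= k <= N):
        raise ValueError(f"require 0 <= k <= N, got k={k}, N={N}")
    if not (0 < w <= G):
        raise ValueError(f"require 0 < w <= G, got w={w}, G={G}")
    if k == 0:
        return 1.0
    if method == "exact":
        return float(stats.binom.sf(k - 1, N, w / G))
    if method == "poisson":
        return float(stats.poisson.sf(k - 1, N * w / G))
    raise ValueError(f"unknown method {method!r}")


def _merge_clusters(
    starts: np.ndarray, ends: np.ndarray
) -> list[tuple[int, int, int]]:
    """Merge overlapping/abutting 1-based closed intervals.

    Returns (start, end, n_reads) per maximal cluster, in coordinate order.
    """
    order = np.argsort(starts, kind="stable")
    starts, ends = starts[order], ends[order]
    out: list[tuple[int, int, int]] = []
    cs, ce, n = int(starts[0]), int(ends[0]), 1
    for s, e in zip(starts[1:], ends[1:]):
        if s <= ce + 1:  # overlap or zero-gap abutment
            ce = max(ce, int(e))
            n += 1
        else:
            out.append((cs, ce, n))
            cs, ce, n = int(s), int(e), 1
    out.append((cs, ce, n))
    return out


def _coverage_windows(
    starts: np.ndarray, ends: np.ndarray, genome_length: int, threshold: int
) -> list[tuple[int, int, int]]:
    """Maximal runs of positions with coverage > threshold, with read counts."""
    diff = np.zeros(genome_length + 2, dtype=np.int32)
    np.add.at(diff, starts, 1)
    np.add.at(diff, ends + 1, -1)
    cov = np.cumsum(diff)[1 : genome_length + 1]
    above = cov > threshold
    if not above.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([False], above, [False]))))
    run_starts, run_ends = edges[::2] + 1, edges[1::2]  # 1-based closed
    out = []
    for rs, re_ in zip(run_starts, run_ends):
        k = int(np.count_nonzero((starts <= re_) & (ends >= rs)))
        out.append((int(rs), int(re_), k))
    return out


def candidate_windows(
    reads: ReadSet, genome_length: int, dense_quantile: float = 0.99
) -> dict[str, list[tuple[int, int, int]]]:
    """Read-defined candidate windows per chromosome.

    Sparse regime (mean coverage < 0.5x): maximal clusters of overlapping
    reads.  Dense regime: maximal runs of coverage above the
    ``dense_quantile`` Poisson quantile of the genome-wide mean coverage.
    """
    by_chrom: dict[str, list[GenomicInterval]] = {}
    total_bases = 0
    for iv in reads.intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
        total_bases += iv.length
    mean_cov = total_bases / genome_length
    threshold = 0
    if mean_cov >= 0.5:
        threshold = int(stats.poisson.ppf(dense_quantile, mean_cov))
    out: dict[str, list[tuple[int, int, int]]] = {}
    for chrom, ivs in by_chrom.items():
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        if threshold == 0:
            out[chrom] = _merge_clusters(starts, ends)
        else:
            out[chrom] = _coverage_windows(starts, ends, genome_length, threshold)
    return out


def call_peaks(
    reads: ReadSet,
    genome_length: int,
    config: Config | None = None,
    null_scores: Optional[np.ndarray] = None,
    keep_all: bool = False,
) -> list[PeakCall]:
    """Call pile-up peaks in one ReadSet against the uniform null.

    Windows are scored with ``peak_pvalue`` (k reads, window width, library
    size, genome size); E-value = p x number of candidate windows.  Windows
    passing the configured threshold (default: p < alpha_peak) are retained
    and returned sorted by (chrom, start).  ``keep_all`` returns every
    candidate window regardless of significance (used for calibration
    studies).  When ``null_scores`` (from ``calibrate_null``) is given, each
    window also gets an empirical rank-based p-value.
    """
    if genome_length <= 0:
        raise ValueError("genome must be non-empty")
    config = config or Config()
    if not reads.intervals:
        return []
    group = reads.group_label
    windows = candidate_windows(reads, genome_length)
    n_windows = sum(len(v) for v in windows.values())
    calls: list[PeakCall] = []
    for chrom in sorted(windows):
        for start, end, k in windows[chrom]:
            w = end - start + 1
            p = peak_pvalue(k, reads.library_size, min(w, genome_length), genome_length)
            e = p * n_windows
            keep = (p if config.peak_threshold_on == "p" else e) < (
                config.alpha_peak if config.peak_threshold_on == "p"
                else config.alpha_peak * n_windows
            )
            if keep_all or keep:
                call = PeakCall(
                    interval=GenomicInterval(chrom, start, end),
                    reads_per_group={group: k},
                    pvalue_per_group={group: p},
                    evalue_per_group={group: e},
                )
                if null_scores is not None:
                    call.empirical_p_per_group = {
                        group: empirical_pvalues(np.array([p]), null_scores)[0]
                    }
                calls.append(call)
    calls.sort(key=lambda c: (c.interval.chrom, c.interval.start))
    return calls


def calibrate_null(
    n_reads: int,
    genome_length: int,
    width_mean: float,
    width_sd: float,
    n_sims: int = 10,
    seed: int = 0,
    min_width: int = 50,
) -> np.ndarray:
    """Null distribution of analytic window scores under uniform placement.

    Simulates ``n_sims`` uniform read sets matching the observed regime
    (read count, genome size, width distribution truncated at
    ``min_width``), forms candidate windows, and returns the sorted array
    of their analytic p-value scores.
    """
    rng = np.random.default_rng(seed)
    scores: list[float] = []
    for _ in range(n_sims):
        widths = np.maximum(
            np.rint(rng.normal(width_mean, width_sd, n_reads)).astype(int), min_width
        )
        starts = rng.integers(1, genome_length + 1, n_reads)
        ends = np.minimum(starts + widths - 1, genome_length)
        for s, e, k in _merge_clusters(starts, ends):
            scores.append(peak_pvalue(k, n_reads, min(e - s + 1, genome_length), genome_length))
    return np.sort(np.asarray(scores))


def empirical_pvalues(scores: np.ndarray, null_scores: np.ndarray) -> np.ndarray:
    """Rank-based p-values: fraction of null scores <= each observed score.

    Smaller score = more extreme.  Uses the (r+1)/(n+1) convention so the
    result is never exactly 0.
    """
    ranks = np.searchsorted(null_scores, scores, side="right")
    return (ranks + 1) / (len(null_scores) + 1)


def count_significant_peaks(
    pvalues_by_group: dict[str, Sequence[Optional[float]]],
    group: str,
    alpha: float,
) -> int:
    """Number of peaks with group p-value strictly below alpha.

    Missing p-values (None/NaN — an explicit "no peak" marker) never count.
    """
    if group not in pvalues_by_group:
        raise KeyError(f"unknown group label {group!r}")
    n = 0
    for p in pvalues_by_group[group]:
        if p is None or (isinstance(p, float) and math.isnan(p)):
            continue
        if p < alpha:
            n += 1
    return n


def annotate_nearest_genes(
    peak: PeakCall, genes: Sequence[GeneRecord]
) -> PeakAnnotation:
    """Attach the nearest gene on each side of a peak.

    The 5' gene is the nearest whose interval lies upstream of (at or
    before) the peak start; the 3' gene the nearest downstream of the peak
    end.  A gene overlapping the peak is reported with distance 0 on the
    side of the gene's midpoint.  A side with no gene on the chromosome is
    None with distance None (rendered blank in tables).
    """
    iv = peak.interval
    peak_mid = (iv.start + iv.end) / 2
    best5: tuple[int, GeneRecord] | None = None
    best3: tuple[int, GeneRecord] | None = None
    for g in genes:
        if g.interval.chrom != iv.chrom:
            continue
        d = g.interval.distance_to(iv)
        if d == 0:
            gene_mid = (g.interval.start + g.interval.end) / 2
            side5 = gene_mid <= peak_mid
            if side5:
                if best5 is None or d < best5[0]:
                    best5 = (0, g)
            else:
                if best3 is None or d < best3[0]:
                    best3 = (0, g)
        elif g.interval.end < iv.start:
            if best5 is None or d < best5[0]:
                best5 = (d, g)
        elif g.interval.start > iv.end:
            if best3 is None or d < best3[0]:
                best3 = (d, g)
    return PeakAnnotation(
        peak=peak,
        gene_5p=best5[1] if best5 else None,
        dist_5p=best5[0] if best5 else None,
        gene_3p=best3[1] if best3 else None,
        dist_3p=best3[0] if best3 else None,
    )


def count_gene_mapped(annotations: Sequence[PeakAnnotation]) -> int:
    """Number of peaks coinciding with a gene (zero distance on a side)."""
    return sum(1 for a in annotations if a.gene_mapped)


def count_gene_mapped_distances(
    dist_5p: Sequence[Optional[float]], dist_3p: Sequence[Optional[float]]
) -> int:
    """Same census computed from tabulated distance columns (NaN = blank)."""

    def _is_zero(d) -> bool:
        return d is not None and not (isinstance(d, float) and math.isnan(d)) and d == 0

    return sum(1 for a, b in zip(dist_5p, dist_3p) if _is_zero(a) or _is_zero(b))


def summarize_peak_lengths(lengths: Sequence[int]) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator) of peak lengths."""
    if len(lengths) < 2:
        raise ValueError("need at least 2 peaks to summarize lengths")
    arr = np.asarray(lengths, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1))
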