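"""Shared domain types and coordinate conventions.

All genomic coordinates are 1-based, fully closed intervals: an interval
``(start, end)`` covers ``end - start + 1`` bases.  BED input/output converts
to and from the 0-based half-open convention at the boundary; everything
internal stays 1-based closed.  Chromosome names are opaque strings — no
"chr"-prefix normalization is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based closed genomic interval.

    ``length = end - start + 1`` so that e.g. 633735..634300 has length 566.
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(
                f"end ({self.end}) < start ({self.start}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def distance_to(self, other: "GenomicInterval") -> Optional[int]:
        """Gap size in bp between two intervals on the same chromosome.

        0 when the intervals overlap or abut with no base between them;
        None when they are on different chromosomes.  A gene at 100-200 and
        a peak at 300-400 are separated by the 99-bp gap 201..299.
        """
        if self.chrom != other.chrom:
            return None
        if self.start <= other.end and other.start <= self.end:
            return 0
        if other.start > self.end:
            return other.start - self.end - 1
        return self.start - other.end - 1

    @classmethod
    def from_bed(cls, chrom: str, start0: int, end0: int) -> "GenomicInterval":
        """Convert a BED (0-based half-open) record to internal coordinates."""
        return cls(chrom, start0 + 1, end0)

    def to_bed(self) -> tuple[str, int, int]:
        return (self.chrom, self.start - 1, self.end)


@dataclass(frozen=True)
class GeneRecord:
    """A gene-level annotation feature."""

    gene_id: str
    interval: GenomicInterval
    strand: str = "unknown"
    biotype: str = ""

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be nonempty")
        if self.strand not in ("+", "-", "unknown"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class ReadSet:
    """A set of aligned fragment intervals for one group/molecule.

    ``library_size`` is the total raw read count of the source library, which
    may exceed the number of mapped intervals (it is the denominator used for
    library-fraction computations, e.g. 124,803 viral reads out of a
    132,252,624-read library).
    """

    group_label: str
    molecule: str
    intervals: list[GenomicInterval]
    library_size: int

    def __post_init__(self) -> None:
        if not self.group_label:
            raise ValueError("group_label must be nonempty")
        if self.molecule not in ("RNA", "DNA"):
            raise ValueError(f"molecule must be RNA or DNA, got {self.molecule!r}")
        if self.library_size < len(self.intervals):
            raise ValueError(
                f"library_size ({self.library_size}) < number of intervals "
                f"({len(self.intervals)})"
            )


@dataclass
class Config:
    """Pipeline thresholds and reporting options.

    alpha_peak
        Peak-retention significance threshold on the uniform-null p-value
        (default 1e-5, strict ``<``).
    alpha_diff
        Differential-abundance threshold (default 0.001, inclusive ``<=`` so
        that a table entry printed as "0.001" qualifies).
    viral_retrieval / viral_positive_id
        (min coverage depth, min contiguous covered run in nt, min read
        count), all inclusive ``>=``.  Retrieval stage defaults are the loose
        screen (5x / 75 nt / 50 reads); positive identification is the strict
        screen (5x / 100 nt / 400 reads).
    g4 parameters
        QGRS-style motif search window and the G4Hunter window/threshold.
    """

    alpha_peak: float = 1e-5
    alpha_diff: float = 1e-3
    peak_threshold_on: str = "p"  # "p" or "evalue"
    viral_retrieval: tuple[float, int, int] = (5.0, 75, 50)
    viral_positive_id: tuple[float, int, int] = (5.0, 100, 400)
    g4_max_length: int = 30
    g4_min_g_group: int = 2
    g4_loop_min: int = 0
    g4_loop_max: int = 36
    g4hunter_window: int = 25
    g4hunter_threshold: float = 1.3
    g4_n_shuffles: int = 100
    g4_pseudocount: float = 0.5
    min_spectral_hits: int = 10
    min_replicates: int = 2
    float_precision: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_peak", "alpha_diff"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0,1), got {v}")
        if self.peak_threshold_on not in ("p", "evalue"):
            raise ValueError("peak_threshold_on must be 'p' or 'evalue'")
        if self.seed < 0 or int(self.seed) != self.seed:
            raise ValueError("seed must be a nonnegative integer")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "Config":
        with open(path) as fh:
            data = json.load(fh)
        for key in ("viral_retrieval", "viral_positive_id"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)
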