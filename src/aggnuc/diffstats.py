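"""Two-group differential abundance statistics on fragment read counts.

Comparisons of two read counts use the Yates continuity-corrected
chi-square on the 2x2 table completed with the remainder of each library,
falling back to the two-tailed Fisher exact test whenever any expected
cell is below 5.  Significance in printed-table mode treats the table's
p column as a ceiling: an entry of "0.001" qualifies at alpha = 0.001
(comparison is <=), and "NS" never qualifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats


@dataclass
class CountRecord:
    """Per-locus two-group read counts.

    ``printed_p`` optionally carries a p-value ceiling from an input table;
    the string "NS" (not significant) is a valid marker.
    """

    locus_id: str
    count_a: int
    count_b: int
    library_a: Optional[int] = None
    library_b: Optional[int] = None
    printed_p: Optional[Union[float, str]] = None

    def __post_init__(self) -> None:
        if self.count_a < 0 or self.count_b < 0:
            raise ValueError(f"{self.locus_id}: negative count")
        for c, lib in ((self.count_a, self.library_a), (self.count_b, self.library_b)):
            if lib is not None and c > lib:
                raise ValueError(f"{self.locus_id}: count exceeds library size")


@dataclass
class DiffResult:
    locus_id: str
    ratio: Optional[float]
    statistic: Optional[float]
    p: Optional[float]
    test_used: str
    direction: str  # "A-enriched", "B-enriched", "none"
    significant: bool


def abundance_ratio(count_a: int, count_b: int) -> Optional[float]:
    """count_a / count_b at full precision; None when count_b is 0.

    Tables report this rounded to two decimals (22800/4958 prints as 4.60).
    """
    if count_b == 0:
        return None
    return count_a / count_b


def yates_chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Continuity-corrected chi-square for a 2x2 table, 1 df.

    Raises on a zero margin (the test is undefined there; use
    ``fisher_exact_2tail`` instead).
    """
    table = np.array([[a, b], [c, d]])
    if (table < 0).any():
        raise ValueError("cell counts must be >= 0")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin: chi-square undefined, use the Fisher exact test")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
    return float(chi2), float(p)


def fisher_exact_2tail(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p: sum of hypergeometric probabilities of
    all tables with the same margins no more probable than the observed."""
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


def welch_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Two-tailed heteroscedastic (Welch/Behrens-Fisher) t test.

    Returns (t, Welch-Satterthwaite df, two-tailed p).  Two zero-variance
    samples with equal means give t = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each sample needs n >= 2")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return 0.0, float(len(x) + len(y) - 2), 1.0
        return math.inf, float(len(x) + len(y) - 2), 0.0
    res = stats.ttest_ind(x, y, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _expected_cells(a: int, b: int, c: int, d: int) -> np.ndarray:
    t = np.array([[a, b], [c, d]], dtype=float)
    n = t.sum()
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / n


def compare_counts(
    count_a: int,
    count_b: int,
    library_a: int,
    library_b: int,
) -> tuple[float, Optional[float], str]:
    """Test one locus's counts against the rest of each library.

    2x2 table: (count_a, count_b) over (library_a - count_a,
    library_b - count_b).  Yates chi-square when all expected cells are
    >= 5, otherwise the two-tailed Fisher exact test.
    Returns (p, statistic or None, test name).
    """
    a, b = count_a, count_b
    c, d = library_a - count_a, library_b - count_b
    if c < 0 or d < 0:
        raise ValueError("counts exceed library sizes")
    try:
        expected = _expected_cells(a, b, c, d)
        use_fisher = (expected < 5).any()
    except ZeroDivisionError:
        use_fisher = True
    if not use_fisher:
        try:
            chi2, p = yates_chi2_2x2(a, b, c, d)
            return p, chi2, "yates_chi2"
        except ValueError:
            pass
    return fisher_exact_2tail(a, b, c, d), None, "fisher_exact"


def _printed_significant(printed_p, alpha: float, locus_id: str) -> bool:
    if printed_p is None or (
        isinstance(printed_p, float) and math.isnan(printed_p)
    ):
        raise ValueError(f"missing printed p-value for locus {locus_id}")
    if isinstance(printed_p, str):
        token = printed_p.strip().upper().replace(" ", "").replace(".", "")
        if token in ("NS", "N S"):
            return False
        printed_p = float(printed_p)
    return printed_p <= alpha


def classify_differentials(
    records: Sequence[CountRecord],
    alpha: float = 1e-3,
    mode: str = "printed_p",
) -> tuple[int, int, int, list[DiffResult]]:
    """Classify loci as A-enriched / B-enriched / not significant.

    ``printed_p`` mode applies the alpha ceiling to the table's p column
    (every record must carry one, "NS" counts as not significant);
    ``computed_p`` mode computes a fresh p per locus from the counts and
    library sizes via ``compare_counts``.  Direction follows the observed
    ratio.  Returns (n_significant, n_a_enriched, n_b_enriched, results).
    """
    if mode not in ("printed_p", "computed_p"):
        raise ValueError(f"unknown mode {mode!r}")
    results: list[DiffResult] = []
    for rec in records:
        ratio = abundance_ratio(rec.count_a, rec.count_b)
        if mode == "printed_p":
            significant = _printed_significant(rec.printed_p, alpha, rec.locus_id)
            p = None if isinstance(rec.printed_p, str) else rec.printed_p
            stat, test = None, "printed"
        else:
            if rec.library_a is None or rec.library_b is None:
                raise ValueError(f"{rec.locus_id}: library sizes required")
            p, stat, test = compare_counts(
                rec.count_a, rec.count_b, rec.library_a, rec.library_b
            )
            significant = p <= alpha
        if not significant or ratio is None or ratio == 1:
            direction = "none"
        elif ratio > 1:
            direction = "A-enriched"
        else:
            direction = "B-enriched"
        results.append(
            DiffResult(
                locus_id=rec.locus_id,
                ratio=ratio,
                statistic=stat,
                p=p,
                test_used=test,
                direction=direction,
                significant=significant,
            )
        )
    n_sig = sum(r.significant for r in results)
    n_a = sum(r.direction == "A-enriched" for r in results)
    n_b = sum(r.direction == "B-enriched" for r in results)
    return n_sig, n_a, n_b, results
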