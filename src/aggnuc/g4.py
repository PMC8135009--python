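"""G-quadruplex motif detection and scoring.

Two complementary detectors:

* A QGRS-style motif search: four equal-length G-runs (G-groups) of at
  least ``min_g_group`` guanines, separated by three loops whose lengths
  lie in [loop_min, loop_max], with total motif length <= max_length.
  Candidates are scored and a maximal non-overlapping set is kept
  (greedy, highest score first).  The G-score rewards longer G-groups,
  shorter total loops and loop-length equality:

      gscore = 20*g - (l1 + l2 + l3) - (max(l) - min(l))

* A G4Hunter-style windowed score: each base in a G-run of length r scores
  +min(r, 4), in a C-run -min(r, 4), else 0; window score is the mean of
  base scores, and |score| >= threshold (default 1.3) flags quadruplex
  propensity on either strand.

Enrichment over random expectation uses seeded mononucleotide shuffles
preserving base composition, with a 0.5 pseudocount and the strict
fold > 100 ("G4-rich") / fold < 20 ("G4-poor") partition.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_VALID = set("ACGTN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _validate(seq: str) -> str:
    seq = seq.upper().replace("U", "T")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class G4Motif:
    """One quadruplex-forming candidate, 1-based closed within the scanned
    sequence, always in + coordinates."""

    start: int
    end: int
    g_group_size: int
    loop_lengths: tuple[int, int, int]
    gscore: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class G4Report:
    locus_id: str
    observed: int
    expected: float
    fold: float
    g4_class: str
    n_shuffles: int
    seed: int


def gscore(g: int, loops: tuple[int, int, int]) -> int:
    return 20 * g - sum(loops) - (max(loops) - min(loops))


def _g_run_lengths(seq: str, base: str = "G") -> np.ndarray:
    """run_len[i] = length of the maximal ``base``-run starting at i (0 if
    seq[i] != base)."""
    n = len(seq)
    run = np.zeros(n, dtype=int)
    i = n - 1
    while i >= 0:
        if seq[i] == base:
            run[i] = run[i + 1] + 1 if i + 1 < n else 1
        i -= 1
    return run


def _candidates(
    seq: str,
    max_length: int,
    min_g_group: int,
    loop_min: int,
    loop_max: int,
    base: str = "G",
) -> list[tuple[int, int, int, tuple[int, int, int]]]:
    """All (start0, end0, g, loops) motif decompositions, 0-based closed."""
    import bisect

    n = len(seq)
    run = _g_run_lengths(seq, base)
    out = []
    max_g = max_length // 4
    for g in range(min_g_group, max_g + 1):
        starts = [i for i in range(n) if run[i] >= g]

        def successors(p: int, end_bound: int) -> list[int]:
            """G-run starts usable as the next group after a group at p."""
            lo = bisect.bisect_left(starts, p + g + loop_min)
            hi = bisect.bisect_right(starts, min(p + g + loop_max, end_bound - g))
            return starts[lo:hi]

        for p1 in starts:
            last = p1 + max_length - 1  # inclusive end bound
            for p2 in successors(p1, last + 1):
                l1 = p2 - (p1 + g)
                for p3 in successors(p2, last + 1):
                    l2 = p3 - (p2 + g)
                    for p4 in successors(p3, last + 1):
                        l3 = p4 - (p3 + g)
                        out.append((p1, p4 + g - 1, g, (l1, l2, l3)))
    return out


def _greedy_select(cands: list[G4Motif]) -> list[G4Motif]:
    """Highest-score non-overlapping subset; ties to smallest start, then
    shortest motif, then smallest loop tuple (a total order, so selection
    is independent of enumeration order)."""
    chosen: list[G4Motif] = []
    taken: list[tuple[int, int]] = []
    for m in sorted(
        cands,
        key=lambda m: (-m.gscore, m.start, m.end, m.loop_lengths,
                       m.g_group_size, m.strand),
    ):
        if all(m.end < s or m.start > e for s, e in taken):
            chosen.append(m)
            taken.append((m.start, m.end))
    chosen.sort(key=lambda m: m.start)
    return chosen


def qgrs_scan(
    sequence: str,
    max_length: int = 30,
    min_g_group: int = 2,
    loop_min: int = 0,
    loop_max: int = 36,
    both_strands: bool = False,
) -> list[G4Motif]:
    """Find QGRS motifs on the + strand (or both), 1-based closed coords.

    Overlapping candidates are resolved by keeping the highest-scoring
    non-overlapping set.  With ``both_strands`` the scan is performed in a
    canonical orientation (the lexicographically smaller of the sequence
    and its reverse complement) so the reported motif set is exactly
    invariant under reverse complementation of the input.
    """
    seq = _validate(sequence)
    if min(max_length, min_g_group) < 1 or loop_min < 0 or loop_max < loop_min:
        raise ValueError("invalid motif search parameters")
    n = len(seq)

    def plus_motifs(s: str, strand: str) -> list[G4Motif]:
        return [
            G4Motif(p1 + 1, p4e + 1, g, loops, gscore(g, loops), strand)
            for p1, p4e, g, loops in _candidates(
                s, max_length, min_g_group, loop_min, loop_max
            )
        ]

    if not both_strands:
        return _greedy_select(plus_motifs(seq, "+"))

    rc = revcomp(seq)
    frame = seq if seq <= rc else rc
    flipped = frame is not seq
    cands = plus_motifs(frame, "+") + [
        G4Motif(n - m.end + 1, n - m.start + 1, m.g_group_size,
                m.loop_lengths[::-1], m.gscore, "-")
        for m in plus_motifs(revcomp(frame), "+")
    ]
    selected = _greedy_select(cands)
    if flipped:
        selected = [
            G4Motif(
                n - m.end + 1,
                n - m.start + 1,
                m.g_group_size,
                m.loop_lengths[::-1],
                m.gscore,
                "+" if m.strand == "-" else "-",
            )
            for m in selected
        ]
        selected.sort(key=lambda m: m.start)
    return selected


def g4hunter_score(sequence: str, window: int = 25) -> np.ndarray:
    """Per-window mean G4Hunter base scores (positive = G-rich strand).

    A window longer than the sequence collapses to a single whole-sequence
    window.
    """
    seq = _validate(sequence)
    if window < 1:
        raise ValueError("window must be >= 1")
    n = len(seq)
    base = np.zeros(n, dtype=float)
    i = 0
    while i < n:
        ch = seq[i]
        j = i
        while j < n and seq[j] == ch:
            j += 1
        if ch == "G":
            base[i:j] = min(j - i, 4)
        elif ch == "C":
            base[i:j] = -min(j - i, 4)
        i = j
    if window >= n:
        return np.array([base.mean()]) if n else np.array([0.0])
    kernel = np.ones(window) / window
    return np.convolve(base, kernel, mode="valid")


def shuffle_expectation(
    sequence: str,
    n_shuffles: int = 100,
    seed: int = 0,
    **scan_kwargs,
) -> float:
    """Mean QGRS motif count over seeded mononucleotide shuffles.

    Shuffling preserves base composition exactly; the result is
    deterministic for a given seed.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    seq = _validate(sequence)
    if "G" not in seq:
        return 0.0
    rng = np.random.default_rng(seed)
    letters = np.array(list(seq))
    total = 0
    for _ in range(n_shuffles):
        shuffled = "".join(rng.permutation(letters))
        total += len(qgrs_scan(shuffled, **scan_kwargs))
    return total / n_shuffles


def classify_g4(
    observed: int, expected: float, pseudo: float = 0.5
) -> tuple[float, str]:
    """Fold-enrichment over random expectation and its class.

    fold = (observed + pseudo) / (expected + pseudo).  Strict cutpoints:
    fold > 100 is "G4-rich", fold < 20 is "G4-poor", anything else
    (including exactly 100 or 20) "intermediate".
    """
    if expected < 0:
        raise ValueError("expected must be >= 0")
    fold = (observed + pseudo) / (expected + pseudo)
    if fold > 100:
        cls = "G4-rich"
    elif fold < 20:
        cls = "G4-poor"
    else:
        cls = "intermediate"
    return fold, cls


def g4_report(
    locus_id: str,
    sequence: str,
    n_shuffles: int = 100,
    seed: int = 0,
    pseudo: float = 0.5,
    **scan_kwargs,
) -> G4Report:
    """Observed vs shuffle-expected motif counts for one locus."""
    observed = len(qgrs_scan(sequence, **scan_kwargs))
    expected = shuffle_expectation(
        sequence, n_shuffles=n_shuffles, seed=seed, **scan_kwargs
    )
    fold, cls = classify_g4(observed, expected, pseudo)
    return G4Report(locus_id, observed, expected, fold, cls, n_shuffles, seed)
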