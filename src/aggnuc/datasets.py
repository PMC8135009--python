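"""Bundled reference tables from sequencing of sarkosyl-insoluble aggregates.

These small TSVs summarize nucleic-acid fragments recovered from pooled
Alzheimer's-disease (AD) and age-matched-control (AMC) hippocampal
aggregates:

* ``dna_peaks_hippocampus`` — 38 DNA fragment pile-up loci (ChIP-seq style)
  with per-group peak counts and uniform-null p-values; a missing ``ad_p``
  marks a locus with no AD peak at all.
* ``rna_diff_hippocampus`` — 49 gene-mapped RNA fragment peaks with AD/AMC
  read counts, printed ratios and differential p-value ceilings
  ("NS" = not significant).
* ``viral_screen_hippocampus`` — per-virus read counts by group and
  molecule; ``*_pass`` flags mark counts that met every screening
  threshold.
* ``viral_library_sizes`` — viral-read numerators and raw-library
  denominators per group/molecule.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str, **kwargs) -> pd.DataFrame:
    ref = resources.files("aggnuc") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", **kwargs)


def load_dna_peak_table() -> pd.DataFrame:
    """DNA fragment peaks: one row per locus, AD/AMC p-values may be NaN."""
    df = _load("dna_peaks_hippocampus.tsv", dtype={"chrom": str})
    return df


def load_rna_diff_table() -> pd.DataFrame:
    """Gene-mapped RNA fragment peaks with two-group read counts."""
    return _load("rna_diff_hippocampus.tsv", dtype={"chrom": str})


def load_viral_screen_table() -> pd.DataFrame:
    """Per-virus read counts by group/molecule with threshold-pass flags."""
    return _load("viral_screen_hippocampus.tsv")


def load_viral_library_sizes() -> pd.DataFrame:
    """Viral read counts and total raw library sizes per group/molecule."""
    return _load("viral_library_sizes.tsv")
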