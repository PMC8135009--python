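"""Readers and writers for the standard formats the pipeline touches.

BED is read as 0-based half-open and converted to the internal 1-based
closed convention; the internal TSV dialect is already 1-based closed.
GFF3 gene features are read through gffutils and kept 1-based closed as-is.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Union

import gffutils
import pandas as pd

from .model import Config, GeneRecord, GenomicInterval

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input line; message names the file and line number."""


def read_intervals(path: PathLike, dialect: str = "bed") -> list[GenomicInterval]:
    """Read genomic intervals from a BED or internal-TSV file.

    dialect="bed": columns chrom/start/end, 0-based half-open (extra BED
    columns ignored).  dialect="tsv": chrom/start/end, 1-based closed, with
    an optional header line.  Ordering of records is preserved.
    """
    if dialect not in ("bed", "tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 columns")
            chrom, s, e = fields[0], fields[1], fields[2]
            if dialect == "tsv" and lineno == 1 and not (
                s.lstrip("-").isdigit() and e.lstrip("-").isdigit()
            ):
                continue  # header row
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinate"
                ) from exc
            try:
                if dialect == "bed":
                    iv = GenomicInterval.from_bed(chrom, start, end)
                else:
                    iv = GenomicInterval(chrom, start, end)
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            out.append(iv)
    return out


def write_intervals_bed(intervals: Iterable[GenomicInterval], path: PathLike) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            chrom, s0, e0 = iv.to_bed()
            fh.write(f"{chrom}\t{s0}\t{e0}\n")


def read_gff_genes(path: PathLike, feature_type: str = "gene") -> list[GeneRecord]:
    """Read gene-level features from a GFF3 file, sorted by (chrom, start).

    Features lacking an ID attribute are skipped with a logged warning.
    """
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    records: list[GeneRecord] = []
    for feat in db.features_of_type(feature_type):
        attr_id = feat.attributes.get("ID", [None])[0]
        if attr_id is None:
            logger.warning(
                "skipping %s feature at %s:%s-%s with no ID attribute",
                feature_type, feat.seqid, feat.start, feat.end,
            )
            continue
        strand = feat.strand if feat.strand in ("+", "-") else "unknown"
        biotype = feat.attributes.get("biotype", [""])[0]
        records.append(
            GeneRecord(
                gene_id=attr_id,
                interval=GenomicInterval(feat.seqid, feat.start, feat.end),
                strand=strand,
                biotype=biotype,
            )
        )
    records.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return records


def write_gff_genes(genes: Iterable[GeneRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            strand = g.strand if g.strand in ("+", "-") else "."
            attrs = f"ID={g.gene_id}"
            if g.biotype:
                attrs += f";biotype={g.biotype}"
            fh.write(
                f"{g.interval.chrom}\tsim\tgene\t{g.interval.start}\t"
                f"{g.interval.end}\t.\t{strand}\t.\t{attrs}\n"
            )


def write_table(records, path: PathLike, config: Config | None = None) -> None:
    """Write tabular results as TSV with a header row.

    ``records`` may be a DataFrame or an iterable of dicts/dataclasses
    sharing a schema.  Floats are rendered at the precision given in Config
    so that a ratio of 4.5986 with 2-decimal reporting prints as "4.60".
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = list(records)
        if rows and hasattr(rows[0], "__dataclass_fields__"):
            from dataclasses import asdict

            rows = [asdict(r) for r in rows]
        df = pd.DataFrame(rows)
    precision = (config or Config()).float_precision
    df.to_csv(path, sep="\t", index=False, float_format=f"%.{precision}f")


def read_table(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
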