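"""Readers and writers for the plain-text interchange formats.

All tabular formats are TSV.  Coordinates in TSV inputs are 1-based fully
closed; BED input is converted from 0-based half-open on load, and GFF3 is
already 1-based.  Annotation is strand-normalized on load so that
``tss``/``tts`` are stored in transcription order.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml

from .types import (
    ALLELE_COUNT_COLUMNS,
    METHYL_CALL_COLUMNS,
    CrossDesign,
    ExpressionMatrix,
    GeneAnnotation,
    ValidationError,
    validate_allele_counts,
    validate_methyl_calls,
)

__all__ = [
    "read_design",
    "read_counts",
    "read_allele_counts",
    "read_methyl_calls",
    "read_annotation",
    "write_table",
    "write_counts",
]


def read_design(path: str | Path) -> CrossDesign:
    """Read a cross-design YAML file.

    Expected layout::

        ploidy: {L2: 2, L4: 4, ...}
        groups:
          L2xL4:
            maternal: L2
            paternal: L4
            samples: [L2xL4_1, L2xL4_2, L2xL4_3]

    Group class (2x hybrid, maternal-/paternal-excess triploid, 4x hybrid,
    parental self) is derived from the parental ploidies, not read.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "groups" not in raw or "ploidy" not in raw:
        raise ValidationError(f"{path}: design file needs top-level 'groups' and 'ploidy'")
    return CrossDesign(groups=raw["groups"], ploidy_of_parent=raw["ploidy"])


def read_counts(path: str | Path, normalized: bool = False) -> ExpressionMatrix:
    """Read a gene x sample count TSV (header ``gene_id<TAB>sample...``)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.name != "gene_id":
        raise ValidationError(f"{path}: first column must be named 'gene_id', got {df.index.name!r}")
    return ExpressionMatrix(values=df, normalized=normalized)


def _read_tsv(path: str | Path, columns: list[str], dtypes: dict) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=dtypes)
    except (ValueError, pd.errors.ParserError) as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    bad = df[columns].isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        raise ValidationError(f"{path}: malformed row at line {int(df.index[bad][0]) + 2}")
    return df[columns]


def read_allele_counts(path: str | Path, design: CrossDesign | None = None) -> pd.DataFrame:
    """Read a per-SNP allelic count TSV and validate against the design."""
    df = _read_tsv(
        path,
        ALLELE_COUNT_COLUMNS,
        {"gene_id": str, "chrom": str, "pos": "Int64", "allele_a": str,
         "allele_b": str, "reads_a": "Int64", "reads_b": "Int64", "sample": str},
    )
    df = df.astype({"pos": int, "reads_a": int, "reads_b": int})
    try:
        return validate_allele_counts(df, design)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def read_methyl_calls(path: str | Path) -> pd.DataFrame:
    """Read an allele-resolved per-cytosine methylation TSV."""
    df = _read_tsv(
        path,
        METHYL_CALL_COLUMNS,
        {"chrom": str, "pos": "Int64", "strand": str, "context": str,
         "allele": str, "meth_reads": "Int64", "total_reads": "Int64", "sample": str},
    )
    df = df.astype({"pos": int, "meth_reads": int, "total_reads": int})
    try:
        return validate_methyl_calls(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def _parse_gff3_attributes(attr: str) -> dict:
    out = {}
    for part in attr.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_annotation(path: str | Path) -> list[GeneAnnotation]:
    """Read gene annotation from BED6 or GFF3 (gene features only).

    BED intervals (0-based half-open) are converted to 1-based closed, then
    strand-normalized: tss/tts are stored in transcription order, so a
    minus-strand gene has tss = interval end.
    """
    path = Path(path)
    text = path.read_text()
    genes: list[GeneAnnotation] = []
    if text.lstrip().startswith("##gff") or path.suffix.lower() in (".gff", ".gff3"):
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValidationError(f"{path}:{lineno}: GFF3 line has {len(fields)} fields")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = fields
            if ftype != "gene":
                continue
            attr = _parse_gff3_attributes(attrs)
            gene_id = attr.get("ID") or attr.get("gene_id")
            if gene_id is None:
                raise ValidationError(f"{path}:{lineno}: gene feature without ID attribute")
            genes.append(_orient(gene_id, chrom, strand, int(start), int(end), f"{path}:{lineno}"))
    else:
        for lineno, line in enumerate(text.splitlines(), start=1):
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValidationError(f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}")
            chrom, start, end, name, _score, strand = fields[:6]
            genes.append(
                _orient(name, chrom, strand, int(start) + 1, int(end), f"{path}:{lineno}")
            )
    return genes


def _orient(gene_id: str, chrom: str, strand: str, start1: int, end1: int, where: str) -> GeneAnnotation:
    if start1 > end1:
        raise ValidationError(f"{where}: interval start > end")
    if strand == "+":
        return GeneAnnotation(gene_id=gene_id, chrom=chrom, strand="+", tss=start1, tts=end1)
    if strand == "-":
        return GeneAnnotation(gene_id=gene_id, chrom=chrom, strand="-", tss=end1, tts=start1)
    raise ValidationError(f"{where}: strand must be '+' or '-', got {strand!r}")


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a result table as TSV with stable column order."""
    df.to_csv(path, sep="\t", index=index)


def write_counts(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def annotation_to_bed(genes: list[GeneAnnotation]) -> str:
    """Render annotations back to BED6 text (inverse of the BED reader)."""
    buf = _io.StringIO()
    for g in genes:
        buf.write(f"{g.chrom}\t{g.start - 1}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
    return buf.getvalue()
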