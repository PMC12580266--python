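"""Core domain types shared by every analysis stage.

The central object is :class:`CrossDesign`, which maps samples to cross
groups and records, per group, which parental genotype (e.g. ``L2``, ``L4``)
was the mother and which the father, together with parental ploidies.  The
same genotype allele is maternal in one reciprocal cross and paternal in the
other; all parent-of-origin resolution therefore goes through the design and
is never stored in allele-level records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "GroupClass",
    "CrossDesign",
    "ExpressionMatrix",
    "GeneAnnotation",
    "ALLELE_COUNT_COLUMNS",
    "METHYL_CALL_COLUMNS",
    "METHYL_CONTEXTS",
    "validate_allele_counts",
    "validate_methyl_calls",
]

METHYL_CONTEXTS = ("CG", "CHG", "CHH")

#: canonical column order of an allele-count table (one row = one SNP x sample)
ALLELE_COUNT_COLUMNS = [
    "gene_id", "chrom", "pos", "allele_a", "allele_b", "reads_a", "reads_b", "sample",
]

#: canonical column order of a per-cytosine allele-resolved methylation table
METHYL_CALL_COLUMNS = [
    "chrom", "pos", "strand", "context", "allele", "meth_reads", "total_reads", "sample",
]


class ValidationError(ValueError):
    """Raised when an input violates a documented invariant."""


class GroupClass:
    """Cross-group classes derived from parental identities and ploidies."""

    HYBRID_2X = "2x_hybrid"
    TRIPLOID_MATERNAL = "3x_maternal_excess"
    TRIPLOID_PATERNAL = "3x_paternal_excess"
    HYBRID_4X = "4x_hybrid"
    PARENTAL_SELF = "parental_self"

    ALL = (HYBRID_2X, TRIPLOID_MATERNAL, TRIPLOID_PATERNAL, HYBRID_4X, PARENTAL_SELF)


def classify_group(maternal: str, paternal: str, ploidy_of: Mapping[str, int]) -> str:
    """Derive the group class from the parental genotypes and their ploidies.

    Maternal-excess triploids come from a 4x mother x 2x father; paternal-excess
    from a 2x mother x 4x father.  A self has identical parents at any ploidy.
    """
    for parent in (maternal, paternal):
        if parent not in ploidy_of:
            raise ValidationError(f"unknown parental genotype {parent!r}: no ploidy given")
        if ploidy_of[parent] not in (2, 4):
            raise ValidationError(
                f"unsupported ploidy {ploidy_of[parent]} for parent {parent!r} (expected 2 or 4)"
            )
    pm, pp = ploidy_of[maternal], ploidy_of[paternal]
    if maternal == paternal:
        return GroupClass.PARENTAL_SELF
    if pm == 2 and pp == 2:
        return GroupClass.HYBRID_2X
    if pm == 4 and pp == 4:
        return GroupClass.HYBRID_4X
    if pm == 4 and pp == 2:
        return GroupClass.TRIPLOID_MATERNAL
    return GroupClass.TRIPLOID_PATERNAL


@dataclass
class CrossDesign:
    """Sample-to-group mapping with parental identities and ploidies.

    Parameters
    ----------
    groups
        Mapping group label -> dict with keys ``maternal``, ``paternal``
        (parental genotype labels) and ``samples`` (list of sample IDs).
        By the field convention the maternal parent is listed first in a
        cross name such as ``L4xL2``.
    ploidy_of_parent
        Mapping parental genotype -> ploidy (2 or 4).
    """

    groups: dict
    ploidy_of_parent: dict
    group_class: dict = field(init=False)

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValidationError("design contains no groups")
        seen: dict[str, str] = {}
        self.group_class = {}
        for name, spec in self.groups.items():
            for key in ("maternal", "paternal", "samples"):
                if key not in spec:
                    raise ValidationError(f"group {name!r} is missing field {key!r}")
            if not spec["samples"]:
                raise ValidationError(f"group {name!r} has an empty sample list")
            for s in spec["samples"]:
                if s in seen:
                    raise ValidationError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {name!r}"
                    )
                seen[s] = name
            self.group_class[name] = classify_group(
                spec["maternal"], spec["paternal"], self.ploidy_of_parent
            )

    # -- lookups ---------------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return [s for g in self.groups.values() for s in g["samples"]]

    def group_of(self, sample: str) -> str:
        for name, spec in self.groups.items():
            if sample in spec["samples"]:
                return name
        raise KeyError(sample)

    def samples_of(self, group: str) -> list[str]:
        return list(self.groups[group]["samples"])

    def maternal_parent(self, group: str) -> str:
        return self.groups[group]["maternal"]

    def paternal_parent(self, group: str) -> str:
        return self.groups[group]["paternal"]

    def class_of(self, group: str) -> str:
        return self.group_class[group]

    def groups_of_class(self, *classes: str) -> list[str]:
        return [g for g, c in self.group_class.items() if c in classes]

    def samples_of_class(self, *classes: str) -> list[str]:
        return [s for g in self.groups_of_class(*classes) for s in self.samples_of(g)]

    def parental_self_groups(self, ploidy: int) -> list[str]:
        """Self-pollination groups whose parent has the requested ploidy."""
        out = []
        for g in self.groups_of_class(GroupClass.PARENTAL_SELF):
            if self.ploidy_of_parent[self.maternal_parent(g)] == ploidy:
                out.append(g)
        return out


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values.

    ``values`` is a DataFrame indexed by gene ID with sample columns.  Raw
    counts must be nonnegative integers; normalized values nonnegative reals.
    """

    values: pd.DataFrame
    normalized: bool = False

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if arr.size and np.nanmin(arr) < 0:
            raise ValidationError("expression matrix contains negative entries")
        if not self.normalized and arr.size:
            if not np.allclose(arr, np.round(arr)):
                raise ValidationError("raw-count matrix contains non-integer entries")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def check_design(self, design: CrossDesign) -> None:
        missing = set(design.samples) - set(self.sample_ids)
        if missing:
            raise ValidationError(f"design samples absent from matrix: {sorted(missing)}")


@dataclass(frozen=True)
class GeneAnnotation:
    """One gene with strand-normalized transcription coordinates.

    ``tss`` and ``tts`` are stored in transcription order (1-based): for a
    minus-strand gene ``tss > tts`` numerically.  All region logic downstream
    (upstream flank, gene body, downstream flank) is strand-aware.
    """

    gene_id: str
    chrom: str
    strand: str
    tss: int
    tts: int

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if self.strand == "+" and self.tss >= self.tts:
            raise ValidationError(f"{self.gene_id}: + strand requires tss < tts")
        if self.strand == "-" and self.tss <= self.tts:
            raise ValidationError(f"{self.gene_id}: - strand requires tss > tts after normalization")

    @property
    def start(self) -> int:
        """Leftmost genomic coordinate of the gene body."""
        return min(self.tss, self.tts)

    @property
    def end(self) -> int:
        """Rightmost genomic coordinate of the gene body."""
        return max(self.tss, self.tts)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _require_columns(df: pd.DataFrame, columns: Iterable[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} table is missing columns {missing}")


def validate_allele_counts(df: pd.DataFrame, design: CrossDesign | None = None) -> pd.DataFrame:
    """Validate an allele-count table (one row per SNP x sample)."""
    _require_columns(df, ALLELE_COUNT_COLUMNS, "allele-count")
    if (df["reads_a"] < 0).any() or (df["reads_b"] < 0).any():
        bad = df.index[(df["reads_a"] < 0) | (df["reads_b"] < 0)][0]
        raise ValidationError(f"negative read count at row {bad}")
    if design is not None:
        known = set(design.samples)
        unknown = set(df["sample"]) - known
        if unknown:
            raise ValidationError(f"samples not in design: {sorted(unknown)}")
        for sample, sub in df.groupby("sample"):
            group = design.group_of(sample)
            parents = {design.maternal_parent(group), design.paternal_parent(group)}
            labels = set(sub["allele_a"]) | set(sub["allele_b"])
            if not labels <= parents:
                raise ValidationError(
                    f"sample {sample!r}: allele labels {sorted(labels - parents)} "
                    f"are not the cross parents {sorted(parents)}"
                )
    dup = df.duplicated(subset=["gene_id", "chrom", "pos", "sample"])
    if dup.any():
        raise ValidationError(
            f"duplicate (gene, chrom, pos, sample) rows, first at row {df.index[dup][0]}"
        )
    return df


def validate_methyl_calls(df: pd.DataFrame) -> pd.DataFrame:
    """Validate an allele-resolved methylation-call table."""
    _require_columns(df, METHYL_CALL_COLUMNS, "methylation-call")
    if (df["meth_reads"] < 0).any() or (df["total_reads"] < 0).any():
        raise ValidationError("negative methylation read counts")
    over = df["meth_reads"] > df["total_reads"]
    if over.any():
        raise ValidationError(
            f"meth_reads > total_reads at row {df.index[over][0]}"
        )
    bad_ctx = ~df["context"].isin(METHYL_CONTEXTS)
    if bad_ctx.any():
        raise ValidationError(
            f"unknown methylation context {df.loc[bad_ctx, 'context'].iloc[0]!r} "
            f"(expected one of {METHYL_CONTEXTS})"
        )
    bad_strand = ~df["strand"].isin(("+", "-"))
    if bad_strand.any():
        raise ValidationError("strand must be '+' or '-'")
    return df
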