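"""Allele-resolved methylation: site levels, region means, the ASM
difference, reciprocal-cross comparison, metagene profiles, and the
gene-body-methylation/expression association.

A cytosine's methylation level is methylated reads over total reads, kept
only when covered by at least 5 reads.  Per gene region (2-kb upstream
flank, gene body TSS..TTS, 2-kb downstream flank — all strand-aware), the
per-allele level is the unweighted mean of qualifying sites, and the ASM
difference is the absolute difference between the two parental-genotype
allele means.  Reciprocal crosses are compared on their ASM-difference
distributions with a Wilcoxon rank-sum test (exact for small samples),
annotated at the displayed tiers (dagger for P < 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .types import GeneAnnotation, ValidationError

__all__ = [
    "site_level",
    "add_site_levels",
    "RegionSpec",
    "region_specs",
    "region_mean",
    "region_mean_table",
    "asm_difference",
    "compare_reciprocal_asm",
    "metagene_profile",
    "gbm_expression_association",
    "MIN_SITE_COVERAGE",
    "DEFAULT_MIN_SITES",
]

MIN_SITE_COVERAGE = 5
DEFAULT_MIN_SITES = 3
REGIONS = ("upstream", "body", "downstream")


def site_level(meth_reads: int, total_reads: int, min_coverage: int = MIN_SITE_COVERAGE) -> float | None:
    """Methylation level of one cytosine, or None below the coverage floor."""
    if meth_reads < 0 or total_reads < 0 or meth_reads > total_reads:
        raise ValidationError("invalid read counts")
    if total_reads < min_coverage:
        return None
    return meth_reads / total_reads


def add_site_levels(calls: pd.DataFrame, min_coverage: int = MIN_SITE_COVERAGE) -> pd.DataFrame:
    """Pool replicates per (site, allele) and attach qualifying levels.

    Read counts are summed over samples at each (chrom, pos, strand,
    context, allele); sites whose pooled coverage is below the floor are
    dropped.  Returns the pooled table with a ``level`` column.
    """
    pooled = (
        calls.groupby(["chrom", "pos", "strand", "context", "allele"], sort=True)[
            ["meth_reads", "total_reads"]
        ]
        .sum()
        .reset_index()
    )
    pooled = pooled[pooled["total_reads"] >= min_coverage].copy()
    pooled["level"] = pooled["meth_reads"] / pooled["total_reads"]
    return pooled


@dataclass(frozen=True)
class RegionSpec:
    """One strand-aware gene region as a closed genomic interval."""

    gene_id: str
    region: str       # upstream | body | downstream
    chrom: str
    start: int        # leftmost genomic coordinate
    end: int          # rightmost genomic coordinate

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"{self.gene_id}/{self.region}: empty interval")


def region_specs(gene: GeneAnnotation, flank: int = 2000) -> dict[str, RegionSpec]:
    """Upstream/body/downstream intervals for a gene, in genomic coordinates.

    Upstream is the ``flank`` bp before the TSS in transcription
    orientation; downstream the ``flank`` bp after the TTS.  The three
    regions partition [start - flank, end + flank] without overlap.
    """
    left, right = gene.start, gene.end
    body = RegionSpec(gene.gene_id, "body", gene.chrom, left, right)
    if gene.strand == "+":
        up = RegionSpec(gene.gene_id, "upstream", gene.chrom, left - flank, left - 1)
        down = RegionSpec(gene.gene_id, "downstream", gene.chrom, right + 1, right + flank)
    else:
        up = RegionSpec(gene.gene_id, "upstream", gene.chrom, right + 1, right + flank)
        down = RegionSpec(gene.gene_id, "downstream", gene.chrom, left - flank, left - 1)
    return {"upstream": up, "body": body, "downstream": down}


def region_mean(
    site_table: pd.DataFrame,
    spec: RegionSpec,
    context: str,
    allele: str,
    min_sites: int = DEFAULT_MIN_SITES,
) -> float | None:
    """Unweighted mean of qualifying site levels in a region, or None.

    ``site_table`` is the output of :func:`add_site_levels`.  Fewer than
    ``min_sites`` qualifying cytosines -> None (missing).
    """
    sel = site_table[
        (site_table["chrom"] == spec.chrom)
        & (site_table["pos"] >= spec.start)
        & (site_table["pos"] <= spec.end)
        & (site_table["context"] == context)
        & (site_table["allele"] == allele)
    ]
    if len(sel) < min_sites:
        return None
    return float(sel["level"].mean())


def asm_difference(mean_allele1: float | None, mean_allele2: float | None) -> float | None:
    """|mean level allele 1 − mean level allele 2|; None if either is missing."""
    if mean_allele1 is None or mean_allele2 is None:
        return None
    return abs(mean_allele1 - mean_allele2)


def region_mean_table(
    calls: pd.DataFrame,
    annotation: list[GeneAnnotation],
    alleles: tuple[str, str],
    cross: str = "",
    flank: int = 2000,
    min_sites: int = DEFAULT_MIN_SITES,
    min_coverage: int = MIN_SITE_COVERAGE,
    genes: set | None = None,
) -> pd.DataFrame:
    """Per-gene, per-region, per-context allele means and the ASM difference.

    Returns one row per (gene, region, context) with mean levels for both
    alleles, ``asm_diff`` and the qualifying site counts; rows where either
    allele mean is missing carry NaN and are excluded from downstream tests.
    """
    site_table = add_site_levels(calls, min_coverage=min_coverage)
    a1, a2 = alleles
    rows = []
    for gene in annotation:
        if genes is not None and gene.gene_id not in genes:
            continue
        for region, spec in region_specs(gene, flank=flank).items():
            in_region = site_table[
                (site_table["chrom"] == spec.chrom)
                & (site_table["pos"] >= spec.start)
                & (site_table["pos"] <= spec.end)
            ]
            for context, sub in in_region.groupby("context"):
                s1 = sub[sub["allele"] == a1]["level"]
                s2 = sub[sub["allele"] == a2]["level"]
                m1 = float(s1.mean()) if len(s1) >= min_sites else None
                m2 = float(s2.mean()) if len(s2) >= min_sites else None
                diff = asm_difference(m1, m2)
                rows.append(
                    {
                        "gene_id": gene.gene_id,
                        "region": region,
                        "context": context,
                        "cross": cross,
                        f"mean_{a1}": np.nan if m1 is None else m1,
                        f"mean_{a2}": np.nan if m2 is None else m2,
                        "asm_diff": np.nan if diff is None else diff,
                        f"n_sites_{a1}": int(len(s1)),
                        f"n_sites_{a2}": int(len(s2)),
                    }
                )
    return pd.DataFrame(rows)


def compare_reciprocal_asm(
    diffs_cross_a: np.ndarray | pd.Series,
    diffs_cross_b: np.ndarray | pd.Series,
    paired: bool = False,
    exact_max_n: int = 25,
) -> dict:
    """Wilcoxon comparison of ASM-difference distributions between crosses.

    Unpaired (default): two-sided rank-sum, exact when both sides have at
    most ``exact_max_n`` values and no ties, otherwise the normal
    approximation with tie correction.  ``paired=True`` switches to the
    signed-rank test on per-gene pairs.  Significance is annotated at the
    displayed tiers: ``†`` for P < 0.1, else ``ns``.
    """
    a = np.asarray(pd.Series(diffs_cross_a).dropna(), dtype=float)
    b = np.asarray(pd.Series(diffs_cross_b).dropna(), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both crosses need at least one ASM difference")
    if paired:
        if a.size != b.size:
            raise ValidationError("paired comparison needs equal-length samples")
        if np.allclose(a, b):
            stat, p = 0.0, 1.0
        else:
            res = stats.wilcoxon(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
    else:
        has_ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
        method = "exact" if (max(a.size, b.size) <= exact_max_n and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        stat, p = float(res.statistic), float(res.pvalue)
    return {
        "statistic": stat,
        "p": p,
        "n_a": int(a.size),
        "n_b": int(b.size),
        "annotation": "†" if p < 0.1 else "ns",
    }


def metagene_profile(
    calls: pd.DataFrame,
    annotation: list[GeneAnnotation],
    context: str,
    allele: str,
    body_bins: int = 40,
    flank_bins: int = 20,
    flank: int = 2000,
    min_coverage: int = MIN_SITE_COVERAGE,
) -> pd.DataFrame:
    """Average methylation profile across the gene body and flanks.

    Flank bins are fixed-width (flank/flank_bins bp); the body is split
    into ``body_bins`` bins proportional to gene length.  Per gene, each
    bin takes the mean level of its qualifying sites; the profile is the
    unweighted mean across genes per bin.  Minus-strand genes are reversed
    so every profile runs 5'->3' (upstream, TSS..TTS, downstream).

    Returns a DataFrame with columns bin, segment, mean_level, n_genes.
    """
    site_table = add_site_levels(calls, min_coverage=min_coverage)
    site_table = site_table[
        (site_table["context"] == context) & (site_table["allele"] == allele)
    ]
    n_bins = body_bins + 2 * flank_bins
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=int)
    for gene in annotation:
        sub = site_table[
            (site_table["chrom"] == gene.chrom)
            & (site_table["pos"] >= gene.start - flank)
            & (site_table["pos"] <= gene.end + flank)
        ]
        if len(sub) == 0:
            continue
        pos = sub["pos"].to_numpy()
        level = sub["level"].to_numpy()
        left, right = gene.start, gene.end
        length = right - left + 1
        bins = np.empty(len(pos), dtype=int)
        before = pos < left
        after = pos > right
        body = ~before & ~after
        # indices in genomic orientation first
        bins[before] = ((pos[before] - (left - flank)) * flank_bins // flank).clip(0, flank_bins - 1)
        bins[body] = flank_bins + ((pos[body] - left) * body_bins // length).clip(0, body_bins - 1)
        bins[after] = (
            flank_bins + body_bins
            + ((pos[after] - (right + 1)) * flank_bins // flank).clip(0, flank_bins - 1)
        )
        if gene.strand == "-":
            bins = n_bins - 1 - bins
        gene_bin_sum = np.zeros(n_bins)
        gene_bin_n = np.zeros(n_bins, dtype=int)
        np.add.at(gene_bin_sum, bins, level)
        np.add.at(gene_bin_n, bins, 1)
        covered = gene_bin_n > 0
        sums[covered] += gene_bin_sum[covered] / gene_bin_n[covered]
        counts[covered] += 1
    with np.errstate(invalid="ignore"):
        mean_level = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    segment = (
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "segment": segment, "mean_level": mean_level, "n_genes": counts}
    )


def gbm_expression_association(
    body_mcg_diff: pd.Series, paternal_fraction: pd.Series
) -> dict:
    """Spearman association between paternal-allele body-CG excess and
    paternal allelic expression share.

    ``body_mcg_diff`` holds per-gene (paternal − maternal) body CG levels;
    ``paternal_fraction`` the paternal share of allelic reads.  Only genes
    with both measures are used; fewer than 3 pairs is an error; a constant
    vector gives an undefined (missing) correlation.
    """
    joined = pd.concat(
        [body_mcg_diff.rename("meth"), paternal_fraction.rename("expr")], axis=1
    ).dropna()
    n = len(joined)
    if n < 3:
        raise ValidationError(f"need at least 3 gene pairs, got {n}")
    if joined["meth"].nunique() == 1 or joined["expr"].nunique() == 1:
        return {"rho": float("nan"), "p": float("nan"), "n": n, "missing": True}
    rho, p = stats.spearmanr(joined["meth"], joined["expr"])
    return {"rho": float(rho), "p": float(p), "n": n, "missing": False}
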