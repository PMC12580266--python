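"""Dosage-aware allele-specific expression and imprinting calls.

In a triploid hybrid the tetraploid parent contributes two of the three
genome copies, so absent any regulation its allele is expected to produce
2/3 of allelic reads (a 2:1 ratio); balanced crosses expect 1/2.  Each
informative SNP is tested against this dosage null with a two-sided exact
binomial test, replicates pooled by summation, SNPs with fewer than 10
pooled reads dropped, and Benjamini-Hochberg FDR applied across all tested
SNPs of a cross.  A gene is an ASEG if any of its SNPs has FDR < 0.05, with
direction taken from the pooled gene-level counts.

Imprinting is called from the two reciprocal crosses: a PEG/MEG shows
significant paternal/maternal bias in *both* cross directions, whereas a
cis-regulated (genotype-attached) bias favors the same genotype allele in
both directions and is reported separately, never as imprinted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CrossDesign, ValidationError

__all__ = [
    "DosageNull",
    "dosage_null",
    "snp_ase_test",
    "aggregate_gene_ase",
    "reciprocal_summary",
    "call_imprinting",
    "MIN_TOTAL_READS",
]

#: minimum pooled reads per SNP across all biological replicates
MIN_TOTAL_READS = 10


@dataclass(frozen=True)
class DosageNull:
    """Expected allelic read fractions for a cross under genome dosage."""

    group: str
    maternal_fraction: float

    @property
    def paternal_fraction(self) -> float:
        return 1.0 - self.maternal_fraction


def dosage_null(design: CrossDesign, group: str) -> DosageNull:
    """Null maternal read fraction for a cross group.

    2/3 when the mother is the tetraploid parent of a triploid, 1/3 when the
    father is, and 1/2 for ploidy-balanced crosses.
    """
    mat = design.maternal_parent(group)
    pat = design.paternal_parent(group)
    pm, pp = design.ploidy_of_parent[mat], design.ploidy_of_parent[pat]
    if pm == 4 and pp == 2:
        f = 2.0 / 3.0
    elif pm == 2 and pp == 4:
        f = 1.0 / 3.0
    else:
        f = 0.5
    return DosageNull(group=group, maternal_fraction=f)


def snp_ase_test(reads_parent1: int, reads_parent2: int, f_null: float) -> float:
    """Two-sided exact binomial P for one SNP against the dosage null.

    ``f_null`` is the expected read fraction of parent 1.  Two-sided by the
    minimum-likelihood convention: the P-value sums the probabilities of
    all outcomes no more likely than the observed one.
    """
    total = reads_parent1 + reads_parent2
    if total < 1:
        raise ValidationError("snp_ase_test requires at least one read")
    return float(stats.binomtest(reads_parent1, total, f_null).pvalue)


def _resolve_maternal(records: pd.DataFrame, design: CrossDesign, group: str) -> pd.DataFrame:
    """Reorient allele_a/allele_b read counts to maternal/paternal."""
    mat = design.maternal_parent(group)
    pat = design.paternal_parent(group)
    labels = set(records["allele_a"]) | set(records["allele_b"])
    if not labels <= {mat, pat}:
        raise ValidationError(
            f"allele labels {sorted(labels - {mat, pat})} are not parents of {group!r}"
        )
    a_is_mat = records["allele_a"] == mat
    out = records.copy()
    out["maternal_reads"] = np.where(a_is_mat, records["reads_a"], records["reads_b"])
    out["paternal_reads"] = np.where(a_is_mat, records["reads_b"], records["reads_a"])
    out["maternal_allele"] = mat
    out["paternal_allele"] = pat
    return out


def aggregate_gene_ase(
    records: pd.DataFrame,
    design: CrossDesign,
    group: str,
    alpha: float = 0.05,
    min_total_reads: int = MIN_TOTAL_READS,
    fdr_scope: str = "per-cross-all-snps",
) -> pd.DataFrame:
    """Gene-level ASE calls for one cross.

    Replicates are pooled by summation per SNP; SNPs below the pooled-read
    floor are dropped; each surviving SNP is tested against the cross's
    dosage null; BH FDR is applied across all tested SNPs of the cross
    (``fdr_scope='per-gene'`` restricts it within each gene).  A gene is
    significant if any SNP has FDR < alpha; its direction comes from the
    pooled gene-level counts, and genes whose significant SNPs disagree in
    direction are classed ``conflicting``.

    Returns one row per gene: gene_id, cross, n_snps, maternal_reads,
    paternal_reads, maternal_fraction, min_fdr, bias_class, plus the cross's
    maternal null fraction.  Genes present in the input but with no SNP
    passing the filter are classed ``filtered``.
    """
    if fdr_scope not in ("per-cross-all-snps", "per-gene"):
        raise ValueError(f"unknown fdr_scope {fdr_scope!r}")
    null = dosage_null(design, group)
    wanted = set(design.samples_of(group))
    sub = records[records["sample"].isin(wanted)]
    all_genes = list(pd.unique(records["gene_id"]))

    resolved = _resolve_maternal(sub, design, group) if len(sub) else sub
    rows = []
    if len(sub):
        pooled = (
            resolved.groupby(["gene_id", "chrom", "pos"], sort=True)[
                ["maternal_reads", "paternal_reads"]
            ]
            .sum()
            .reset_index()
        )
        pooled["total"] = pooled["maternal_reads"] + pooled["paternal_reads"]
        tested = pooled[pooled["total"] >= min_total_reads].copy()
        if len(tested):
            tested["p"] = [
                snp_ase_test(m, p, null.maternal_fraction)
                for m, p in zip(tested["maternal_reads"], tested["paternal_reads"])
            ]
            if fdr_scope == "per-cross-all-snps":
                tested["fdr"] = multipletests(tested["p"], method="fdr_bh")[1]
            else:
                tested["fdr"] = np.nan
                for g, idx in tested.groupby("gene_id").groups.items():
                    tested.loc[idx, "fdr"] = multipletests(
                        tested.loc[idx, "p"], method="fdr_bh"
                    )[1]

        by_gene = {k: v for k, v in tested.groupby("gene_id")} if len(tested) else {}
        for gene in all_genes:
            gsnps = by_gene.get(gene)
            if gsnps is None or len(gsnps) == 0:
                rows.append((gene, group, 0, 0, 0, np.nan, np.nan, "filtered"))
                continue
            mat_reads = int(gsnps["maternal_reads"].sum())
            pat_reads = int(gsnps["paternal_reads"].sum())
            frac = mat_reads / (mat_reads + pat_reads)
            min_fdr = float(gsnps["fdr"].min())
            sig = gsnps[gsnps["fdr"] < alpha]
            if len(sig) == 0:
                cls = "unbiased"
            else:
                sig_frac = sig["maternal_reads"] / (sig["maternal_reads"] + sig["paternal_reads"])
                directions = set(np.sign(sig_frac - null.maternal_fraction)) - {0.0}
                if len(directions) > 1:
                    cls = "conflicting"
                elif frac > null.maternal_fraction:
                    cls = "maternal_biased"
                elif frac < null.maternal_fraction:
                    cls = "paternal_biased"
                else:
                    cls = "conflicting"
            rows.append((gene, group, len(gsnps), mat_reads, pat_reads, frac, min_fdr, cls))
    else:
        rows = [(g, group, 0, 0, 0, np.nan, np.nan, "filtered") for g in all_genes]

    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "cross", "n_snps", "maternal_reads", "paternal_reads",
            "maternal_fraction", "min_fdr", "bias_class",
        ],
    )
    out["null_maternal_fraction"] = null.maternal_fraction
    out["maternal_allele"] = design.maternal_parent(group)
    out["paternal_allele"] = design.paternal_parent(group)
    return out


@dataclass
class ReciprocalSummary:
    """Cross-level ASEG counts plus per-gene allelic-contribution pairs."""

    counts: pd.DataFrame        # cross, n_maternal_biased, n_paternal_biased, n_informative
    scatter: pd.DataFrame       # gene_id, allele, pct_when_maternal, pct_when_paternal
    maternal_share_of_biased: float   # fraction of biased calls that are maternal
    paternal_inheritance_uplift: float  # mean allelic % gain when paternally inherited


def reciprocal_summary(results_a: pd.DataFrame, results_b: pd.DataFrame) -> ReciprocalSummary:
    """Summarize ASE over the two reciprocal crosses.

    ``counts`` gives per-cross maternal-/paternal-biased ASEG numbers with
    the informative-gene denominator (genes passing the SNP and read
    filters).  ``scatter`` pairs, per genotype allele of each ASEG observed
    in both crosses, its read percentage when maternally vs paternally
    inherited.  The asymmetry summary reports the maternal share of biased
    calls (gene-quantity axis) and the mean percentage-point uplift an
    allele gains when paternally inherited (magnitude axis).
    """
    counts_rows = []
    for res in (results_a, results_b):
        informative = res[res["bias_class"] != "filtered"]
        counts_rows.append(
            {
                "cross": res["cross"].iloc[0] if len(res) else "",
                "n_maternal_biased": int((res["bias_class"] == "maternal_biased").sum()),
                "n_paternal_biased": int((res["bias_class"] == "paternal_biased").sum()),
                "n_informative": int(len(informative)),
            }
        )
    counts = pd.DataFrame(counts_rows)

    biased_a = results_a[results_a["bias_class"].isin(["maternal_biased", "paternal_biased"])]
    biased_b = results_b[results_b["bias_class"].isin(["maternal_biased", "paternal_biased"])]
    aseg_genes = set(biased_a["gene_id"]) | set(biased_b["gene_id"])

    ia = results_a.set_index("gene_id")
    ib = results_b.set_index("gene_id")
    scatter_rows = []
    for gene in sorted(aseg_genes):
        if gene not in ia.index or gene not in ib.index:
            continue  # absent from one cross: kept in counts, excluded from scatter
        ra, rb = ia.loc[gene], ib.loc[gene]
        if ra["bias_class"] == "filtered" or rb["bias_class"] == "filtered":
            continue
        for allele in (ra["maternal_allele"], ra["paternal_allele"]):
            pct = {}
            for r in (ra, rb):
                share = (
                    r["maternal_fraction"]
                    if allele == r["maternal_allele"]
                    else 1.0 - r["maternal_fraction"]
                )
                role = "maternal" if allele == r["maternal_allele"] else "paternal"
                pct[role] = 100.0 * share
            scatter_rows.append(
                {
                    "gene_id": gene,
                    "allele": allele,
                    "pct_when_maternal": pct["maternal"],
                    "pct_when_paternal": pct["paternal"],
                }
            )
    scatter = pd.DataFrame(
        scatter_rows,
        columns=["gene_id", "allele", "pct_when_maternal", "pct_when_paternal"],
    )

    n_mat = int(counts["n_maternal_biased"].sum())
    n_pat = int(counts["n_paternal_biased"].sum())
    maternal_share = n_mat / (n_mat + n_pat) if (n_mat + n_pat) else float("nan")
    uplift = (
        float((scatter["pct_when_paternal"] - scatter["pct_when_maternal"]).mean())
        if len(scatter)
        else float("nan")
    )
    return ReciprocalSummary(
        counts=counts,
        scatter=scatter,
        maternal_share_of_biased=maternal_share,
        paternal_inheritance_uplift=uplift,
    )


def call_imprinting(results_a: pd.DataFrame, results_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene imprinting status from the two reciprocal crosses.

    PEG: paternal bias in both crosses.  MEG: maternal bias in both.
    cis_biased: significant bias toward the same genotype allele in both
    crosses (maternal in one direction, paternal in the other) — the
    sequence-attached confounder that must not be counted as imprinting.
    Everything else (including genes biased in only one cross) is ``none``.

    Returns gene_id, status, and the per-cross evidence columns.
    """
    ia = results_a.set_index("gene_id")
    ib = results_b.set_index("gene_id")
    shared = ia.index.intersection(ib.index)
    rows = []
    for gene in shared:
        ra, rb = ia.loc[gene], ib.loc[gene]
        ca, cb = ra["bias_class"], rb["bias_class"]
        biased = {"maternal_biased", "paternal_biased"}
        if ca in biased and cb in biased:
            if ca == "paternal_biased" and cb == "paternal_biased":
                status = "PEG"
            elif ca == "maternal_biased" and cb == "maternal_biased":
                status = "MEG"
            else:
                # opposite parental direction: favored genotype allele?
                fav_a = ra["maternal_allele"] if ca == "maternal_biased" else ra["paternal_allele"]
                fav_b = rb["maternal_allele"] if cb == "maternal_biased" else rb["paternal_allele"]
                status = "cis_biased" if fav_a == fav_b else "none"
        else:
            status = "none"
        rows.append(
            {
                "gene_id": gene,
                "status": status,
                "bias_a": ca,
                "fdr_a": ra["min_fdr"],
                "bias_b": cb,
                "fdr_b": rb["min_fdr"],
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "status", "bias_a", "fdr_a", "bias_b", "fdr_b"]
    )
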