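"""End-to-end demo pipeline over synthetic data.

Runs simulate -> differential expression -> clustering -> allele-specific
expression -> imprinting -> allele-specific methylation -> diurnal on one
seeded synthetic dataset, writes per-stage TSVs plus a summary of
planted-truth recovery, and records a run manifest (parameters, seeds,
output checksums, version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ase import aggregate_gene_ase, call_imprinting, reciprocal_summary
from .asm import compare_reciprocal_asm, region_mean_table
from .clustering import assign_members, fuzzy_cmeans, kmeans_subcluster, standardize_profiles
from .diffexpr import factorial_deg_summary, run_contrasts
from .diurnal import diurnal_summary, reciprocal_timepoint_tests
from .io import write_counts, write_table
from .synthetic import (
    SimulationParams,
    default_design,
    simulate_allele_counts,
    simulate_diurnal,
    simulate_expression,
    simulate_methylomes,
    synthetic_annotation,
)

log = logging.getLogger("triploase")

__all__ = ["demo_params", "run_demo"]


def demo_params(seed: int = 0, n_genes: int = 600) -> SimulationParams:
    """Default planted-truth scenario for the demo pipeline.

    Effect-set sizes follow the factorial hierarchy the analysis is built
    to detect (parent-of-origin > ploidy > hybridity), with strong planted
    allelic and methylation signals for the ASE/ASM stages.
    """
    params = SimulationParams(n_genes=n_genes, seed=seed)
    genes = params.gene_ids()
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(genes))
    n_poe, n_ploidy, n_hyb = int(0.2 * n_genes), int(0.075 * n_genes), int(0.015 * n_genes)
    params.poe_genes = {g: 3.0 for g in shuffled[:n_poe]}
    params.ploidy_genes = {g: 3.0 for g in shuffled[n_poe:n_poe + n_ploidy]}
    params.hybridity_genes = {
        g: 3.0 for g in shuffled[n_poe + n_ploidy:n_poe + n_ploidy + n_hyb]
    }
    rest = shuffled[n_poe + n_ploidy + n_hyb:]
    params.peg_genes = {g: 0.9 for g in rest[:10]}
    params.meg_genes = {g: 0.9 for g in rest[10:20]}
    params.cis_genes = {g: ("L4", 0.9) for g in rest[20:30]}
    params.biased_genes = {g: 0.9 for g in rest[30:45]}
    params.gbm_asm_genes = {g: ("paternal", 0.4) for g in rest[:10]}
    params.allelic_depth_mean = 50.0
    params.diurnal_truth = {
        ("geneD0", "L2xL4"): (1.0, 0.3, 12.0),   # dampened in paternal excess
        ("geneD0", "L4xL2"): (1.0, 0.5, 6.0),
    }
    return params


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_demo(out_dir: str | Path, seed: int = 0, n_genes: int = 600) -> dict:
    """Run the full synthetic pipeline and write a combined report.

    Returns the summary dictionary (also written as ``summary.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    design = default_design()
    params = demo_params(seed=seed, n_genes=n_genes)
    summary: dict = {"seed": seed, "n_genes": n_genes}

    log.info("simulating expression for %d genes, %d samples", n_genes, len(design.samples))
    matrix, expr_truth = simulate_expression(design, params)
    write_counts(matrix, out / "counts.tsv")

    # --- differential expression / factorial contribution ----------------
    de = run_contrasts(matrix, design)
    write_table(de, out / "de.tsv")
    fact = factorial_deg_summary(de)
    write_table(fact.table, out / "de_summary.tsv")
    summary["factorial_ranking"] = fact.ranking
    summary["factorial_score_mode"] = fact.score_mode
    truth_sets = {
        cls: set(expr_truth.loc[expr_truth["effect_class"] == cls, "gene_id"])
        for cls in ("poe", "ploidy", "hybridity")
    }
    poe_sig = set(de.loc[(de["contrast"] == "poe") & de["significant"], "gene_id"])
    if truth_sets["poe"]:
        summary["poe_deg_recall"] = len(poe_sig & truth_sets["poe"]) / len(truth_sets["poe"])
    null_genes = set(matrix.genes) - set().union(*truth_sets.values())
    summary["poe_null_fp_rate"] = len(poe_sig & null_genes) / len(null_genes)

    # --- clustering -------------------------------------------------------
    deg_genes = sorted(set(de.loc[de["significant"], "gene_id"]))
    profiles, flagged = standardize_profiles(matrix, design)
    usable = [g for g in deg_genes if not flagged.get(g, True)]
    if len(usable) >= 5:
        model = fuzzy_cmeans(profiles.loc[usable], c=5, m=2.0, seed=seed)
        labels = assign_members(model, threshold=0.7)
        labels.rename_axis("gene_id").reset_index().to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )
        counts = labels.value_counts()
        biggest = counts.drop("unassigned", errors="ignore").idxmax()
        members = labels.index[labels == biggest]
        sub = kmeans_subcluster(
            profiles.loc[members], k=min(10, len(members)), seed=seed
        )
        sub.rename_axis("gene_id").reset_index().to_csv(
            out / "subclusters.tsv", sep="\t", index=False
        )
        summary["n_clustered_degs"] = int((labels != "unassigned").sum())

    # --- allele-specific expression and imprinting ------------------------
    records, ase_truth = simulate_allele_counts(design, params, groups=["L4xL2", "L2xL4"])
    write_table(records, out / "allele_counts.tsv")
    res_a = aggregate_gene_ase(records, design, "L4xL2")
    res_b = aggregate_gene_ase(records, design, "L2xL4")
    write_table(res_a, out / "ase_L4xL2.tsv")
    write_table(res_b, out / "ase_L2xL4.tsv")
    recip = reciprocal_summary(res_a, res_b)
    write_table(recip.counts, out / "ase_counts.tsv")
    write_table(recip.scatter, out / "ase_scatter.tsv")
    imprint = call_imprinting(res_a, res_b)
    write_table(imprint, out / "imprinting.tsv")
    truth_pegs = set(ase_truth.loc[ase_truth["truth_class"] == "peg", "gene_id"])
    truth_cis = {
        g for g, c in zip(ase_truth["gene_id"], ase_truth["truth_class"]) if c.startswith("cis")
    }
    called_pegs = set(imprint.loc[imprint["status"] == "PEG", "gene_id"])
    if truth_pegs:
        summary["peg_sensitivity"] = len(called_pegs & truth_pegs) / len(truth_pegs)
    summary["cis_called_peg"] = len(called_pegs & truth_cis)
    summary["maternal_share_of_biased"] = recip.maternal_share_of_biased

    # --- allele-specific methylation --------------------------------------
    n_meth_genes = min(n_genes, 60)
    annotation = synthetic_annotation(n_meth_genes, seed=seed)
    meth_gene_ids = {a.gene_id for a in annotation}
    asm_params = demo_params(seed=seed, n_genes=n_genes)
    asm_params.gbm_asm_genes = {
        g: d for g, d in asm_params.gbm_asm_genes.items() if g in meth_gene_ids
    }
    calls_a, _ = simulate_methylomes(annotation, asm_params, paternal_allele="L2")
    asm_params_b = demo_params(seed=seed + 1, n_genes=n_genes)
    asm_params_b.gbm_asm_genes = asm_params.gbm_asm_genes
    calls_b, _ = simulate_methylomes(annotation, asm_params_b, paternal_allele="L4")
    asm_a = region_mean_table(calls_a, annotation, alleles=("L2", "L4"), cross="L4xL2")
    asm_b = region_mean_table(calls_b, annotation, alleles=("L2", "L4"), cross="L2xL4")
    write_table(pd.concat([asm_a, asm_b]), out / "asm.tsv")
    body_cg_a = asm_a[(asm_a["region"] == "body") & (asm_a["context"] == "CG")]
    body_cg_b = asm_b[(asm_b["region"] == "body") & (asm_b["context"] == "CG")]
    wtest = compare_reciprocal_asm(body_cg_a["asm_diff"], body_cg_b["asm_diff"])
    summary["asm_body_cg_wilcoxon_p"] = wtest["p"]

    # --- diurnal -----------------------------------------------------------
    series = simulate_diurnal(params, genes=["geneD0"], groups=["L2xL4", "L4xL2"])
    write_table(series, out / "diurnal.tsv")
    sa = series[series["group"] == "L2xL4"]
    sb = series[series["group"] == "L4xL2"]
    summary["diurnal_L2xL4"] = diurnal_summary(sa)
    summary["diurnal_L4xL2"] = diurnal_summary(sb)
    ztests = reciprocal_timepoint_tests(sa, sb)
    write_table(ztests, out / "diurnal_tests.tsv")

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)

    manifest = {
        "version": __version__,
        "seed": seed,
        "n_genes": n_genes,
        "outputs": {
            p.name: _checksum(p) for p in sorted(out.iterdir()) if p.suffix in (".tsv", ".json")
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return summary
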