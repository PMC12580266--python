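"""Synthetic data with the statistical structure the analysis assumes.

Every generator plants a known ground truth and returns it alongside the
data, so each downstream stage can be tested for recovery:

* :func:`simulate_expression` — negative-binomial counts over the full
  factorial group structure (reciprocal 2x/3x/4x hybrids plus parental
  selfs, 3 replicates each), with multiplicative parent-of-origin, ploidy
  and hybridity effects on designated gene sets.
* :func:`simulate_allele_counts` — per-SNP allelic reads under the parental
  dosage binomial (tetraploid-parent allele expected at 2/3 in a triploid),
  with planted biased genes, imprinted genes (bias attached to parent of
  origin, i.e. reproduced in both reciprocal crosses) and cis-regulated
  genes (bias attached to one genotype allele in both crosses).
* :func:`simulate_methylomes` — allele-resolved cytosine calls in the CG,
  CHG and CHH contexts across upstream/body/downstream gene regions, with
  planted gene-body CG asymmetry between alleles.
* :func:`simulate_diurnal` — cosinor-shaped relative-expression series at
  ZT0/6/12/18 with replicate noise.

All randomness flows from a single integer seed; identical parameters and
seed give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .types import (
    ALLELE_COUNT_COLUMNS,
    METHYL_CALL_COLUMNS,
    CrossDesign,
    ExpressionMatrix,
    GeneAnnotation,
    GroupClass,
    ValidationError,
)

__all__ = [
    "SimulationParams",
    "default_design",
    "simulate_expression",
    "simulate_allele_counts",
    "simulate_methylomes",
    "simulate_diurnal",
    "synthetic_annotation",
]

ZT_POINTS = (0, 6, 12, 18)


def default_design(n_replicates: int = 3) -> CrossDesign:
    """The study's factorial group structure.

    Two diploid (L2, R2) and two tetraploid (L4, R4) parental genotypes;
    reciprocal diploid hybrids, reciprocal maternal-/paternal-excess
    triploids, reciprocal tetraploid hybrids, and the four parental selfs.
    Three biological replicates per group by default.
    """
    crosses = [
        ("R2xL2", "R2", "L2"), ("L2xR2", "L2", "R2"),            # 2x hybrids
        ("L4xL2", "L4", "L2"), ("R4xL2", "R4", "L2"),            # 3x maternal excess
        ("L2xL4", "L2", "L4"), ("L2xR4", "L2", "R4"),            # 3x paternal excess
        ("L4xR4", "L4", "R4"), ("R4xL4", "R4", "L4"),            # 4x hybrids
        ("L2self", "L2", "L2"), ("L4self", "L4", "L4"),          # parental selfs
        ("R2self", "R2", "R2"), ("R4self", "R4", "R4"),
    ]
    groups = {
        name: {
            "maternal": mat,
            "paternal": pat,
            "samples": [f"{name}_{i + 1}" for i in range(n_replicates)],
        }
        for name, mat, pat in crosses
    }
    return CrossDesign(groups=groups, ploidy_of_parent={"L2": 2, "L4": 4, "R2": 2, "R4": 4})


@dataclass
class SimulationParams:
    """Ground-truth parameters for all generators.

    Effect sizes are log2 fold changes applied multiplicatively to
    negative-binomial means.  Allelic fractions refer to the favored
    allele's share of allelic reads.
    """

    n_genes: int = 2000
    seed: int = 0

    # expression
    mean_library_size: float = 1e6
    dispersion: float = 0.05
    poe_genes: dict = dc_field(default_factory=dict)        # gene -> log2 effect, 3x(p) vs 3x(m)
    ploidy_genes: dict = dc_field(default_factory=dict)     # gene -> log2 effect, 3x vs parents
    hybridity_genes: dict = dc_field(default_factory=dict)  # gene -> log2 effect, hybrids vs selfs

    # allelic counts
    snps_per_gene_mean: float = 3.0
    allelic_depth_mean: float = 30.0
    biased_genes: dict = dc_field(default_factory=dict)     # gene -> maternal fraction (per cross)
    peg_genes: dict = dc_field(default_factory=dict)        # gene -> paternal fraction, both crosses
    meg_genes: dict = dc_field(default_factory=dict)        # gene -> maternal fraction, both crosses
    cis_genes: dict = dc_field(default_factory=dict)        # gene -> (genotype allele, fraction)

    # methylation
    methyl_coverage_mean: float = 10.0
    sites_per_kb: dict = dc_field(
        default_factory=lambda: {"CG": 8.0, "CHG": 6.0, "CHH": 20.0}
    )
    baseline_levels: dict = dc_field(
        default_factory=lambda: {
            # plant-typical region baselines per context
            ("upstream", "CG"): 0.15, ("body", "CG"): 0.40, ("downstream", "CG"): 0.15,
            ("upstream", "CHG"): 0.10, ("body", "CHG"): 0.10, ("downstream", "CHG"): 0.10,
            ("upstream", "CHH"): 0.05, ("body", "CHH"): 0.05, ("downstream", "CHH"): 0.05,
        }
    )
    gbm_asm_genes: dict = dc_field(default_factory=dict)    # gene -> (allele role, +delta body mCG)

    # diurnal
    diurnal_mesor: float = 1.0
    diurnal_amplitude: float = 0.5
    diurnal_peak_zt: float = 12.0
    diurnal_replicate_sd: float = 0.05
    diurnal_truth: dict = dc_field(default_factory=dict)    # (gene, group) -> (mesor, amp, peak)

    def gene_ids(self) -> list[str]:
        return [f"gene{i:05d}" for i in range(self.n_genes)]

    def validate(self) -> None:
        known = set(self.gene_ids())
        for name, eff in (
            ("poe_genes", self.poe_genes),
            ("ploidy_genes", self.ploidy_genes),
            ("hybridity_genes", self.hybridity_genes),
            ("biased_genes", self.biased_genes),
            ("peg_genes", self.peg_genes),
            ("meg_genes", self.meg_genes),
            ("cis_genes", self.cis_genes),
            ("gbm_asm_genes", self.gbm_asm_genes),
        ):
            unknown = set(eff) - known
            if unknown:
                raise ValidationError(f"{name}: unknown genes {sorted(unknown)[:3]}")
        for g, f in {**self.biased_genes, **self.peg_genes, **self.meg_genes}.items():
            if not 0.0 <= f <= 1.0:
                raise ValidationError(f"allelic fraction for {g} outside [0, 1]")
        overlap = set(self.peg_genes) & set(self.cis_genes)
        if overlap:
            raise ValidationError(f"genes planted both PEG and cis: {sorted(overlap)[:3]}")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with mean/dispersion parameterization (Var = mu + disp*mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_expression(
    design: CrossDesign, params: SimulationParams
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate a raw-count matrix with planted factorial effects.

    Parent-of-origin effects are applied symmetrically (paternal-excess
    triploids x 2^(+lfc/2), maternal-excess x 2^(-lfc/2)) so the planted
    reciprocal fold change is 2^lfc while the pooled triploid mean stays
    near baseline.  Ploidy effects multiply all triploids; hybridity effects
    multiply all hybrid groups relative to parental selfs.

    Returns the count matrix and a truth table (gene, effect class, log2
    effect) for the planted genes.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    genes = params.gene_ids()
    gene_index = {g: i for i, g in enumerate(genes)}

    # per-gene baseline relative abundance (log-normal), normalized to library size
    base = rng.lognormal(mean=0.0, sigma=1.0, size=params.n_genes)
    base = base / base.sum() * params.mean_library_size

    samples = design.samples
    mu = np.tile(base[:, None], (1, len(samples)))
    cls = np.array([design.class_of(design.group_of(s)) for s in samples])
    is_3xp = cls == GroupClass.TRIPLOID_PATERNAL
    is_3xm = cls == GroupClass.TRIPLOID_MATERNAL
    is_3x = is_3xp | is_3xm
    is_hybrid = cls != GroupClass.PARENTAL_SELF

    for g, lfc in params.poe_genes.items():
        i = gene_index[g]
        mu[i, is_3xp] *= 2.0 ** (lfc / 2.0)
        mu[i, is_3xm] *= 2.0 ** (-lfc / 2.0)
    for g, lfc in params.ploidy_genes.items():
        mu[gene_index[g], is_3x] *= 2.0 ** lfc
    for g, lfc in params.hybridity_genes.items():
        mu[gene_index[g], is_hybrid] *= 2.0 ** lfc

    counts = _nb_draw(rng, mu, params.dispersion)
    matrix = ExpressionMatrix(
        values=pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"), columns=samples),
        normalized=False,
    )
    truth_rows = (
        [(g, "poe", lfc) for g, lfc in params.poe_genes.items()]
        + [(g, "ploidy", lfc) for g, lfc in params.ploidy_genes.items()]
        + [(g, "hybridity", lfc) for g, lfc in params.hybridity_genes.items()]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "effect_class", "log2_effect"])
    return matrix, truth


def _tetraploid_fraction_null(design: CrossDesign, group: str) -> tuple[str, float]:
    """(allele label whose fraction is simulated, its null fraction) for a group."""
    mat, pat = design.maternal_parent(group), design.paternal_parent(group)
    pm = design.ploidy_of_parent[mat]
    pp = design.ploidy_of_parent[pat]
    if pm == 4 and pp == 2:
        return mat, 2.0 / 3.0
    if pm == 2 and pp == 4:
        return pat, 2.0 / 3.0
    return mat, 0.5


def simulate_allele_counts(
    design: CrossDesign,
    params: SimulationParams,
    groups: list[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-SNP allelic read counts for hybrid groups.

    Under the null, the tetraploid parent's allele draws reads at fraction
    2/3 in a triploid (2:1 genome dosage) and 1/2 in balanced crosses.
    Planted classes override the null fraction:

    * ``biased_genes`` — maternal fraction per cross (not reciprocal-consistent),
    * ``peg_genes``/``meg_genes`` — paternal/maternal fraction in *both*
      reciprocal crosses (parent-of-origin-attached),
    * ``cis_genes`` — fraction for one *genotype* allele in both crosses.

    Returns (records, truth).  Records follow the allele-count table schema;
    ``allele_a``/``allele_b`` carry the two parental genotype labels in
    sorted order.  Truth lists gene, class and planted fraction.
    """
    params.validate()
    rng = np.random.default_rng(params.seed + 1)
    genes = params.gene_ids()
    if groups is None:
        groups = design.groups_of_class(
            GroupClass.TRIPLOID_MATERNAL, GroupClass.TRIPLOID_PATERNAL
        )

    n_snps = rng.poisson(params.snps_per_gene_mean, size=params.n_genes)
    rows: list[tuple] = []
    for gi, gene in enumerate(genes):
        if n_snps[gi] == 0:
            continue
        positions = gi * 100000 + np.arange(1, n_snps[gi] + 1) * 100
        for group in groups:
            mat = design.maternal_parent(group)
            pat = design.paternal_parent(group)
            ref_allele, f = _tetraploid_fraction_null(design, group)
            if gene in params.biased_genes:
                ref_allele, f = mat, params.biased_genes[gene]
            if gene in params.meg_genes:
                ref_allele, f = mat, params.meg_genes[gene]
            if gene in params.peg_genes:
                ref_allele, f = pat, params.peg_genes[gene]
            if gene in params.cis_genes:
                allele, frac = params.cis_genes[gene]
                if allele not in (mat, pat):
                    raise ValidationError(
                        f"cis allele {allele!r} for {gene} is not a parent of {group}"
                    )
                ref_allele, f = allele, frac
            a_label, b_label = sorted((mat, pat))
            for sample in design.samples_of(group):
                totals = rng.poisson(params.allelic_depth_mean, size=len(positions))
                ref_reads = rng.binomial(totals, f)
                if ref_allele == a_label:
                    ra, rb = ref_reads, totals - ref_reads
                else:
                    ra, rb = totals - ref_reads, ref_reads
                for pos, x, y in zip(positions, ra, rb):
                    rows.append((gene, "chr1", int(pos), a_label, b_label, int(x), int(y), sample))

    records = pd.DataFrame(rows, columns=ALLELE_COUNT_COLUMNS)
    truth_rows = (
        [(g, "biased", f) for g, f in params.biased_genes.items()]
        + [(g, "peg", f) for g, f in params.peg_genes.items()]
        + [(g, "meg", f) for g, f in params.meg_genes.items()]
        + [(g, f"cis:{a}", f) for g, (a, f) in params.cis_genes.items()]
    )
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "truth_class", "fraction"])
    return records, truth


def synthetic_annotation(
    n_genes: int,
    gene_length: int = 2000,
    spacing: int = 10000,
    flank: int = 2000,
    seed: int = 0,
) -> list[GeneAnnotation]:
    """Evenly spaced single-chromosome gene models with random strands."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        start = flank + 1 + i * (gene_length + spacing)
        end = start + gene_length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        tss, tts = (start, end) if strand == "+" else (end, start)
        genes.append(
            GeneAnnotation(gene_id=f"gene{i:05d}", chrom="chr1", strand=strand, tss=tss, tts=tts)
        )
    return genes


def simulate_methylomes(
    annotation: list[GeneAnnotation],
    params: SimulationParams,
    alleles: tuple[str, str] = ("L2", "L4"),
    samples: tuple[str, ...] = ("rep1", "rep2", "rep3"),
    flank: int = 2000,
    paternal_allele: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate allele-resolved cytosine calls around each annotated gene.

    Cytosines are placed uniformly in the upstream flank, gene body and
    downstream flank at per-context densities; coverage is Poisson and
    methylated reads binomial at the region/context baseline level.  Genes
    in ``params.gbm_asm_genes`` get a +delta offset on the designated
    allele's body CG level ("paternal" resolves via ``paternal_allele``).

    Returns (calls, truth) where truth lists gene, allele and planted delta.
    """
    rng = np.random.default_rng(params.seed + 2)
    rows: list[tuple] = []
    truth_rows: list[tuple] = []
    for gene in annotation:
        left, right = gene.start, gene.end
        regions = {
            "body": (left, right),
            "upstream": (left - flank, left - 1) if gene.strand == "+" else (right + 1, right + flank),
            "downstream": (right + 1, right + flank) if gene.strand == "+" else (left - flank, left - 1),
        }
        planted = params.gbm_asm_genes.get(gene.gene_id)
        offset_allele, delta = (None, 0.0)
        if planted is not None:
            offset_allele, delta = planted
            if offset_allele == "paternal":
                if paternal_allele is None:
                    raise ValidationError(
                        "gbM offset designated 'paternal' but no paternal_allele given"
                    )
                offset_allele = paternal_allele
            truth_rows.append((gene.gene_id, offset_allele, delta))
        for region, (lo, hi) in regions.items():
            length = hi - lo + 1
            for context, per_kb in params.sites_per_kb.items():
                n_sites = rng.poisson(per_kb * length / 1000.0)
                if n_sites == 0:
                    continue
                pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_sites, replace=False))
                strands = np.where(rng.random(n_sites) < 0.5, "+", "-")
                base_level = params.baseline_levels[(region, context)]
                for allele in alleles:
                    level = base_level
                    if region == "body" and context == "CG" and allele == offset_allele:
                        level = min(1.0, base_level + delta)
                    for sample in samples:
                        cov = rng.poisson(params.methyl_coverage_mean, size=n_sites)
                        meth = rng.binomial(cov, level)
                        for p, s, m, t in zip(pos, strands, meth, cov):
                            rows.append(
                                ("chr1", int(p), s, context, allele, int(m), int(t), sample)
                            )
    calls = pd.DataFrame(rows, columns=METHYL_CALL_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=["gene_id", "allele", "body_cg_delta"])
    return calls, truth


def simulate_diurnal(
    params: SimulationParams,
    genes: list[str] | None = None,
    groups: list[str] | None = None,
    n_replicates: int = 3,
) -> pd.DataFrame:
    """Cosinor-shaped relative-expression series at ZT0/6/12/18.

    value(t) = mesor + amplitude * cos(2*pi*(t - peak)/24) plus additive
    Gaussian replicate noise.  Per-(gene, group) truth overrides come from
    ``params.diurnal_truth``; otherwise the global defaults apply.

    Returns a long DataFrame (gene, group, zt, replicate, value).
    """
    rng = np.random.default_rng(params.seed + 3)
    if genes is None:
        genes = ["geneD0"]
    if groups is None:
        groups = ["L2xL4", "L4xL2"]
    rows = []
    for gene in genes:
        for group in groups:
            mesor, amp, peak = params.diurnal_truth.get(
                (gene, group),
                (params.diurnal_mesor, params.diurnal_amplitude, params.diurnal_peak_zt),
            )
            for zt in ZT_POINTS:
                clean = mesor + amp * np.cos(2.0 * np.pi * (zt - peak) / 24.0)
                noise = rng.normal(0.0, params.diurnal_replicate_sd, size=n_replicates)
                for rep, v in enumerate(clean + noise, start=1):
                    rows.append((gene, group, zt, rep, max(float(v), 1e-9)))
    return pd.DataFrame(rows, columns=["gene_id", "group", "zt", "replicate", "value"])
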