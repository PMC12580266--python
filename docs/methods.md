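# Methods

This note documents the statistical models behind `triploase`, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical choices made where the design was open.

## The cross design and the dosage null

All parent-of-origin resolution flows through the `CrossDesign`: allele
records carry *genotype-of-origin* labels (e.g. L2, L4), never
maternal/paternal, because the same genotype allele is maternal in one
reciprocal cross and paternal in the other. Group classes are derived
from parental ploidies: a self has identical parents; 2x×2x and 4x×4x
crosses are balanced hybrids; a 4x mother × 2x father gives a
maternal-excess triploid and the reciprocal a paternal-excess triploid.

In a triploid, the tetraploid parent contributes two of three genome
copies, so absent any regulation its allele should draw reads at
*f* = 2/3; balanced crosses expect 1/2. This dosage null is the anchor of
the ASE module: testing against 1/2 in a triploid would misread genome
dosage as regulatory bias.

## Allele-specific expression

Per SNP, replicate read counts are pooled by summation (the informative-
SNP filter of ≥ 10 total reads is defined across all biological
replicates, which implies pooling); per-replicate concordance is a
diagnostic, not a filter. Each pooled SNP is tested with the two-sided
exact binomial test in the minimum-likelihood convention (sum of
probabilities of all outcomes no more likely than the observed one;
`scipy.stats.binomtest`). At the modal outcome (e.g. 20:10 under 2/3)
the p-value is exactly 1.

BH adjustment defaults to all tested SNPs of a cross, since the scope of
the correction is otherwise ambiguous; a per-gene scope is available
(`fdr_scope`). A gene is an ASEG if any SNP reaches FDR < α (default
0.05). Direction comes from the pooled gene-level counts rather than the
best SNP; genes whose significant SNPs disagree in direction are classed
`conflicting` and excluded from biased tallies. Percentages are reported
against the informative-gene denominator (genes passing both the SNP and
read filters), so a gene with no informative SNP is *unassayable*, not a
miss — sensitivity figures in the tests and acceptance script are
computed over assayable genes.

Imprinting calls require significant, same-parent bias in both reciprocal
crosses (PEG paternal, MEG maternal). Bias following one genotype allele
in both directions is `cis_biased` — the sequence-attached confounder a
reciprocal design exists to exclude — and is never counted as imprinted.

Known limitation: no mapping-bias correction is applied to the 2/3 null;
reference-biased alignment would shift all fractions coherently and
should be assessed upstream.

## Differential expression substitute

The DE test is deliberately simple and fully specified: per-sample size
factors by median-of-ratios (median over genes, expressed in all samples,
of count/geometric-mean; a totals mode exists), then a per-gene Wald test
on the log ratio of normalized group means. The NB variance model
Var = μ + φμ² gives the delta-method variance of a log group mean as
(1/μ + φ)/n; φ is the method-of-moments estimate (s² − m)/m² pooled
across the two groups by degrees of freedom and floored at 1e-8. With
3 + 3 replicates the dispersion estimate is noisy and raw Wald p-values
alone would be anti-conservative; the joint DEG rule — |log₂FC| ≥ 1 *and*
P < 0.05, with no multiple-testing correction — is what is calibrated,
and the null simulation keeps the significant fraction below 7% (observed
≈ 0% at the default depth, because a true fold change ≥ 2 is far outside
the sampling spread of the log ratio). When a group mean is zero, a
pseudocount of 1 enters the fold change; fewer than 2 replicates on a
side yields a fold change with a missing p-value and no call. log₂FC is
antisymmetric under group exchange by construction.

The factorial summary counts DEGs per contrast (up/down split by the sign
of log₂FC, side B over side A) and ranks factors by their score across
member contrasts — `max` by default, mirroring per-comparison reporting;
`sum` pools a class; the mode used is recorded in the output. Ties break
alphabetically. The high/low-relatedness triploid contrast takes a
user-supplied group map, as relatedness is a property of the pedigree,
not the count matrix.

## Clustering

Profiles are z-scores of *group means* (one value per cross group,
ddof = 1), matching the group-axis presentation of factorial designs;
replicate-level standardization is available behind a flag. Constant
genes are flagged and excluded. Fuzzy c-means uses the standard Bezdek
updates (Euclidean distance, u_ij = 1/Σ_k (d_ij/d_ik)^{2/(m−1)}, centers
Σu^m x/Σu^m) with k-means++-style seeding from an explicit seed,
tolerance 1e-6 on the objective, and exact-zero distances resolved to
full membership. The objective Σ u^m d² is non-increasing across
iterations (asserted in tests). Genes are assigned to the argmax cluster
only when max membership ≥ 0.7 (inclusive). The cluster "highest in
paternal-excess triploids" is chosen as the cluster whose center attains
its maximum at that group. Sub-clustering is scikit-learn's k-means
(Lloyd, best of n_init seeded restarts).

## Allele-specific methylation

Cytosine levels are methylated/total reads at ≥ 5 reads, pooled across
replicates per (site, allele). Region means are unweighted means of site
levels — matching the per-cytosine level definition — with a read-weighted
mode unnecessary for the shipped analyses; regions with fewer than
`min_sites = 3` qualifying cytosines are missing (no floor is inherent to
the statistic, but single-site regions would dominate ASM-difference
distributions). Regions are strand-aware: upstream = 2 kb before the TSS
in transcription orientation, body = TSS→TTS, downstream = 2 kb after the
TTS; the three partition the extended locus without overlap. CG-dyad
strand collapsing is off by default (calls arrive per strand) and the
partition logic never infers context from sequence.

The ASM difference |mean_L2 − mean_L4| is symmetric and bounded in [0,1].
Reciprocal crosses are compared on their ASM-difference distributions
with a two-sided rank-sum test — exact when both sides have ≤ 25 values
and no ties, otherwise the normal approximation with tie correction —
annotated at the displayed tiers († for P < 0.1). The comparison is
unpaired by default (the two crosses need not share assayable genes); a
paired signed-rank mode exists.

Metagene profiles bin flanks at fixed width (2000/flank_bins bp) and the
body into proportional bins; each gene contributes its per-bin mean
before the unweighted cross-gene average, so long genes do not dominate;
minus-strand genes are reversed to 5'→3'. The gbM–expression association
is a Spearman correlation between per-gene (paternal − maternal) body-CG
level and the paternal allelic read fraction; fewer than 3 pairs is an
error, a constant margin yields a missing correlation.

## Diurnal module

2^−ΔΔCt is the closed form ΔCt = Ct_target − Ct_reference,
ΔΔCt = ΔCt_sample − ΔCt_calibrator, fold = 2^−ΔΔCt; normalizing a sample
against itself gives exactly 1. With only four Zeitgeber times per cycle,
peak/nadir are the argmax/argmin of per-ZT replicate means (ties toward
the earlier ZT, flagged), amplitude is max − min of those means — i.e.
peak-to-trough, 2A for a cosinor whose extremes are sampled — and
relative amplitude (max−min)/mean is scale-invariant. No rhythmicity or
period estimation is attempted from a single cycle; a least-squares
cosinor fit is provided as a diagnostic only. Per-ZT reciprocal
comparisons use a two-sided Welch t-test (unequal variances are plausible
at 3 replicates; a rank-sum option exists) with star tiers at
0.05/0.01/0.001. Note that at 3 + 3 replicates the Welch degrees of
freedom are ≈ 2, so even a 4-fold separation typically lands near
p ≈ 3×10⁻³ (two stars), not below 10⁻³.

## Synthetic data: what it emulates and what it does not

The generator reproduces the *statistical structure* the analysis
assumes, with planted truth returned alongside every output:

- **Expression**: NB counts (shared per-gene dispersion 0.05 across
  groups, log-normal baseline abundances scaled to a 10⁶ library) over
  the full factorial design — reciprocal 2x, 3x(m), 3x(p), 4x hybrids and
  the four parental selfs, 3 replicates each. POE effects are applied
  symmetrically (3x(p) × 2^{+lfc/2}, 3x(m) × 2^{−lfc/2}) so the planted
  reciprocal fold change is 2^lfc without shifting the pooled triploid
  mean into the ploidy contrasts; ploidy effects multiply all triploids,
  hybridity effects all hybrids.
- **Allelic counts**: per-SNP totals Poisson around a per-sample depth
  (default 30; SNPs per gene Poisson mean 3, so ≈5% of genes draw none
  and are unassayable), favored-allele reads binomial at 2/3 (triploid
  null), or at the planted fraction for biased genes (per-cross), PEGs/
  MEGs (parent-attached, both crosses), and cis genes (genotype-attached,
  both crosses) — the caller's positive and negative controls. Allelic
  depth is simulated independently of total gene expression, since the
  ASE test consumes only allelic counts.
- **Methylomes**: cytosines placed at plant-typical densities and
  baselines (body CG 0.40, flank CG 0.15, CHG 0.10, CHH 0.05), Poisson
  coverage (mean 10), binomial methylated reads, and a planted +Δ body-CG
  offset on a designated allele for gbM-ASM genes.
- **Diurnal**: cosinor mesor + A·cos(2π(t − peak)/24) at ZT0/6/12/18 with
  additive Gaussian replicate noise (SD 0.05 at mesor 1).

Not emulated: mapping bias and allele-dropout, overdispersed or
correlated SNPs within a gene, distributional coupling of expression and
allelic depth, sequence-determined cytosine positions, batch effects.
Passing tests therefore demonstrate correctness of the statistics under
the stated models, not robustness to alignment artifacts.

## Problem sizes and determinism

Tests and the acceptance script use desk-scale sizes chosen to make their
statistical assertions well-powered: 2000 genes × 36 samples for DE
calibration and ranking recovery (100 seeded replicates), ~10,000 SNPs
for FDR calibration, 1000 genes (50 PEG + 50 cis planted) at depth
50/SNP for imprinting discrimination, 500 replicates for Wilcoxon null
uniformity, 120 profiles for clustering recovery. Every generator takes
one integer seed; identical parameters and seed give byte-identical
outputs, and the demo pipeline records seeds, parameters and output
checksums in a run manifest.
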