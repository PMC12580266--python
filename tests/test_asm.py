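"""Site levels, region means, ASM differences, metagene profiles, and the
gene-body-methylation/expression association."""

import numpy as np
import pandas as pd
import pytest

from triploase import (
    GeneAnnotation,
    SimulationParams,
    asm_difference,
    compare_reciprocal_asm,
    gbm_expression_association,
    metagene_profile,
    region_mean,
    region_mean_table,
    region_specs,
    simulate_methylomes,
    site_level,
    synthetic_annotation,
)
from triploase.asm import add_site_levels, RegionSpec
from triploase.types import METHYL_CALL_COLUMNS, ValidationError


def _calls(rows):
    return pd.DataFrame(rows, columns=METHYL_CALL_COLUMNS)


class TestSiteLevel:
    @pytest.mark.parametrize(
        "meth,total,expected",
        [(5, 10, 0.5), (0, 8, 0.0), (5, 5, 1.0)],
    )
    def test_ratio(self, meth, total, expected):
        assert site_level(meth, total) == expected

    def test_below_coverage_floor_excluded(self):
        assert site_level(2, 4) is None

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            site_level(5, 4)

    def test_replicates_pooled_before_floor(self):
        rows = [("chr1", 10, "+", "CG", "L2", 1, 2, f"s{i}") for i in range(3)]
        pooled = add_site_levels(_calls(rows))
        assert len(pooled) == 1
        assert pooled.iloc[0]["level"] == pytest.approx(0.5)


class TestRegions:
    def test_partition_covers_without_overlap(self):
        for strand, tss, tts in (("+", 5001, 7000), ("-", 7000, 5001)):
            gene = GeneAnnotation("g", "chr1", strand, tss, tts)
            specs = region_specs(gene, flank=2000)
            ivals = sorted((s.start, s.end) for s in specs.values())
            assert ivals[0][0] == 3001 and ivals[-1][1] == 9000
            for (a, b), (c, d) in zip(ivals, ivals[1:]):
                assert b + 1 == c  # adjacent, no overlap, no gap

    def test_upstream_is_before_tss_in_transcription_orientation(self):
        minus = GeneAnnotation("g", "chr1", "-", 7000, 5001)
        up = region_specs(minus, flank=2000)["upstream"]
        assert (up.start, up.end) == (7001, 9000)

    def test_region_mean_examples(self):
        rows = [
            ("chr1", 100, "+", "CG", "L2", 2, 10, "s1"),   # 0.2
            ("chr1", 150, "+", "CG", "L2", 4, 10, "s1"),   # 0.4
            ("chr1", 200, "+", "CG", "L2", 6, 10, "s1"),   # 0.6
        ]
        table = add_site_levels(_calls(rows))
        spec = RegionSpec("g", "body", "chr1", 50, 250)
        assert region_mean(table, spec, "CG", "L2") == pytest.approx(0.4)
        assert region_mean(table, spec, "CG", "L2", min_sites=4) is None
        # two qualifying sites with the default floor of 3 -> missing
        assert region_mean(table.iloc[:2], spec, "CG", "L2") is None

    def test_region_mean_recovers_planted_level(self):
        rng = np.random.default_rng(0)
        rows = []
        for i in range(50):
            cov = 20
            meth = rng.binomial(cov, 0.8)
            rows.append(("chr1", 100 + i, "+", "CG", "L2", int(meth), cov, "s1"))
        table = add_site_levels(_calls(rows))
        spec = RegionSpec("g", "body", "chr1", 1, 1000)
        assert region_mean(table, spec, "CG", "L2") == pytest.approx(0.8, abs=0.03)


class TestAsmDifference:
    @pytest.mark.parametrize("a,b,expected", [(0.8, 0.1, 0.7), (0.5, 0.5, 0.0)])
    def test_absolute_difference(self, a, b, expected):
        assert asm_difference(a, b) == pytest.approx(expected)

    def test_missing_allele_gives_missing(self):
        assert asm_difference(None, 0.5) is None
        assert asm_difference(0.5, None) is None

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(200):
            a, b = rng.random(2)
            d = asm_difference(a, b)
            assert d == asm_difference(b, a)
            assert 0.0 <= d <= 1.0


class TestReciprocalComparison:
    def test_identical_samples_not_significant(self):
        x = np.linspace(0.0, 0.5, 30)
        res = compare_reciprocal_asm(x, x.copy())
        assert res["p"] > 0.1 and res["annotation"] == "ns"

    def test_planted_shift_detected_and_matches_permutation_oracle(self):
        """+0.2 location shift, n=100/side, SD 0.1: p < 0.001, consistent
        with a 10,000-draw permutation oracle on the rank-sum statistic."""
        rng = np.random.default_rng(2)
        a = rng.normal(0.3, 0.1, 100)
        b = rng.normal(0.5, 0.1, 100)
        res = compare_reciprocal_asm(a, b)
        assert res["p"] < 0.001 and res["annotation"] == "†"

        pooled = np.concatenate([a, b])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[:100].sum()
        perm = np.array([
            rng.permutation(ranks)[:100].sum() for _ in range(10_000)
        ])
        p_perm = (np.abs(perm - perm.mean()) >= abs(obs - perm.mean())).mean()
        assert p_perm < 0.001

    def test_exact_small_sample_branch(self):
        a = [0.1, 0.2, 0.3]
        b = [0.6, 0.7, 0.8]
        res = compare_reciprocal_asm(a, b)
        # exact two-sided rank-sum p for complete separation at 3v3 = 0.1
        assert res["p"] == pytest.approx(0.1)

    def test_empty_side_rejected(self):
        with pytest.raises(ValidationError):
            compare_reciprocal_asm([], [0.1])

    def test_paired_mode(self):
        a = np.full(20, 0.3)
        res = compare_reciprocal_asm(a, a.copy(), paired=True)
        assert res["p"] == 1.0

    def test_null_pvalues_uniform(self):
        """Both crosses from the same distribution, 500 replicates: the
        rank-sum p-values pass a KS test for uniformity."""
        from scipy import stats

        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(500):
            a = rng.normal(0.4, 0.1, 60)
            b = rng.normal(0.4, 0.1, 60)
            pvals.append(compare_reciprocal_asm(a, b)["p"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestMetagene:
    def test_uniform_methylome_is_flat(self):
        ann = synthetic_annotation(12, seed=4)
        p = SimulationParams(n_genes=12, seed=4, methyl_coverage_mean=20.0)
        p.baseline_levels = {k: 0.5 for k in p.baseline_levels}
        calls, _ = simulate_methylomes(ann, p)
        prof = metagene_profile(calls, ann, context="CG", allele="L2")
        lv = prof["mean_level"].dropna()
        # binomial sampling spread around 0.5 at this coverage/site density
        assert (np.abs(lv - 0.5) < 3 * lv.std() + 0.05).all()

    def test_body_only_signal_elevates_exactly_body_bins(self):
        """Body level 0.8, flanks 0.05: elevated bins are the body segment."""
        ann = synthetic_annotation(15, seed=5)
        p = SimulationParams(n_genes=15, seed=5, methyl_coverage_mean=25.0)
        p.baseline_levels = {
            (region, ctx): (0.8 if region == "body" else 0.05)
            for (region, ctx) in p.baseline_levels
        }
        calls, _ = simulate_methylomes(ann, p)
        prof = metagene_profile(calls, ann, context="CG", allele="L2")
        body = prof[prof["segment"] == "body"]["mean_level"]
        flank = prof[prof["segment"] != "body"]["mean_level"]
        assert (body > 0.5).all()
        assert (flank < 0.3).all()

    def test_minus_strand_upstream_signal_lands_in_upstream_bins(self):
        gene = GeneAnnotation("g", "chr1", "-", 7000, 5001)
        rows = []
        # genomic positions just right of the gene = transcriptional upstream
        for i in range(30):
            rows.append(("chr1", 7100 + i * 20, "+", "CG", "L2", 8, 10, "s1"))
        prof = metagene_profile(_calls(rows), [gene], context="CG", allele="L2")
        covered = prof[prof["n_genes"] > 0]
        assert set(covered["segment"]) == {"upstream"}


class TestGbmAssociation:
    def test_planted_coupling_detected(self):
        """Methylation offset proportional to expression bias over 200
        genes gives a strong positive rank correlation."""
        rng = np.random.default_rng(6)
        frac = rng.uniform(0.3, 0.95, 200)
        meth = 0.5 * (frac - 0.5) + rng.normal(0, 0.05, 200)
        res = gbm_expression_association(
            pd.Series(meth, index=[f"g{i}" for i in range(200)]),
            pd.Series(frac, index=[f"g{i}" for i in range(200)]),
        )
        assert res["rho"] > 0.5 and res["p"] < 0.01 and res["n"] == 200

    def test_constant_difference_reported_missing(self):
        idx = ["g1", "g2", "g3"]
        res = gbm_expression_association(
            pd.Series([0.2, 0.2, 0.2], index=idx), pd.Series([0.5, 0.6, 0.7], index=idx)
        )
        assert res["missing"] and np.isnan(res["rho"])

    def test_too_few_pairs_rejected(self):
        idx = ["g1", "g2"]
        with pytest.raises(ValidationError, match="at least 3"):
            gbm_expression_association(
                pd.Series([0.1, 0.2], index=idx), pd.Series([0.5, 0.6], index=idx)
            )


class TestRegionMeanTable:
    def test_planted_body_offset_appears_in_table(self):
        ann = synthetic_annotation(8, seed=7)
        planted = {a.gene_id for a in ann[:3]}
        p = SimulationParams(
            n_genes=8, seed=7, methyl_coverage_mean=30.0,
            gbm_asm_genes={g: ("L4", 0.5) for g in planted},
        )
        calls, _ = simulate_methylomes(ann, p)
        table = region_mean_table(calls, ann, alleles=("L2", "L4"), cross="L2xL4")
        body_cg = table[(table["region"] == "body") & (table["context"] == "CG")]
        body_cg = body_cg.set_index("gene_id")
        for g in planted:
            assert body_cg.loc[g, "asm_diff"] > 0.3
        others = body_cg.drop(index=planted)["asm_diff"].dropna()
        assert (others < 0.15).all()
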