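"""Dosage null, exact binomial SNP test, gene aggregation, and imprinting."""

import numpy as np
import pandas as pd
import pytest

from triploase import (
    CrossDesign,
    SimulationParams,
    aggregate_gene_ase,
    call_imprinting,
    dosage_null,
    reciprocal_summary,
    simulate_allele_counts,
    snp_ase_test,
)
from triploase.types import ValidationError

from conftest import make_allele_records


class TestDosageNull:
    def test_tetraploid_mother_expects_two_thirds(self, reciprocal_design):
        assert dosage_null(reciprocal_design, "L4xL2").maternal_fraction == 2.0 / 3.0

    def test_tetraploid_father_expects_one_third(self, reciprocal_design):
        null = dosage_null(reciprocal_design, "L2xL4")
        assert null.maternal_fraction == 1.0 / 3.0
        assert null.paternal_fraction == pytest.approx(2.0 / 3.0)

    def test_balanced_cross_expects_half(self, design):
        assert dosage_null(design, "R2xL2").maternal_fraction == 0.5
        assert dosage_null(design, "L4xR4").maternal_fraction == 0.5


class TestSnpTest:
    def test_modal_expectation_gives_p_one(self):
        """20 vs 10 under a 2/3 null is the modal outcome: p = 1 exactly."""
        assert snp_ase_test(20, 10, 2.0 / 3.0) == 1.0

    def test_extreme_outcome_matches_enumeration_oracle(self, binom_oracle):
        assert snp_ase_test(30, 0, 2.0 / 3.0) == pytest.approx(
            binom_oracle(30, 30, 2.0 / 3.0), abs=1e-12
        )

    def test_strong_paternal_bias_is_tiny(self):
        """~95.5% paternal reads against a 1/3 paternal null."""
        p = snp_ase_test(191, 9, 1.0 / 3.0)
        assert p < 1e-10

    @pytest.mark.parametrize("f", [1.0 / 3.0, 0.5, 2.0 / 3.0])
    def test_oracle_equivalence_spot_grid(self, binom_oracle, f):
        for n in (1, 7, 23, 41):
            for k in range(n + 1):
                assert snp_ase_test(k, n - k, f) == pytest.approx(
                    binom_oracle(k, n, f), abs=1e-12
                )

    def test_zero_reads_rejected(self):
        with pytest.raises(ValidationError):
            snp_ase_test(0, 0, 0.5)

    def test_reciprocity_relabel_swap(self):
        """Swapping parental labels and the null fraction leaves p unchanged."""
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(10, 200))
            k = int(rng.integers(0, n + 1))
            p1 = snp_ase_test(k, n - k, 2.0 / 3.0)
            p2 = snp_ase_test(n - k, k, 1.0 - 2.0 / 3.0)
            assert p1 == pytest.approx(p2, rel=1e-9)


class TestGeneAggregation:
    def test_read_floor_filters_gene(self, reciprocal_design):
        """One SNP totalling 9 pooled reads (< 10) leaves the gene filtered."""
        rows = [("g1", "chr1", 100, "L2", "L4", 2, 1, s)
                for s in ("L4xL2_1", "L4xL2_2", "L4xL2_3")]
        res = aggregate_gene_ase(make_allele_records(rows), reciprocal_design, "L4xL2")
        assert res.loc[res["gene_id"] == "g1", "bias_class"].item() == "filtered"

    def test_read_floor_is_pooled_across_replicates(self, reciprocal_design):
        """4 reads in each of 3 replicates pools to 12 >= 10: tested."""
        rows = [("g1", "chr1", 100, "L2", "L4", 2, 2, s)
                for s in ("L4xL2_1", "L4xL2_2", "L4xL2_3")]
        res = aggregate_gene_ase(make_allele_records(rows), reciprocal_design, "L4xL2")
        assert res.loc[res["gene_id"] == "g1", "bias_class"].item() != "filtered"

    def test_counts_at_exact_null_ratio_are_unbiased(self, reciprocal_design):
        rows = []
        for i, s in enumerate(("L4xL2_1", "L4xL2_2", "L4xL2_3")):
            rows += [("g1", "chr1", 100, "L2", "L4", 10, 20, s),
                     ("g2", "chr1", 900, "L2", "L4", 30, 60, s)]
        res = aggregate_gene_ase(make_allele_records(rows), reciprocal_design, "L4xL2")
        assert (res["bias_class"] == "unbiased").all()

    def test_direction_from_pooled_counts(self, reciprocal_design):
        # maternal (L4) fraction 0.95 across plenty of reads
        rows = [("g1", "chr1", 100, "L2", "L4", 5, 95, s)
                for s in ("L4xL2_1", "L4xL2_2", "L4xL2_3")]
        res = aggregate_gene_ase(make_allele_records(rows), reciprocal_design, "L4xL2")
        row = res[res["gene_id"] == "g1"].iloc[0]
        assert row["bias_class"] == "maternal_biased"
        assert row["maternal_fraction"] == pytest.approx(0.95)
        assert row["min_fdr"] < 0.05

    def test_conflicting_directions_flagged(self, reciprocal_design):
        rows = []
        for s in ("L4xL2_1", "L4xL2_2", "L4xL2_3"):
            rows += [("g1", "chr1", 100, "L2", "L4", 2, 98, s),    # maternal up
                     ("g1", "chr1", 300, "L2", "L4", 98, 2, s)]    # paternal up
        res = aggregate_gene_ase(make_allele_records(rows), reciprocal_design, "L4xL2")
        assert res.loc[res["gene_id"] == "g1", "bias_class"].item() == "conflicting"

    def test_fdr_scope_per_gene_option(self, reciprocal_design):
        rows = [("g1", "chr1", 100, "L2", "L4", 5, 95, "L4xL2_1"),
                ("g2", "chr1", 500, "L2", "L4", 40, 80, "L4xL2_1")]
        res = aggregate_gene_ase(
            make_allele_records(rows), reciprocal_design, "L4xL2", fdr_scope="per-gene"
        )
        assert set(res["gene_id"]) == {"g1", "g2"}
        with pytest.raises(ValueError):
            aggregate_gene_ase(
                make_allele_records(rows), reciprocal_design, "L4xL2", fdr_scope="nope"
            )

    def test_null_snp_pvalues_super_uniform(self, reciprocal_design):
        """Under the 2:1 null at depth >= 30 the SNP p-values are
        (super-)uniform: the empirical CDF never exceeds the uniform CDF by
        more than Monte-Carlo error."""
        rng = np.random.default_rng(5)
        n_snps = 4000
        totals = rng.poisson(60, size=n_snps).clip(30)
        mat = rng.binomial(totals, 2.0 / 3.0)
        pvals = np.array([
            snp_ase_test(int(m), int(t - m), 2.0 / 3.0) for m, t in zip(mat, totals)
        ])
        grid = np.linspace(0.01, 0.99, 50)
        ecdf = np.searchsorted(np.sort(pvals), grid, side="right") / n_snps
        margin = 3.0 * np.sqrt(grid * (1 - grid) / n_snps)
        assert (ecdf <= grid + margin).all()

    def test_power_monotone_in_depth_and_deviation(self, reciprocal_design):
        """Gene detection rate rises with read depth and with the distance
        of the true fraction from the 2/3 null."""
        def rate(depth, frac, seed, design=reciprocal_design):
            genes = SimulationParams(n_genes=120).gene_ids()
            p = SimulationParams(
                n_genes=120, seed=seed, allelic_depth_mean=depth,
                biased_genes={g: frac for g in genes},
            )
            rec, _ = simulate_allele_counts(design, p, groups=["L4xL2"])
            res = aggregate_gene_ase(rec, design, "L4xL2")
            return (res["bias_class"] == "maternal_biased").mean()

        by_depth = [rate(d, 0.85, 77) for d in (5, 15, 60)]
        assert by_depth == sorted(by_depth)
        by_frac = [rate(30, f, 78) for f in (0.70, 0.80, 0.95)]
        assert by_frac == sorted(by_frac)


def _ase_row(gene, cross, frac, fdr, cls, mat_allele, pat_allele):
    return {
        "gene_id": gene, "cross": cross, "n_snps": 2,
        "maternal_reads": int(frac * 100), "paternal_reads": int((1 - frac) * 100),
        "maternal_fraction": frac, "min_fdr": fdr, "bias_class": cls,
        "null_maternal_fraction": 2.0 / 3.0 if mat_allele == "L4" else 1.0 / 3.0,
        "maternal_allele": mat_allele, "paternal_allele": pat_allele,
    }


class TestReciprocalSummaryAndImprinting:
    def _results(self):
        # cross A = L4xL2 (maternal L4), cross B = L2xL4 (maternal L2)
        res_a = pd.DataFrame([
            _ase_row("peg1", "L4xL2", 0.10, 1e-6, "paternal_biased", "L4", "L2"),
            _ase_row("meg1", "L4xL2", 0.95, 1e-4, "maternal_biased", "L4", "L2"),
            _ase_row("cis1", "L4xL2", 0.95, 1e-4, "maternal_biased", "L4", "L2"),
            _ase_row("one1", "L4xL2", 0.95, 1e-4, "maternal_biased", "L4", "L2"),
            _ase_row("null1", "L4xL2", 0.66, 0.9, "unbiased", "L4", "L2"),
        ])
        res_b = pd.DataFrame([
            _ase_row("peg1", "L2xL4", 0.05, 1e-6, "paternal_biased", "L2", "L4"),
            _ase_row("meg1", "L2xL4", 0.90, 1e-4, "maternal_biased", "L2", "L4"),
            _ase_row("cis1", "L2xL4", 0.05, 1e-5, "paternal_biased", "L2", "L4"),
            _ase_row("one1", "L2xL4", 0.34, 0.8, "unbiased", "L2", "L4"),
            _ase_row("null1", "L2xL4", 0.33, 0.9, "unbiased", "L2", "L4"),
        ])
        return res_a, res_b

    def test_imprinting_rules(self):
        res_a, res_b = self._results()
        calls = call_imprinting(res_a, res_b).set_index("gene_id")
        assert calls.loc["peg1", "status"] == "PEG"       # paternal both crosses
        assert calls.loc["meg1", "status"] == "MEG"       # maternal both crosses
        assert calls.loc["cis1", "status"] == "cis_biased"  # L4 allele both crosses
        assert calls.loc["one1", "status"] == "none"      # one cross only
        assert calls.loc["null1", "status"] == "none"

    def test_summary_counts_and_scatter(self):
        res_a, res_b = self._results()
        s = reciprocal_summary(res_a, res_b)
        a_row = s.counts[s.counts["cross"] == "L4xL2"].iloc[0]
        assert a_row["n_maternal_biased"] == 3 and a_row["n_paternal_biased"] == 1
        assert a_row["n_informative"] == 5
        # every ASEG present in both crosses contributes both alleles
        assert set(s.scatter["gene_id"]) == {"peg1", "meg1", "cis1", "one1"}
        peg_l2 = s.scatter[(s.scatter["gene_id"] == "peg1") & (s.scatter["allele"] == "L2")]
        assert peg_l2["pct_when_paternal"].item() == pytest.approx(90.0)
        assert peg_l2["pct_when_maternal"].item() == pytest.approx(5.0)

    def test_no_asegs_zero_counts_empty_scatter(self):
        res_a, res_b = self._results()
        for r in (res_a, res_b):
            r["bias_class"] = "unbiased"
        s = reciprocal_summary(res_a, res_b)
        assert (s.counts[["n_maternal_biased", "n_paternal_biased"]] == 0).all().all()
        assert s.scatter.empty

    def test_gene_absent_from_one_cross_excluded_from_scatter(self):
        res_a, res_b = self._results()
        res_b = res_b[res_b["gene_id"] != "peg1"]
        s = reciprocal_summary(res_a, res_b)
        assert "peg1" not in set(s.scatter["gene_id"])
        # still counted in cross A's biased tally
        assert s.counts[s.counts["cross"] == "L4xL2"]["n_paternal_biased"].item() == 1

    def test_planted_bias_counts_recovered(self, reciprocal_design):
        """100 planted maternal- and 20 paternal-biased genes per cross are
        recovered within binomial sampling error."""
        genes = SimulationParams(n_genes=160).gene_ids()
        p = SimulationParams(
            n_genes=160, seed=13, allelic_depth_mean=60.0,
            meg_genes={g: 0.95 for g in genes[:100]},
            peg_genes={g: 0.95 for g in genes[100:120]},
        )
        rec, _ = simulate_allele_counts(reciprocal_design, p, groups=["L4xL2", "L2xL4"])
        res_a = aggregate_gene_ase(rec, reciprocal_design, "L4xL2")
        res_b = aggregate_gene_ase(rec, reciprocal_design, "L2xL4")
        s = reciprocal_summary(res_a, res_b)
        for _, row in s.counts.iterrows():
            # ~5% of planted genes draw zero SNPs (Poisson mean 3) and are unassayable
            assert row["n_maternal_biased"] >= 85
            assert 14 <= row["n_paternal_biased"] <= 22

    def test_planted_peg_and_cis_discrimination(self, reciprocal_design):
        genes = SimulationParams(n_genes=40).gene_ids()
        p = SimulationParams(
            n_genes=40, seed=14, allelic_depth_mean=60.0,
            peg_genes={g: 0.9 for g in genes[:10]},
            cis_genes={g: ("L4", 0.9) for g in genes[10:20]},
        )
        rec, truth = simulate_allele_counts(reciprocal_design, p, groups=["L4xL2", "L2xL4"])
        res_a = aggregate_gene_ase(rec, reciprocal_design, "L4xL2")
        res_b = aggregate_gene_ase(rec, reciprocal_design, "L2xL4")
        calls = call_imprinting(res_a, res_b).set_index("gene_id")
        truth_pegs = set(truth.loc[truth["truth_class"] == "peg", "gene_id"]) & set(calls.index)
        truth_cis = set(truth.loc[truth["truth_class"] == "cis:L4", "gene_id"]) & set(calls.index)
        assert all(calls.loc[g, "status"] == "PEG" for g in truth_pegs)
        assert all(calls.loc[g, "status"] == "cis_biased" for g in truth_cis)
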