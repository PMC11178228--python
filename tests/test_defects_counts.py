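"""Defect models, transcription rates and count emission."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from splicescreen.simulate import (
    DefectModel,
    apply_defect_model,
    assign_rates,
    simulate_gene_counts,
    simulate_junction_counts,
)
from splicescreen.simulate.defects import TruthTable

from conftest import make_gene


class TestAssignRates:
    def test_degenerate_sigma_collapses_to_exp_mu(self):
        genes = [make_gene(f"g{i}") for i in range(20)]
        rates = assign_rates(genes, mu=2.0, sigma=1e-12, seed=1)
        assert np.allclose(rates["rate"], np.exp(2.0))

    def test_log_rate_mean_matches_mu(self):
        genes = [make_gene(f"g{i}") for i in range(10_000)]
        rates = assign_rates(genes, mu=2.0, sigma=1.0, seed=1)
        assert (rates["rate"] > 0).all()
        assert abs(np.log(rates["rate"]).mean() - 2.0) < 0.05

    def test_deterministic_and_validates(self):
        genes = [make_gene(f"g{i}") for i in range(5)]
        a = assign_rates(genes, 1.0, 0.5, seed=9)
        b = assign_rates(genes, 1.0, 0.5, seed=9)
        pd.testing.assert_frame_equal(a, b)
        with pytest.raises(ValueError):
            assign_rates(genes, 1.0, 0.0, seed=9)
        assert assign_rates([], 1.0, 1.0, seed=0).empty


class TestDefectModel:
    def test_none_kind_equals_zero_penalty_motif(self, three_intron_gene):
        genome, gene = three_intron_gene
        rates = pd.DataFrame({"gene_id": [gene.gene_id], "rate": [5.0]})
        none = apply_defect_model([gene], rates, DefectModel(kind="none"), 3, genome)
        motif0 = apply_defect_model(
            [gene], rates, DefectModel(kind="motif_dependent", gamma=0.0), 3, genome
        )
        np.testing.assert_allclose(
            none.introns["true_se"], motif0.introns["true_se"]
        )

    def test_full_penalty_motif_gives_zero_se(self):
        gene = make_gene("g1", n_introns=1)
        # donor hexamer CCCCCC: six mismatches against GTAAGT
        genome = {"chr1": "A" * 99 + "CCCCCC" + "A" * 400}
        rates = pd.DataFrame({"gene_id": ["g1"], "rate": [1.0]})
        model = DefectModel(kind="motif_dependent", gamma=1.0)
        truth = apply_defect_model([gene], rates, model, 1, genome)
        assert truth.introns["true_se"].iloc[0] == 0.0

    def test_logistic_affected_probability_matches_closed_form(self):
        n = 10_000
        genes = [make_gene(f"g{i}") for i in range(n)]
        model = DefectModel(kind="transcription_coupled", alpha=-6.0, beta=3.0)
        for log_rate, p_true in ((2.0, expit(0.0)), (0.0, expit(-6.0))):
            rates = pd.DataFrame(
                {"gene_id": [g.gene_id for g in genes], "rate": np.exp(log_rate)}
            )
            truth = apply_defect_model(genes, rates, model, 17, None)
            p_hat = truth.genes["gene_affected"].mean()
            tol = 4 * np.sqrt(p_true * (1 - p_true) / n) + 1e-3
            assert abs(p_hat - p_true) < tol

    def test_unaffected_genes_keep_wild_type_baseline(self):
        genes = [make_gene(f"g{i}", n_introns=2) for i in range(300)]
        rates = pd.DataFrame({"gene_id": [g.gene_id for g in genes], "rate": 1.0})
        wt = apply_defect_model(genes, rates, DefectModel(kind="none"), 5, genotype="WT")
        mut = apply_defect_model(
            genes,
            rates,
            DefectModel(kind="transcription_coupled", alpha=0.0, beta=0.0),
            5,
            genotype="mut",
        )
        merged = wt.introns.merge(mut.introns, on="intron_id", suffixes=("_wt", "_mut"))
        aff = dict(zip(mut.genes["gene_id"], mut.genes["gene_affected"]))
        unaffected = merged[~merged["gene_id_wt"].map(aff)]
        affected = merged[merged["gene_id_wt"].map(aff)]
        assert len(unaffected) and len(affected)
        np.testing.assert_allclose(unaffected["true_se_wt"], unaffected["true_se_mut"])
        assert (affected["true_se_mut"] <= affected["true_se_wt"] + 1e-12).all()

    def test_gamma_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            DefectModel(kind="motif_dependent", gamma=1.5).validate()


class TestJunctionCountSim:
    @staticmethod
    def _truth(se_values):
        introns = pd.DataFrame(
            {
                "genotype": "WT",
                "gene_id": [f"g{i}" for i in range(len(se_values))],
                "intron_index": 1,
                "intron_id": [f"g{i}.i1" for i in range(len(se_values))],
                "true_se": se_values,
            }
        )
        genes = pd.DataFrame(
            {
                "genotype": "WT",
                "gene_id": introns["gene_id"],
                "true_rate": 1.0,
                "gene_affected": False,
            }
        )
        return TruthTable(introns=introns, genes=genes)

    def test_full_efficiency_emits_no_unspliced(self):
        truth = self._truth([1.0] * 50)
        rates = pd.DataFrame({"gene_id": truth.genes["gene_id"], "rate": 1.0})
        counts = simulate_junction_counts(truth, rates, depth=50.0, seed=2)
        assert (counts[["unspliced5", "unspliced3"]] == 0).all().all()

    def test_binomial_concentration_recovers_se(self):
        truth = self._truth([0.7] * 200)
        rates = pd.DataFrame({"gene_id": truth.genes["gene_id"], "rate": 1.0})
        counts = simulate_junction_counts(truth, rates, depth=2500.0, seed=2)
        se_hat = (counts["spliced5"] + counts["spliced3"]) / counts[
            ["spliced5", "unspliced5", "spliced3", "unspliced3"]
        ].sum(axis=1)
        assert (np.abs(se_hat - 0.7) < 0.02).mean() >= 0.95
        assert abs(se_hat.mean() - 0.7) < 0.005

    def test_zero_depth_rejected(self):
        truth = self._truth([0.5])
        rates = pd.DataFrame({"gene_id": ["g0"], "rate": 1.0})
        with pytest.raises(ValueError):
            simulate_junction_counts(truth, rates, depth=0.0, seed=1)

    def test_replicates_use_distinct_subseeds(self):
        truth = self._truth([0.5] * 30)
        rates = pd.DataFrame({"gene_id": truth.genes["gene_id"], "rate": 1.0})
        counts = simulate_junction_counts(truth, rates, depth=20.0, seed=4, n_reps=2)
        r1 = counts[counts["replicate"] == 1].reset_index(drop=True)
        r2 = counts[counts["replicate"] == 2].reset_index(drop=True)
        assert not r1[["spliced5", "unspliced5"]].equals(r2[["spliced5", "unspliced5"]])
        again = simulate_junction_counts(truth, rates, depth=20.0, seed=4, n_reps=1)
        pd.testing.assert_frame_equal(r1, again[again["replicate"] == 1].reset_index(drop=True))


class TestGeneCountSim:
    def test_poisson_limit_null_fold_change(self):
        rates = pd.DataFrame({"gene_id": [f"g{i}" for i in range(500)], "rate": 20.0})
        counts = simulate_gene_counts(rates, {}, dispersion=np.inf, n_reps=2, seed=6)
        wt = counts[[c for c in counts if c.startswith("WT")]].to_numpy().mean()
        mut = counts[[c for c in counts if c.startswith("mut")]].to_numpy().mean()
        assert abs(mut / wt - 1.0) < 0.05

    def test_fold_change_recovered_within_25_percent(self):
        rates = pd.DataFrame({"gene_id": ["g0"], "rate": 50.0})
        counts = simulate_gene_counts(
            rates, {"g0": 4.0}, dispersion=5.0, n_reps=200, seed=6
        )
        wt = counts.loc["g0", [c for c in counts if c.startswith("WT")]].mean()
        mut = counts.loc["g0", [c for c in counts if c.startswith("mut")]].mean()
        assert abs(mut / wt - 4.0) < 1.0

    def test_empty_and_invalid_inputs(self):
        empty = simulate_gene_counts(
            pd.DataFrame({"gene_id": [], "rate": []}), {}, 10.0, 2, 1
        )
        assert empty.empty
        rates = pd.DataFrame({"gene_id": ["g0"], "rate": 1.0})
        with pytest.raises(ValueError):
            simulate_gene_counts(rates, {}, dispersion=0.0, n_reps=2, seed=1)
        with pytest.raises(ValueError):
            simulate_gene_counts(rates, {}, dispersion=1.0, n_reps=1, seed=1)
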