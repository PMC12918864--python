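"""Gene summation, normalization, dispersion, and the NB Wald test."""

import numpy as np
import pandas as pd
import pytest

from mechanoscreen import enrichment as enr, synthetic as syn


def _cond_map(columns):
    return {c: ("inlet" if c.startswith("inlet") else "outlet") for c in columns}


class TestSumGeneCounts:
    def test_simple_sum_and_conservation(self, small_library, screen_counts):
        counts, _, _ = screen_counts
        gc = enr.sum_gene_counts(counts, small_library)
        assert (gc.sum() == counts.sum()).all()
        g = small_library["gene"].iloc[0]
        members = small_library.loc[small_library["gene"] == g, "guide_id"]
        assert (gc.loc[g] == counts.loc[members].sum()).all()

    def test_row_permutation_invariance(self, small_library, screen_counts):
        counts, _, _ = screen_counts
        rng = np.random.default_rng(1)
        perm = counts.iloc[rng.permutation(len(counts))]
        pd.testing.assert_frame_equal(
            enr.sum_gene_counts(counts, small_library),
            enr.sum_gene_counts(perm, small_library),
        )

    def test_orphan_guides_error(self, small_library, screen_counts):
        counts, _, _ = screen_counts
        bad = counts.rename(index={counts.index[0]: "ROGUE_g1"})
        with pytest.raises(ValueError, match="ROGUE"):
            enr.sum_gene_counts(bad, small_library)


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        gc = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        s = enr.size_factors(gc)
        assert np.allclose(s, 1.0)

    def test_three_fold_column(self):
        # direct evaluation of median-of-ratios: col2 = 3 x col1 -> s2/s1 = 3
        rng = np.random.default_rng(2)
        base = rng.integers(10, 1000, size=100)
        gc = pd.DataFrame({"a": base, "b": 3 * base})
        s = enr.size_factors(gc)
        assert s["b"] / s["a"] == pytest.approx(3.0, rel=1e-12)
        assert np.exp(np.mean(np.log(s))) == pytest.approx(1.0, rel=1e-12)

    def test_gene_reorder_invariance(self, small_library, screen_counts):
        counts, _, _ = screen_counts
        gc = enr.sum_gene_counts(counts, small_library)
        rng = np.random.default_rng(3)
        perm = gc.iloc[rng.permutation(len(gc))]
        assert np.allclose(enr.size_factors(gc), enr.size_factors(perm))

    def test_no_all_positive_gene_errors(self):
        gc = pd.DataFrame({"a": [0, 5], "b": [5, 0]})
        with pytest.raises(ValueError, match="reference"):
            enr.size_factors(gc)


class TestDispersions:
    def test_poisson_counts_have_floor_level_dispersion(self):
        # Poisson data carries no overdispersion: the moments estimates sit
        # at the floor for most genes
        rng = np.random.default_rng(4)
        mu = rng.uniform(100, 1000, size=500)
        gc = pd.DataFrame(
            {f"inlet_r{i}": rng.poisson(mu) for i in range(1, 5)}
            | {f"outlet_r{i}": rng.poisson(mu) for i in range(1, 5)}
        )
        s = enr.size_factors(gc)
        # gene-wise moments component: recompute via the public API with a
        # single condition so no trend can dominate
        alpha = enr.estimate_dispersions(gc, s, _cond_map(gc.columns))
        assert alpha.median() < 0.01

    def test_nb_dispersion_recovered(self):
        # gene-level NB counts at alpha = 0.1, 4 replicates, 1000 genes
        rng = np.random.default_rng(5)
        mu = rng.uniform(200, 2000, size=1000)
        size = 1.0 / 0.1
        cols = {}
        for cond in ("inlet", "outlet"):
            for r in range(1, 5):
                cols[f"{cond}_r{r}"] = rng.negative_binomial(
                    size, size / (size + mu)
                )
        gc = pd.DataFrame(cols)
        s = enr.size_factors(gc)
        alpha = enr.estimate_dispersions(gc, s, _cond_map(gc.columns))
        assert 0.05 <= alpha.median() <= 0.2

    def test_floor_always_respected(self, small_library, screen_counts):
        counts, _, _ = screen_counts
        gc = enr.sum_gene_counts(counts, small_library)
        s = enr.size_factors(gc)
        alpha = enr.estimate_dispersions(gc, s, _cond_map(gc.columns))
        assert (alpha >= enr.ALPHA_MIN).all()

    def test_single_replicate_warns(self):
        gc = pd.DataFrame({"inlet_r1": [10, 20], "outlet_r1": [15, 25]})
        s = pd.Series(1.0, index=gc.columns)
        with pytest.warns(UserWarning, match="replicated"):
            alpha = enr.estimate_dispersions(gc, s, _cond_map(gc.columns))
        assert (alpha == enr.ALPHA_MIN).all()


class TestWaldTest:
    @staticmethod
    def _simulate(n_genes, effect_genes, seed, depth=300, replicates=4):
        lib = syn.make_guide_library(n_genes, 4, seed=seed)
        genes = lib["gene"].unique()
        effects = {genes[i]: {"outlet4": 8.0} for i in effect_genes}
        truth = syn.make_screen_truth(lib, effects, dispersion=0.1, seed=seed + 1)
        design = syn.ScreenDesign(outlets=("outlet4",), replicates=replicates)
        counts, _ = syn.simulate_screen_counts(
            lib, design, truth, depth=depth * len(lib)
        )
        gc = enr.sum_gene_counts(counts, lib)
        s = enr.size_factors(gc)
        alpha = enr.estimate_dispersions(gc, s, _cond_map(gc.columns))
        inlet = [c for c in gc.columns if c.startswith("inlet")]
        outlet = [c for c in gc.columns if c.startswith("outlet")]
        return gc, s, alpha, inlet, outlet, [genes[i] for i in effect_genes]

    def test_eightfold_gene_detected_with_log2fc_three(self):
        gc, s, alpha, inlet, outlet, planted = self._simulate(300, [5], seed=10)
        fit = enr.nb_wald_test(gc, inlet, outlet, s, alpha)
        row = fit.loc[planted[0]]
        assert row["log2FC"] == pytest.approx(3.0, abs=0.4)
        assert row["padj"] < 0.001

    def test_label_swap_negates_log2fc(self):
        gc, s, alpha, inlet, outlet, _ = self._simulate(100, [3], seed=20)
        fwd = enr.nb_wald_test(gc, inlet, outlet, s, alpha)
        rev = enr.nb_wald_test(gc, outlet, inlet, s, alpha)
        assert np.allclose(fwd["log2FC"], -rev["log2FC"], atol=1e-6)
        assert np.allclose(fwd["pvalue"], rev["pvalue"], atol=1e-8)

    def test_depth_rescaling_invariance(self):
        gc, s, alpha, inlet, outlet, _ = self._simulate(100, [3], seed=30)
        scaled = gc.copy()
        scaled[outlet] = scaled[outlet] * 4
        s2 = enr.size_factors(scaled)
        fit1 = enr.nb_wald_test(gc, inlet, outlet, s, alpha)
        fit2 = enr.nb_wald_test(scaled, inlet, outlet, s2, alpha)
        # size factors absorb the per-sample depth change
        assert np.allclose(fit1["log2FC"], fit2["log2FC"], atol=0.05)

    def test_all_zero_gene_excluded(self):
        gc = pd.DataFrame({
            "inlet_r1": [100, 0], "inlet_r2": [120, 0],
            "outlet_r1": [90, 0], "outlet_r2": [105, 0],
        }, index=pd.Index(["G1", "G2"], name="gene"))
        s = pd.Series(1.0, index=gc.columns)
        alpha = pd.Series(0.01, index=gc.index)
        fit = enr.nb_wald_test(gc, ["inlet_r1", "inlet_r2"],
                               ["outlet_r1", "outlet_r2"], s, alpha)
        assert not fit.loc["G2", "tested"]
        assert fit.loc["G1", "tested"]


class TestGuideFoldChanges:
    def test_equal_means_unit_fc(self):
        counts = pd.DataFrame({
            "inlet_r1": [100, 50], "outlet_r1": [100, 50],
        }, index=pd.Index(["GENE0001_g1", "GENE0001_g2"], name="guide_id"))
        lib = pd.DataFrame({
            "guide_id": ["GENE0001_g1", "GENE0001_g2"],
            "gene": ["GENE0001"] * 2,
            "protospacer": ["A" * 20, "C" * 20],
        })
        s = pd.Series(1.0, index=counts.columns)
        fc, gene_max = enr.guide_fold_changes(
            counts, s, ["inlet_r1"], ["outlet_r1"], lib
        )
        assert np.allclose(fc, 1.0)
        assert gene_max["GENE0001"] == pytest.approx(1.0)

    def test_hundredfold_worked_example(self):
        # inlet 2 reads, outlet 250 (normalized), pc 0.5 -> 250.5/2.5 = 100.2
        counts = pd.DataFrame({
            "inlet_r1": [2], "outlet_r1": [250],
        }, index=pd.Index(["GENE0001_g1"], name="guide_id"))
        lib = pd.DataFrame({
            "guide_id": ["GENE0001_g1"], "gene": ["GENE0001"],
            "protospacer": ["A" * 20],
        })
        s = pd.Series(1.0, index=counts.columns)
        fc, gene_max = enr.guide_fold_changes(
            counts, s, ["inlet_r1"], ["outlet_r1"], lib, pseudocount=0.5
        )
        assert fc.iloc[0] == pytest.approx(100.2)
        assert gene_max.iloc[0] > 100.0


class TestClassifyHits:
    def test_partition(self, small_library, screen_counts):
        counts, _, design = screen_counts
        manifest = pd.DataFrame(
            [{"sample": s_, "role": c, "replicate": r} for s_, c, r in design.samples]
        )
        results, summary = enr.run_outlet_enrichment(counts, small_library, manifest)
        t = results["outlet4"]
        assert (t["status"].isin(["enriched", "depleted", "ns"])).all()
        row = summary.loc["outlet4"]
        assert row["enriched"] + row["depleted"] + row["ns"] == len(t)

    def test_all_padj_one_gives_no_hits(self):
        fit = pd.DataFrame({
            "log2FC": [1.0, -1.0], "padj": [1.0, 1.0], "tested": [True, True],
        }, index=["G1", "G2"])
        out = enr.classify_hits(fit)
        assert (out["status"] == "ns").all()

    def test_planted_gene_is_enriched_hit(self, small_library, screen_counts):
        counts, truth, design = screen_counts
        manifest = pd.DataFrame(
            [{"sample": s_, "role": c, "replicate": r} for s_, c, r in design.samples]
        )
        results, _ = enr.run_outlet_enrichment(counts, small_library, manifest)
        assert results["outlet4"].loc["GENE0003", "status"] == "enriched"
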