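import numpy as np
import pandas as pd
import pytest

from kernomics.io import CONTEXTS, TREATMENTS
from kernomics.kernels import similarity
from kernomics.mediation import path_C
from kernomics.preprocess import methylation_levels
from kernomics.simulate import (
    SyntheticTruth,
    make_paper_like_dataset,
    methylation_to_counts,
    simulate_expression,
    simulate_genotypes,
    simulate_methylation,
    simulate_phenotypes,
)


class TestGenotypes:
    def test_empirical_maf_law_of_large_numbers(self):
        geno = simulate_genotypes(500, 200, maf_range=(0.05, 0.5), seed=1)
        freq = geno.values.mean(axis=0) / 2.0
        maf = np.minimum(freq, 1 - freq)
        assert maf.max() <= 0.6
        assert abs(maf.mean() - 0.275) < 0.05  # mean of U(0.05, 0.5)

    def test_block_size_one_gives_independent_snps(self):
        geno = simulate_genotypes(500, 60, ld_block=1, r_within=0.0, seed=2)
        r2 = np.corrcoef(geno.values.to_numpy().T) ** 2
        off = r2[np.triu_indices_from(r2, 1)]
        assert off.mean() < 0.05

    def test_block_structure_creates_ld(self):
        geno = simulate_genotypes(300, 40, ld_block=10, r_within=0.9, seed=3)
        arr = geno.values.to_numpy().T
        within = np.corrcoef(arr[:10]) ** 2
        assert within[np.triu_indices_from(within, 1)].mean() > 0.3

    def test_inbred_lines_have_no_heterozygotes(self):
        geno = simulate_genotypes(100, 100, seed=4)
        vals = geno.values.to_numpy()
        assert set(np.unique(vals[~np.isnan(vals)])) <= {0.0, 2.0}

    def test_invalid_maf_range_rejected(self):
        with pytest.raises(ValueError, match="maf_range"):
            simulate_genotypes(10, 10, maf_range=(0.6, 0.7))

    def test_deterministic(self):
        a = simulate_genotypes(30, 50, seed=9).values
        b = simulate_genotypes(30, 50, seed=9).values
        pd.testing.assert_frame_equal(a, b)


class TestMethylation:
    def test_levels_in_unit_interval(self):
        meth = simulate_methylation(50, 500, seed=5)
        vals = meth.values.to_numpy()
        assert vals.min() >= 0 and vals.max() <= 1

    def test_context_proportions(self):
        meth = simulate_methylation(5, 10000, context_proportions=(0.5, 0.3, 0.2), seed=6)
        counts = meth.feature_meta["context"].value_counts(normalize=True)
        assert counts["CG"] == pytest.approx(0.5, abs=0.03)
        assert counts["CHG"] == pytest.approx(0.3, abs=0.03)
        assert counts["CHH"] == pytest.approx(0.2, abs=0.03)

    def test_zero_line_effect_makes_lines_identical(self):
        meth = simulate_methylation(10, 50, line_effect_sd=0.0, seed=7)
        arr = meth.values.to_numpy()
        assert np.allclose(arr, arr[0])

    def test_counts_round_trip_through_levels(self):
        meth = simulate_methylation(8, 40, seed=8)
        counts = methylation_to_counts(meth, mean_coverage=200, seed=9)
        levels = methylation_levels(counts, min_coverage=5, min_presence=0.8)
        shared = [c for c in levels.feature_ids]
        assert len(shared) > 30
        # high coverage -> observed proportions close to the latent levels
        latent = meth.values
        site_map = dict(zip(
            (meth.feature_meta["chrom"].astype(str) + ":" + meth.feature_meta["start"].astype(str)
             + "-" + meth.feature_meta["end"].astype(str) + ":" + meth.feature_meta["context"]),
            meth.values.columns,
        ))
        recovered = levels.values.rename(columns=site_map)
        common = recovered.columns.intersection(latent.columns)
        diff = (recovered[common] - latent.loc[recovered.index, common]).abs()
        assert diff.to_numpy().mean() < 0.05


class TestExpression:
    def test_tpm_non_negative_and_expressed_genes_positive(self):
        expr, _ = simulate_expression(20, 100, seed=10)
        vals = expr.values.to_numpy()
        assert (vals >= 0).all()
        # expressed genes are strictly positive everywhere
        expressed = (vals > 0).all(axis=0)
        assert expressed.sum() >= 80

    def test_off_genes_have_zero_median(self):
        from kernomics.preprocess import filter_expression

        expr, _ = simulate_expression(50, 200, zero_gene_fraction=0.2, seed=15)
        _, report = filter_expression(expr)
        assert report.removals["low_expression"] >= 20

    def test_no_treatment_effect_when_a_zero(self):
        expr, med = simulate_expression(200, 50, n_mediators=20, a=0.0,
                                        zero_gene_fraction=0.0, seed=11)
        logv = np.log(expr.values.to_numpy())
        t = np.array([1.0 if s.endswith(TREATMENTS[1]) else 0.0 for s in expr.values.index])
        tstats = []
        for j in range(20):
            x1, x0 = logv[t == 1, j], logv[t == 0, j]
            se = np.sqrt(x1.var(ddof=1) / len(x1) + x0.var(ddof=1) / len(x0))
            tstats.append((x1.mean() - x0.mean()) / se)
        assert abs(np.mean(tstats)) < 0.5
        assert np.std(tstats) < 2.0

    def test_mediator_genes_respond_to_treatment(self):
        expr, med = simulate_expression(100, 50, n_mediators=5, a=2.0, seed=12)
        logv = np.log(expr.values[med].to_numpy())
        t = np.array([1.0 if s.endswith(TREATMENTS[1]) else 0.0 for s in expr.values.index])
        assert (logv[t == 1].mean(axis=0) - logv[t == 0].mean(axis=0)).min() > 1.0

    def test_zero_trans_h2_decouples_from_genotype(self):
        geno = simulate_genotypes(80, 200, seed=13)
        expr, _ = simulate_expression(80, 300, genotypes=geno, trans_h2=0.0, seed=14)
        Kg = similarity(geno).K
        Ke_lines = similarity(expr).K  # sample-level kernel
        # compare line-level genotype kernel against averaged expression kernel
        n = 80
        Ke = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                Ke[i, j] = Ke_lines[2 * i: 2 * i + 2, 2 * j: 2 * j + 2].mean()
        iu = np.triu_indices(n, 1)
        r = np.corrcoef(Kg[iu], Ke[iu])[0, 1]
        assert abs(r) < 0.1


class TestPhenotypes:
    def make_bundle(self, n_lines=50):
        geno = simulate_genotypes(n_lines, 200, seed=20)
        meth = simulate_methylation(n_lines, 200, seed=21)
        expr, _ = simulate_expression(n_lines, 150, genotypes=geno, seed=22)
        return geno, meth, expr

    def test_component_variances_hit_fractions_exactly(self):
        geno, meth, expr = self.make_bundle()
        truth = SyntheticTruth(
            pv2={"treatment": 0.05, "line": 0.15, "snp": 0.30, "meth": 0.10,
                 "expr": 0.20, "resid": 0.20}
        )
        ph = simulate_phenotypes(truth, genotypes=geno, methylation=meth,
                                 expression=expr, seed=23, return_components=True)
        comps = ph.components
        total = sum(np.var(v, ddof=1) for v in comps.values())
        for name, frac in truth.pv2.items():
            np.testing.assert_allclose(np.var(comps[name], ddof=1), frac * total,
                                       rtol=1e-10)

    def test_all_residual_trait_uncorrelated_with_kernels(self):
        geno, meth, expr = self.make_bundle(75)
        truth = SyntheticTruth(
            pv2={"treatment": 0, "line": 0, "snp": 0, "meth": 0, "expr": 0, "resid": 1.0}
        )
        ph = simulate_phenotypes(truth, genotypes=geno, seed=25, n_lines=75)
        y = ph.data["grain_yield"].to_numpy()
        K = similarity(geno).K
        top_pc = np.linalg.eigh(K)[1][:, -1]
        per_line = y.reshape(-1, 2).mean(axis=1)
        assert abs(np.corrcoef(per_line, top_pc)[0, 1]) < 0.15

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            SyntheticTruth(pv2={"treatment": 0.5, "resid": 0.4})

    def test_explicit_treatment_effect_recovered_by_path_c(self):
        geno, meth, expr = self.make_bundle(75)
        truth = SyntheticTruth(
            pv2={"treatment": 0.05, "line": 0.15, "snp": 0.30, "meth": 0.10,
                 "expr": 0.20, "resid": 0.20},
            treatment_effect=-0.78,
        )
        ph = simulate_phenotypes(truth, genotypes=geno, methylation=meth,
                                 expression=expr, seed=25)
        beta, p = path_C(ph, "grain_yield")
        # SE from the REML engine is ~ |beta|/5 in this design
        assert beta == pytest.approx(-0.78, abs=0.45)
        assert p < 0.01

    def test_determinism(self):
        geno, meth, expr = self.make_bundle(20)
        truth = {"treatment": 0.1, "line": 0.2, "snp": 0.3, "meth": 0, "expr": 0,
                 "resid": 0.4}
        a = simulate_phenotypes(SyntheticTruth(pv2=dict(truth)), genotypes=geno, seed=30)
        b = simulate_phenotypes(SyntheticTruth(pv2=dict(truth)), genotypes=geno, seed=30)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestPaperLikeDataset:
    def test_structure_at_reduced_scale(self):
        data = make_paper_like_dataset(seed=1, n_lines=20, n_snps=300,
                                       n_meth_sites=200, n_genes=150, n_mediators=5)
        assert data["genotypes"].shape == (20, 300)
        assert data["methylation"].shape == (20, 200)
        assert data["expression"].shape == (40, 150)  # per-sample rows
        ph = data["phenotypes"]
        assert set(ph.traits) == {"grain_yield", "tkw", "protein", "nitrogen_uptake"}
        assert len(ph.data) == 40
        assert set(data["truths"]) == set(ph.traits)
        for truth in data["truths"].values():
            assert abs(sum(truth.pv2.values()) - 1.0) < 1e-9
        assert set(data["methylation"].feature_meta["context"]) <= set(CONTEXTS)
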