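import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from kernomics.io import OmicsMatrix, PhenotypeTable, TREATMENTS
from kernomics.lmm import fit_lmm
from kernomics.mediation import (
    MediationScanResult,
    PathAScanEngine,
    bh_adjust,
    classify_mediators,
    overlap_summary,
    path_A_scan,
    path_B_scan,
    path_C,
    path_D,
    permutation_threshold,
    run_mediation_scan,
)
from kernomics.simulate import simulate_mediation_dataset

from conftest import balanced_pheno, make_lines, sample_matrix


class TestPathC:
    def test_deterministic_contrast_is_exact(self):
        n = 20
        y = np.tile([0.0, 1.0], n)  # +1 under water scarcity, no noise
        ph = balanced_pheno(y)
        beta, p = path_C(ph, "grain_yield")
        assert beta == pytest.approx(1.0, abs=1e-8)

    def test_single_treatment_is_hard_error(self):
        df = pd.DataFrame(
            {"line": ["l1", "l2"], "treatment": ["control"] * 2, "grain_yield": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="both treatments"):
            path_C(PhenotypeTable(df), "grain_yield")

    def test_null_pvalues_uniform_over_replicates(self):
        """With no treatment effect, path-C p-values are U(0,1) (KS test)."""
        rng = np.random.default_rng(2024)
        pvals = []
        for _ in range(500):
            n = 75
            y = np.repeat(rng.standard_normal(n), 2) * 0.8 + rng.standard_normal(2 * n)
            ph = balanced_pheno(y)
            _, p = path_C(ph, "grain_yield")
            pvals.append(p)
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestPathA:
    def test_perfect_signal_has_tiny_pvalue(self):
        rng = np.random.default_rng(0)
        lines = make_lines(40)
        t = np.tile([0.0, 1.0], 40)
        feat = t + rng.standard_normal(80) * 0.1
        om = sample_matrix(np.exp(feat[:, None]), lines)
        ph = balanced_pheno(rng.standard_normal(80), lines)
        tab = path_A_scan(om, ph)
        assert tab["p_A"].iloc[0] < 1e-6

    def test_constant_feature_contract(self):
        lines = make_lines(10)
        om = sample_matrix(np.full((20, 1), 3.0), lines)
        ph = balanced_pheno(np.random.default_rng(1).standard_normal(20), lines)
        tab = path_A_scan(om, ph)
        assert tab["beta_A"].iloc[0] == 0.0
        assert tab["p_A"].iloc[0] == 1.0

    def test_alignment_mismatch_is_hard_error(self):
        lines = make_lines(5)
        om = sample_matrix(np.random.default_rng(2).random((10, 2)), lines)
        other = balanced_pheno(np.zeros(12), make_lines(6))
        with pytest.raises(ValueError, match="not found"):
            path_A_scan(om, other)

    def test_null_scan_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(3)
        lines = make_lines(75)
        Y = np.exp(np.repeat(rng.standard_normal((75, 300)), 2, axis=0) * 0.7
                   + rng.standard_normal((150, 300)))
        om = sample_matrix(Y, lines)
        ph = balanced_pheno(rng.standard_normal(150), lines)
        tab = path_A_scan(om, ph)
        assert stats.kstest(tab["p_A"], "uniform").pvalue > 1e-4


class TestPathB:
    def test_feature_identical_to_treatment_flagged(self):
        rng = np.random.default_rng(4)
        lines = make_lines(30)
        t = np.tile([0.0, 1.0], 30)
        om = sample_matrix(t[:, None] + 1.0, lines)  # collinear with treatment
        ph = balanced_pheno(rng.standard_normal(60), lines)
        tab = path_B_scan(ph, "grain_yield", om)
        assert bool(tab["aliased"].iloc[0])
        assert tab["p_B"].iloc[0] == 1.0

    def test_null_feature_beta_within_3_se(self):
        rng = np.random.default_rng(5)
        lines = make_lines(60)
        feat = np.exp(rng.standard_normal(120))
        om = sample_matrix(feat[:, None], lines)
        y = np.repeat(rng.standard_normal(60), 2) + rng.standard_normal(120)
        ph = balanced_pheno(y, lines)
        tab = path_B_scan(ph, "grain_yield", om)
        # SE from the exact single-feature fit
        t = np.tile([0.0, 1.0], 60)
        X = np.column_stack([np.ones(120), t, feat])
        fit = fit_lmm(y, X, np.repeat(lines, 2), term_names=["intercept", "treatment", "feat"])
        assert abs(tab["beta_mediatorB"].iloc[0]) < 3 * fit.se["feat"]
        assert tab["beta_mediatorB"].iloc[0] == pytest.approx(fit.beta["feat"], abs=1e-3)

    def test_true_mediator_attenuates_treatment(self):
        """In the causal chain the path-B treatment beta shrinks towards 0."""
        hits = 0
        n_sims = 60
        for s in range(n_sims):
            ph, expr, med = simulate_mediation_dataset(
                n_lines=40, n_genes=1, n_mediators=1, a=1.5, b=1.0,
                direct_effect=-0.1, seed=1000 + s,
            )
            beta_c, _ = path_C(ph, "grain_yield")
            tab = path_B_scan(ph, "grain_yield", expr)
            if abs(tab["beta_treatmentB"].iloc[0]) < abs(beta_c):
                hits += 1
        assert hits / n_sims >= 0.95


class TestBHAdjust:
    def test_hand_computed_stepup(self):
        q, sig = bh_adjust([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5], atol=1e-10)
        assert sig.tolist() == [True, True, False, False]

    def test_all_ones(self):
        q, sig = bh_adjust([1.0, 1.0, 1.0])
        assert (q == 1.0).all() and not sig.any()

    def test_single_p_identity(self):
        q, _ = bh_adjust([0.03])
        assert q[0] == pytest.approx(0.03)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_q_never_below_p_and_monotone(self, pvals):
        q, _ = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestPermutationThreshold:
    def _null_engine(self, n_lines=75, m=100, seed=0, line_sd=0.0):
        rng = np.random.default_rng(seed)
        lines = make_lines(n_lines)
        Y = np.exp(
            np.repeat(rng.standard_normal((n_lines, m)) * line_sd, 2, axis=0)
            + rng.standard_normal((2 * n_lines, m))
        )
        om = sample_matrix(Y, lines)
        engine = PathAScanEngine(om)
        t = np.tile([0.0, 1.0], n_lines)
        line_vec = np.repeat(lines, 2)
        return engine, t, line_vec

    def test_threshold_matches_order_statistic_oracle(self):
        """With m iid uniform p-values per scan the min p is ~Beta(1, m),
        so the threshold must land on the Beta(1, m) alpha-quantile."""
        m, n_perm, alpha = 100, 1000, 0.05
        rng = np.random.default_rng(13)

        def uniform_scan(labels):
            return rng.uniform(size=m)

        lines = np.repeat(make_lines(75), 2)
        t = np.tile([0.0, 1.0], 75)
        thr = permutation_threshold(uniform_scan, t, lines, n_perm=n_perm, alpha=alpha, seed=11)
        q_true = stats.beta(1, m).ppf(alpha)
        dens = stats.beta(1, m).pdf(q_true)
        mc_se = np.sqrt(alpha * (1 - alpha) / n_perm) / dens
        assert abs(thr - q_true) < 2 * mc_se

    def test_lmm_scan_threshold_in_order_statistic_ballpark(self):
        """End to end, the threshold from real LMM scans stays within a small
        factor of the Beta(1, m) quantile (asymptotic LRT tail slack)."""
        m = 100
        engine, t, lines = self._null_engine(m=m, seed=7)
        thr = permutation_threshold(engine, t, lines, n_perm=1000, alpha=0.05, seed=11)
        q_true = stats.beta(1, m).ppf(0.05)
        assert q_true / 3 < thr < 3 * q_true

    def test_too_few_permutations_rejected(self):
        engine, t, lines = self._null_engine(m=5, seed=1)
        with pytest.raises(ValueError, match=">= 100"):
            permutation_threshold(engine, t, lines, n_perm=2)

    def test_same_seed_same_threshold(self):
        engine, t, lines = self._null_engine(m=20, seed=2)
        a = permutation_threshold(engine, t, lines, n_perm=150, seed=5)
        b = permutation_threshold(engine, t, lines, n_perm=150, seed=5)
        assert a == b

    def test_callable_scan_fn_agrees_with_batched_engine(self):
        engine, t, lines = self._null_engine(m=10, seed=3)
        thr_fast = permutation_threshold(engine, t, lines, n_perm=120, seed=9)
        thr_slow = permutation_threshold(engine.pvalues, t, lines, n_perm=120, seed=9)
        assert thr_fast == pytest.approx(thr_slow, rel=1e-6)


class TestClassifyMediators:
    def _result(self, rows, beta_c=-0.78):
        tab = pd.DataFrame(rows).set_index("feature")
        return MediationScanResult(
            trait="grain_yield", table=tab, beta_treatmentC=beta_c, p_C=1e-4
        )

    def test_significant_and_attenuated_is_mediator(self):
        res = self._result(
            [{"feature": "g1", "q_A": 0.5, "p_A": 0.5, "beta_A": 0.0,
              "q_B": 0.01, "p_B": 0.001, "beta_mediatorB": 0.3, "beta_treatmentB": -0.50}]
        )
        assert classify_mediators(res) == {"g1"}

    def test_significant_but_not_attenuated_is_not(self):
        res = self._result(
            [{"feature": "g1", "q_A": 0.5, "p_A": 0.5, "beta_A": 0.0,
              "q_B": 0.01, "p_B": 0.001, "beta_mediatorB": 0.3, "beta_treatmentB": 0.90}]
        )
        assert classify_mediators(res) == set()

    def test_empty_significant_set_gives_empty(self):
        res = self._result(
            [{"feature": "g1", "q_A": 0.5, "p_A": 0.5, "beta_A": 0.0,
              "q_B": 0.8, "p_B": 0.6, "beta_mediatorB": 0.0, "beta_treatmentB": -0.1}]
        )
        assert classify_mediators(res) == set()

    def test_output_subset_of_significant_b(self):
        rng = np.random.default_rng(6)
        rows = [
            {"feature": f"g{i}", "q_A": rng.random(), "p_A": rng.random(), "beta_A": 0.0,
             "q_B": rng.random() * 0.2, "p_B": rng.random() * 0.2,
             "beta_mediatorB": rng.standard_normal(),
             "beta_treatmentB": rng.standard_normal()}
            for i in range(50)
        ]
        res = self._result(rows)
        assert classify_mediators(res) <= res.significant_B("bh")


class TestOverlapSummary:
    def _scan(self, trait, sig_a, sig_b, attenuated, all_features):
        rows = []
        for f in all_features:
            rows.append(
                {"feature": f,
                 "beta_A": 0.0, "p_A": 0.001 if f in sig_a else 0.9,
                 "q_A": 0.01 if f in sig_a else 0.9,
                 "beta_mediatorB": 0.1,
                 "p_B": 0.001 if f in sig_b else 0.9,
                 "q_B": 0.01 if f in sig_b else 0.9,
                 "beta_treatmentB": -0.1 if f in attenuated else -2.0}
            )
        return MediationScanResult(
            trait=trait, table=pd.DataFrame(rows).set_index("feature"),
            beta_treatmentC=-0.78, p_C=1e-5,
        )

    def test_pairwise_intersection_counts(self):
        feats = [f"g{i}" for i in range(6)]
        scan = self._scan("grain_yield", {"g1", "g2", "g3"}, {"g2", "g3", "g4"}, set(feats), feats)
        summ = overlap_summary({"grain_yield": scan})
        row = summ.within_trait.loc["grain_yield"]
        assert row["n_A"] == 3 and row["n_B"] == 3 and row["n_A_and_B"] == 2

    def test_inclusion_exclusion_identity(self):
        feats = [f"g{i}" for i in range(8)]
        scan = self._scan("tkw", {"g0", "g1"}, {"g1", "g2", "g3"}, set(feats), feats)
        summ = overlap_summary({"tkw": scan})
        row = summ.within_trait.loc["tkw"]
        assert row["n_A"] + row["n_B"] - row["n_A_and_B"] == row["n_A_or_B"]

    def test_disjoint_traits_have_zero_cross_counts(self):
        feats = [f"g{i}" for i in range(6)]
        s1 = self._scan("grain_yield", set(), {"g1"}, {"g1"}, feats)
        s2 = self._scan("tkw", set(), {"g4"}, {"g4"}, feats)
        summ = overlap_summary({"grain_yield": s1, "tkw": s2})
        assert (summ.cross_trait["n_shared"] == 0).all()

    def test_requires_at_least_one_scan(self):
        with pytest.raises(ValueError):
            overlap_summary({})


class TestEndToEndScan:
    def test_run_mediation_scan_finds_planted_mediators(self):
        ph, expr, med = simulate_mediation_dataset(
            n_lines=75, n_genes=300, n_mediators=10, a=1.5, b=1.0, seed=77
        )
        res = run_mediation_scan(ph, "grain_yield", expr)
        found = classify_mediators(res, rule="bh")
        assert len(found & set(med)) >= 8
        assert res.p_C < 0.05

    def test_path_d_refuses(self):
        with pytest.raises(NotImplementedError, match="two-mediator"):
            path_D()
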