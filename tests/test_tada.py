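import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import oracles
from mitodnv.simulate import make_truth, simulate_rate_table
from mitodnv.tada import (
    TadaHyperParams,
    Tier,
    assign_tier,
    bayesian_fdr,
    class_bayes_factor,
    estimate_gamma_from_burden,
    gene_bayes_factor,
    run_tada,
    run_tada_meta,
    tier_counts,
)


class TestClassBayesFactor:
    def test_point_mass_prior_at_one_is_null(self):
        """gamma_mean = 1 with huge beta makes H1 coincide with H0: BF -> 1."""
        for x in range(6):
            bf = class_bayes_factor(x, 1e-5, 1000, gamma_mean=1.0, beta=1e7)
            assert bf == pytest.approx(1.0, rel=1e-4)

    def test_zero_count_is_evidence_against_risk(self):
        bf = class_bayes_factor(0, 1e-5, 5000, gamma_mean=20.0, beta=1.0)
        assert bf < 1.0

    def test_matches_quadrature_worked_example(self):
        # lambda = 2 N mu = 0.001
        bf = class_bayes_factor(2, 0.001 / (2 * 1000), 1000, gamma_mean=20.0, beta=1.0)
        oracle = oracles.bayes_factor_quadrature(2, 0.001, 20.0, 1.0)
        assert bf == pytest.approx(oracle, rel=1e-6)
        assert bf == pytest.approx(411.28, rel=1e-3)

    def test_strictly_increasing_in_count(self):
        bfs = [
            class_bayes_factor(x, 2e-5, 5000, gamma_mean=10.0, beta=1.0)
            for x in range(8)
        ]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_vectorized_matches_scalar(self):
        xs = np.array([0, 1, 2, 3])
        mus = np.array([1e-5, 2e-5, 1e-6, 5e-5])
        vec = class_bayes_factor(xs, mus, 3000, 15.0, 1.0)
        for i in range(4):
            assert vec[i] == pytest.approx(
                class_bayes_factor(int(xs[i]), float(mus[i]), 3000, 15.0, 1.0)
            )

    def test_rejects_zero_mu(self):
        with pytest.raises(ValueError):
            class_bayes_factor(1, 0.0, 1000, 20.0, 1.0)

    def test_extreme_counts_remain_usable_evidence(self):
        bf = class_bayes_factor(100, 1e-6, 10000, gamma_mean=50.0, beta=1.0)
        assert np.isfinite(bf) and bf > 1e10
        # evidence beyond float range degrades gracefully to q = 0
        huge = class_bayes_factor(500, 1e-6, 10000, gamma_mean=50.0, beta=1.0)
        assert huge > 1e300 or np.isinf(huge)
        q = bayesian_fdr({"g": huge, "h": 1.0}, pi=0.05)
        assert q["g"] == 0.0


class TestGeneBayesFactor:
    def test_identities(self):
        assert gene_bayes_factor(1.0, 1.0) == pytest.approx(1.0)
        assert gene_bayes_factor(2.0, 3.0) == pytest.approx(6.0)
        assert gene_bayes_factor([2.0, 3.0], 4.0) == pytest.approx(24.0)
        assert gene_bayes_factor(0.0, 5.0) == 0.0

    def test_pooled_mode_invariant_to_count_split(self, rate_table):
        """Pooled meta depends only on summed counts, not how they split."""
        genes = list(rate_table.index)
        rng = np.random.default_rng(17)
        total = pd.DataFrame(
            {"n_dmis": rng.poisson(0.5, len(genes)), "n_ptv": rng.poisson(0.3, len(genes))},
            index=genes,
        )
        params = TadaHyperParams()
        for seed in range(3):
            r = np.random.default_rng(seed)
            split_d = r.binomial(total["n_dmis"], 0.5)
            split_p = r.binomial(total["n_ptv"], 0.5)
            c1 = pd.DataFrame({"n_dmis": split_d, "n_ptv": split_p}, index=genes)
            c2 = total - c1
            pooled = run_tada_meta(
                {"A": c1, "B": c2}, rate_table, {"A": 700, "B": 300}, params, mode="pooled"
            )
            direct = run_tada(total, rate_table, 1000, params)
            pd.testing.assert_series_equal(
                pooled["bf_total"].sort_index(), direct["bf_total"].sort_index()
            )

    def test_product_mode_multiplies_cohort_evidence(self, rate_table):
        genes = list(rate_table.index)
        counts = pd.DataFrame({"n_dmis": 0, "n_ptv": 0}, index=genes)
        counts.loc[genes[0], "n_ptv"] = 2
        params = TadaHyperParams()
        per_a = run_tada(counts, rate_table, 500, params)
        per_b = run_tada(counts, rate_table, 800, params)
        prod = run_tada_meta(
            {"A": counts, "B": counts}, rate_table, {"A": 500, "B": 800}, params,
            mode="product",
        )
        expected = per_a.loc[genes[0], "bf_total"] * per_b.loc[genes[0], "bf_total"]
        assert prod.loc[genes[0], "bf_total"] == pytest.approx(expected, rel=1e-10)


class TestEstimateGamma:
    @pytest.mark.parametrize(
        "oe,pi,expected", [(1.0, 0.05, 1.0), (1.54, 0.05, 11.8), (0.8, 0.05, 1.0)]
    )
    def test_examples(self, oe, pi, expected):
        assert estimate_gamma_from_burden(oe, pi) == pytest.approx(expected, abs=1e-9)

    def test_recovers_generating_gamma_at_scale(self):
        """Method-of-moments gamma from a simulated O/E is within 15% at N=50k."""
        n_genes, n_samples, gamma_mean, pi = 2000, 50000, 20.0, 0.05
        rates = simulate_rate_table(n_genes, seed=4)
        estimates = []
        for seed in range(5):
            truth = make_truth(
                rates.index, pi=pi, gamma_mean_ptv=gamma_mean, seed=seed
            )
            lam = 2 * n_samples * rates["mu_ptv"].to_numpy()
            rng = np.random.default_rng(1000 + seed)
            counts = rng.poisson(lam * truth.gamma["ptv"].to_numpy())
            oe = counts.sum() / lam.sum()
            estimates.append(estimate_gamma_from_burden(oe, pi))
        assert abs(np.mean(estimates) - gamma_mean) / gamma_mean < 0.15


class TestBayesianFdr:
    def test_huge_bf_drives_q_to_zero(self):
        q = bayesian_fdr({"g": 1e12}, pi=0.05)
        assert q["g"] < 1e-9

    def test_all_null_bfs_give_prior(self):
        q = bayesian_fdr({f"g{i}": 1.0 for i in range(10)}, pi=0.05)
        assert np.allclose(q.to_numpy(), 0.95)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(23)
        bfs = np.concatenate([rng.lognormal(0, 2, 95), np.ones(5)])  # include ties
        genes = [f"g{i}" for i in range(100)]
        q = bayesian_fdr(pd.Series(bfs, index=genes), pi=0.05)
        oracle = oracles.bayesian_fdr_bruteforce(bfs, 0.05)
        assert np.allclose(q.to_numpy(), oracle)

    def test_monotone_along_bf_ordering(self):
        rng = np.random.default_rng(31)
        bfs = pd.Series(rng.lognormal(0, 3, 200), index=[f"g{i}" for i in range(200)])
        q = bayesian_fdr(bfs, pi=0.05)
        ordered = q[bfs.sort_values(ascending=False).index].to_numpy()
        assert np.all(np.diff(ordered) >= -1e-12)


class TestTiers:
    @pytest.mark.parametrize(
        "q,tier",
        [
            (0.0, Tier.STRONG),
            (0.05, Tier.STRONG),
            (0.07, Tier.POSSIBLE),
            (0.1, Tier.POSSIBLE),
            (0.15, Tier.SUGGESTIVE),
            (0.2, Tier.SUGGESTIVE),
            (0.5, Tier.NONE),
        ],
    )
    def test_boundaries_inclusive(self, q, tier):
        assert assign_tier(q) is tier

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            assign_tier(1.5)


class TestRunTada:
    def test_zero_count_genes_retained_with_small_bf(self, rate_table):
        genes = list(rate_table.index)
        counts = pd.DataFrame({"n_dmis": 0, "n_ptv": 0}, index=genes)
        counts.loc[genes[0], "n_ptv"] = 4
        res = run_tada(counts, rate_table, 5000)
        assert len(res) == len(genes)
        assert res.index[0] == genes[0]
        assert (res["bf_total"].iloc[1:] < 1).all()

    def test_ranks_true_risk_genes(self):
        rates = simulate_rate_table(300, seed=9)
        truth = make_truth(rates.index, pi=0.05, seed=9)
        n = 20000
        rng = np.random.default_rng(77)
        counts = pd.DataFrame(
            {
                "n_dmis": rng.poisson(
                    2 * n * rates["mu_dmis"].to_numpy() * truth.gamma["dmis"].to_numpy()
                ),
                "n_ptv": rng.poisson(
                    2 * n * rates["mu_ptv"].to_numpy() * truth.gamma["ptv"].to_numpy()
                ),
            },
            index=rates.index,
        )
        res = run_tada(counts, rates, n)
        top = set(res.index[: truth.n_risk])
        recall = len(top & truth.risk_genes) / truth.n_risk
        assert recall >= 0.5
        counts_by_tier = tier_counts(res)
        assert sum(counts_by_tier.values()) == len(rates)
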