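"""The zero-spiked DP sampler, its exact oracle, and posterior summaries."""

import numpy as np
import pandas as pd
import pytest

from npbmix.npb import (
    NPBChain,
    NPBConfig,
    compute_pip,
    convergence_report,
    exact_spike_slab_pip,
    npb_fit,
    sensitivity_sweep,
    summarize_posterior,
)

from .conftest import make_selection_design, standardized_columns


def make_chain(beta_draws, names=None):
    beta = np.atleast_2d(np.asarray(beta_draws, dtype=float))
    if beta.shape[0] == 1:
        beta = beta.T
    T, p = beta.shape
    names = names or [f"v{j}" for j in range(p)]
    return NPBChain(
        beta=beta,
        zeta=np.zeros((T, 0)),
        gamma=np.zeros((T, 0)),
        sigma2=np.ones(T),
        alpha1=np.ones(T),
        alpha2=np.ones(T),
        pi0_main=np.full(T, 0.5),
        pi0_inter=np.full(T, 0.5),
        k_main=np.ones(T, dtype=int),
        k_inter=np.ones(T, dtype=int),
        beta_names=names,
        zeta_names=[],
        gamma_names=[],
        outcome="birth_weight",
        config=NPBConfig(n_iter=200, n_burn=50, thin=1),
    )


class TestComputePip:
    def test_three_of_four_nonzero(self):
        chain = make_chain([1.0, 2.0, 0.0, 3.0])
        assert compute_pip(chain, "v0") == 0.75

    def test_always_spike_is_zero(self):
        chain = make_chain([0.0] * 10)
        assert compute_pip(chain, "v0") == 0.0

    def test_matches_recount_oracle(self):
        rng = np.random.default_rng(0)
        draws = rng.standard_normal(500) * (rng.random(500) < 0.3)
        chain = make_chain(draws)
        recount = 1.0 - np.mean(draws == 0.0)
        assert compute_pip(chain, "v0") == pytest.approx(recount, abs=1e-12)

    def test_unknown_term_raises(self):
        with pytest.raises(KeyError):
            compute_pip(make_chain([1.0]), "nope")


class TestSummarizePosterior:
    def test_constant_draws(self):
        chain = make_chain([5.0] * 120)
        summ = summarize_posterior(chain)
        row = summ.loc["v0"]
        assert row["mean"] == 5.0 and row["lo"] == 5.0 and row["hi"] == 5.0

    def test_model_averaged_mean_includes_zeros(self):
        chain = make_chain([0.0, 0.0, 0.0, 10.0] * 30)
        row = summarize_posterior(chain).loc["v0"]
        assert row["mean"] == pytest.approx(2.5)
        assert row["pip"] == pytest.approx(0.25)

    def test_interval_matches_quantile_recount(self):
        rng = np.random.default_rng(1)
        draws = rng.standard_normal(400)
        chain = make_chain(draws)
        row = summarize_posterior(chain).loc["v0"]
        assert row["lo"] == np.quantile(draws, 0.025)
        assert row["hi"] == np.quantile(draws, 0.975)

    def test_too_few_draws_raises(self):
        with pytest.raises(ValueError, match="100"):
            summarize_posterior(make_chain([1.0] * 50))


class TestExactOracle:
    def test_vanishing_slab_limit(self):
        """tau -> 0 makes spike and slab indistinguishable: PIP = 1 - pi0."""
        rng = np.random.default_rng(2)
        x = standardized_columns(rng, 25, 3)
        y = rng.standard_normal(25)
        pip = exact_spike_slab_pip(x, y, sigma2=1.0, pi0=0.7, tau=1e-8)
        assert np.allclose(pip, 0.3, atol=1e-6)

    def test_orthogonal_column_not_selected(self):
        rng = np.random.default_rng(3)
        x = standardized_columns(rng, 200, 2)
        y = x[:, 0] * 2.0  # exactly orthogonal to nothing but noiseless in col 0
        y = y - x[:, 1] * (x[:, 1] @ y) / (x[:, 1] @ x[:, 1])  # orthogonalize
        pip = exact_spike_slab_pip(x, y + 1e-6 * rng.standard_normal(200), 1.0, 0.5, 1.0)
        assert pip[1] < 0.5

    def test_perfect_predictor_selected(self):
        rng = np.random.default_rng(4)
        x = standardized_columns(rng, 40, 2)
        y = 3.0 * x[:, 0] + 1e-4 * rng.standard_normal(40)
        pip = exact_spike_slab_pip(x, y, sigma2=1e-2, pi0=0.5, tau=2.0)
        assert pip[0] > 0.999

    def test_enumeration_bound(self):
        with pytest.raises(ValueError, match="p <= 12"):
            exact_spike_slab_pip(np.ones((5, 13)), np.ones(5), 1.0, 0.5, 1.0)


class TestSamplerAgainstOracle:
    def test_independent_mode_matches_enumeration(self):
        """Cluster-free sampler PIPs converge to the exact enumeration."""
        rng = np.random.default_rng(5)
        n, p = 30, 3
        x = standardized_columns(rng, n, p)
        y = x @ np.array([0.8, 0.0, -0.4]) + 0.7 * rng.standard_normal(n)
        sigma2, pi0, tau = 0.49, 0.6, 1.0
        exact = exact_spike_slab_pip(x, y, sigma2, pi0, tau)
        design = make_selection_design(x, y)
        cfg = NPBConfig(
            n_iter=8000, n_burn=1000, thin=1, mode="independent_spike_slab",
            fix_sigma2=sigma2, fix_pi0=pi0, slab_sd=tau,
            standardize_outcome=False, seed=6,
        )
        chain = npb_fit(design, cfg)
        pips = np.array([compute_pip(chain, f"v{j}") for j in range(p)])
        assert np.abs(pips - exact).max() < 0.04


class TestDPFit:
    def test_seeded_determinism(self):
        rng = np.random.default_rng(7)
        x = standardized_columns(rng, 60, 4)
        y = 2.0 * x[:, 0] + rng.standard_normal(60)
        design = make_selection_design(x, y)
        cfg = NPBConfig(n_iter=400, n_burn=100, thin=1, seed=8)
        a, b = npb_fit(design, cfg), npb_fit(design, cfg)
        assert np.array_equal(a.beta, b.beta)
        assert np.array_equal(a.sigma2, b.sigma2)

    def test_exact_zeros_and_cluster_coherence(self):
        """Spike draws are exact zeros; distinct atom values never exceed
        the recorded cluster count (members share atoms bit-for-bit)."""
        rng = np.random.default_rng(9)
        n, p = 150, 6
        x = standardized_columns(rng, n, p)
        y = x @ np.array([1.5, 1.5, 0, 0, 0, 0.0]) + rng.standard_normal(n)
        design = make_selection_design(x, y)
        chain = npb_fit(design, NPBConfig(n_iter=600, n_burn=100, thin=1, seed=10))
        assert (chain.beta == 0.0).any()  # spike visited with exact zeros
        for t in range(0, chain.n_retained, 50):
            assert len(np.unique(chain.beta[t])) <= chain.k_main[t]

    def test_strong_effect_recovered_small_problem(self):
        rng = np.random.default_rng(11)
        n = 200
        x = standardized_columns(rng, n, 5)
        y = 100.0 + 30.0 * x[:, 2] + 10.0 * rng.standard_normal(n)
        design = make_selection_design(x, y)
        idx = pd.RangeIndex(n)
        design.w = pd.DataFrame({"intercept": np.ones(n)}, index=idx)
        chain = npb_fit(design, NPBConfig(n_iter=1200, n_burn=200, thin=1, seed=12))
        summ = summarize_posterior(chain)
        assert summ.loc["v2", "pip"] > 0.95
        # posterior mean within 3 sampling SEs (10/sqrt(200) ~ 0.71) of truth
        assert summ.loc["v2", "mean"] == pytest.approx(30.0, abs=3 * 10.0 / np.sqrt(n))
        assert summ.loc["v2", "hi"] - summ.loc["v2", "lo"] > 0
        assert abs(chain.intercept.mean() - 100.0) < 3.0

    def test_permutation_equivariance_statistical(self):
        """Permuting exposure columns permutes PIPs within MC error."""
        rng = np.random.default_rng(13)
        n, p = 150, 4
        x = standardized_columns(rng, n, p)
        y = 2.0 * x[:, 1] + rng.standard_normal(n)
        perm = [3, 1, 0, 2]
        d1 = make_selection_design(x, y, names=[f"v{j}" for j in range(p)])
        d2 = make_selection_design(x[:, perm], y, names=[f"v{j}" for j in perm])
        c1 = npb_fit(d1, NPBConfig(n_iter=3000, n_burn=500, thin=1, seed=14))
        c2 = npb_fit(d2, NPBConfig(n_iter=3000, n_burn=500, thin=1, seed=15))
        for j in range(p):
            assert compute_pip(c1, f"v{j}") == pytest.approx(
                compute_pip(c2, f"v{j}"), abs=0.1
            )

    def test_degenerate_column_identified(self):
        rng = np.random.default_rng(16)
        x = standardized_columns(rng, 30, 2)
        design = make_selection_design(x, rng.standard_normal(30))
        design.x["v1"] = 0.0
        with pytest.raises(ValueError, match="v1"):
            npb_fit(design, NPBConfig(n_iter=300, n_burn=100, thin=1))

    def test_retention_floor(self):
        design = make_selection_design(np.zeros((20, 0)), np.arange(20.0))
        with pytest.raises(ValueError, match=">= 100"):
            npb_fit(design, NPBConfig(n_iter=150, n_burn=100, thin=1))


class TestSweepAndDiagnostics:
    def test_singleton_grid(self):
        rng = np.random.default_rng(17)
        x = standardized_columns(rng, 80, 3)
        y = 3.0 * x[:, 0] + rng.standard_normal(80)
        design = make_selection_design(x, y)
        res = sensitivity_sweep(
            design, NPBConfig(n_iter=400, n_burn=100, thin=1, seed=18), grid=(1.0,)
        )
        assert res.jaccard.shape == (1, 1) and res.jaccard.iloc[0, 0] == 1.0

    def test_white_noise_ess_near_draw_count(self):
        rng = np.random.default_rng(19)
        chain = make_chain(rng.standard_normal(1000))
        rep = convergence_report(chain, terms=["v0"])
        assert rep.loc["v0", "ess"] == pytest.approx(1000, rel=0.2)

    def test_constant_chain_ess_floor(self):
        chain = make_chain([2.0] * 400)
        rep = convergence_report(chain, terms=["v0"])
        assert rep.loc["v0", "ess"] == 1.0
        assert bool(rep.loc["v0", "flagged"])

    def test_two_chain_psrf_on_planted_effect(self):
        rng = np.random.default_rng(20)
        n = 150
        x = standardized_columns(rng, n, 3)
        y = 25.0 * x[:, 0] + 5.0 * rng.standard_normal(n)
        design = make_selection_design(x, y)
        chains = [
            npb_fit(design, NPBConfig(n_iter=1500, n_burn=500, thin=1, seed=s))
            for s in (21, 22)
        ]
        rep = convergence_report(chains, terms=["v0"])
        assert rep.loc["sigma2", "rhat"] < 1.1
        assert rep.loc["v0", "rhat"] < 1.1
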