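"""Two-epoch model inference: densities, likelihood, MCMC machinery."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist
from scipy.stats import multivariate_normal, norm

from cdtkit import (
    Alignment,
    SubstitutionModel,
    TwoEpochModel,
    coalescent_loglik,
    compare_models,
    demographic_size,
    extract_posterior,
    hpd_interval,
    marginal_likelihood,
    run_tem_mcmc,
    simulate_coalescent,
    tree_loglik,
)
from cdtkit.tem_inference import MCMCTrace, stepping_stone_from_samples
from cdtkit.trees import Genealogy

from conftest import random_genealogy


class TestDemographicSize:
    def test_logistic_inflection_is_half_growth(self):
        m = TwoEpochModel("logistic", 0.03, 0.003, 1e-3)
        assert demographic_size(m, 1e-3) == pytest.approx((0.03 + 0.003) / 2)

    def test_deep_time_limit(self):
        m = TwoEpochModel("logistic", 0.03, 0.003, 1e-3)
        assert demographic_size(m, 1.0) == pytest.approx(0.003, rel=1e-6)

    def test_degenerate_exponential_constant(self):
        m = TwoEpochModel("exponential", 0.01, 0.01, 5e-4)
        t = np.linspace(0, 0.1, 20)
        assert np.allclose(demographic_size(m, t), 0.01)

    def test_negative_time_rejected(self):
        m = TwoEpochModel("exponential", 0.01, 0.01, 5e-4)
        with pytest.raises(ValueError):
            demographic_size(m, -1e-6)


def _quadrature_coal_loglik(gen, model):
    events = np.sort(gen.times[gen.n_tips:])
    lp, t_prev, k = 0.0, 0.0, gen.n_tips
    for t in events:
        kink = model.transition_time
        integral, _ = quad(
            lambda u: 1.0 / model.size(u), t_prev, t,
            limit=500, epsabs=1e-13, epsrel=1e-12,
            points=[kink] if t_prev < kink < t else None,
        )
        lp += -k * (k - 1) / 2.0 * integral - math.log(model.size(t))
        t_prev, k = t, k - 1
    return lp


class TestCoalescentLoglik:
    def test_kingman_pair_closed_form(self):
        theta, t = 0.7, 0.4
        g = Genealogy([2, 2, -1], [0, 0, t], ["a", "b"])
        m = TwoEpochModel("exponential", theta, theta, 1.0)
        assert coalescent_loglik(g, m) == pytest.approx(-math.log(theta) - t / theta)

    @pytest.mark.parametrize("kind", ["exponential", "logistic"])
    def test_matches_quadrature_oracle(self, kind):
        m = TwoEpochModel(kind, 0.02, 0.0004, 2.5e-4)
        for seed in range(20):
            g = simulate_coalescent(5 + seed % 4, m, seed=seed)
            assert coalescent_loglik(g, m) == pytest.approx(
                _quadrature_coal_loglik(g, m), abs=1e-8
            )

    @pytest.mark.parametrize("kind", ["exponential", "logistic"])
    def test_degenerate_equals_constant_formula(self, kind, constant_model):
        g = simulate_coalescent(8, constant_model, seed=3)
        m = TwoEpochModel(kind, 0.01, 0.01, 1e-3)
        events = np.sort(g.times[8:])
        lp, t_prev, k = 0.0, 0.0, 8
        for t in events:
            lp += -k * (k - 1) / 2.0 * (t - t_prev) / 0.01 - math.log(0.01)
            t_prev, k = t, k - 1
        assert coalescent_loglik(g, m) == pytest.approx(lp, rel=1e-12)


def _hky_q(kappa, freqs):
    q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i != j:
                q[i, j] = (kappa if (i, j) in transitions else 1.0) * freqs[j]
    np.fill_diagonal(q, -q.sum(axis=1))
    mu = -(freqs * np.diag(q)).sum()
    return q / mu


def _gamma_rates(shape, k):
    edges = gamma_dist.ppf(np.linspace(0, 1, k + 1), a=shape, scale=1 / shape)
    upper = gamma_dist.cdf(edges, a=shape + 1, scale=1 / shape)
    r = k * np.diff(upper)
    return r / r.mean()


CODES = {"A": 0, "C": 1, "G": 2, "T": 3}


def _brute_force_loglik(aln, gen, kappa, freqs, gamma_shape, ncat=4):
    """Exhaustive sum over internal-state assignments with expm matrices."""
    q = _hky_q(kappa, np.asarray(freqs))
    rates = _gamma_rates(gamma_shape, ncat) if gamma_shape else np.ones(1)
    children = gen.children()
    bl = gen.branch_lengths()
    n = gen.n_tips
    internal = list(range(n, gen.n_nodes))
    total = 0.0
    seq_codes = [[CODES[c] for c in s] for s in aln.sequences]
    order = {lab: i for i, lab in enumerate(aln.labels)}
    tip_state = [seq_codes[order[lab]] for lab in gen.labels]
    for site in range(aln.length):
        site_lik = 0.0
        for rate in rates:
            p_mats = {v: expm(q * bl[v] * rate) for v in range(gen.n_nodes)}
            import itertools

            lik = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                states = {v: a for v, a in zip(internal, assign)}
                for tip in range(n):
                    states[tip] = tip_state[tip][site]
                term = freqs[states[gen.root]]
                for v in range(gen.n_nodes):
                    if gen.parent[v] >= 0:
                        term *= p_mats[v][states[gen.parent[v]], states[v]]
                lik += term
            site_lik += lik / len(rates)
        total += math.log(site_lik)
    return total


class TestTreeLoglik:
    def test_constant_alignment_zero_height_tree(self):
        aln = Alignment(["ACGT", "ACGT", "ACGT"], ["a", "b", "c"])
        g = Genealogy([3, 3, 4, 4, -1], [0, 0, 0, 0, 0], ["a", "b", "c"])
        freqs = np.array([0.1, 0.2, 0.3, 0.4])
        sub = SubstitutionModel(kappa=2.0, base_frequencies=freqs, gamma_shape=0.7)
        assert tree_loglik(aln, g, sub) == pytest.approx(np.log(freqs).sum())

    def test_two_tip_matches_matrix_exponential(self):
        t = 0.07
        g = Genealogy([2, 2, -1], [0, 0, t / 2], ["a", "b"])
        freqs = np.array([0.3, 0.2, 0.3, 0.2])
        aln = Alignment(["ACGTAC", "AGGTAT"], ["a", "b"])
        sub = SubstitutionModel(kappa=5.0, base_frequencies=freqs)
        p = expm(_hky_q(5.0, freqs) * t)
        expect = sum(
            math.log((freqs * p[:, CODES[y]] * np.eye(4)[CODES[x]]).sum())
            for x, y in zip(*aln.sequences)
        )
        assert tree_loglik(aln, g, sub) == pytest.approx(expect, abs=1e-10)

    @pytest.mark.parametrize("n_tips,seed", [(4, 0), (4, 5), (5, 1)])
    def test_matches_exhaustive_state_sum(self, n_tips, seed, hky_gamma):
        from cdtkit import simulate_sequences

        gen = random_genealogy(n_tips, seed)
        aln = simulate_sequences(gen, hky_gamma, 10, seed=seed + 50)
        got = tree_loglik(aln, gen, hky_gamma)
        expect = _brute_force_loglik(
            aln, gen, hky_gamma.kappa, hky_gamma.base_frequencies, hky_gamma.gamma_shape
        )
        assert got == pytest.approx(expect, abs=1e-8)

    def test_label_mismatch_rejected(self, hky_gamma):
        g = Genealogy([2, 2, -1], [0, 0, 0.1], ["a", "b"])
        aln = Alignment(["ACGT", "ACGT"], ["a", "zzz"])
        with pytest.raises(ValueError):
            tree_loglik(aln, g, hky_gamma)


class TestMcmcMechanics:
    def test_record_count_and_columns(self, expansion_alignment):
        trace = run_tem_mcmc(
            expansion_alignment, "logistic", "strict",
            chain={"length": 2000, "sample_interval": 100, "min_ess": 1},
            seed=0, keep_trees=True,
        )
        assert len(trace.params) == 2000 // 100 + 1
        assert len(trace.trees) == len(trace.params)
        for col in ("posterior", "likelihood", "transition_time",
                    "theta_modern", "theta_ancient", "tmrca", "kappa"):
            assert col in trace.params.columns

    def test_short_chain_flags_nonconvergence(self, expansion_alignment):
        trace = run_tem_mcmc(
            expansion_alignment, "exponential", "strict",
            chain={"length": 1000, "sample_interval": 50, "min_ess": 500},
            seed=1,
        )
        assert not trace.converged
        assert any("converge" in w for w in trace.warnings)

    def test_relaxed_clock_runs_and_records_rates(self, expansion_alignment):
        trace = run_tem_mcmc(
            expansion_alignment, "logistic", "exponential_relaxed",
            chain={"length": 1500, "sample_interval": 100, "min_ess": 1},
            seed=2,
        )
        assert trace.params["mean_branch_rate"].std() > 0

    def test_invalid_inputs_rejected(self, expansion_alignment):
        with pytest.raises(ValueError):
            run_tem_mcmc(expansion_alignment, "cubic", "strict")
        with pytest.raises(ValueError):
            run_tem_mcmc(expansion_alignment, "logistic", "warped_clock")


class TestPosteriorSummaries:
    def test_burn_in_record_arithmetic(self):
        # 10,000 records at 10% burn-in leave 9,000
        df = __import__("pandas").DataFrame({
            "state": np.arange(10_000), "x": np.random.default_rng(0).normal(size=10_000)
        })
        trace = MCMCTrace(df, [], 10_000, 1, 0, {}, {}, True)
        ps = extract_posterior(trace, "x", burn_in_fraction=0.1)
        assert ps.samples.size == 9_000
        assert extract_posterior(trace, "x", 0.0).samples.size == 10_000

    def test_constant_trace_zero_width_hpd(self):
        df = __import__("pandas").DataFrame({"state": range(50), "x": [2.5] * 50})
        trace = MCMCTrace(df, [], 50, 1, 0, {}, {}, True)
        ps = extract_posterior(trace, "x", 0.0)
        assert ps.median == ps.mean == 2.5
        assert ps.hpd_upper - ps.hpd_lower == 0.0

    def test_unknown_parameter_rejected(self):
        df = __import__("pandas").DataFrame({"state": [0], "x": [1.0]})
        trace = MCMCTrace(df, [], 1, 1, 0, {}, {}, True)
        with pytest.raises(ValueError):
            extract_posterior(trace, "not_there")

    def test_hpd_is_shortest_interval(self, rng):
        x = np.concatenate([rng.normal(0, 1, 5000), rng.normal(8, 0.1, 200)])
        lo, hi = hpd_interval(x, 0.95)
        assert lo > -3 and hi < 4  # excludes the tiny far mode


class TestMarginalLikelihood:
    def _conjugate_power_samples(self, rng, betas, x, sigma, m0, tau, n_draws=4000):
        n = x.size
        out = {}
        for b in betas:
            prec = b * n / sigma**2 + 1.0 / tau**2
            mean = (b * x.sum() / sigma**2 + m0 / tau**2) / prec
            mus = rng.normal(mean, 1 / math.sqrt(prec), size=n_draws)
            out[float(b)] = np.array([
                norm.logpdf(x, loc=mu, scale=sigma).sum() for mu in mus
            ])
        return out

    def test_stepping_stone_recovers_conjugate_marginal(self, rng):
        sigma, m0, tau, n = 1.0, 0.0, 2.0, 12
        x = rng.normal(1.3, sigma, size=n)
        cov = sigma**2 * np.eye(n) + tau**2 * np.ones((n, n))
        analytic = multivariate_normal.logpdf(x, mean=np.full(n, m0), cov=cov)
        betas = (np.arange(16) / 16) ** (1 / 0.3)
        samples = self._conjugate_power_samples(rng, betas, x, sigma, m0, tau)
        assert stepping_stone_from_samples(samples) == pytest.approx(analytic, abs=0.1)

    def test_self_comparison_bayes_factor_near_zero(self, rng):
        sigma, m0, tau, n = 1.0, 0.0, 2.0, 12
        x = rng.normal(0.5, sigma, size=n)
        betas = (np.arange(16) / 16) ** (1 / 0.3)
        a = stepping_stone_from_samples(
            self._conjugate_power_samples(rng, betas, x, sigma, m0, tau))
        b = stepping_stone_from_samples(
            self._conjugate_power_samples(rng, betas, x, sigma, m0, tau))
        assert abs(2 * (a - b)) < 0.2

    def test_power_ladder_feeds_stepping_stone(self, expansion_alignment):
        trace = run_tem_mcmc(
            expansion_alignment, "logistic", "strict",
            chain={"length": 4000, "sample_interval": 40, "min_ess": 1}, seed=4,
            keep_trees=False, power_ladder=list((np.arange(8) / 8) ** (1 / 0.3)),
        )
        assert trace.power_samples and 0.0 in trace.power_samples
        est, se = marginal_likelihood(trace, method="stepping_stone", n_bootstrap=50)
        assert np.isfinite(est) and est < 0 and se >= 0

    def test_harmonic_mean_runs_on_trace(self, expansion_alignment):
        trace = run_tem_mcmc(
            expansion_alignment, "logistic", "strict",
            chain={"length": 3000, "sample_interval": 30, "min_ess": 1}, seed=3,
            keep_trees=False,
        )
        est, se = marginal_likelihood(trace, method="harmonic_mean")
        assert est < 0 and se >= 0
        with pytest.raises(ValueError):
            marginal_likelihood(trace, method="stepping_stone")


class TestModelComparison:
    def test_printed_example_pair(self):
        cmp = compare_models({"exp_exp": -1012.3, "logi_exp": -1008.9})
        assert cmp.bf_matrix.loc["logi_exp", "exp_exp"] == pytest.approx(6.8)
        assert cmp.bf_matrix.loc["exp_exp", "logi_exp"] == pytest.approx(-6.8)
        assert cmp.best_model == "logi_exp"

    def test_antisymmetry_and_permutation_invariance(self):
        mml = {"a": -10.0, "b": -12.5, "c": -9.1}
        cmp1 = compare_models(mml)
        cmp2 = compare_models(dict(reversed(list(mml.items()))))
        assert cmp1.best_model == cmp2.best_model == "c"
        m = cmp1.bf_matrix.to_numpy()
        assert np.allclose(m, -m.T)

    def test_single_model(self):
        cmp = compare_models({"only": -5.0})
        assert cmp.best_model == "only"
        assert cmp.bf_matrix.shape == (1, 1)
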