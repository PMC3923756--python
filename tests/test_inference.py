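"""MCMC engine: known targets, determinism, diagnostics, summaries."""

from dataclasses import replace

import numpy as np
import pytest

import dietmix as dm
from dietmix.inference import _alpha_from_sticks, _sticks_from_alpha

from conftest import make_plain_scenario


def _chains_from_named(named):
    """Wrap pre-computed traces in a PosteriorChains for diagnostics tests."""

    class _Fixed:
        def __init__(self, named):
            self._named = named

        def named_draws(self, z):
            return self._named

    any_tr = next(iter(named.values()))
    C, T = any_tr.shape
    cfg = dm.SamplerConfig(seed=0, n_chains=max(C, 2), n_iterations=2, burn_in=1)
    return dm.PosteriorChains(z=np.zeros((C, T, 1)), target=_Fixed(named),
                              config=cfg, acceptance=np.ones((1, C)))


class TestStickBreaking:
    def test_zero_maps_to_barycenter(self):
        alpha, _ = _alpha_from_sticks(np.zeros((1, 4)))
        np.testing.assert_allclose(alpha, np.full((1, 5), 0.2), atol=1e-12)

    def test_roundtrip(self):
        rng = np.random.default_rng(0)
        a = rng.dirichlet(np.ones(6), size=8)
        back, _ = _alpha_from_sticks(_sticks_from_alpha(a))
        np.testing.assert_allclose(back, a, atol=1e-10)


class TestRunMcmc:
    def test_standard_normal_target(self):
        target = dm.ArrayTarget(lambda z: -0.5 * np.sum(z**2, axis=1), dim=2)
        cfg = dm.SamplerConfig(seed=1, n_chains=4, n_iterations=10_000, burn_in=2_000, thin=1)
        chains = dm.run_mcmc(target, cfg)
        pooled = np.concatenate([chains.pooled(f"z[{d}]") for d in range(2)])
        assert pooled.mean() == pytest.approx(0.0, abs=0.05)
        assert pooled.std() == pytest.approx(1.0, abs=0.05)

    def test_noiseless_determined_system_concentrates(self):
        # two sources at 0 and 10, consumer at 5: unique solution (0.5, 0.5)
        sc = make_plain_scenario([0.0, 10.0], consumer_mean=5.0, consumer_sd=0.01)
        cfg = dm.SamplerConfig(seed=2, n_chains=2, n_iterations=8_000, burn_in=2_000, thin=1)
        chains = dm.run_mcmc(dm.build_posterior_log_density(sc), cfg)
        a = chains.pooled("alpha[G0]")
        assert a.mean() == pytest.approx(0.5, abs=0.005)
        assert a.std() < 0.01

    def test_bitwise_reproducible(self, table1):
        cfg = dm.SamplerConfig(seed=5, n_chains=2, n_iterations=2_000, burn_in=500)
        post = dm.build_posterior_log_density(table1)
        z1 = dm.run_mcmc(post, cfg).z
        z2 = dm.run_mcmc(post, cfg).z
        np.testing.assert_array_equal(z1, z2)

    def test_hard_constraint_never_violated(self):
        sc = make_plain_scenario([0.0, 10.0], consumer_mean=5.0, consumer_sd=np.inf,
                                 constraints=("G0 > G1",))
        cfg = dm.SamplerConfig(seed=3, n_chains=2, n_iterations=6_000, burn_in=1_000)
        chains = dm.run_mcmc(dm.build_posterior_log_density(sc), cfg)
        a0, a1 = chains.pooled("alpha[G0]"), chains.pooled("alpha[G1]")
        assert np.all(a0 >= a1)
        np.testing.assert_allclose(a0 + a1, 1.0, atol=1e-12)

    def test_unsatisfiable_constraints_error_at_init(self):
        sc = make_plain_scenario([0.0, 10.0], consumer_mean=5.0,
                                 constraints=("G0 > G1", "G1 - G0 > 0.1"))
        with pytest.raises(RuntimeError, match="starting point"):
            dm.run_mcmc(dm.build_posterior_log_density(sc),
                        dm.SamplerConfig(seed=1, n_chains=2, n_iterations=100, burn_in=10,
                                         max_init_retries=20))

    def test_acceptance_rates_in_adaptation_band(self, table1):
        cfg = dm.SamplerConfig(seed=9, n_chains=2, n_iterations=8_000, burn_in=4_000)
        chains = dm.run_mcmc(dm.build_posterior_log_density(table1), cfg)
        assert np.all(chains.acceptance > 0.15) and np.all(chains.acceptance < 0.6)


class TestBuildPosterior:
    def test_invalid_scenario_rejected_before_sampling(self, table1):
        broken = replace(table1, weight_mean=np.array([[90.0]]))
        with pytest.raises(dm.ScenarioError, match="invalid scenario"):
            dm.build_posterior_log_density(broken)

    def test_likelihood_maximal_at_true_state(self, table1):
        """At the simulated truth the only stochastic term is the consumer
        likelihood, which peaks at its own mean."""
        post = dm.build_posterior_log_density(table1)
        z_true = _sticks_from_alpha(np.array([[0.7, 0.2, 0.1]]))
        lp_true = post.logpdf(z_true)[0]
        rng = np.random.default_rng(4)
        for _ in range(30):
            a = rng.dirichlet(np.ones(3))
            lp = post.logpdf(_sticks_from_alpha(a[None]))[0]
            # compare densities net of the (alpha-dependent) Jacobian
            jac_true = _alpha_from_sticks(z_true)[1][0]
            jac = _alpha_from_sticks(_sticks_from_alpha(a[None]))[1][0]
            assert lp - jac <= lp_true - jac_true + 1e-9

    def test_satisfied_inequality_changes_nothing(self, table1):
        post_plain = dm.build_posterior_log_density(table1)
        post_con = dm.build_posterior_log_density(table1, constraints=("Plant > Fish",))
        z = _sticks_from_alpha(np.array([[0.7, 0.2, 0.1]]))
        assert post_con.logpdf(z)[0] == pytest.approx(post_plain.logpdf(z)[0])

    def test_latent_count_for_pig_scenario(self, hare):
        post = dm.build_posterior_log_density(hare)
        kinds = {}
        for latent in post.latents:
            kinds[latent.kind] = kinds.get(latent.kind, 0) + 1
        # 20 uncertain source signals, 15 active concentrations (protein,
        # energy, bulk across 5 groups; lipids are inert), 1 routing weight,
        # 3 offsets
        assert kinds == {"signal": 20, "conc": 15, "weight": 1, "offset": 3}


class TestDiagnose:
    def test_constant_chains_flagged_not_crashing(self):
        named = {"x": np.ones((2, 200))}
        diag = dm.diagnose(_chains_from_named(named))
        assert bool(diag.loc["x", "flagged"]) and diag.loc["x", "reason"] == "constant chain"

    def test_independent_draws_pass(self):
        rng = np.random.default_rng(0)
        named = {"x": rng.normal(size=(4, 2_000))}
        diag = dm.diagnose(_chains_from_named(named))
        assert diag.loc["x", "rhat"] == pytest.approx(1.0, abs=0.01)
        assert not diag.loc["x", "flagged"]

    def test_unmixed_chains_flagged(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 1_000))
        x[1] += 10.0  # two chains stuck in different modes
        diag = dm.diagnose(_chains_from_named({"x": x}))
        assert diag.loc["x", "rhat"] > 1.05
        assert bool(diag.loc["x", "flagged"])


class TestSummarize:
    def test_percentiles_linear_interpolation(self):
        named = {"x": np.arange(1.0, 101.0).reshape(2, 50)}
        s = dm.summarize(_chains_from_named(named))
        assert s.loc["x", "p50"] == pytest.approx(50.5)
        assert s.loc["x", "median"] == s.loc["x", "p50"]
        assert s.loc["x", "p2.5"] == pytest.approx(np.percentile(np.arange(1, 101), 2.5))
        assert list(s.loc["x", ["p2.5", "p16", "p50", "p84", "p97.5"]]) == sorted(
            s.loc["x", ["p2.5", "p16", "p50", "p84", "p97.5"]])

    def test_constant_chain_degenerate_percentiles(self):
        named = {"x": np.full((2, 50), 3.14)}
        s = dm.summarize(_chains_from_named(named))
        np.testing.assert_allclose(
            s.loc["x", ["mean", "median", "p2.5", "p97.5"]].astype(float), 3.14,
            rtol=1e-12)

    def test_alpha_rows_sum_to_one(self, table1):
        cfg = dm.SamplerConfig(seed=8, n_chains=2, n_iterations=3_000, burn_in=1_000)
        chains = dm.run_mcmc(dm.build_posterior_log_density(table1), cfg)
        s = dm.summarize(chains, [f"alpha[{g}]" for g in table1.groups])
        assert s["mean"].sum() == pytest.approx(1.0, abs=1e-9)
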