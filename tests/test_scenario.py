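"""Forward-model computations: routed mixing, fraction intakes, proxy shares."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dietmix as dm
from dietmix.scenario import ScenarioError

from conftest import make_plain_scenario

# Hand-computed (exact rational arithmetic) forward values for the pig-feed
# scenario at the true diet alpha = (0, 0, 0, 0.69, 0.31), all latents at
# their means.
HARE_TRUTH_FORWARD = {
    "13Ccoll": -8.951966500199015,
    "15Ncoll": 7.458165829145728,
    "13Cglu": -2.7226990049751243,
}
HARE_TRUTH_BETA_PROTEIN = 0.33001658374792703
HARE_TRUTH_PI_13CCOLL = [0.0, 0.0, 0.0, 0.4200176314742027, 0.5799823685257973]


class TestPredictConsumerSignal:
    def test_simulated_three_source_value(self, table1):
        state = dm.LatentState.from_means(table1, [0.7, 0.2, 0.1])
        assert dm.predict_consumer_signal(table1, state, "d15N") == pytest.approx(6.6, abs=1e-12)

    def test_single_source_collapse(self, table1):
        state = dm.LatentState.from_means(table1, [1.0, 0.0, 0.0])
        assert dm.predict_consumer_signal(table1, state, "d15N") == pytest.approx(3.0 + 2.0)

    @pytest.mark.parametrize("proxy,expected", sorted(HARE_TRUTH_FORWARD.items()))
    def test_routed_pig_feed_values(self, hare, proxy, expected):
        state = dm.LatentState.from_means(hare, dm.hare_true_intake())
        assert dm.predict_consumer_signal(hare, state, proxy) == pytest.approx(expected, abs=1e-9)

    def test_degenerate_fraction_mass_raises(self, hare):
        # all intake on groups whose routed fraction has zero concentration
        sc = hare
        conc = sc.conc_mean.copy()
        conc[3, :] = 0.0  # Corn contributes nothing anywhere
        from dataclasses import replace

        broken = replace(sc, conc_mean=conc)
        state = dm.LatentState.from_means(broken, [0, 0, 0, 1.0, 0.0])
        with pytest.raises(ScenarioError, match="no dietary mass"):
            dm.predict_consumer_signal(broken, state, "13Ccoll")

    def test_convexity_within_source_range(self, table1):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.dirichlet([1, 1, 1])
            state = dm.LatentState.from_means(table1, a)
            p = dm.predict_consumer_signal(table1, state, "d15N") - 3.0
            assert 2.0 - 1e-12 <= p <= 10.0 + 1e-12

    @given(st.lists(st.floats(-30, 30), min_size=2, max_size=5),
           st.lists(st.floats(0.01, 1.0), min_size=5, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_reduces_to_linear_mixing_for_single_uniform_fraction(self, sigs, raw):
        """With one fraction at uniform concentration the routed model is the
        classical linear mixture offset + sum_i alpha_i S_i."""
        n = len(sigs)
        alpha = np.array(raw[:n]) / np.sum(raw[:n])
        sc = make_plain_scenario(sigs, consumer_mean=0.0, offset=1.5)
        state = dm.LatentState.from_means(sc, alpha)
        got = dm.predict_consumer_signal(sc, state, "P")
        assert got == pytest.approx(1.5 + float(alpha @ np.asarray(sigs)), rel=1e-9, abs=1e-9)

    def test_group_permutation_equivariance(self, hare):
        perm = [4, 2, 0, 1, 3]
        from dataclasses import replace

        permuted = replace(
            hare,
            groups=tuple(hare.groups[i] for i in perm),
            signal_mean=hare.signal_mean[perm],
            signal_sd=hare.signal_sd[perm],
            signal_ok=hare.signal_ok[perm],
            conc_mean=hare.conc_mean[perm],
            conc_sd=hare.conc_sd[perm],
        )
        alpha = np.array([0.1, 0.2, 0.3, 0.25, 0.15])
        s1 = dm.LatentState.from_means(hare, alpha)
        s2 = dm.LatentState.from_means(permuted, alpha[perm])
        for proxy in hare.proxies:
            assert dm.predict_consumer_signal(hare, s1, proxy) == pytest.approx(
                dm.predict_consumer_signal(permuted, s2, proxy), abs=1e-12)
        np.testing.assert_allclose(
            dm.proxy_contribution(alpha, hare, proxy="13Ccoll")[perm],
            dm.proxy_contribution(alpha[perm], permuted, proxy="13Ccoll"), atol=1e-12)


class TestFractionIntake:
    def test_single_fraction_is_unity(self, table1):
        np.testing.assert_allclose(dm.fraction_intake([0.3, 0.3, 0.4], table1), [1.0])

    def test_symmetric_two_fraction_split(self):
        sc = dm.DietaryScenario(
            groups=("A", "B"), fractions=("f1", "f2"), proxies=("P",),
            signal_mean=np.zeros((2, 2, 1)), signal_sd=np.zeros((2, 2, 1)),
            signal_ok=np.ones((2, 2, 1), bool),
            conc_mean=np.array([[40.0, 60.0], [60.0, 40.0]]), conc_sd=np.zeros((2, 2)),
            weight_mean=np.array([[50.0], [50.0]]), weight_sd=np.zeros((2, 1)),
            offset_mean=np.zeros(1), offset_sd=np.zeros(1),
            consumer_mean=np.zeros(1), consumer_sd=np.ones(1))
        np.testing.assert_allclose(dm.fraction_intake([0.5, 0.5], sc), [0.5, 0.5])

    def test_pig_feed_protein_share(self, hare):
        beta = dm.fraction_intake(dm.hare_true_intake(), hare)
        assert list(hare.diet_fractions) == ["Protein", "Energy"]
        assert beta[0] == pytest.approx(HARE_TRUTH_BETA_PROTEIN, abs=1e-12)
        assert beta.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_total_mass_raises(self, table1):
        from dataclasses import replace

        broken = replace(table1, conc_mean=np.zeros((3, 1)))
        with pytest.raises(ScenarioError, match="zero"):
            dm.fraction_intake([0.5, 0.3, 0.2], broken)


class TestProxyContribution:
    def test_equal_concentration_returns_alpha(self, table1):
        alpha = np.array([0.7, 0.2, 0.1])
        np.testing.assert_allclose(
            dm.proxy_contribution(alpha, table1, proxy="d15N"), alpha, atol=1e-12)

    def test_pig_feed_collagen_shares(self, hare):
        pi = dm.proxy_contribution(dm.hare_true_intake(), hare, proxy="13Ccoll")
        np.testing.assert_allclose(pi, HARE_TRUTH_PI_13CCOLL, atol=1e-12)

    def test_simplex_for_random_states(self, hare):
        rng = np.random.default_rng(3)
        for _ in range(25):
            alpha = rng.dirichlet(np.ones(5))
            for proxy in hare.proxies:
                pi = dm.proxy_contribution(alpha, hare, proxy=proxy)
                assert np.all(pi >= -1e-15)
                assert pi.sum() == pytest.approx(1.0, abs=1e-9)


class TestValidateScenario:
    def test_builtin_fixtures_are_valid(self, table1, hare):
        assert dm.validate_scenario(table1) == []
        assert dm.validate_scenario(hare) == []

    def test_weights_not_exhausting_signal(self, table1):
        from dataclasses import replace

        broken = replace(table1, weight_mean=np.array([[90.0]]))
        issues = dm.validate_scenario(broken)
        assert len(issues) == 1 and "d15N" in issues[0] and "90" in issues[0]

    def test_missing_signal_for_routed_fraction(self, hare):
        from dataclasses import replace

        ok = hare.signal_ok.copy()
        ok[3, 0, 0] = False  # Corn protein signal for 13Ccoll
        broken = replace(hare, signal_ok=ok)
        issues = dm.validate_scenario(broken)
        assert any("Corn" in v and "Protein" in v and "13Ccoll" in v for v in issues)

    def test_negative_sd_and_duplicate_names(self, table1):
        from dataclasses import replace

        broken = replace(table1, groups=("Plant", "Plant", "Fish"),
                         consumer_sd=np.array([-0.1]))
        issues = dm.validate_scenario(broken)
        assert any("duplicate" in v for v in issues)
        assert any("negative sd" in v for v in issues)


def test_uncertain_value_conventions():
    assert dm.UncertainValue(4.8, 0.5).fixed is False
    assert dm.UncertainValue(26.0).fixed is True
    with pytest.raises(ValueError):
        dm.UncertainValue(1.0, -0.1)


def test_diet_proportions_requires_simplex():
    with pytest.raises(ValueError):
        dm.DietProportions(np.array([0.5, 0.6]))
    with pytest.raises(ValueError):
        dm.DietProportions(np.array([1.2, -0.2]))
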