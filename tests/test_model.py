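"""Decision-model layer: sampling, conditioning, odds mapping, net benefit."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from threshsa.model import (
    CorrelatedBlock,
    MarginalSpec,
    ModelConfigError,
    load_model,
    model_to_config,
    net_benefit,
    odds_to_prob,
    sample_conditional,
    sample_prior,
    samples_to_frame,
    save_config,
)


class TestMarginalSpec:
    def test_unknown_family_rejected(self):
        with pytest.raises(ModelConfigError):
            MarginalSpec("x", "gamma", (1.0, 1.0))

    @pytest.mark.parametrize(
        "family,params",
        [("normal", (0.0, -1.0)), ("beta", (0.0, 2.0)), ("lognormal", (0.0, 0.0))],
    )
    def test_invalid_params_rejected(self, family, params):
        with pytest.raises(ModelConfigError):
            MarginalSpec("x", family, params)

    def test_constant_draws_are_exact(self):
        spec = MarginalSpec.constant("lam", 7.5e4)
        assert np.all(spec.sample(np.random.default_rng(0), 100) == 7.5e4)

    def test_support_respected(self):
        rng = np.random.default_rng(1)
        assert np.all(MarginalSpec.lognormal("o", -1.5, 0.11).sample(rng, 2000) > 0)
        q = MarginalSpec.logitnormal("q", 0.6, 1 / 36).sample(rng, 2000)
        assert np.all((q > 0) & (q < 1))

    def test_logitnormal_mean_matches_monte_carlo(self):
        spec = MarginalSpec.logitnormal("q", 0.6, 1 / 36)
        draws = spec.sample(np.random.default_rng(2), 200_000)
        se = draws.std(ddof=1) / np.sqrt(len(draws))
        assert abs(spec.mean() - draws.mean()) < 3 * se


class TestPriorSampling:
    def test_moments_of_builtin(self, builtin):
        n = 100_000
        theta = sample_prior(builtin, n, np.random.default_rng(3))
        L = theta[:, builtin.index("L")]
        assert abs(L.mean() - 30.0) < 3 * 5.0 / np.sqrt(n)
        assert abs(L.var(ddof=1) - 25.0) < 3 * 25.0 * np.sqrt(2 / n)

    def test_block_correlation_of_odds_ratios(self, builtin):
        n = 100_000
        theta = sample_prior(builtin, n, np.random.default_rng(4))
        r = np.corrcoef(
            np.log(theta[:, builtin.index("OR_E_d2")]),
            np.log(theta[:, builtin.index("OR_E_d3")]),
        )[0, 1]
        expected = 0.02 / np.sqrt(0.11 * 0.06)
        assert abs(r - expected) < 3 * (1 - expected**2) / np.sqrt(n)

    def test_reproducible_given_seed(self, builtin):
        a = sample_prior(builtin, 100, np.random.default_rng(5))
        b = sample_prior(builtin, 100, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)


class TestConditionalSampling:
    def test_partner_conditional_matches_closed_form(self, builtin):
        # fix C_T_d3 at its mean 2e4: partner C_T_d2 | . ~ N(1.5e4, 280)
        n = 200_000
        j = builtin.index("C_T_d3")
        theta = sample_conditional(builtin, j, 2.0e4, n, np.random.default_rng(6))
        partner = theta[:, builtin.index("C_T_d2")]
        assert np.all(theta[:, j] == 2.0e4)
        assert abs(partner.mean() - 1.5e4) < 3 * np.sqrt(280 / n)
        assert abs(partner.var(ddof=1) - 280.0) < 3 * 280.0 * np.sqrt(2 / n)

    def test_lognormal_partner_conditioning(self, builtin):
        # fix OR_E_d3 = exp(-1.75): log OR_E_d2 | . ~ N(-1.5, 0.11 - 0.02^2/0.06)
        n = 200_000
        j = builtin.index("OR_E_d3")
        theta = sample_conditional(
            builtin, j, float(np.exp(-1.75)), n, np.random.default_rng(7)
        )
        y = np.log(theta[:, builtin.index("OR_E_d2")])
        var = 0.11 - 0.02**2 / 0.06
        assert abs(y.mean() + 1.5) < 3 * np.sqrt(var / n)
        assert abs(y.var(ddof=1) - var) < 3 * var * np.sqrt(2 / n)

    def test_unlinked_components_keep_prior_distribution(self, builtin):
        n = 10_000
        j = builtin.index("Q_SE")
        cond = sample_conditional(builtin, j, 0.7, n, np.random.default_rng(8))
        prior = sample_prior(builtin, n, np.random.default_rng(9))
        ce = builtin.index("C_E")
        assert stats.ks_2samp(cond[:, ce], prior[:, ce]).pvalue > 0.01

    def test_out_of_support_value_rejected(self, builtin):
        with pytest.raises(ValueError):
            sample_conditional(
                builtin, builtin.index("OR_E_d3"), -0.1, 10, np.random.default_rng(0)
            )

    def test_plug_in_replaces_linear_variables(self, builtin):
        j = builtin.index("P_SE_d3")
        theta = sample_conditional(
            builtin, j, 0.25, 50, np.random.default_rng(10), plug_in=True
        )
        assert np.all(theta[:, builtin.index("L")] == 30.0)
        assert np.all(theta[:, builtin.index("C_E")] == 2.0e5)
        # the nonlinear event-probability variables are still sampled
        assert len(np.unique(theta[:, builtin.index("P_E_d1")])) > 1


class TestOddsToProb:
    def test_unit_odds_ratio_is_identity(self):
        assert odds_to_prob(0.15, 1.0) == pytest.approx(0.15)

    @given(
        p=st.floats(0.01, 0.99),
        orr=st.floats(1e-3, 1e3),
    )
    @settings(max_examples=100, derandomize=True)
    def test_round_trip_recovers_odds_ratio(self, p, orr):
        q = odds_to_prob(p, orr)
        assert 0 < q < 1
        recovered = (q / (1 - q)) / (p / (1 - p))
        assert recovered == pytest.approx(orr, rel=1e-9)

    def test_worked_value(self):
        assert odds_to_prob(0.15, 0.2231) == pytest.approx(0.0378796, abs=1e-6)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            odds_to_prob(1.0, 2.0)
        with pytest.raises(ValueError):
            odds_to_prob(0.5, -1.0)


class TestNetBenefit:
    def _theta(self, builtin, **overrides):
        vals = {v.name: v.mean() for v in builtin.variables}
        vals.update(overrides)
        return np.array([[vals[v.name] for v in builtin.variables]])

    def test_hand_computed_value_for_standard_of_care(self, builtin):
        # d1 is cost- and side-effect-free: f = P_E (lam L (1+Q_E)/2 - C_E)
        #                                       + (1-P_E) lam L
        theta = self._theta(builtin, L=30.0, Q_E=0.6, P_E_d1=0.15, C_E=2.0e5)
        f = net_benefit(builtin, "d1", theta)[0]
        assert f == pytest.approx(2_152_500.0)

    def test_zero_event_probability_degenerates_to_lambda_L(self, builtin):
        theta = self._theta(builtin, L=25.0, P_E_d1=1e-300)
        assert net_benefit(builtin, "d1", theta)[0] == pytest.approx(7.5e4 * 25.0)

    def test_outcome_partition(self, builtin):
        # with all costs and QALY decrements zero and Q_E = 1, every outcome
        # yields lam*L, so the four probability weights must sum to one
        theta = self._theta(
            builtin, Q_E=1.0 - 1e-12, Q_SE=0.0, C_E=0.0, C_SE=0.0,
            C_T_d2=0.0, C_T_d3=0.0,
        )
        for d in builtin.options:
            assert net_benefit(builtin, d, theta)[0] == pytest.approx(
                7.5e4 * 30.0, rel=1e-9
            )

    def test_unknown_option_rejected(self, builtin):
        with pytest.raises(KeyError):
            net_benefit(builtin, "d4", self._theta(builtin))

    @pytest.mark.parametrize("name", ["L", "Q_SE", "C_E", "C_SE", "C_T_d2", "C_T_d3"])
    def test_plug_in_mean_preserves_expectation(self, builtin, name):
        # multilinearity: replacing a linearly entering variable by its exact
        # mean leaves the Monte Carlo mean unchanged up to noise
        n = 100_000
        theta = sample_prior(builtin, n, np.random.default_rng(11))
        full = net_benefit(builtin, "d2", theta)
        theta2 = theta.copy()
        theta2[:, builtin.index(name)] = builtin.spec(builtin.index(name)).mean()
        plugged = net_benefit(builtin, "d2", theta2)
        se = np.sqrt(full.var(ddof=1) + plugged.var(ddof=1)) / np.sqrt(n)
        assert abs(full.mean() - plugged.mean()) < 3 * se


class TestConfigRoundTrip:
    @pytest.mark.parametrize("suffix", [".yaml", ".json"])
    def test_round_trip_preserves_samples(self, builtin, tmp_path, suffix):
        path = tmp_path / f"model{suffix}"
        save_config(builtin, path)
        reloaded = load_model(path)
        a = sample_prior(builtin, 500, np.random.default_rng(12))
        b = sample_prior(reloaded, 500, np.random.default_rng(12))
        np.testing.assert_array_equal(a, b)

    def test_block_marginal_consistency_enforced(self, builtin):
        cfg = model_to_config(builtin)
        cfg["variables"][5]["params"] = [1.0e4, 300.0]  # disagree with block
        with pytest.raises(ModelConfigError):
            load_model(cfg)

    def test_unregistered_utility_requires_callable(self, builtin):
        cfg = model_to_config(builtin)
        cfg["utility"] = "mystery"
        with pytest.raises(ModelConfigError):
            load_model(cfg)

    def test_samples_export_frame(self, builtin):
        theta = sample_prior(builtin, 10, np.random.default_rng(13))
        frame = samples_to_frame(builtin, theta)
        assert list(frame.columns) == [v.name for v in builtin.variables]
        assert len(frame) == 10


def test_block_covariance_validation():
    with pytest.raises(ModelConfigError):
        CorrelatedBlock((0, 1), (0.0, 0.0), ((1.0, 2.0), (2.0, 1.0)))  # not PD
    with pytest.raises(ModelConfigError):
        CorrelatedBlock((0, 1), (0.0, 0.0), ((1.0, 0.5), (0.4, 1.0)))  # asym
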