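"""Filter/smoother correctness, MLE behaviour, SEs and summary identities."""

import math

import numpy as np
import pytest
from scipy.stats import norm

import cpiswitch as cs
from cpiswitch.markov_switching import (
    FilterError,
    _hessian_direct,
    _hessian_from_gradient,
    _pack,
    _run_filter,
    _unpack,
)

from conftest import ROOT_SEED, random_params


class TestFilterAgainstOracles:
    def test_matches_path_enumeration_over_random_draws(self):
        """Forward recursion equals explicit 2^T path summation."""
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(50):
            params = random_params(rng)
            T = int(rng.integers(2, 13))
            y = rng.normal(0.05, 0.05, size=T)
            ll_filter, probs = cs.hamilton_filter(y, params)
            ll_brute = cs.brute_force_loglik(y, params)
            worst = max(worst, abs(ll_filter - ll_brute))
            assert np.max(np.abs(probs.filtered.sum(axis=1) - 1.0)) < 1e-10
        assert worst < 1e-8

    def test_matches_enumeration_with_ar_terms(self):
        rng = np.random.default_rng(11)
        params = random_params(rng, ar_order=1)
        spec = cs.ModelSpec(ar_order=1)
        y = rng.normal(0.05, 0.05, size=9)
        assert cs.hamilton_filter(y, params, spec)[0] == pytest.approx(
            cs.brute_force_loglik(y, params, spec), abs=1e-8
        )

    def test_indistinguishable_regimes_reduce_to_iid_gaussian(self, refrescos):
        """Equal means and a shared sigma make the chain irrelevant."""
        params = cs.ModelParams(
            p11=refrescos.p11, p22=refrescos.p22, mu=(0.04, 0.04), sigma=(0.02, 0.02)
        )
        y = np.random.default_rng(3).normal(0.04, 0.02, size=40)
        ll, _ = cs.hamilton_filter(y, params)
        assert ll == pytest.approx(norm.logpdf(y, 0.04, 0.02).sum(), abs=1e-9)

    def test_half_half_transitions_are_independent_mixtures(self):
        params = cs.ModelParams(p11=0.5, p22=0.5, mu=(0.0, 0.1), sigma=(0.02, 0.05))
        y = np.random.default_rng(4).normal(0.05, 0.05, size=8)
        ll = cs.brute_force_loglik(y, params)
        per_month = np.log(
            0.5 * norm.pdf(y, 0.0, 0.02) + 0.5 * norm.pdf(y, 0.1, 0.05)
        ).sum()
        assert ll == pytest.approx(per_month, abs=1e-8)

    def test_single_observation_is_a_stationary_mixture(self):
        params = cs.ModelParams(p11=0.9, p22=0.8, mu=(0.0, 0.1), sigma=(0.02, 0.03))
        w = cs.stationary_distribution(params.p11, params.p22)
        y = np.array([0.04])
        expected = math.log(
            w[0] * norm.pdf(0.04, 0.0, 0.02) + w[1] * norm.pdf(0.04, 0.1, 0.03)
        )
        assert cs.brute_force_loglik(y, params) == pytest.approx(expected, abs=1e-10)
        assert cs.hamilton_filter(y, params)[0] == pytest.approx(expected, abs=1e-10)

    def test_relabelling_states_leaves_likelihood_unchanged(self):
        rng = np.random.default_rng(8)
        y = rng.normal(0.05, 0.05, size=30)
        for _ in range(10):
            params = random_params(rng)
            assert cs.hamilton_filter(y, params)[0] == pytest.approx(
                cs.hamilton_filter(y, params.swapped())[0], abs=1e-9
            )

    def test_agrees_with_statsmodels_markov_regression(self, refrescos, pan_dulce):
        """Independent implementation check of the exact likelihood."""
        from statsmodels.tsa.regime_switching.markov_regression import MarkovRegression

        for params, sv, seed in ((refrescos, False, 7), (pan_dulce, True, 9)):
            infl = cs.simulate_inflation(
                cs.SimulationConfig(params=params, n_months=84, seed=seed)
            )
            ours, _ = cs.hamilton_filter(infl, params)
            mod = MarkovRegression(
                infl.values, k_regimes=2, trend="c", switching_variance=sv
            )
            vec = [params.p11, 1 - params.p22, params.mu[0], params.mu[1],
                   params.sigma[0] ** 2]
            if sv:
                vec.append(params.sigma[1] ** 2)
            assert ours == pytest.approx(mod.loglike(np.array(vec)), abs=1e-8)

    def test_zero_sigma_is_rejected(self):
        params = cs.ModelParams(p11=0.9, p22=0.9, mu=(0.0, 0.1), sigma=(0.0, 0.1))
        with pytest.raises(FilterError, match="positive"):
            cs.hamilton_filter(np.array([0.0, 0.1]), params)

    def test_enumeration_refuses_long_series(self, refrescos):
        with pytest.raises(ValueError, match="enumeration"):
            cs.brute_force_loglik(np.zeros(20), refrescos)


class TestKimSmoother:
    def test_matches_path_posterior_marginals(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            params = random_params(rng)
            T = int(rng.integers(2, 11))
            y = rng.normal(0.05, 0.05, size=T)
            _, probs = cs.hamilton_filter(y, params)
            smoothed = cs.kim_smoother(probs, params).smoothed
            post = cs.brute_force_posteriors(y, params)
            assert np.max(np.abs(smoothed - post)) < 1e-8
            assert np.max(np.abs(smoothed.sum(axis=1) - 1.0)) < 1e-10

    def test_last_month_smoothed_equals_filtered(self, short_inflation, refrescos):
        _, probs = cs.hamilton_filter(short_inflation, refrescos)
        out = cs.kim_smoother(probs, refrescos)
        np.testing.assert_allclose(out.smoothed[-1], probs.filtered[-1], atol=1e-14)

    def test_single_month_smoothed_equals_filtered(self, refrescos):
        _, probs = cs.hamilton_filter(np.array([0.05]), refrescos)
        out = cs.kim_smoother(probs, refrescos)
        np.testing.assert_allclose(out.smoothed, probs.filtered)


class TestFit:
    def test_recovers_refrescos_preset(self, refrescos):
        """Parameter recovery at T=600 from the sticky low/high-mean preset."""
        infl = cs.simulate_inflation(
            cs.SimulationConfig(params=refrescos, n_months=600, seed=ROOT_SEED)
        )
        res = cs.fit(infl, starts=8, seed=0)
        assert res.converged
        assert abs(res.params.mu[0] - refrescos.mu[0]) < 0.005
        assert abs(res.params.mu[1] - refrescos.mu[1]) < 0.005
        assert abs(res.params.sigma[0] - refrescos.sigma[0]) < 0.002
        assert abs(res.params.p11 - refrescos.p11) < 0.03
        assert abs(res.params.p22 - refrescos.p22) < 0.03
        # MLE dominates the truth on the sample it maximizes
        assert res.loglik >= cs.hamilton_filter(infl, refrescos)[0] - 1e-6

    def test_canonical_order_durations_and_ic_identities(self, refrescos):
        infl = cs.simulate_inflation(
            cs.SimulationConfig(params=refrescos, n_months=200, seed=ROOT_SEED + 1)
        )
        res = cs.fit(infl, starts=4, seed=0)
        p = res.params
        assert p.mu[0] < p.mu[1]
        assert res.durations[0] == 1.0 / (1.0 - p.p11)
        assert res.durations[1] == 1.0 / (1.0 - p.p22)
        aic, bic = cs.information_criteria(res.loglik, res.n_params, res.n_obs)
        assert res.aic == pytest.approx(aic) and res.bic == pytest.approx(bic)
        assert res.n_params == 5 and res.n_obs == 200

    def test_fit_is_deterministic_given_seed(self, refrescos):
        infl = cs.simulate_inflation(
            cs.SimulationConfig(params=refrescos, n_months=150, seed=ROOT_SEED + 2)
        )
        a = cs.fit(infl, starts=6, seed=123)
        b = cs.fit(infl, starts=6, seed=123)
        assert a.loglik == b.loglik
        assert a.params == b.params

    def test_far_separated_regimes_are_classified_nearly_perfectly(self):
        """|mu2 - mu1| = 50 sigma makes labelling essentially deterministic."""
        params = cs.ModelParams(p11=0.95, p22=0.9, mu=(0.0, 0.5), sigma=(0.01, 0.01))
        cfg = cs.SimulationConfig(params=params, n_months=300, seed=ROOT_SEED)
        path = cs.simulate_regime_path(cfg)
        infl = cs.simulate_inflation(cfg)
        res = cs.fit(infl, starts=4, seed=0)
        labels, _ = cs.classify_regimes(res.probs)
        assert np.mean(labels == path) >= 0.99

    def test_fit_result_serializes_to_json(self, refrescos):
        import json

        infl = cs.simulate_inflation(
            cs.SimulationConfig(params=refrescos, n_months=120, seed=ROOT_SEED + 3)
        )
        res = cs.fit(infl, starts=2, seed=0)
        payload = json.loads(res.to_json())
        assert payload["params"]["p11"] == res.params.p11
        assert payload["n_obs"] == 120
        frame = res.probs.to_frame(start_month=res.start_month)
        assert list(frame.columns) == [
            "date", "predicted_low", "filtered_low", "smoothed_low",
        ]
        assert frame["date"].iloc[0] == "2010-01"


class TestStandardErrors:
    def test_two_differentiation_schemes_agree(self, refrescos):
        infl = cs.simulate_inflation(
            cs.SimulationConfig(params=refrescos, n_months=200, seed=ROOT_SEED + 4)
        )
        res = cs.fit(infl, starts=4, seed=0, se_kind=None)
        spec = res.spec
        x = _pack(res.params, spec)

        def total(xv):
            return _run_filter(infl.values, _unpack(xv, spec), spec)["loglik"]

        H1 = _hessian_direct(total, x)
        H2 = _hessian_from_gradient(total, x)
        denom = np.maximum(np.abs(H1), 1.0)
        assert np.max(np.abs(H1 - H2) / denom) < 1e-4

    def test_unidentified_regimes_raise_singular_hessian(self):
        y = np.random.default_rng(17).normal(0.04, 0.02, size=80)
        params = cs.ModelParams(p11=0.9, p22=0.9, mu=(0.04, 0.04), sigma=(0.02, 0.02))
        with pytest.raises(np.linalg.LinAlgError, match="singular"):
            cs.standard_errors(y, params, kind="hessian")

    def test_hessian_and_robust_kinds_are_both_finite(self, refrescos):
        infl = cs.simulate_inflation(
            cs.SimulationConfig(params=refrescos, n_months=300, seed=ROOT_SEED + 5)
        )
        res = cs.fit(infl, starts=4, seed=0, se_kind=None)
        for kind in ("hessian", "robust"):
            se = cs.standard_errors(infl, res.params, res.spec, kind=kind)
            assert se.kind == kind
            assert np.isfinite([se.p11, se.p22, *se.mu, *se.sigma, *se.durations]).all()
            assert se.mu[0] > 0 and se.durations[0] > 0

    def test_two_se_intervals_cover_the_true_low_mean(self, refrescos):
        """~95% nominal coverage of mu_low across seeded replicates."""
        hits = trials = 0
        for rep in range(50):
            infl = cs.simulate_inflation(
                cs.SimulationConfig(params=refrescos, n_months=400, seed=20_000 + rep)
            )
            try:
                res = cs.fit(infl, starts=4, seed=rep)
            except cs.FitError:
                continue
            if res.se is None:
                continue
            trials += 1
            hits += (
                abs(res.params.mu[0] - refrescos.mu[0]) <= 2.0 * res.se.mu[0]
            )
        assert trials >= 40
        assert 0.84 <= hits / trials <= 1.0


class TestSummaries:
    def test_expected_duration_reference_values(self):
        assert cs.expected_duration(0.96) == pytest.approx(25.0)
        assert cs.expected_duration(0.9353) == pytest.approx(15.456, abs=5e-4)
        assert f"{cs.expected_duration(0.9353):.2f}" == "15.46"
        assert cs.expected_duration(0.0) == 1.0

    @pytest.mark.parametrize("bad", [1.0, -0.1, 1.2])
    def test_expected_duration_rejects_invalid_probability(self, bad):
        with pytest.raises(ValueError):
            cs.expected_duration(bad)

    def test_stationary_distribution_closed_form(self):
        assert cs.stationary_distribution(0.9, 0.9) == pytest.approx((0.5, 0.5))
        pi = cs.stationary_distribution(0.96, 0.9353)
        assert pi == pytest.approx((0.6179, 0.3821), abs=1e-4)
        P = np.array([[0.96, 0.04], [0.0647, 0.9353]])
        np.testing.assert_allclose(np.array(pi) @ P, pi, atol=1e-12)
        rng = np.random.default_rng(0)
        for _ in range(20):
            pi = cs.stationary_distribution(rng.uniform(0, 1), rng.uniform(0, 1))
            assert sum(pi) == pytest.approx(1.0)

    def test_stationary_distribution_rejects_reducible_chain(self):
        with pytest.raises(ValueError, match="reducible"):
            cs.stationary_distribution(1.0, 1.0)

    def test_information_criteria_zero_case(self):
        assert cs.information_criteria(0.0, 0, 10) == (0.0, 0.0)

    def test_classify_regimes_all_low(self, refrescos):
        probs = cs.RegimeProbabilities(
            predicted=np.tile([0.6, 0.4], (5, 1)),
            filtered=np.tile([0.7, 0.3], (5, 1)),
            smoothed=np.tile([1.0, 0.0], (5, 1)),
        )
        labels, breaks = cs.classify_regimes(probs)
        assert np.all(labels == 1) and breaks == []

    def test_classify_threshold_boundary_is_strict(self):
        sm = np.array([[0.5, 0.5], [0.4, 0.6]])
        probs = cs.RegimeProbabilities(predicted=sm, filtered=sm, smoothed=sm)
        labels_eq, _ = cs.classify_regimes(probs, threshold=0.5)
        labels_above, _ = cs.classify_regimes(probs, threshold=0.5 + 1e-9)
        # strictly-greater semantics: an exactly-at-threshold month stays low
        assert labels_eq[0] == 1 and labels_above[0] == 1
        assert labels_eq[1] == 2 and labels_above[1] == 2

    def test_classify_requires_smoothed(self, short_inflation, refrescos):
        _, probs = cs.hamilton_filter(short_inflation, refrescos)
        with pytest.raises(ValueError, match="smoothed"):
            cs.classify_regimes(probs)
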