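"""Stepwise model equations: hand-derived examples, closed forms and
independent numerical oracles (quadrature, conjugate counting)."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

from bayesq import _kernels, models
from bayesq.models import (
    BetaPair,
    BQParams,
    BQState,
    InfeasibleMomentsError,
    QParams,
    QState,
    bq_choice_prob,
    bq_predict,
    bq_update,
    effective_learning_rate,
    moment_match,
    q_choice_prob,
    q_step,
    run_model_forward,
    transition_kernel,
)


class TestQStep:
    def test_zero_learning_rate_leaves_state_unchanged(self):
        state = QState(0.5, 0.5)
        params = QParams(alpha1=0.0, alpha2=0.0, k1=1.0, k2=0.5, beta=3.0)
        for action, reward in [(0, 1), (1, 0)]:
            out = q_step(state, params, action, reward)
            assert out == state

    def test_hand_evaluated_update(self):
        # chosen: 0.8*0.5 + 0.2*1 = 0.6; unchosen: 0.9*0.5 = 0.45
        out = q_step(
            QState(0.5, 0.5),
            QParams(alpha1=0.2, alpha2=0.1, k1=1.0, k2=0.0, beta=1.0),
            action=0,
            reward=1,
        )
        assert out.qL == pytest.approx(0.6)
        assert out.qR == pytest.approx(0.45)

    def test_no_forgetting_leaves_unchosen_untouched(self):
        params = QParams.original_q(alpha1=0.5, k1=1.0, beta=1.0)
        out = q_step(QState(0.5, 0.5), params, action=0, reward=1)
        assert out.qR == 0.5

    def test_nonreward_moves_toward_negative_target(self):
        params = QParams(alpha1=0.5, alpha2=0.0, k1=1.0, k2=0.8, beta=1.0)
        out = q_step(QState(0.5, 0.5), params, action=0, reward=0)
        assert out.qL == pytest.approx(0.5 * 0.5 + 0.5 * (-0.8))

    @pytest.mark.parametrize("action,reward", [(2, 1), ("X", 0), (0, 2), (1, -1)])
    def test_invalid_inputs_rejected(self, action, reward):
        with pytest.raises(ValueError):
            q_step(QState(), QParams(0.1, 0.1, 1.0, 0.0, 1.0), action, reward)


class TestQChoiceProb:
    def test_symmetric_values_give_half(self):
        assert q_choice_prob(QState(0.3, 0.3), QParams(0.1, 0.1, 1, 0, 5.0)) == 0.5

    def test_flat_policy_at_zero_beta(self):
        assert q_choice_prob(QState(0.9, 0.1), QParams(0.1, 0.1, 1, 0, 0.0)) == 0.5

    def test_direct_evaluation(self):
        p = q_choice_prob(QState(0.6, 0.4), QParams(0.1, 0.1, 1, 0, 5.0))
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)


class TestTransitionKernel:
    def test_symmetric_case(self):
        pair = transition_kernel(0.5, 2.0)
        assert (pair.x, pair.y) == (2.0, 2.0)
        assert pair.mode == pytest.approx(0.5)

    def test_mode_equals_previous_value(self):
        pair = transition_kernel(0.3, 10.0)
        assert (pair.x, pair.y) == (4.0, 8.0)
        assert pair.mode == pytest.approx(0.3)

    def test_small_G_approaches_uniform(self):
        pair = transition_kernel(0.9, 1e-9)
        assert pair.x == pytest.approx(1.0, abs=1e-8)
        assert pair.y == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("q", [0.0, 1.0, -0.1, 1.5])
    def test_rejects_out_of_range(self, q):
        with pytest.raises(ValueError):
            transition_kernel(q, 5.0)

    @given(q=st.floats(0.01, 0.99), G=st.floats(0.1, 100.0))
    @settings(deadline=None, max_examples=50)
    def test_mode_property_and_spread_monotone(self, q, G):
        pair = transition_kernel(q, G)
        assert pair.mode == pytest.approx(q, rel=1e-9)
        wider = transition_kernel(q, G / 2.0)
        assert wider.var > pair.var


class TestMomentMatch:
    def test_uniform_moments(self):
        pair = moment_match(0.5, 1.0 / 12.0)
        assert pair.x == pytest.approx(1.0)
        assert pair.y == pytest.approx(1.0)

    def test_beta_2_1_moments(self):
        pair = moment_match(2.0 / 3.0, 1.0 / 18.0)
        assert pair.x == pytest.approx(2.0)
        assert pair.y == pytest.approx(1.0)

    def test_infeasible_variance_raises(self):
        with pytest.raises(InfeasibleMomentsError):
            moment_match(0.5, 0.3)

    def test_nonpositive_variance_raises(self):
        with pytest.raises(ValueError):
            moment_match(0.5, 0.0)

    @given(
        x=st.floats(0.2, 50.0),
        y=st.floats(0.2, 50.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_round_trip_through_moments(self, x, y):
        pair = BetaPair(x, y)
        back = moment_match(pair.mean, pair.var)
        assert back.x == pytest.approx(x, rel=1e-8)
        assert back.y == pytest.approx(y, rel=1e-8)


def _quadrature_moments(prior: BetaPair, G: float) -> tuple[float, float]:
    """Numerical-integration oracle for the kernel-mixed prior's moments.

    Integrates the kernel's conditional moments (scipy's own beta-moment
    formulas, independent of the implementation under test) against the
    prior density over q'."""

    def m1_int(qp):
        return stats.beta.mean(1.0 + G * qp, 1.0 + G * (1.0 - qp)) * stats.beta.pdf(
            qp, prior.x, prior.y
        )

    def m2_int(qp):
        a, b = 1.0 + G * qp, 1.0 + G * (1.0 - qp)
        mean, var = stats.beta.stats(a, b, moments="mv")
        return (var + mean**2) * stats.beta.pdf(qp, prior.x, prior.y)

    m1, _ = integrate.quad(m1_int, 0, 1, epsabs=1e-10, epsrel=1e-10, limit=200)
    m2, _ = integrate.quad(m2_int, 0, 1, epsabs=1e-10, epsrel=1e-10, limit=200)
    return m1, m2


def test_predict_moments_match_full_double_integral():
    """Fully brute-force check of the marginal's first two moments."""
    prior, G = BetaPair(5.0, 2.0), 10.0

    def integrand(q, qp, power):
        return (
            q**power
            * stats.beta.pdf(q, 1.0 + G * qp, 1.0 + G * (1.0 - qp))
            * stats.beta.pdf(qp, prior.x, prior.y)
        )

    out = bq_predict(prior, G)
    m1, _ = integrate.dblquad(integrand, 0, 1, 0, 1, args=(1,), epsabs=1e-9, epsrel=1e-9)
    m2, _ = integrate.dblquad(integrand, 0, 1, 0, 1, args=(2,), epsabs=1e-9, epsrel=1e-9)
    assert out.mean == pytest.approx(m1, abs=1e-6)
    assert out.second_moment == pytest.approx(m2, abs=1e-6)


class TestBQPredict:
    def test_uniform_prior_keeps_mean_half(self):
        for G in (0.5, 5.0, 50.0):
            assert bq_predict(BetaPair(1, 1), G).mean == pytest.approx(0.5)

    def test_infinite_G_returns_prior(self):
        prior = BetaPair(5.0, 2.0)
        assert bq_predict(prior, math.inf) is prior

    def test_large_G_converges_to_prior_moments(self):
        prior = BetaPair(5.0, 2.0)
        out = bq_predict(prior, 1e9)
        assert out.mean == pytest.approx(prior.mean, abs=1e-8)
        assert out.var == pytest.approx(prior.var, rel=1e-6)

    @pytest.mark.parametrize("x,y", [(1.0, 1.0), (5.0, 2.0), (0.7, 3.0), (10.0, 10.0)])
    @pytest.mark.parametrize("G", [0.5, 5.0, 50.0])
    def test_moments_match_numerical_quadrature(self, x, y, G):
        prior = BetaPair(x, y)
        out = bq_predict(prior, G)
        m1, m2 = _quadrature_moments(prior, G)
        assert out.mean == pytest.approx(m1, abs=1e-6)
        assert out.second_moment == pytest.approx(m2, abs=1e-6)

    @given(
        x=st.floats(0.2, 40.0),
        y=st.floats(0.2, 40.0),
        G=st.floats(0.1, 500.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_mean_contraction_toward_half(self, x, y, G):
        prior = BetaPair(x, y)
        out = bq_predict(prior, G)
        expected = (G / (2.0 + G)) * (prior.mean - 0.5)
        assert out.mean - 0.5 == pytest.approx(expected, abs=1e-12)


class TestBQUpdate:
    def test_conjugate_reward_step(self):
        out = bq_update(BetaPair(1, 1), reward=1, k=1.0)
        assert (out.x, out.y) == (2.0, 1.0)
        assert out.mean == pytest.approx(2.0 / 3.0)

    def test_nonreward_ignored_when_k_zero(self):
        pair = BetaPair(2, 3)
        assert bq_update(pair, reward=0, k=0.0) is pair

    def test_fractional_nonreward_weight(self):
        out = bq_update(BetaPair(2, 3), reward=0, k=0.5)
        assert (out.x, out.y) == (2.0, 3.5)


class TestEffectiveLearningRate:
    def test_uniform_prior_reward_rate(self):
        assert effective_learning_rate(BetaPair(1, 1), 1, k=1.0) == pytest.approx(1.0 / 3.0)

    def test_zero_k_nonreward_gives_zero(self):
        assert effective_learning_rate(BetaPair(7, 3), 0, k=0.0) == 0.0

    def test_nonreward_closed_form(self):
        assert effective_learning_rate(BetaPair(2, 2), 0, k=1.0) == pytest.approx(0.2)

    @pytest.mark.parametrize("reward", [0, 1])
    def test_closed_form_equals_mean_shift_definition(self, reward):
        # independent check: eA == (mean_after - mean_before)/(r - mean_before)
        k = 0.7
        for x, y in [(1.0, 1.0), (3.0, 2.0), (0.5, 4.0), (12.0, 9.0)]:
            pair = BetaPair(x, y)
            after = bq_update(pair, reward, k)
            expected = (after.mean - pair.mean) / (reward - pair.mean)
            assert effective_learning_rate(pair, reward, k) == pytest.approx(expected, abs=1e-12)

    def test_strictly_decreasing_in_concentration(self):
        sums = np.linspace(2.0, 40.0, 25)
        for reward, k in [(1, 1.0), (0, 0.5)]:
            rates = [effective_learning_rate(BetaPair(s / 2, s / 2), reward, k) for s in sums]
            assert np.all(np.diff(rates) < 0)
            assert all(0.0 < r < 1.0 for r in rates)

    def test_increasing_in_variance_at_fixed_mean(self):
        mean = 0.4
        variances = np.linspace(0.002, 0.9 * mean * (1 - mean), 20)
        pairs = [moment_match(mean, v) for v in variances]
        rates = [effective_learning_rate(p, 1, k=1.0) for p in pairs]
        assert np.all(np.diff(rates) > 0)


class TestBQChoiceProb:
    def test_identical_distributions_give_half(self):
        state = BQState(BetaPair(3, 2), BetaPair(3, 2))
        assert bq_choice_prob(state, BQParams(G=5, k=1, beta=10, phi=2.0)) == 0.5

    def test_phi_zero_reduces_to_softmax_on_means(self):
        state = BQState(BetaPair(6, 4), BetaPair(4, 6))
        p = bq_choice_prob(state, BQParams(G=5, k=1, beta=5, phi=0.0))
        assert p == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-12)

    def test_phi_sign_semantics(self):
        # equal means, left wider: Beta(1,1) vs Beta(10,10)
        state = BQState(BetaPair(1, 1), BetaPair(10, 10))
        seek = bq_choice_prob(state, BQParams(G=5, k=1, beta=5, phi=2.0))
        avoid = bq_choice_prob(state, BQParams(G=5, k=1, beta=5, phi=-2.0))
        assert seek > 0.5 > avoid


class TestRunModelForward:
    @pytest.mark.parametrize("variant,params", [
        ("Q", QParams.original_q(0.3, 1.0, 5.0)),
        ("FQ", QParams.fq(0.3, 1.0, 0.5, 5.0)),
        ("dFQ", QParams(0.3, 0.1, 1.0, 0.5, 5.0)),
        ("originalBQ", BQParams.original_bq(10.0, 5.0, 1.0)),
        ("asymmetricBQ", BQParams.asymmetric_bq(10.0, 5.0, 1.0)),
        ("asymmetricBQ_phi0", BQParams(G=10.0, k=0.0, beta=5.0, phi=0.0)),
        ("generalizedBQ", BQParams(G=10.0, k=0.7, beta=5.0, phi=1.0)),
    ])
    def test_symmetric_initial_state_predicts_half(self, variant, params):
        traj = run_model_forward([0], [1], variant, params)
        assert traj.p_left[0] == 0.5

    def test_bq_three_trial_hand_trace(self):
        # Manual trace with G=2, k=1, beta=4, phi=0; choices L,L,R; rewards 1,0,1.
        G, beta = 2.0, 4.0

        def predict(x, y):
            s = x + y
            m = x / s
            m2 = x * (x + 1) / (s * (s + 1))
            e1 = (1 + G * m) / (2 + G)
            e2 = (2 + 3 * G * m + G * G * m2) / ((2 + G) * (3 + G))
            v = e2 - e1 * e1
            c = e1 * (1 - e1) / v - 1
            return e1 * c, (1 - e1) * c

        xL = yL = xR = yR = 1.0
        expected_p = []
        for choice, reward in [(0, 1), (0, 0), (1, 1)]:
            xL, yL = predict(xL, yL)
            xR, yR = predict(xR, yR)
            mL, mR = xL / (xL + yL), xR / (xR + yR)
            expected_p.append(1.0 / (1.0 + math.exp(-beta * (mL - mR))))
            if choice == 0:
                xL, yL = (xL + 1, yL) if reward else (xL, yL + 1)
            else:
                xR, yR = (xR + 1, yR) if reward else (xR, yR + 1)

        traj = run_model_forward([0, 0, 1], [1, 0, 1], "originalBQ",
                                 BQParams.original_bq(G=G, beta=beta, phi=0.0))
        assert traj.p_left == pytest.approx(expected_p, abs=1e-12)

    def test_generalized_with_k_one_equals_original(self):
        rng = np.random.default_rng(3)
        c, r = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        a = run_model_forward(c, r, "originalBQ", BQParams.original_bq(8.0, 6.0, 1.5))
        b = run_model_forward(c, r, "generalizedBQ", BQParams(G=8.0, k=1.0, beta=6.0, phi=1.5))
        assert np.array_equal(a.p_left, b.p_left)

    def test_q_nesting_identities(self):
        rng = np.random.default_rng(4)
        c, r = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        fq = run_model_forward(c, r, "FQ", QParams.fq(0.25, 1.0, 0.4, 6.0))
        dfq = run_model_forward(c, r, "dFQ", QParams(0.25, 0.25, 1.0, 0.4, 6.0))
        assert np.array_equal(fq.p_left, dfq.p_left)
        q = run_model_forward(c, r, "Q", QParams.original_q(0.25, 1.0, 6.0))
        dfq0 = run_model_forward(c, r, "dFQ", QParams(0.25, 0.0, 1.0, 0.0, 6.0))
        assert np.array_equal(q.p_left, dfq0.p_left)

    def test_variant_constraints_enforced(self):
        with pytest.raises(ValueError):
            run_model_forward([0], [1], "FQ", QParams(0.3, 0.1, 1.0, 0.0, 5.0))
        with pytest.raises(ValueError):
            run_model_forward([0], [1], "originalBQ", BQParams(G=5, k=0.5, beta=5, phi=0))
        with pytest.raises(ValueError):
            run_model_forward([0], [1], "badname", BQParams(G=5, k=1, beta=5, phi=0))

    def test_empty_session_rejected(self):
        with pytest.raises(ValueError):
            run_model_forward([], [], "FQ", QParams.fq(0.3, 1.0, 0.0, 5.0))

    def test_conjugacy_oracle_without_forgetting(self):
        # G -> inf disables the prediction step; with k = 1 the posterior per
        # action must equal Beta(1 + #rewards, 1 + #non-rewards) exactly.
        rng = np.random.default_rng(11)
        c = rng.integers(0, 2, 100)
        r = rng.integers(0, 2, 100)
        params = BQParams(G=math.inf, k=1.0, beta=3.0, phi=0.0)
        traj = run_model_forward(c, r, "originalBQ", params)
        final_predicted = traj.states[-1]
        # reconstruct the state *after* the final update
        last = final_predicted.pair(int(c[-1]))
        updated = bq_update(last, int(r[-1]), 1.0)
        for action, pair in ((c[-1], updated), (1 - c[-1], final_predicted.pair(int(1 - c[-1])))):
            mask = c == action
            n_rew = int(r[mask].sum())
            n_non = int(mask.sum() - n_rew)
            assert pair.x == 1.0 + n_rew
            assert pair.y == 1.0 + n_non

    def test_ceiling_below_one_and_increasing_in_G(self):
        # all-reward sequence with k=0: the chosen mean converges to a fixed
        # point strictly below 1 whose height grows with the retention G
        ceilings = []
        for G in (5.0, 20.0, 80.0):
            traj = run_model_forward([0] * 400, [1] * 400, "asymmetricBQ",
                                     BQParams.asymmetric_bq(G=G, beta=5.0, phi=0.0))
            ceilings.append(traj.mu[-1, 0])
        assert all(0.5 < m < 1.0 for m in ceilings)
        assert ceilings[0] < ceilings[1] < ceilings[2]


class TestCompiledKernelsMatchReference:
    """The numba fast path must agree with the pure-Python equations."""

    def test_bq_forward_bitwise_equal(self):
        rng = np.random.default_rng(5)
        c = rng.integers(0, 2, 200)
        r = rng.integers(0, 2, 200)
        for G, k, beta, phi in [(20.0, 0.0, 12.0, 1.0), (3.0, 1.0, 6.0, -2.0), (100.0, 0.5, 2.0, 0.0)]:
            ref = run_model_forward(c, r, "generalizedBQ", BQParams(G=G, k=k, beta=beta, phi=phi))
            p, mu, sd, ea = _kernels.bq_forward(
                np.ascontiguousarray(c), np.ascontiguousarray(r), G, k, beta, phi
            )
            assert np.array_equal(ref.p_left, p)
            assert np.array_equal(ref.mu, mu)
            assert np.array_equal(ref.sd, sd)
            assert np.array_equal(ref.ealpha, ea)

    def test_q_forward_bitwise_equal(self):
        rng = np.random.default_rng(6)
        c = rng.integers(0, 2, 200)
        r = rng.integers(0, 2, 200)
        params = QParams(0.3, 0.1, 1.2, 0.4, 7.0)
        ref = run_model_forward(c, r, "dFQ", params)
        p, q = _kernels.q_forward(
            np.ascontiguousarray(c), np.ascontiguousarray(r),
            params.alpha1, params.alpha2, params.k1, params.k2, params.beta,
        )
        assert np.array_equal(ref.p_left, p)


class TestParameterValidation:
    def test_beta_pair_requires_positive_finite(self):
        for bad in [(0.0, 1.0), (1.0, -2.0), (math.nan, 1.0), (math.inf, 1.0)]:
            with pytest.raises(ValueError):
                BetaPair(*bad)

    def test_qparams_bounds(self):
        with pytest.raises(ValueError):
            QParams(alpha1=1.5, alpha2=0.0, k1=1.0, k2=0.0, beta=1.0)
        with pytest.raises(ValueError):
            QParams(alpha1=0.5, alpha2=0.0, k1=-1.0, k2=0.0, beta=1.0)

    def test_bqparams_bounds(self):
        with pytest.raises(ValueError):
            BQParams(G=0.0, k=1.0, beta=1.0, phi=0.0)
        with pytest.raises(ValueError):
            BQParams(G=1.0, k=-0.1, beta=1.0, phi=0.0)
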