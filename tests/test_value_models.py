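"""Forgetting-Q model fitting, uncertainty splits, WSLS and history regression."""

import numpy as np
import pytest

from pushpull import agents, task_engine
from pushpull.agents import AgentState, QAgentParams, q_update, softmax_choice_prob
from pushpull.value_models import (
    ChoiceSeries,
    LagRegressionResult,
    _q_forward,
    fit_q_model,
    q_trajectory_nll,
    repeat_choice_regression,
    series_from_session,
    uncertainty_split,
    vigor_by_value_summary,
    wsls_stats,
)


def make_series(choices, rewards, **kw):
    return ChoiceSeries(choices=list(choices), rewards=list(rewards), **kw)


def simulate_q_series(alpha, beta, n, seed):
    agent = agents.QAgent(QAgentParams(alpha=alpha, beta=beta))
    log = task_engine.run_bandit_session(
        agent, task_engine.ValueTaskConfig(), n, np.random.default_rng(seed)
    )
    return series_from_session(log)


class TestNll:
    def test_zero_beta_is_coin_flipping(self):
        s = make_series(["push", "pull", "push", "push"], [1, 0, 1, 1])
        nll, _, _ = q_trajectory_nll(s, alpha=0.5, beta=0.0)
        assert nll == pytest.approx(4 * np.log(2))

    def test_single_trial_symmetric_start(self):
        s = make_series(["pull"], [1])
        nll, _, _ = q_trajectory_nll(s, alpha=0.3, beta=7.0)
        assert nll == pytest.approx(np.log(2))

    def test_three_trial_forward_pass_oracle(self):
        """Step-by-step hand recursion for (alpha=.5, beta=2)."""
        s = make_series(["push", "push", "pull"], [1, 0, 1])
        alpha, beta = 0.5, 2.0
        qp = ql = 0.0
        nll_ref = 0.0
        for choice, reward in zip(s.choices, s.rewards):
            p_push = 1 / (1 + np.exp(-beta * (qp - ql)))
            nll_ref -= np.log(p_push if choice == "push" else 1 - p_push)
            if choice == "push":
                qp, ql = qp + alpha * (reward - qp), (1 - alpha) * ql
            else:
                ql, qp = ql + alpha * (reward - ql), (1 - alpha) * qp
        nll, qp_traj, ql_traj = q_trajectory_nll(s, alpha, beta)
        assert nll == pytest.approx(nll_ref, abs=1e-10)
        assert qp_traj[2] == pytest.approx(0.25)  # 0.5 learned, then lost, kept
        assert ql_traj[2] == pytest.approx(0.0)

    def test_forward_pass_matches_agent_updates(self):
        """The fitting recursion and the simulated agent share one rule."""
        rng = np.random.default_rng(17)
        choices = ["push" if rng.random() < 0.5 else "pull" for _ in range(200)]
        rewards = rng.integers(0, 2, 200).tolist()
        s = make_series(choices, rewards)
        params = QAgentParams(alpha=0.37, beta=4.2)
        qp, ql = _q_forward(
            np.array([1.0 if c == "push" else -1.0 for c in choices]),
            np.asarray(rewards, dtype=float),
            params.alpha,
        )
        state = AgentState(0.0, 0.0)
        nll_agent = 0.0
        for t, (c, r) in enumerate(zip(choices, rewards)):
            assert (state.q_push, state.q_pull) == pytest.approx((qp[t], ql[t]))
            p = softmax_choice_prob(state, params)
            nll_agent -= np.log(p if c == "push" else 1 - p)
            state = q_update(state, c, r, params)
        nll, _, _ = q_trajectory_nll(s, params.alpha, params.beta)
        assert nll == pytest.approx(nll_agent, rel=1e-12)

    def test_push_pull_relabel_invariance(self):
        rng = np.random.default_rng(11)
        choices = ["push" if rng.random() < 0.6 else "pull" for _ in range(300)]
        rewards = rng.integers(0, 2, 300).tolist()
        flipped = ["pull" if c == "push" else "push" for c in choices]
        a, _, _ = q_trajectory_nll(make_series(choices, rewards), 0.4, 3.0)
        b, _, _ = q_trajectory_nll(make_series(flipped, rewards), 0.4, 3.0)
        assert a == pytest.approx(b, rel=1e-12)

    def test_invalid_params_rejected(self):
        s = make_series(["push"], [1])
        with pytest.raises(ValueError):
            q_trajectory_nll(s, 0.0, 1.0)
        with pytest.raises(ValueError):
            q_trajectory_nll(s, 0.5, -1.0)


class TestFit:
    def test_deterministic(self, q_agent_series):
        a = fit_q_model(q_agent_series)
        b = fit_q_model(q_agent_series)
        assert (a.alpha_hat, a.beta_hat, a.neg_log_likelihood) == (
            b.alpha_hat, b.beta_hat, b.neg_log_likelihood
        )

    def test_recovers_generative_parameters(self, q_agent_series):
        fit = fit_q_model(q_agent_series)
        assert abs(fit.alpha_hat - 0.5) <= 0.1
        assert 2.0 <= fit.beta_hat <= 4.0

    def test_nll_beats_generative_parameters(self, q_agent_series):
        fit = fit_q_model(q_agent_series)
        gen_nll, _, _ = q_trajectory_nll(q_agent_series, 0.5, 3.0)
        assert fit.neg_log_likelihood <= gen_nll + 1e-9

    def test_random_agent_fits_near_zero_beta(self):
        agent = agents.RandomAgent()
        log = task_engine.run_bandit_session(
            agent, task_engine.ValueTaskConfig(), 5000, np.random.default_rng(23)
        )
        fit = fit_q_model(series_from_session(log))
        assert fit.beta_hat <= 0.5

    def test_short_series_warns(self):
        s = make_series(["push", "pull"] * 10, [1, 0] * 10)
        with pytest.warns(UserWarning, match="noisy"):
            fit_q_model(s)

    def test_degenerate_series_boundary_warning(self):
        s = make_series(["push"] * 150, [1] * 150)
        with pytest.warns(UserWarning, match="boundary"):
            fit = fit_q_model(s)
        assert fit.boundary_warning


class TestUncertaintySplit:
    @staticmethod
    def fit_with_delta(dq):
        dq = np.asarray(dq, dtype=float)
        from pushpull.value_models import QFitResult

        return QFitResult(0.5, 3.0, 1.0, q_push=dq, q_pull=np.zeros_like(dq))

    def test_median_split_masks(self):
        split = uncertainty_split(self.fit_with_delta([0.1, 0.2, 0.3, 0.4]))
        assert list(split.high_uncertainty) == [True, True, False, False]
        assert list(split.low_uncertainty) == [False, False, True, True]
        assert (split.high_uncertainty | split.low_uncertainty).all()

    def test_constant_delta_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            split = uncertainty_split(self.fit_with_delta([0.0, 0.0, 0.0]))
        assert split.low_uncertainty.all()

    def test_sign_invariance(self):
        a = uncertainty_split(self.fit_with_delta([0.1, -0.4, 0.2, -0.05]))
        b = uncertainty_split(self.fit_with_delta([-0.1, 0.4, -0.2, 0.05]))
        assert np.array_equal(a.high_uncertainty, b.high_uncertainty)


class TestWsls:
    def test_wsls_agent_is_exactly_wsls(self):
        agent = agents.WslsAgent()
        log = task_engine.run_bandit_session(
            agent, task_engine.ValueTaskConfig(), 2000, np.random.default_rng(2)
        )
        stats = wsls_stats(series_from_session(log))
        assert stats.p_stay_given_win == 1.0
        assert stats.p_switch_given_lose == 1.0

    def test_random_agent_near_half(self):
        agent = agents.RandomAgent()
        log = task_engine.run_bandit_session(
            agent, task_engine.ValueTaskConfig(), 10_000, np.random.default_rng(6)
        )
        stats = wsls_stats(series_from_session(log))
        assert stats.p_stay_given_win == pytest.approx(0.5, abs=0.03)
        assert stats.p_switch_given_lose == pytest.approx(0.5, abs=0.03)

    def test_hand_counted_series(self):
        s = make_series(["push", "push", "pull", "push"], [1, 0, 0, 1])
        stats = wsls_stats(s)
        assert (stats.n_win, stats.n_lose) == (1, 2)
        assert stats.p_stay_given_win == 1.0  # the one win is followed by a stay
        assert stats.p_switch_given_lose == 1.0  # both losses precede switches

    def test_q_agent_stays_more_after_wins(self, q_agent_series):
        stats = wsls_stats(q_agent_series)
        p_stay_lose = 1.0 - stats.p_switch_given_lose
        assert stats.p_stay_given_win > p_stay_lose

    def test_too_short(self):
        with pytest.raises(ValueError):
            wsls_stats(make_series(["push"], [1]))


class TestRepeatChoiceRegression:
    def test_wsls_data_signs(self):
        agent = agents.WslsAgent()
        log = task_engine.run_bandit_session(
            agent, task_engine.ValueTaskConfig(), 3000, np.random.default_rng(8)
        )
        res = repeat_choice_regression(series_from_session(log))
        assert res.rewarded_weights[0] > 2.0
        assert res.unrewarded_weights[0] < -2.0

    def test_outcome_independent_agent_null_weights(self):
        rng = np.random.default_rng(13)
        n = 10_000
        choices = ["push" if rng.random() < 0.5 else "pull" for _ in range(n)]
        rewards = rng.integers(0, 2, n).tolist()
        res = repeat_choice_regression(make_series(choices, rewards))
        assert abs(res.rewarded_weights[0]) < 0.1
        assert abs(res.unrewarded_weights[0]) < 0.1

    def test_recovers_generative_weights(self):
        """Choices generated from logit P(repeat) = 1.5 win - 1.0 lose."""
        rng = np.random.default_rng(19)
        w_r, w_u, n = 1.5, -1.0, 20_000
        choices = ["push"]
        rewards = [int(rng.random() < 0.5)]
        for _ in range(n - 1):
            w = w_r if rewards[-1] else w_u
            p_repeat = 1 / (1 + np.exp(-w))
            stay = rng.random() < p_repeat
            prev = choices[-1]
            choices.append(prev if stay else ("pull" if prev == "push" else "push"))
            rewards.append(int(rng.random() < 0.5))
        res = repeat_choice_regression(make_series(choices, rewards))
        assert res.rewarded_weights[0] == pytest.approx(w_r, abs=0.15)
        assert res.unrewarded_weights[0] == pytest.approx(w_u, abs=0.15)
        assert res.intercept == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            repeat_choice_regression(make_series(["push", "pull"] * 10, [1, 0] * 10))


def traced_volume_session(vigor_gain, latency_gain, seed=55, n=320):
    """Changing-volume bandit session with traces and attached kinematics."""
    agent = agents.QAgent(
        QAgentParams(alpha=0.6, beta=4.0, vigor_gain=vigor_gain,
                     latency_gain=latency_gain, volume_sensitive=True)
    )
    cfg = task_engine.ValueTaskConfig(changing_volume=True)
    log = task_engine.run_bandit_session(
        agent, cfg, n, np.random.default_rng(seed),
        trace_policy=task_engine.TracePolicy(),
    )
    from pushpull.pipeline import bandit_trial_kinematics

    kin = bandit_trial_kinematics(log)
    return series_from_session(log, attach_kinematics=kin)


@pytest.fixture(scope="module")
def flat_vigor_session():
    series = traced_volume_session(0.0, 0.0)
    return series, fit_q_model(series)


@pytest.fixture(scope="module")
def coupled_vigor_session():
    series = traced_volume_session(2.5, 350.0)
    return series, fit_q_model(series)


class TestVigorByValue:
    def test_requires_kinematics(self, q_agent_series):
        with pytest.raises(ValueError, match="kinematics"):
            vigor_by_value_summary(q_agent_series)

    def test_reps_zero_gives_stats_only(self, flat_vigor_session):
        series, fit = flat_vigor_session
        out = vigor_by_value_summary(series, fit, permutation_reps=0, rng=0)
        for entry in out["volume"]["trend"].values():
            assert "p" not in entry and "stat" in entry

    def test_coupled_agent_reproduces_volume_trends(self, coupled_vigor_session):
        """Value-invigorated agent: displacement rises and latency falls
        with reward volume."""
        series, fit = coupled_vigor_session
        out = vigor_by_value_summary(series, fit, permutation_reps=300, rng=3)
        trends = out["volume"]["trend"]
        assert trends["peak_displacement"]["stat"] > 0
        assert trends["choice_latency"]["stat"] < 0
        assert trends["peak_displacement"]["p"] < 0.05

    def test_uncoupled_agent_shows_no_volume_trend(self, flat_vigor_session):
        series, fit = flat_vigor_session
        out = vigor_by_value_summary(series, fit, permutation_reps=300, rng=4)
        assert out["volume"]["trend"]["peak_displacement"]["p"] > 0.05

    def test_uncertainty_contrast_directions(self, flat_vigor_session):
        series, fit = flat_vigor_session
        out = vigor_by_value_summary(series, fit, permutation_reps=200, rng=1)
        contrasts = out["uncertainty"]["contrasts"]
        # positive stat = larger under high uncertainty
        assert contrasts["n_bouts"]["stat"] > 0
        assert contrasts["path_length"]["stat"] > 0
        assert contrasts["directional_consistency"]["stat"] < 0


def test_series_excludes_incomplete_trials(traced_bandit_session):
    series = series_from_session(traced_bandit_session)
    counts = traced_bandit_session.outcome_counts()
    assert len(series) == counts["rewarded"] + counts["unrewarded"]
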