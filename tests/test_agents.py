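"""Decision agents: softmax, Oracle, IB particle filter, LK, DT, comparison RL."""

import numpy as np
import pytest

import viforage as vf
from viforage.agents import (
    DirectActorAgent,
    FQAgent,
    FQChoiceTraceAgent,
    FQUpAgent,
    IndirectActorAgent,
    Observation,
    RandomAgent,
)


class TestSoftmax:
    def test_zero_beta_is_uniform(self):
        np.testing.assert_allclose(
            vf.softmax_probabilities(np.array([3.0, -1.0, 7.0]), 0.0), [1 / 3] * 3
        )

    def test_equal_values_are_uniform(self):
        np.testing.assert_allclose(
            vf.softmax_probabilities(np.array([0.4, 0.4]), 5.0), [0.5, 0.5]
        )

    def test_direct_evaluation(self):
        p = vf.softmax_probabilities(np.array([1.0, 0.0]), 2.0)
        e2 = np.exp(2.0)
        np.testing.assert_allclose(p, [e2 / (e2 + 1), 1 / (e2 + 1)])

    def test_sums_to_one_under_extreme_values(self):
        p = vf.softmax_probabilities(np.array([1000.0, -1000.0]), 50.0)
        assert p.sum() == pytest.approx(1.0)
        assert np.isfinite(p).all()

    def test_negative_beta_rejected(self):
        with pytest.raises(ValueError):
            vf.softmax_probabilities(np.array([1.0, 0.0]), -1.0)


class TestOracle:
    def test_strict_argmax(self, rng):
        agent = vf.OracleAgent()
        assert agent.choose(Observation(true_p=np.array([0.1, 0.4])), rng) == 1

    def test_tie_broken_uniformly(self, rng):
        agent = vf.OracleAgent()
        obs = Observation(true_p=np.array([0.25, 0.25]))
        picks = [agent.choose(obs, rng) for _ in range(400)]
        assert 0.4 < np.mean(picks) < 0.6

    def test_steady_state_period_five_on_01_04(self, rng):
        """Constant pset (0.1, 0.4): the lean option is revisited exactly
        every fifth trial once the cycle locks in."""
        sched = vf.make_schedule("fixed", blocks=[(1000, (0.1, 0.4))])
        rec = vf.run_session(vf.OracleAgent(), vf.TaskConfig(schedule=sched), rng)
        tail = rec.choices[-500:]
        left_picks = np.flatnonzero(tail == 0)
        assert np.all(np.diff(left_picks) == 5)


class TestIBAgent:
    def test_single_particle_posterior_and_jitter(self):
        rng = np.random.default_rng(0)
        agent = vf.IBAgent(n_particles=1, jitter=0.025, rng=rng)
        agent.particles[:] = 0.5
        agent.update(0, 1)
        assert abs(agent.particles[0, 0] - 0.5) <= 0.025

    def test_zero_likelihood_particle_falls_back_with_warning(self):
        rng = np.random.default_rng(0)
        agent = vf.IBAgent(n_particles=1, rng=rng)
        agent.particles[0, :] = 0.0  # reward impossible under this particle
        with pytest.warns(RuntimeWarning):
            agent.update(0, 1)

    @pytest.mark.parametrize(
        "particle_value,ti,expected",
        [(0.3, 0, 0.3), (0.1, 4, 0.40951)],
    )
    def test_values_degenerate_cloud(self, particle_value, ti, expected):
        agent = vf.IBAgent(n_particles=50, rng=np.random.default_rng(0))
        agent.particles[:] = particle_value
        agent.ti[:] = ti
        assert agent.values()[0] == pytest.approx(expected)

    def test_values_mixed_cloud(self):
        agent = vf.IBAgent(n_particles=2, rng=np.random.default_rng(0))
        agent.particles[0] = [0.0, 1.0]
        agent.ti[:] = 0
        assert agent.values()[0] == pytest.approx(0.5)

    def test_unchosen_cloud_untouched(self):
        agent = vf.IBAgent(n_particles=20, rng=np.random.default_rng(0))
        before = agent.particles[1].copy()
        agent.update(0, 1)
        np.testing.assert_array_equal(agent.particles[1], before)

    def test_estimates_converge_to_set_probability(self):
        # rich option chosen almost always under a high beta: its particle
        # mean must home in on the true set probability
        rng = np.random.default_rng(42)
        agent = vf.IBAgent(rng=rng)
        sched = vf.make_schedule("fixed", blocks=[(1000, (0.9, 0.1))])
        vf.run_session(agent, vf.TaskConfig(schedule=sched), rng)
        assert agent.estimates()[0] == pytest.approx(0.9, abs=0.08)


class TestLKAgent:
    def test_psi_resets_for_chosen_grows_for_unchosen(self):
        agent = vf.LKAgent(alpha=0.2, tau_psi=0.3, beta=5.0)
        agent.psi[:] = 0.5
        agent.alpha_psi = 0.2
        # freeze alpha_psi by zeroing its learning rate for a clean check
        agent.tau_psi = 0.0
        agent.update(0, 1)
        assert agent.psi[0] == 0.0
        assert agent.psi[1] == pytest.approx(0.5 + 0.2 * 0.5)

    def test_chosen_q_tracks_qset_estimate(self):
        # with psi = 0 for the chosen option the recursion gives Q = Qset
        agent = vf.LKAgent(alpha=0.1, tau_psi=0.1, beta=5.0)
        rng = np.random.default_rng(3)
        for _ in range(500):
            agent.update(0, int(rng.random() < 0.3))
        assert agent.q[0] == pytest.approx(agent.qset[0])
        assert agent.qset[0] == pytest.approx(0.3, abs=0.15)

    def test_out_of_range_reward_rejected(self):
        agent = vf.LKAgent(alpha=0.2, tau_psi=0.3, beta=5.0)
        with pytest.raises(ValueError):
            agent.update(0, 2.0)

    def test_alpha_psi_stays_in_unit_interval(self):
        agent = vf.LKAgent(alpha=0.5, tau_psi=0.9, beta=5.0)
        rng = np.random.default_rng(8)
        for _ in range(300):
            agent.update(int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            assert 0.0 <= agent.alpha_psi <= 1.0
            assert np.all((agent.psi >= 0) & (agent.psi <= 1))


class TestDTAgent:
    def test_full_rate_trace_is_one_hot(self):
        agent = vf.DTAgent(alpha=0.5, beta=1.0, tau_f=1.0, tau_s=0.2, phi=-1.0, vartheta=1.0)
        agent.update(1, 0)
        np.testing.assert_array_equal(agent.f, [0.0, 1.0])

    def test_q_update_direct_value(self):
        agent = vf.DTAgent(alpha=0.75, beta=1.0, tau_f=0.5, tau_s=0.2, phi=0.0, vartheta=0.0)
        agent.q[:] = 0.5
        agent.update(0, 0)
        assert agent.q[0] == pytest.approx(0.125)

    def test_trace_complement_exact_on_random_history(self, rng):
        agent = vf.DTAgent(alpha=0.4, beta=2.0, tau_f=0.7, tau_s=0.2, phi=-2.0, vartheta=3.0)
        for _ in range(500):
            agent.update(int(rng.integers(0, 2)), int(rng.integers(0, 2)))
            assert agent.f[0] + agent.f[1] == pytest.approx(1.0, abs=1e-14)
            assert agent.s[0] + agent.s[1] == pytest.approx(1.0, abs=1e-14)

    def test_zero_scalings_reduce_to_fq(self, rng):
        dt = vf.DTAgent(alpha=0.3, beta=3.0, tau_f=0.7, tau_s=0.2, phi=0.0, vartheta=0.0)
        fq = FQAgent(alpha=0.3, beta=3.0)
        for _ in range(200):
            c, r = int(rng.integers(0, 2)), int(rng.integers(0, 2))
            np.testing.assert_allclose(dt.probabilities(), fq.probabilities())
            dt.update(c, r)
            fq.update(c, r)

    def test_large_beta_is_argmax(self, rng):
        agent = vf.DTAgent(alpha=0.5, beta=500.0, tau_f=0.5, tau_s=0.2, phi=-1.0, vartheta=1.0)
        agent.q[:] = [0.2, 0.8]
        assert agent.choose(None, rng) == int(np.argmax(agent.values()))

    def test_constrained_signs_enforced_at_construction(self):
        with pytest.raises(ValueError):
            vf.DTAgent(alpha=0.5, beta=1.0, tau_f=0.5, tau_s=0.2,
                       phi=0.5, vartheta=1.0, constrained=True)
        vf.DTAgent(alpha=0.5, beta=1.0, tau_f=0.5, tau_s=0.2,
                   phi=-0.5, vartheta=1.0, constrained=True)


class TestComparisonModels:
    def test_indirect_actor_freezes_unchosen(self):
        agent = IndirectActorAgent(alpha=0.5, beta=1.0)
        agent.q[:] = [0.3, 0.6]
        agent.update(0, 1)
        assert agent.q[1] == 0.6

    def test_fq_forgets_unchosen(self):
        agent = FQAgent(alpha=0.3, beta=1.0)
        agent.q[:] = [0.2, 0.6]
        agent.update(0, 1)
        assert agent.q[1] == pytest.approx(0.42)

    def test_direct_actor_no_update_at_reward_equal_c(self):
        agent = DirectActorAgent(alpha=0.5, beta=1.0, c=1.0)
        agent.q[:] = [0.3, 0.6]
        agent.update(0, 1)
        np.testing.assert_allclose(agent.q, [0.3, 0.6])

    def test_fq_up_raises_unchosen_toward_ceiling(self):
        agent = FQUpAgent(alpha=0.5, alpha_up=0.2, ceiling=1.0, beta=1.0,
                          q_init=np.array([0.5, 0.5]))
        agent.update(0, 1)
        assert agent.q[1] == pytest.approx(0.5 + 0.2 * (1.0 - 0.5))

    def test_fq_up_uniform_initialization(self):
        qs = [FQUpAgent(0.5, 0.2, 1.0, 1.0, rng=np.random.default_rng(s)).q
              for s in range(200)]
        qs = np.array(qs).ravel()
        assert (qs >= 0).all() and (qs <= 1).all()
        assert 0.4 < qs.mean() < 0.6


class TestRunSession:
    def test_reproducible_with_same_seed(self):
        sched = vf.make_schedule("fixed", blocks=[(300, (0.1, 0.4))])
        cfg = vf.TaskConfig(schedule=sched, seed=5)
        rec1 = vf.run_session(vf.make_agent("dt", dict(alpha=.5, beta=2., tau_f=.7,
                              tau_s=.2, phi=-1., vartheta=1.)), cfg, np.random.default_rng(5))
        rec2 = vf.run_session(vf.make_agent("dt", dict(alpha=.5, beta=2., tau_f=.7,
                              tau_s=.2, phi=-1., vartheta=1.)), cfg, np.random.default_rng(5))
        np.testing.assert_array_equal(rec1.choices, rec2.choices)
        np.testing.assert_array_equal(rec1.rewards, rec2.rewards)

    def test_random_agent_balanced(self, rng):
        sched = vf.make_schedule("fixed", blocks=[(2000, (0.3, 0.3))])
        rec = vf.run_session(RandomAgent(), vf.TaskConfig(schedule=sched), rng)
        assert rec.choices.mean() == pytest.approx(0.5, abs=0.05)

    def test_record_carries_probability_traces(self, rng):
        sched = vf.make_schedule("mouse-like", rng)
        rec = vf.run_session(RandomAgent(), vf.TaskConfig(schedule=sched), rng)
        assert rec.true_p.shape == (len(rec), 2)
        assert rec.pset_trace.shape == (len(rec), 2)
        assert len(np.unique(rec.block_id)) == 9


class TestInformationHygiene:
    @pytest.mark.parametrize("model,params", [
        ("dt", dict(alpha=.5, beta=2., tau_f=.7, tau_s=.2, phi=-1., vartheta=1.)),
        ("lk", dict(alpha=.3, tau_psi=.3, beta=5.)),
        ("fq", dict(alpha=.3, beta=3.)),
    ])
    def test_non_oracle_agents_ignore_true_probabilities(self, model, params, rng):
        """Behavior must be identical whether or not true_p is exposed."""
        a1, a2 = vf.make_agent(model, params), vf.make_agent(model, params)
        r1, r2 = np.random.default_rng(11), np.random.default_rng(11)
        for _ in range(100):
            c1 = a1.choose(Observation(true_p=np.array([0.9, 0.1])), r1)
            c2 = a2.choose(Observation(true_p=None), r2)
            assert c1 == c2
            a1.update(c1, 1)
            a2.update(c2, 1)


def test_make_agent_unknown_model_rejected():
    with pytest.raises(ValueError, match="unknown model"):
        vf.make_agent("q_lambda")
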