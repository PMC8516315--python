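"""Likelihood evaluation, annealing search, AUC, cross-validated comparison."""

import numpy as np
import pytest
from scipy import optimize

import viforage as vf
from viforage._engine import batch_replay_loglik
from viforage.fitting import MODEL_PARAMS, canonicalize_dt, dict_to_theta
from conftest import random_session

DT_PARAMS = dict(alpha=0.75, beta=1.6, tau_f=0.71, tau_s=0.24, phi=-2.22, vartheta=3.31)


class TestSessionLogLikelihood:
    def test_constant_half_probability_closed_form(self, rng):
        # beta = 0 makes every model emit P = 0.5 on every trial
        sess = random_session(rng, 200)
        ll, per_trial = vf.session_log_likelihood("fq", dict(alpha=0.5, beta=0.0), [sess])
        assert ll == pytest.approx(-200 * np.log(2))
        assert len(per_trial) == 200

    def test_near_perfect_prediction_approaches_zero(self):
        # a strongly alternating DT model on strictly alternating data
        n = 100
        sess = vf.SessionRecord(choices=np.arange(n) % 2, rewards=np.zeros(n, int),
                                block_id=np.zeros(n, int))
        params = dict(alpha=0.0, beta=50.0, tau_f=1.0, tau_s=0.0, phi=-25.0, vartheta=0.0)
        ll, _ = vf.session_log_likelihood("dt", params, [sess])
        # first trial is 50:50; everything after is predicted almost surely
        assert ll > -np.log(2) - 1e-6

    def test_out_of_bounds_params_rejected(self, rng):
        with pytest.raises(ValueError, match="outside bounds"):
            vf.session_log_likelihood("fq", dict(alpha=1.5, beta=1.0),
                                      [random_session(rng, 10)])

    @pytest.mark.parametrize("model,params", [
        ("dt", DT_PARAMS),
        ("fq", dict(alpha=0.3, beta=3.0)),
        ("fq_wc", dict(alpha=0.3, beta=3.0, tau_f=0.5, phi=-1.0)),
        ("indirect", dict(alpha=0.5, beta=2.0)),
        ("direct", dict(alpha=0.2, beta=1.5, c=0.3)),
        ("lk", dict(alpha=0.4, tau_psi=0.3, beta=4.0)),
    ])
    def test_batch_engine_matches_object_replay(self, model, params, rng):
        """The vectorized engine and the object-oriented reference agent
        are two independent routes to the same likelihood."""
        sessions = [random_session(rng, 250), random_session(rng, 150)]
        ll_obj, _ = vf.session_log_likelihood(model, params, sessions)
        ll_batch = batch_replay_loglik(model, dict_to_theta(model, params)[None, :],
                                       sessions)[0]
        assert ll_batch == pytest.approx(ll_obj, abs=1e-9)

    def test_fq_up_batch_matches_object_replay_with_shared_seed(self, rng):
        sessions = [random_session(rng, 200)]
        params = dict(alpha=0.3, alpha_up=0.1, ceiling=0.8, beta=2.0)
        ll_obj, _ = vf.session_log_likelihood("fq_up", params, sessions,
                                              rng=np.random.default_rng(3))
        ll_batch = batch_replay_loglik("fq_up", dict_to_theta("fq_up", params)[None, :],
                                       sessions, rng=np.random.default_rng(3))[0]
        assert ll_batch == pytest.approx(ll_obj, abs=1e-9)


class TestAnnealFit:
    def test_single_free_parameter_matches_scalar_oracle(self, rng, dt_sessions):
        """Pin every DT parameter except beta and compare the annealing
        optimum with a bounded scalar search on the exact likelihood."""
        sessions = dt_sessions[0][:3]
        pins = {k: (v, v) for k, v in DT_PARAMS.items() if k != "beta"}
        bounds = [pins.get(name, (lo, hi)) for name, lo, hi in MODEL_PARAMS["dt"]]

        def negll(beta):
            p = dict(DT_PARAMS, beta=float(beta))
            return -batch_replay_loglik("dt", dict_to_theta("dt", p)[None, :], sessions)[0]

        oracle = optimize.minimize_scalar(negll, bounds=(0, 50), method="bounded")
        fit = vf.anneal_fit("dt", sessions, bounds=bounds, rng=rng,
                            n_draws=300, n_restarts=1)
        assert fit.theta_hat["beta"] == pytest.approx(oracle.x, abs=0.05)

    def test_reproducible_with_fixed_seed(self, dt_sessions):
        sessions = dt_sessions[0][:2]
        f1 = vf.anneal_fit("fq", sessions, rng=np.random.default_rng(4),
                           n_draws=200, n_restarts=1)
        f2 = vf.anneal_fit("fq", sessions, rng=np.random.default_rng(4),
                           n_draws=200, n_restarts=1)
        assert f1.theta_hat == f2.theta_hat

    def test_search_trace_monotone_nondecreasing(self, dt_sessions):
        fit = vf.anneal_fit("dt", dt_sessions[0][:2], rng=np.random.default_rng(9),
                            n_draws=300, n_restarts=1)
        trace = np.asarray(fit.search_trace)
        assert np.all(np.diff(trace) >= 0)

    def test_recovers_generating_learning_rate(self, dt_sessions):
        sessions, manifest = dt_sessions
        fit = vf.anneal_fit("dt", sessions, rng=np.random.default_rng(21))
        theta = canonicalize_dt(fit.theta_hat)
        assert theta["alpha"] == pytest.approx(manifest["true_params"]["alpha"], abs=0.1)


class TestLikelihoodDominance:
    def test_true_parameters_beat_perturbed_alpha(self, dt_sessions):
        sessions = dt_sessions[0]
        true_theta = dict_to_theta("dt", DT_PARAMS)
        shifted = true_theta.copy()
        shifted[0] = max(0.0, shifted[0] - 0.3)
        lls = batch_replay_loglik("dt", np.vstack([true_theta, shifted]), sessions)
        assert lls[0] > lls[1]

    def test_true_parameters_beat_random_vectors(self, dt_sessions, rng):
        sessions = dt_sessions[0][:5]
        spec = MODEL_PARAMS["dt"]
        lo = np.array([b[1] for b in spec])
        hi = np.array([b[2] for b in spec])
        randoms = rng.uniform(lo, hi, size=(200, len(spec)))
        lls = batch_replay_loglik("dt", np.vstack([dict_to_theta("dt", DT_PARAMS),
                                                   randoms]), sessions)
        wins = np.mean(lls[0] > lls[1:])
        assert wins >= 0.95


class TestAUC:
    @pytest.mark.parametrize("scores,labels,expected", [
        ([0.9, 0.8, 0.3], [1, 0, 0], 1.0),
        ([0.9, 0.8, 0.3], [1, 0, 1], 0.5),
        ([0.1, 0.2, 0.9], [1, 1, 0], 0.0),
    ])
    def test_pair_counting_examples(self, scores, labels, expected):
        assert vf.auc(np.array(scores), np.array(labels)) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            vf.auc(np.array([0.1, 0.9]), np.array([1, 1]))

    def test_matches_brute_force_pair_counting(self, rng):
        def brute_force(scores, labels):
            pos = scores[labels == 1]
            neg = scores[labels == 0]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            return wins / (len(pos) * len(neg))

        for _ in range(300):
            n = int(rng.integers(5, 40))
            scores = np.round(rng.random(n), 2)  # rounded to force ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            assert vf.auc(scores, labels) == pytest.approx(brute_force(scores, labels))


@pytest.fixture(scope="module")
def comparison():
    from viforage.synthetic import RecoverySpec, generate_recovery_dataset

    spec = RecoverySpec(true_params=DT_PARAMS, n_runs=4,
                        trials_per_session=500, seed=31)
    sessions, _ = generate_recovery_dataset(spec)
    return vf.crossval_compare(
        ["dt", "fq", "indirect"], sessions, rng=np.random.default_rng(17),
        n_draws=300, n_restarts=2,
    )


class TestCrossvalCompare:
    def test_generating_model_dominates(self, comparison):
        nll = {r.model: r.mean_test_nll for r in comparison}
        assert nll["dt"] < nll["indirect"]
        assert nll["dt"] < nll["fq"]

    def test_nesting_sanity(self, comparison):
        # F-Q is DT with phi = vartheta = 0, so DT cannot do much worse
        nll = {r.model: r.mean_test_nll for r in comparison}
        assert nll["dt"] <= nll["fq"] + 0.05

    def test_metrics_well_formed(self, comparison):
        for r in comparison:
            assert r.mean_test_nll >= 0
            assert 0.0 <= r.mean_test_auc <= 1.0
            assert len(r.per_fold) == 5

    def test_fold_sizes_paired_across_models(self, comparison):
        # the comparison is paired: identical fold partitions for every model
        for r in comparison[1:]:
            assert [m["fold"] for m in r.per_fold] == [m["fold"] for m in comparison[0].per_fold]


class TestCanonicalizeDT:
    def test_mirrored_solution_is_reordered(self):
        mirrored = dict(alpha=0.5, beta=1.0, tau_f=0.2, tau_s=0.7, phi=3.0, vartheta=-2.0)
        fixed = canonicalize_dt(mirrored)
        assert fixed["phi"] == -2.0 and fixed["vartheta"] == 3.0
        assert fixed["tau_f"] == 0.7 and fixed["tau_s"] == 0.2

    def test_canonical_solution_unchanged(self):
        assert canonicalize_dt(DT_PARAMS) == DT_PARAMS

    def test_swap_preserves_likelihood(self, rng):
        sess = random_session(rng, 300)
        mirrored = dict(alpha=0.5, beta=1.0, tau_f=0.2, tau_s=0.7, phi=3.0, vartheta=-2.0)
        ll1, _ = vf.session_log_likelihood("dt", mirrored, [sess])
        ll2, _ = vf.session_log_likelihood("dt", canonicalize_dt(mirrored), [sess])
        assert ll1 == pytest.approx(ll2)
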