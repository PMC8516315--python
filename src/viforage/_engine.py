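"""Vectorized engines: many parameter draws evaluated in one pass.

The object-oriented agents in :mod:`viforage.agents` are the reference
implementation of every update rule.  The fitting and regret-optimization
pipelines, however, must score hundreds to thousands of candidate
parameter vectors, so the same recursions are re-expressed here with
numpy broadcasting over draws: state arrays have shape ``(n_draws, 2)``
and one pass over a session updates all draws at once.  Equality of the
two routes (batch with ``n_draws = 1`` versus object replay) is enforced
by the test suite.

Two-option sessions only — the derivations the batch forms rely on
(value differences through a logistic) are two-option.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .env import BlockSchedule, SessionRecord

__all__ = ["batch_replay_loglik", "batch_simulate", "BATCH_MODELS"]

_PROB_FLOOR = 1e-12
_LOG_FLOOR = float(np.log(_PROB_FLOOR))


def _one_hot(choices: np.ndarray) -> np.ndarray:
    d = np.zeros((len(choices), 2))
    d[np.arange(len(choices)), choices] = 1.0
    return d


# --------------------------------------------------------------- state init

def _init_state(model: str, theta: np.ndarray, rng: np.random.Generator | None) -> dict:
    n = theta.shape[0]
    if model == "dt":
        return {
            "q": np.zeros((n, 2)),
            "f": np.full((n, 2), 0.5),
            "s": np.full((n, 2), 0.5),
        }
    if model == "fq_wc":
        return {"q": np.zeros((n, 2)), "f": np.full((n, 2), 0.5)}
    if model in ("fq", "indirect", "direct"):
        return {"q": np.zeros((n, 2))}
    if model == "fq_up":
        if rng is None:
            raise ValueError("fq_up requires an rng for its uniform Q initialization")
        return {"q": rng.uniform(0.0, 1.0, size=(n, 2))}
    if model == "lk":
        return {
            "qset": np.full((n, 2), 0.5),
            "q": np.full((n, 2), 0.5),
            "psi": np.zeros((n, 2)),
            "alpha_psi": np.full(n, 0.5),
        }
    raise ValueError(f"model {model!r} has no batch engine")


def _values(model: str, theta: np.ndarray, st: dict) -> np.ndarray:
    if model == "dt":
        phi, vth = theta[:, 4:5], theta[:, 5:6]
        return st["q"] + phi * st["f"] + vth * st["s"]
    if model == "fq_wc":
        return st["q"] + theta[:, 3:4] * st["f"]
    return st["q"]


def _beta(model: str, theta: np.ndarray) -> np.ndarray:
    if model == "fq_up":
        return theta[:, 3]
    if model == "lk":
        return theta[:, 2]
    return theta[:, 1]


def _update(
    model: str,
    theta: np.ndarray,
    st: dict,
    choice: int,
    reward: float,
    probs: np.ndarray | None,
) -> None:
    """In-place state update after one (recorded or simulated) trial.

    ``choice``/``reward`` are scalars when replaying a recorded session;
    in closed loop they are per-draw arrays and broadcasting does the rest.
    """
    alpha = theta[:, 0]
    if np.isscalar(choice) or np.ndim(choice) == 0:
        delta = np.zeros(2)
        delta[choice] = 1.0
        delta = np.broadcast_to(delta, (theta.shape[0], 2))
    else:
        delta = _one_hot(np.asarray(choice))
    r = np.asarray(reward, dtype=float)
    r_col = r[..., None] if r.ndim else r

    if model in ("dt", "fq", "fq_wc"):
        st["q"] += alpha[:, None] * (delta * r_col - st["q"])
        if model in ("dt", "fq_wc"):
            tau_f = theta[:, 2]
            st["f"] += tau_f[:, None] * (delta - st["f"])
        if model == "dt":
            tau_s = theta[:, 3]
            st["s"] += tau_s[:, None] * (delta - st["s"])
    elif model == "indirect":
        st["q"] += delta * alpha[:, None] * (r_col - st["q"])
    elif model == "direct":
        c = theta[:, 2]
        st["q"] += alpha[:, None] * (delta - probs) * (r_col - c[:, None])
    elif model == "fq_up":
        alpha_up = theta[:, 1]
        ceil = theta[:, 2]
        st["q"] += delta * alpha[:, None] * (r_col - st["q"]) + (1 - delta) * alpha_up[
            :, None
        ] * (ceil[:, None] - st["q"])
    elif model == "lk":
        tau_psi = theta[:, 1]
        q_chosen = (st["q"] * delta).sum(axis=1)
        pe = r - q_chosen
        st["qset"] += delta * alpha[:, None] * (r_col - st["qset"])
        st["alpha_psi"] += tau_psi * ((pe + 1.0) / 2.0 - st["alpha_psi"])
        st["psi"] = (1 - delta) * (st["psi"] + st["alpha_psi"][:, None] * (1.0 - st["psi"]))
        st["q"] = 1.0 - (1.0 - st["qset"]) * (1.0 - st["q"] * st["psi"])
    else:  # pragma: no cover
        raise ValueError(f"model {model!r} has no batch engine")


BATCH_MODELS = ("dt", "fq", "fq_wc", "indirect", "direct", "fq_up", "lk")


def _fast_replay_difference(
    model: str, theta: np.ndarray, sessions: list[SessionRecord]
) -> np.ndarray:
    """Two-option replay via value-difference recursions for dt/fq/fq_wc.

    With two options the forgetting-Q and choice-trace updates close
    over the value *difference* (right minus left): with x = 2c - 1,

        dQ <- (1-alpha) dQ + alpha * x * R,   dF <- (1-tau) dF + tau * x,

    starting from dQ = dF = dS = 0 (Q init 0, traces init 0.5 each).
    This halves the state and lets the log-likelihood accumulate
    through a stable logaddexp, and is exactly equal to the full
    two-column recursion.
    """
    n = theta.shape[0]
    alpha, beta = theta[:, 0:1], theta[:, 1:2]
    one_m_alpha = 1.0 - alpha
    if model in ("dt", "fq_wc"):
        tau_f = theta[:, 2:3]
        one_m_tf = 1.0 - tau_f
        phi = theta[:, 4:5] if model == "dt" else theta[:, 3:4]
    if model == "dt":
        tau_s = theta[:, 3:4]
        one_m_ts = 1.0 - tau_s
        vth = theta[:, 5:6]

    # equal-length sessions share the trial loop: state arrays are
    # (n_draws, n_sessions) and one pass covers the whole group
    by_length: dict[int, list[SessionRecord]] = {}
    for sess in sessions:
        by_length.setdefault(len(sess), []).append(sess)

    ll = np.zeros(n)
    for T, group in by_length.items():
        x = np.stack([2.0 * s.choices - 1.0 for s in group], axis=1)  # (T, m)
        xr = np.stack([(2.0 * s.choices - 1.0) * s.rewards for s in group], axis=1)
        m = len(group)
        dq = np.zeros((n, m))
        df = np.zeros((n, m)) if model in ("dt", "fq_wc") else None
        ds = np.zeros((n, m)) if model == "dt" else None
        acc = np.zeros((n, m))
        for t in range(T):
            dv = dq
            if model in ("dt", "fq_wc"):
                dv = dv + phi * df
            if model == "dt":
                dv = dv + vth * ds
            # log P(recorded choice) = -log(1 + exp(-x_t * beta * dv)),
            # floored to match the generic path's probability floor
            acc += np.maximum(-np.logaddexp(0.0, -x[t] * (beta * dv)), _LOG_FLOOR)
            dq = one_m_alpha * dq + alpha * xr[t]
            if model in ("dt", "fq_wc"):
                df = one_m_tf * df + tau_f * x[t]
            if model == "dt":
                ds = one_m_ts * ds + tau_s * x[t]
        ll += acc.sum(axis=1)
    return ll


def batch_replay_loglik(
    model: str,
    theta: np.ndarray,
    sessions: list[SessionRecord],
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Teacher-forced total log-likelihood of recorded sessions per draw.

    ``theta`` is ``(n_draws, n_params)`` in the model's canonical
    parameter order (see :data:`viforage.fitting.MODEL_PARAMS`).  The
    model's state resets at every session boundary.  Probabilities are
    floored at 1e-12 before the log.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    if model in ("dt", "fq", "fq_wc"):
        return _fast_replay_difference(model, theta, sessions)
    n = theta.shape[0]
    ll = np.zeros(n)
    beta = _beta(model, theta)
    for sess in sessions:
        st = _init_state(model, theta, rng)
        for choice, reward in zip(sess.choices, sess.rewards):
            v = _values(model, theta, st)
            p1 = expit(beta * (v[:, 1] - v[:, 0]))
            p_choice = p1 if choice == 1 else 1.0 - p1
            ll += np.log(np.maximum(p_choice, _PROB_FLOOR))
            probs = np.column_stack([1.0 - p1, p1]) if model == "direct" else None
            _update(model, theta, st, int(choice), float(reward), probs)
    return ll


def batch_simulate(
    model: str,
    theta: np.ndarray | None,
    schedule: BlockSchedule,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Closed-loop simulation of ``n_draws`` independent runs on one schedule.

    Every draw experiences its own Bernoulli reward stream; the block
    structure is shared.  ``model`` may also be ``"oracle"`` or
    ``"random"`` (``theta`` ignored, pass an ``(n, 0)``-shaped array or
    ``None`` with ``n_runs`` encoded by a ``(n, 1)`` dummy).  Returns
    per-draw totals: collected rewards, the running maximal expected
    reward ``mu_star`` along each realized trajectory, and the choice
    and reward matrices.
    """
    if theta is None:
        raise ValueError("theta must be an (n_draws, k) array; use k=0 for policy-free agents")
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    n = theta.shape[0]
    T = schedule.n_trials
    pset = schedule.pset_per_trial()  # (T, 2), pset governing trial t (0-based row t-1)

    p_env = np.broadcast_to(pset[0], (n, 2)).copy()
    mu_star = np.zeros(n)
    collected = np.zeros(n)
    choices = np.empty((n, T), dtype=np.int8)
    rewards = np.empty((n, T), dtype=np.int8)

    is_policy_free = model in ("oracle", "random")
    st = None if is_policy_free else _init_state(model, theta, rng)
    beta = None if is_policy_free else _beta(model, theta)

    rows = np.arange(n)
    for t in range(T):
        mu_star += p_env.max(axis=1)
        if model == "oracle":
            gap = p_env[:, 1] - p_env[:, 0]
            choice = (gap > 0).astype(np.int8)
            tie = gap == 0
            if tie.any():
                choice[tie] = (rng.random(tie.sum()) < 0.5).astype(np.int8)
            probs = None
        elif model == "random":
            choice = (rng.random(n) < 0.5).astype(np.int8)
            probs = None
        else:
            v = _values(model, theta, st)
            p1 = expit(beta * (v[:, 1] - v[:, 0]))
            choice = (rng.random(n) < p1).astype(np.int8)
            probs = np.column_stack([1.0 - p1, p1]) if model == "direct" else None

        reward = (rng.random(n) < p_env[rows, choice]).astype(np.int8)
        choices[:, t] = choice
        rewards[:, t] = reward
        collected += reward

        pset_next = pset[t + 1] if t + 1 < T else pset[-1]
        p_env = 1.0 - (1.0 - pset_next) * (1.0 - p_env)
        p_env[rows, choice] = pset_next[choice]

        if not is_policy_free:
            _update(model, theta, st, choice, reward.astype(float), probs)

    return {
        "collected": collected,
        "mu_star": mu_star,
        "regret": mu_star - collected,
        "choices": choices,
        "rewards": rewards,
    }
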