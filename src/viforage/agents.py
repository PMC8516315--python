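"""Decision agents for the variable-interval foraging task.

Three classes of agents are provided behind one choose/update contract:

* optimal agents — the Oracle (greedy on the true momentary reward
  probabilities), the inference-based (IB) particle agent that infers
  the set probabilities by Bayesian reweighting of a particle cloud
  under the baiting likelihood, and the LK model that learns both the
  set probabilities (Rescorla–Wagner) and a dynamic baiting factor;
* the double-trace (DT) model — a forgetting-Q learner whose softmax
  values add a fast and a slow exponentially decaying choice trace;
* comparison RL models — indirect actor, direct actor, forgetting-Q
  (F-Q), F-Q with a single choice trace, and F-Q "up".

All agents except the Oracle observe only their own choices and
rewards.  The Oracle reads the true momentary probabilities from the
:class:`Observation` handed to it by the closed-loop driver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .env import EnvState, SessionRecord, TaskConfig, init_env, step

__all__ = [
    "Observation",
    "Agent",
    "softmax_probabilities",
    "OracleAgent",
    "RandomAgent",
    "IBAgent",
    "LKAgent",
    "DTAgent",
    "IndirectActorAgent",
    "DirectActorAgent",
    "FQAgent",
    "FQChoiceTraceAgent",
    "FQUpAgent",
    "make_agent",
    "run_session",
]


@dataclass
class Observation:
    """What the environment exposes to an agent before a choice.

    ``true_p`` is only meaningful to the Oracle; every other agent
    must behave identically whether or not it is present.
    """

    true_p: np.ndarray | None = None


def softmax_probabilities(values: np.ndarray, beta: float) -> np.ndarray:
    """Numerically stable softmax with inverse temperature ``beta``.

    ``beta = 0`` yields the uniform distribution regardless of values.
    """
    if beta < 0:
        raise ValueError("inverse temperature must be non-negative")
    z = beta * np.asarray(values, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


class Agent:
    """choose/update contract shared by every agent."""

    n_options: int = 2
    needs_true_p: bool = False

    def reset(self, rng: np.random.Generator | None = None) -> None:  # pragma: no cover
        pass

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        raise NotImplementedError

    def choose(self, obs: Observation | None, rng: np.random.Generator) -> int:
        p = self.probabilities(obs)
        return int(rng.choice(self.n_options, p=p))

    def update(self, choice: int, reward: int) -> None:
        raise NotImplementedError


class OracleAgent(Agent):
    """Greedy on the true momentary reward probabilities; ties split uniformly."""

    needs_true_p = True

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        if obs is None or obs.true_p is None:
            raise ValueError("the Oracle requires the true probabilities")
        p = np.asarray(obs.true_p, dtype=float)
        best = p == p.max()
        return best / best.sum()

    def choose(self, obs: Observation | None, rng: np.random.Generator) -> int:
        p = self.probabilities(obs)
        winners = np.flatnonzero(p > 0)
        if len(winners) == 1:
            return int(winners[0])
        return int(rng.choice(winners))

    def update(self, choice: int, reward: int) -> None:
        pass


class RandomAgent(Agent):
    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return np.full(self.n_options, 1.0 / self.n_options)

    def update(self, choice: int, reward: int) -> None:
        pass


class IBAgent(Agent):
    """Inference-based agent: particle cloud over each option's set probability.

    Each option carries ``n_particles`` estimates of its set reward
    probability, initialized uniformly on [0, 1].  On every trial each
    particle predicts the momentary reward probability through the
    baiting closed form (exponent ``ti + 1`` with ``ti`` the trials
    since the option was chosen), and the option's value is the
    particle mean of these predictions.  After the outcome of the
    chosen option is observed, its particles are reweighted by the
    Bernoulli likelihood of the outcome, resampled in proportion to
    the posterior mass, jittered by U[-jitter, +jitter] and clipped to
    [0, 1].  The unchosen option's cloud is untouched.
    """

    def __init__(
        self,
        n_particles: int = 1000,
        jitter: float = 0.025,
        beta: float = 10.0,
        n_options: int = 2,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.n_particles = n_particles
        self.jitter = jitter
        self.beta = beta
        self.n_options = n_options
        self.reset(rng if rng is not None else np.random.default_rng())

    def reset(self, rng: np.random.Generator | None = None) -> None:
        if rng is not None:
            self._rng = rng
        self.particles = self._rng.uniform(0.0, 1.0, size=(self.n_options, self.n_particles))
        self.ti = np.zeros(self.n_options, dtype=int)

    def predicted_reward_probabilities(self) -> np.ndarray:
        """(n_options, n_particles) momentary probability predicted by each particle."""
        expo = (self.ti + 1)[:, None]
        return 1.0 - (1.0 - self.particles) ** expo

    def values(self) -> np.ndarray:
        return self.predicted_reward_probabilities().mean(axis=1)

    def estimates(self) -> np.ndarray:
        """Per-option particle-mean estimate of the set reward probability."""
        return self.particles.mean(axis=1)

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return softmax_probabilities(self.values(), self.beta)

    def update(self, choice: int, reward: int) -> None:
        p_hat = 1.0 - (1.0 - self.particles[choice]) ** (self.ti[choice] + 1)
        w = p_hat if reward else 1.0 - p_hat
        total = w.sum()
        if total <= 0.0 or not np.isfinite(total):
            warnings.warn(
                "all particle weights vanished; falling back to uniform resampling",
                RuntimeWarning,
            )
            w = np.full(self.n_particles, 1.0 / self.n_particles)
        else:
            w = w / total
        idx = self._rng.choice(self.n_particles, size=self.n_particles, p=w)
        new = self.particles[choice, idx]
        new = new + self._rng.uniform(-self.jitter, self.jitter, size=self.n_particles)
        self.particles[choice] = np.clip(new, 0.0, 1.0)
        self.ti += 1
        self.ti[choice] = 0


class LKAgent(Agent):
    """Learns set probabilities and a dynamic baiting factor ψ.

    ``Qset`` tracks each option's set reward probability by a
    Rescorla–Wagner rule on the chosen option.  The baiting factor
    ``ψ`` resets to 0 for the chosen option and grows toward 1 for
    unchosen options at a rate ``α_ψ`` that itself adapts to the
    prediction error.  The momentary value estimate recombines the two
    through the baiting recursion Q = 1 - (1 - Qset)(1 - Q·ψ).
    """

    def __init__(self, alpha: float, tau_psi: float, beta: float, n_options: int = 2) -> None:
        if not 0.0 <= alpha <= 1.0 or not 0.0 <= tau_psi <= 1.0:
            raise ValueError("learning rates must lie in [0, 1]")
        self.alpha = alpha
        self.tau_psi = tau_psi
        self.beta = beta
        self.n_options = n_options
        self.reset()

    def reset(self, rng: np.random.Generator | None = None) -> None:
        self.qset = np.full(self.n_options, 0.5)
        self.q = np.full(self.n_options, 0.5)
        self.psi = np.zeros(self.n_options)
        self.alpha_psi = 0.5

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return softmax_probabilities(self.q, self.beta)

    def update(self, choice: int, reward: float) -> None:
        if not 0.0 <= reward <= 1.0:
            raise ValueError("LK model requires rewards bounded in [0, 1]")
        pe = reward - self.q[choice]
        self.qset[choice] += self.alpha * (reward - self.qset[choice])
        self.alpha_psi += self.tau_psi * ((pe + 1.0) / 2.0 - self.alpha_psi)
        unchosen = np.ones(self.n_options, dtype=bool)
        unchosen[choice] = False
        self.psi = np.where(
            unchosen, self.psi + self.alpha_psi * (1.0 - self.psi), 0.0
        )
        self.q = 1.0 - (1.0 - self.qset) * (1.0 - self.q * self.psi)


class DTAgent(Agent):
    """Double-trace model: forgetting-Q value plus fast and slow choice traces.

    Softmax value of option i is ``Q_i + φ F_i + ϑ S_i``.  Q follows
    the forgetting-Q update toward the (choice-gated) reward; F and S
    decay toward the one-hot choice indicator with learning rates τ_F
    and τ_S.  In the constrained variant φ must be non-positive
    (short-term alternation) and ϑ non-negative (long-term
    perseverance), as observed in animals.
    """

    def __init__(
        self,
        alpha: float,
        beta: float,
        tau_f: float,
        tau_s: float,
        phi: float,
        vartheta: float,
        constrained: bool = False,
        n_options: int = 2,
    ) -> None:
        for name, rate in (("alpha", alpha), ("tau_f", tau_f), ("tau_s", tau_s)):
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {rate}")
        if beta < 0:
            raise ValueError("beta must be non-negative")
        if constrained and (phi > 0 or vartheta < 0):
            raise ValueError(
                "constrained DT model requires phi <= 0 and vartheta >= 0"
            )
        self.alpha, self.beta = alpha, beta
        self.tau_f, self.tau_s = tau_f, tau_s
        self.phi, self.vartheta = phi, vartheta
        self.constrained = constrained
        self.n_options = n_options
        self.reset()

    def reset(self, rng: np.random.Generator | None = None) -> None:
        self.q = np.zeros(self.n_options)
        self.f = np.full(self.n_options, 0.5)
        self.s = np.full(self.n_options, 0.5)

    def values(self) -> np.ndarray:
        return self.q + self.phi * self.f + self.vartheta * self.s

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return softmax_probabilities(self.values(), self.beta)

    def update(self, choice: int, reward: int) -> None:
        delta = np.zeros(self.n_options)
        delta[choice] = 1.0
        self.q += self.alpha * (delta * reward - self.q)
        self.f += self.tau_f * (delta - self.f)
        self.s += self.tau_s * (delta - self.s)


class IndirectActorAgent(Agent):
    """Rescorla–Wagner on the chosen option only; unchosen values frozen."""

    def __init__(self, alpha: float, beta: float, n_options: int = 2) -> None:
        self.alpha, self.beta = alpha, beta
        self.n_options = n_options
        self.reset()

    def reset(self, rng: np.random.Generator | None = None) -> None:
        self.q = np.zeros(self.n_options)

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return softmax_probabilities(self.q, self.beta)

    def update(self, choice: int, reward: int) -> None:
        self.q[choice] += self.alpha * (reward - self.q[choice])


class DirectActorAgent(Agent):
    """Policy-gradient-like update scaled by the reward minus an average-reward offset c."""

    def __init__(self, alpha: float, beta: float, c: float, n_options: int = 2) -> None:
        self.alpha, self.beta, self.c = alpha, beta, c
        self.n_options = n_options
        self.reset()

    def reset(self, rng: np.random.Generator | None = None) -> None:
        self.q = np.zeros(self.n_options)

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return softmax_probabilities(self.q, self.beta)

    def update(self, choice: int, reward: int) -> None:
        p = self.probabilities()
        delta = np.zeros(self.n_options)
        delta[choice] = 1.0
        self.q += self.alpha * (delta - p) * (reward - self.c)


class FQAgent(Agent):
    """Forgetting-Q: unchosen option values decay toward zero."""

    def __init__(self, alpha: float, beta: float, n_options: int = 2) -> None:
        self.alpha, self.beta = alpha, beta
        self.n_options = n_options
        self.reset()

    def reset(self, rng: np.random.Generator | None = None) -> None:
        self.q = np.zeros(self.n_options)

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return softmax_probabilities(self.q, self.beta)

    def update(self, choice: int, reward: int) -> None:
        delta = np.zeros(self.n_options)
        delta[choice] = 1.0
        self.q += self.alpha * (delta * reward - self.q)


class FQChoiceTraceAgent(Agent):
    """Forgetting-Q plus a single choice trace F scaled by φ."""

    def __init__(
        self, alpha: float, beta: float, tau_f: float, phi: float, n_options: int = 2
    ) -> None:
        self.alpha, self.beta, self.tau_f, self.phi = alpha, beta, tau_f, phi
        self.n_options = n_options
        self.reset()

    def reset(self, rng: np.random.Generator | None = None) -> None:
        self.q = np.zeros(self.n_options)
        self.f = np.full(self.n_options, 0.5)

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return softmax_probabilities(self.q + self.phi * self.f, self.beta)

    def update(self, choice: int, reward: int) -> None:
        delta = np.zeros(self.n_options)
        delta[choice] = 1.0
        self.q += self.alpha * (delta * reward - self.q)
        self.f += self.tau_f * (delta - self.f)


class FQUpAgent(Agent):
    """Chosen option learns the reward; unchosen options grow toward a ceiling C.

    Initial values are drawn uniformly from [0, 1] (pass ``q_init`` to
    pin them, e.g. for teacher-forced replay comparisons).
    """

    def __init__(
        self,
        alpha: float,
        alpha_up: float,
        ceiling: float,
        beta: float,
        n_options: int = 2,
        q_init: np.ndarray | None = None,
        rng: np.random.Generator | None = None,
    ) -> None:
        self.alpha, self.alpha_up, self.ceiling, self.beta = alpha, alpha_up, ceiling, beta
        self.n_options = n_options
        self._q_init = None if q_init is None else np.asarray(q_init, dtype=float)
        self.reset(rng if rng is not None else np.random.default_rng())

    def reset(self, rng: np.random.Generator | None = None) -> None:
        if rng is not None:
            self._rng = rng
        if self._q_init is not None:
            self.q = self._q_init.copy()
        else:
            self.q = self._rng.uniform(0.0, 1.0, size=self.n_options)

    def probabilities(self, obs: Observation | None = None) -> np.ndarray:
        return softmax_probabilities(self.q, self.beta)

    def update(self, choice: int, reward: int) -> None:
        delta = np.zeros(self.n_options)
        delta[choice] = 1.0
        self.q += delta * self.alpha * (reward - self.q) + (1 - delta) * self.alpha_up * (
            self.ceiling - self.q
        )


_AGENT_FACTORIES = {
    "oracle": OracleAgent,
    "random": RandomAgent,
    "ib": IBAgent,
    "lk": LKAgent,
    "dt": DTAgent,
    "indirect": IndirectActorAgent,
    "direct": DirectActorAgent,
    "fq": FQAgent,
    "fq_wc": FQChoiceTraceAgent,
    "fq_up": FQUpAgent,
}


def make_agent(model: str, params: Mapping | None = None, **kwargs) -> Agent:
    """Construct an agent from ``{model_name, parameters}``."""
    try:
        factory = _AGENT_FACTORIES[model]
    except KeyError:
        raise ValueError(
            f"unknown model {model!r}; choose from {sorted(_AGENT_FACTORIES)}"
        ) from None
    params = dict(params or {})
    params.update(kwargs)
    return factory(**params)


def run_session(
    agent: Agent, config: TaskConfig, rng: np.random.Generator
) -> SessionRecord:
    """Closed-loop simulation of one session.

    Records the full behavioral trace together with the true
    momentary and set probabilities so that downstream regret and
    regression analyses need no access to the live environment.
    """
    state: EnvState = init_env(config)
    n = config.n_trials
    choices = np.empty(n, dtype=int)
    rewards = np.empty(n, dtype=int)
    true_p = np.empty((n, config.n_options))
    pset_trace = np.empty((n, config.n_options))
    block_id = config.schedule.block_per_trial()

    for t in range(n):
        true_p[t] = state.p
        pset_trace[t] = state.pset
        obs = Observation(true_p=state.p if agent.needs_true_p else None)
        choice = agent.choose(obs, rng)
        reward, state = step(state, choice, rng)
        agent.update(choice, reward)
        choices[t] = choice
        rewards[t] = reward

    return SessionRecord(
        choices=choices,
        rewards=rewards,
        block_id=block_id,
        true_p=true_p,
        pset_trace=pset_trace,
        meta={"agent": type(agent).__name__, "seed": config.seed},
    )
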