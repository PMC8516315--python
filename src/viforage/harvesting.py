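"""Regret computation and regret-minimizing parameter optimization.

Regret is the cumulative maximal expected reward minus the rewards
actually collected:

    Regret = mu* - sum_t R_t = sum_t max_a P(R|a,t) - sum_t R_t

where P(R|a,t) is the true momentary probability along the *realized*
trajectory (trajectory mode, the default).  An alternative baseline
replaces mu* with the reward total of an independent Oracle run on the
same schedule (oracle_run mode).

Parameter optimization in simulated environments follows a two-stage
sampling scheme: score uniform draws by mean regret over a few fresh
sessions, keep the lowest-regret 5%, redraw Gaussian proposals spread
three standard deviations around them, keep the lowest 10%, and
re-test each survivor many times before returning the draw with the
lowest mean regret.  Every draw is evaluated under different reward
randomness (per-draw seeds fan out from the master seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._engine import batch_simulate
from .env import BlockSchedule, SessionRecord, alternating_schedule
from .regression import choice_decay_curve, reward_decay_curve

__all__ = [
    "RegretResult",
    "EnvOptimizationResult",
    "HARVEST_BOUNDS",
    "regret",
    "make_condition",
    "evaluate_policy",
    "optimize_in_env",
    "trace_shapes",
]

# Search space for regret optimization.  phi <= 0 and vartheta >= 0 are
# built into the bounds, so the constrained-DT sign contract holds for
# every draw the optimizer can return.
HARVEST_BOUNDS: dict[str, tuple[tuple[str, float, float], ...]] = {
    "dt": (
        ("alpha", 0.0, 1.0),
        ("beta", 0.0, 10.0),
        ("tau_f", 0.0, 1.0),
        ("tau_s", 0.0, 1.0),
        ("phi", -2.0, 0.0),
        ("vartheta", 0.0, 2.0),
    ),
    "fq": (("alpha", 0.0, 1.0), ("beta", 0.0, 10.0)),
    "fq_wc": (
        ("alpha", 0.0, 1.0),
        ("beta", 0.0, 10.0),
        ("tau_f", 0.0, 1.0),
        ("phi", -2.0, 0.0),
    ),
    "indirect": (("alpha", 0.0, 1.0), ("beta", 0.0, 10.0)),
    "direct": (("alpha", 0.0, 1.0), ("beta", 0.0, 10.0), ("c", -2.0, 2.0)),
    "lk": (("alpha", 0.0, 1.0), ("tau_psi", 0.0, 1.0), ("beta", 0.0, 10.0)),
}


@dataclass
class RegretResult:
    mu_star: float
    collected: float
    regret: float
    per_trial: np.ndarray
    baseline_mode: str = "trajectory"


@dataclass
class EnvOptimizationResult:
    model: str
    theta_star: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    mean_regret: float
    condition: str
    search_trace: list[float] = field(default_factory=list)


def regret(
    session: SessionRecord,
    mode: str = "trajectory",
    rng: np.random.Generator | None = None,
) -> RegretResult:
    """Regret of a recorded (simulated) session.

    Trajectory mode compares the collected rewards with the sum over
    trials of the maximal true momentary probability.  Oracle-run mode
    instead simulates an independent Oracle on the session's schedule
    (reconstructed from its set-probability trace) and uses that
    agent's reward total as mu*.
    """
    if session.true_p is None:
        raise ValueError("regret requires the true probability trace")
    collected_t = session.rewards.astype(float)
    if mode == "trajectory":
        mu_t = session.true_p.max(axis=1)
    elif mode == "oracle_run":
        if session.pset_trace is None:
            raise ValueError("oracle_run mode requires the set-probability trace")
        if rng is None:
            rng = np.random.default_rng()
        schedule = _schedule_from_trace(session)
        out = batch_simulate("oracle", np.zeros((1, 0)), schedule, rng)
        mu_t = np.full(len(session), out["collected"][0] / len(session))
    else:
        raise ValueError(f"unknown regret mode {mode!r}")
    per_trial = mu_t - collected_t
    return RegretResult(
        mu_star=float(mu_t.sum()),
        collected=float(collected_t.sum()),
        regret=float(per_trial.sum()),
        per_trial=per_trial,
        baseline_mode=mode,
    )


def _schedule_from_trace(session: SessionRecord) -> BlockSchedule:
    blocks = []
    ids = session.block_id
    for b in np.unique(ids):
        mask = ids == b
        blocks.append((int(mask.sum()), tuple(session.pset_trace[mask][0])))
    return BlockSchedule(tuple(blocks))


def make_condition(name: str, n_trials: int = 1000) -> tuple[str, BlockSchedule]:
    """Named environment conditions for regret benchmarking.

    ``volatility:<block>`` — blocks of the given length (50, 100 or
    500) alternating 0.10:0.40 / 0.40:0.10.
    ``delta:<p0>,<p1>`` — alternating blocks of 100 trials with the
    given pair; the probability pairs used in the benchmarks are
    {0.20:0.80, 0.30:0.70, 0.40:0.60} in one variant and {0.45:0.05,
    0.40:0.10, 0.35:0.15} in the other, both available here.
    """
    kind, _, arg = name.partition(":")
    if kind == "volatility":
        block = int(arg)
        return name, alternating_schedule((0.10, 0.40), block, n_trials)
    if kind == "delta":
        p0, p1 = (float(x) for x in arg.split(","))
        return name, alternating_schedule((p0, p1), 100, n_trials)
    raise ValueError(f"unknown condition {name!r}")


def _draw_seeds(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(2**31, size=n)


def evaluate_policy(
    model: str,
    theta: np.ndarray | None,
    schedule: BlockSchedule,
    n_sessions: int,
    rng: np.random.Generator,
) -> float:
    """Mean per-session regret of one parameter vector (or a policy-free agent)."""
    if model in ("oracle", "random"):
        theta_mat = np.zeros((n_sessions, 0))
    else:
        theta_mat = np.tile(np.asarray(theta, dtype=float), (n_sessions, 1))
    out = batch_simulate(model, theta_mat, schedule, rng)
    return float(out["regret"].mean())


def _score_draws(
    model: str,
    theta: np.ndarray,
    schedule: BlockSchedule,
    n_sessions: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Mean regret per draw over ``n_sessions`` independently seeded sessions."""
    n = theta.shape[0]
    stacked = np.repeat(theta, n_sessions, axis=0)
    out = batch_simulate(model, stacked, schedule, rng)
    return out["regret"].reshape(n, n_sessions).mean(axis=1)


def optimize_in_env(
    model: str,
    condition: str,
    rng: np.random.Generator | None = None,
    n_initial: int = 10_000,
    n_stage2: int = 5_000,
    n_eval_sessions: int = 4,
    n_trials: int = 1000,
    keep_frac1: float = 0.05,
    keep_frac2: float = 0.10,
    n_retest: int = 100,
) -> EnvOptimizationResult:
    """Two-stage regret-minimizing parameter search in a named condition.

    Stage 1 scores ``n_initial`` uniform draws by mean regret over
    ``n_eval_sessions`` sessions of ``n_trials`` with fresh reward
    randomness, keeping the lowest ``keep_frac1``.  Stage 2 redraws
    ``n_stage2`` Gaussian proposals spread three standard deviations
    around the survivors, keeps the lowest ``keep_frac2``, re-tests
    each survivor ``n_retest`` times and returns the draw with the
    lowest mean regret over those re-tests.
    """
    if model not in HARVEST_BOUNDS:
        raise ValueError(f"no harvesting bounds for model {model!r}")
    if rng is None:
        rng = np.random.default_rng()
    _, schedule = make_condition(condition, n_trials)
    spec = HARVEST_BOUNDS[model]
    lo = np.array([b[1] for b in spec])
    hi = np.array([b[2] for b in spec])

    theta1 = rng.uniform(lo, hi, size=(n_initial, len(spec)))
    scores1 = _score_draws(
        model, theta1, schedule, n_eval_sessions, np.random.default_rng(_draw_seeds(rng, 1)[0])
    )
    k1 = max(1, int(round(keep_frac1 * n_initial)))
    top1 = theta1[np.argsort(scores1)[:k1]]

    mu, sd = top1.mean(axis=0), top1.std(axis=0)
    theta2 = np.clip(rng.normal(mu, 3.0 * sd, size=(n_stage2, len(spec))), lo, hi)
    scores2 = _score_draws(
        model, theta2, schedule, n_eval_sessions, np.random.default_rng(_draw_seeds(rng, 1)[0])
    )
    k2 = max(1, int(round(keep_frac2 * n_stage2)))
    top2 = theta2[np.argsort(scores2)[:k2]]

    retest = _score_draws(
        model, top2, schedule, n_retest, np.random.default_rng(_draw_seeds(rng, 1)[0])
    )
    best = int(np.argmin(retest))
    trace = [float(scores1.min()), float(scores2.min()), float(retest[best])]
    names = [b[0] for b in spec]
    return EnvOptimizationResult(
        model=model,
        theta_star={n: float(v) for n, v in zip(names, top2[best])},
        bounds={n: (float(l), float(h)) for n, l, h in spec},
        mean_regret=float(retest[best]),
        condition=condition,
        search_trace=trace,
    )


def trace_shapes(
    params: dict[str, float], M: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Implied reward and choice coefficient curves of a DT parameter set.

    Returns (b_R, b_C) over lags m = 1..M with
    b_R,m = alpha (1-alpha)^(m-1) and
    b_C,m = phi (1-tau_f) tau_f^(m-1) + vartheta (1-tau_s) tau_s^(m-1).
    """
    b_r = reward_decay_curve(params["alpha"], M)
    b_c = choice_decay_curve(
        params["phi"], params["tau_f"], params["vartheta"], params["tau_s"], M
    )
    return b_r, b_c
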