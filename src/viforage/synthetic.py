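"""Ground-truth dataset generation for parameter recovery and edge fixtures.

The recovery protocol mirrors the simulation study conditions: the DT
model is run closed-loop on schedules of 100-trial blocks alternating
set probabilities 0.1:0.4 and 0.4:0.1, 1000 trials per session, with
the true parameters recorded in a JSON-serializable manifest.  One
master seed fans out deterministically to every session so any fixture
is reproducible from a single integer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .agents import DTAgent, run_session
from .env import BlockSchedule, SessionRecord, TaskConfig, alternating_schedule

__all__ = [
    "RECOVERY_BOUNDS",
    "RecoverySpec",
    "generate_recovery_dataset",
    "random_true_params",
    "edge_fixtures",
]

# Ranges the recovery study draws true DT parameters from: learning
# rates over their full range, moderate inverse temperature, fast-trace
# scaling negative (alternation), slow-trace scaling positive
# (perseverance).
RECOVERY_BOUNDS: dict[str, tuple[float, float]] = {
    "alpha": (0.0, 1.0),
    "tau_f": (0.0, 1.0),
    "tau_s": (0.0, 1.0),
    "beta": (0.0, 4.0),
    "vartheta": (0.0, 4.0),
    "phi": (-4.0, 0.0),
}

# Best-fit DT parameters for mouse behavior, used as a realistic
# generating parameter set.
MOUSE_DT_PARAMS: dict[str, float] = {
    "alpha": 0.75,
    "beta": 1.60,
    "tau_f": 0.71,
    "tau_s": 0.24,
    "vartheta": 3.31,
    "phi": -2.22,
}

HUMAN_DT_PARAMS: dict[str, float] = {
    "alpha": 0.73,
    "beta": 2.62,
    "tau_f": 0.56,
    "tau_s": 0.40,
    "vartheta": 1.97,
    "phi": -2.10,
}


def recovery_schedule(n_trials: int = 1000, block_length: int = 100) -> BlockSchedule:
    """100-trial blocks alternating 0.1:0.4 and 0.4:0.1."""
    return alternating_schedule((0.1, 0.4), block_length, n_trials)


@dataclass
class RecoverySpec:
    true_params: dict[str, float]
    n_runs: int = 1
    trials_per_session: int = 1000
    schedule: BlockSchedule | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.schedule is None:
            self.schedule = recovery_schedule(self.trials_per_session)


def generate_recovery_dataset(
    spec: RecoverySpec,
) -> tuple[list[SessionRecord], dict]:
    """Closed-loop DT simulations plus a ground-truth manifest.

    The manifest records the true parameters, the per-session seeds,
    and flags the ``tau_f == tau_s`` degeneracy (identical fast and
    slow traces make phi and vartheta unidentifiable apart from their
    sum).
    """
    master = np.random.default_rng(spec.seed)
    session_seeds = master.integers(2**31, size=max(spec.n_runs, 1))[: spec.n_runs]
    sessions = []
    for s in session_seeds:
        rng = np.random.default_rng(int(s))
        agent = DTAgent(**spec.true_params)
        config = TaskConfig(schedule=spec.schedule, seed=int(s))
        sessions.append(run_session(agent, config, rng))
    manifest = {
        "schema_version": 1,
        "model": "dt",
        "true_params": dict(spec.true_params),
        "n_runs": spec.n_runs,
        "trials_per_session": spec.trials_per_session,
        "master_seed": spec.seed,
        "session_seeds": [int(s) for s in session_seeds],
        "degenerate_traces": bool(
            np.isclose(spec.true_params["tau_f"], spec.true_params["tau_s"])
        ),
    }
    return sessions, manifest


def random_true_params(
    bounds: dict[str, tuple[float, float]],
    n: int,
    rng: np.random.Generator,
) -> list[dict[str, float]]:
    """Uniform parameter draws within per-parameter bounds."""
    for name, (lo, hi) in bounds.items():
        if lo > hi:
            raise ValueError(f"inverted bounds for {name}: [{lo}, {hi}]")
    return [
        {name: float(rng.uniform(lo, hi)) for name, (lo, hi) in bounds.items()}
        for _ in range(n)
    ]


def _fixture(choices, rewards, pset=(0.4, 0.1)) -> SessionRecord:
    choices = np.asarray(choices, dtype=int)
    rewards = np.asarray(rewards, dtype=int)
    n = len(choices)
    return SessionRecord(
        choices=choices,
        rewards=rewards,
        block_id=np.zeros(n, dtype=int),
        pset_trace=np.tile(np.asarray(pset, dtype=float), (n, 1)),
        meta={"synthetic": True},
    )


def edge_fixtures() -> dict[str, SessionRecord]:
    """Deterministic degenerate sessions used across module tests.

    ``all_left``          60 trials, option 0 only (single-class response).
    ``strict_alternation`` 200 trials of 0,1,0,1,...
    ``single_trial``      one trial.
    ``shorter_than_lags`` 5 trials (shorter than common lag counts).
    ``all_rewarded``      every trial rewarded.
    """
    rng = np.random.default_rng(12345)  # fixed content: fixtures are constants
    alt = np.arange(200) % 2
    return {
        "all_left": _fixture(np.zeros(60), rng.integers(0, 2, 60)),
        "strict_alternation": _fixture(alt, rng.integers(0, 2, 200)),
        "single_trial": _fixture([1], [1]),
        "shorter_than_lags": _fixture([0, 1, 1, 0, 1], [1, 0, 1, 0, 0]),
        "all_rewarded": _fixture(rng.integers(0, 2, 120), np.ones(120)),
    }
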