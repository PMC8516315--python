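"""Discrete variable-interval (VI, "baiting") environment.

Each of two (or more) options carries a *set* reward probability
``pset``.  On every trial a reward is (conceptually) baited onto an
option with probability ``pset`` and, once baited, persists until the
option is chosen.  The momentary probability that a choice of option
``i`` is rewarded therefore grows with the number of trials since
``i`` was last chosen:

    p[i] <- 1 - (1 - pset[i]) * (1 - p[i] * (1 - delta_i))

where ``delta_i`` is 1 when option ``i`` was just chosen.  Under a
constant ``pset`` this recursion has the closed form
``1 - (1 - pset)**(ti + 1)`` with ``ti`` the number of completed
trials since the option was last chosen.

Set probabilities change only at block transitions; the accumulated
probability of unchosen options carries over across a transition and
continues to grow under the new set probability.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BlockSchedule",
    "TaskConfig",
    "EnvState",
    "SessionRecord",
    "init_env",
    "step",
    "closed_form_probability",
    "make_schedule",
]

MOUSE_PAIRS = ((0.25, 0.25), (0.40, 0.10), (0.10, 0.40))
HUMAN_PAIRS = ((0.40, 0.10), (0.10, 0.40))


@dataclass(frozen=True)
class BlockSchedule:
    """Ordered blocks of (length, per-option set reward probabilities)."""

    blocks: tuple[tuple[int, tuple[float, ...]], ...]

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("schedule must contain at least one block")
        for length, pset in self.blocks:
            if length < 1:
                raise ValueError(f"block length must be >= 1, got {length}")
            for p in pset:
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"set probability {p} outside [0, 1]")

    @property
    def n_trials(self) -> int:
        return sum(length for length, _ in self.blocks)

    @property
    def n_options(self) -> int:
        return len(self.blocks[0][1])

    def pset_per_trial(self) -> np.ndarray:
        """(n_trials, n_options) array of the set probability governing each trial."""
        rows = []
        for length, pset in self.blocks:
            rows.append(np.tile(np.asarray(pset, dtype=float), (length, 1)))
        return np.concatenate(rows, axis=0)

    def block_per_trial(self) -> np.ndarray:
        return np.repeat(
            np.arange(len(self.blocks)), [length for length, _ in self.blocks]
        )


@dataclass(frozen=True)
class TaskConfig:
    schedule: BlockSchedule
    n_options: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_options < 2:
            raise ValueError("need at least two options")
        if self.schedule.n_options != self.n_options:
            raise ValueError(
                "schedule option count does not match n_options "
                f"({self.schedule.n_options} != {self.n_options})"
            )

    @property
    def n_trials(self) -> int:
        return self.schedule.n_trials


@dataclass
class EnvState:
    """Live environment state.

    ``p`` is the momentary per-option reward probability, ``pset`` the
    set probability of the current block, ``t`` the 1-based index of
    the upcoming trial, and ``ti`` the per-option count of completed
    trials since that option was last chosen.
    """

    p: np.ndarray
    pset: np.ndarray
    t: int
    ti: np.ndarray
    config: TaskConfig = field(repr=False)

    def copy(self) -> "EnvState":
        return EnvState(self.p.copy(), self.pset.copy(), self.t, self.ti.copy(), self.config)


@dataclass
class SessionRecord:
    """Universal behavioral trace: per-trial choice, reward and block id.

    Simulated sessions additionally carry the true momentary
    probabilities (``true_p``) and set probabilities (``pset_trace``),
    both (n_trials, n_options).
    """

    choices: np.ndarray
    rewards: np.ndarray
    block_id: np.ndarray
    true_p: np.ndarray | None = None
    pset_trace: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=int)
        self.rewards = np.asarray(self.rewards, dtype=int)
        self.block_id = np.asarray(self.block_id, dtype=int)
        n = len(self.choices)
        if len(self.rewards) != n or len(self.block_id) != n:
            raise ValueError("choices, rewards and block_id must have equal length")
        if not np.isin(self.rewards, (0, 1)).all():
            raise ValueError("rewards must be binary")
        for trace in (self.true_p, self.pset_trace):
            if trace is not None and len(trace) != n:
                raise ValueError("probability traces must match session length")

    def __len__(self) -> int:
        return len(self.choices)

    @property
    def n_options(self) -> int:
        if self.pset_trace is not None:
            return self.pset_trace.shape[1]
        return int(self.choices.max(initial=1)) + 1

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path: str | Path) -> None:
        """Write ``trial,choice,reward,block,pset_0,pset_1[,p_0,p_1]`` plus a JSON sidecar."""
        path = Path(path)
        n = len(self)
        data: dict[str, np.ndarray] = {
            "trial": np.arange(1, n + 1),
            "choice": self.choices,
            "reward": self.rewards,
            "block": self.block_id,
        }
        if self.pset_trace is not None:
            for i in range(self.pset_trace.shape[1]):
                data[f"pset_{i}"] = self.pset_trace[:, i]
        if self.true_p is not None:
            for i in range(self.true_p.shape[1]):
                data[f"p_{i}"] = self.true_p[:, i]
        pd.DataFrame(data).to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps({"schema_version": 1, **_jsonable(self.meta)}, indent=2))

    @classmethod
    def from_csv(cls, path: str | Path) -> "SessionRecord":
        path = Path(path)
        df = pd.read_csv(path)
        pset_cols = sorted(c for c in df.columns if c.startswith("pset_"))
        p_cols = sorted(c for c in df.columns if c.startswith("p_") and not c.startswith("pset_"))
        meta: dict = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            meta.pop("schema_version", None)
        return cls(
            choices=df["choice"].to_numpy(),
            rewards=df["reward"].to_numpy(),
            block_id=df["block"].to_numpy(),
            pset_trace=df[pset_cols].to_numpy() if pset_cols else None,
            true_p=df[p_cols].to_numpy() if p_cols else None,
            meta=meta,
        )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


# -------------------------------------------------------------- operations

def closed_form_probability(pset: float, ti: int) -> float:
    """Momentary reward probability after ``ti`` unchosen trials under constant ``pset``.

    Equals ``1 - (1 - pset)**(ti + 1)``; ``ti = 0`` means the option
    was chosen on the previous trial, so the probability is ``pset``.
    """
    if not 0.0 <= pset <= 1.0:
        raise ValueError(f"pset {pset} outside [0, 1]")
    if ti < 0:
        raise ValueError("ti must be non-negative")
    return 1.0 - (1.0 - pset) ** (ti + 1)


def init_env(config: TaskConfig) -> EnvState:
    """Initial state: momentary probabilities start at the first block's set probabilities."""
    pset0 = np.asarray(config.schedule.blocks[0][1], dtype=float)
    return EnvState(
        p=pset0.copy(),
        pset=pset0.copy(),
        t=1,
        ti=np.zeros(config.n_options, dtype=int),
        config=config,
    )


def _pset_for_trial(schedule: BlockSchedule, t: int) -> np.ndarray:
    """Set probabilities governing trial ``t`` (trials past the end keep the last block's)."""
    remaining = t
    for length, pset in schedule.blocks:
        if remaining <= length:
            return np.asarray(pset, dtype=float)
        remaining -= length
    return np.asarray(schedule.blocks[-1][1], dtype=float)


def step(
    state: EnvState, choice: int, rng: np.random.Generator
) -> tuple[int, EnvState]:
    """Realize one trial: draw the reward, then advance the baiting dynamics.

    The reward is a Bernoulli draw on the chosen option's momentary
    probability.  Afterwards the chosen option resets to the (possibly
    new block's) set probability, while every unchosen option
    accumulates under the new set probability.
    """
    n = state.config.n_options
    if not 0 <= choice < n:
        raise ValueError(f"choice {choice} out of range for {n} options")
    reward = int(rng.random() < state.p[choice])

    pset_next = _pset_for_trial(state.config.schedule, state.t + 1)
    p_next = 1.0 - (1.0 - pset_next) * (1.0 - state.p)
    p_next[choice] = pset_next[choice]
    ti_next = state.ti + 1
    ti_next[choice] = 0
    next_state = EnvState(
        p=p_next, pset=pset_next, t=state.t + 1, ti=ti_next, config=state.config
    )
    return reward, next_state


def make_schedule(
    protocol: str,
    rng: np.random.Generator | None = None,
    *,
    n_trials: int = 1000,
    n_blocks: int | None = None,
    blocks: Sequence[tuple[int, tuple[float, float]]] | None = None,
) -> BlockSchedule:
    """Build a block schedule for a named protocol.

    Protocols
    ---------
    ``oracle-uniform``
        A single block of ``n_trials`` with each option's set
        probability drawn independently from U[0, 0.5].
    ``mouse-like``
        9 blocks (override with ``n_blocks``) of U{50..150} trials,
        each block's pair drawn from {0.25:0.25, 0.40:0.10, 0.10:0.40}.
    ``human-like``
        6 blocks (override with ``n_blocks``) of U{20..30} trials,
        pairs from {0.40:0.10, 0.10:0.40}.
    ``fixed``
        Echo the explicit ``blocks`` specification.
    """
    if protocol == "fixed":
        if blocks is None:
            raise ValueError("protocol 'fixed' requires an explicit blocks list")
        return BlockSchedule(tuple((int(l), tuple(p)) for l, p in blocks))

    if rng is None:
        raise ValueError(f"protocol {protocol!r} requires an rng")
    if protocol == "oracle-uniform":
        pset = tuple(rng.uniform(0.0, 0.5, size=2))
        return BlockSchedule(((n_trials, pset),))
    if protocol == "mouse-like":
        nb = 9 if n_blocks is None else n_blocks
        out = []
        for _ in range(nb):
            length = int(rng.integers(50, 151))
            pair = MOUSE_PAIRS[rng.integers(len(MOUSE_PAIRS))]
            out.append((length, pair))
        return BlockSchedule(tuple(out))
    if protocol == "human-like":
        nb = 6 if n_blocks is None else n_blocks
        out = []
        for _ in range(nb):
            length = int(rng.integers(20, 31))
            pair = HUMAN_PAIRS[rng.integers(len(HUMAN_PAIRS))]
            out.append((length, pair))
        return BlockSchedule(tuple(out))
    raise ValueError(f"unknown protocol {protocol!r}")


def task_config_from_file(path: str | Path) -> TaskConfig:
    """Load a TaskConfig from its YAML/JSON mirror.

    Expected keys: ``blocks`` (list of ``[length, [p0, p1]]``),
    optional ``n_options`` (default 2) and ``seed``.
    """
    import yaml

    text = Path(path).read_text()
    data = yaml.safe_load(text)  # YAML is a superset of JSON
    if not isinstance(data, dict) or "blocks" not in data:
        raise ValueError(f"config {path} must be a mapping with a 'blocks' key")
    schedule = BlockSchedule(
        tuple((int(length), tuple(float(p) for p in pset)) for length, pset in data["blocks"])
    )
    return TaskConfig(
        schedule=schedule,
        n_options=int(data.get("n_options", 2)),
        seed=data.get("seed"),
    )


def task_config_to_file(config: TaskConfig, path: str | Path) -> None:
    """Write the YAML/JSON mirror of a TaskConfig."""
    import yaml

    data = {
        "n_options": config.n_options,
        "seed": config.seed,
        "blocks": [[length, list(pset)] for length, pset in config.schedule.blocks],
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def alternating_schedule(
    pair: tuple[float, float], block_length: int, n_trials: int = 1000
) -> BlockSchedule:
    """Blocks of ``block_length`` alternating between ``pair`` and its mirror."""
    blocks = []
    total = 0
    flip = False
    while total < n_trials:
        length = min(block_length, n_trials - total)
        pset = (pair[1], pair[0]) if flip else pair
        blocks.append((length, pset))
        total += length
        flip = not flip
    return BlockSchedule(tuple(blocks))
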