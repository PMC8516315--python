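"""Lagged choice/reward-history logistic regression with an elastic net.

The influence of past rewards and past choices on the upcoming choice
is summarized by the coefficients of a penalized logistic regression.
For each usable trial t the predictors are the signed reward history
R(t-1..t-M), with R = R_right - R_left in {-1, 0, +1}, and the choice
history C(t-1..t-M) in {0, 1}; the response is the current choice
C(t) (1 = right).  The penalty is the fixed-mixing elastic net
lambda * sum_j (0.25 b_j^2 + 0.5 |b_j|), i.e. an equal L1/L2 blend,
with lambda picked at the minimum mean held-out binomial deviance in
a five-fold cross-validation and the final coefficients refit on all
rows at the selected lambda.

An extended variant decomposes the reward history into six named
blocks (unsigned rewards, choices, right rewards, left rewards, right
no-rewards, left no-rewards) to separate reward- from no-reward-driven
history effects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.linear_model import LogisticRegression

from .env import SessionRecord

__all__ = [
    "LagDesign",
    "RegressionFit",
    "DecayFit",
    "build_design",
    "build_extended_design",
    "fit_elastic_net",
    "fit_decay_model",
    "condition_correlation",
    "default_lambda_grid",
]

BASIC_BLOCKS = ("reward", "choice")
EXTENDED_BLOCKS = (
    "unsigned_reward",
    "choice",
    "reward_right",
    "reward_left",
    "noreward_right",
    "noreward_left",
)


@dataclass
class LagDesign:
    """Trial-by-regressor design matrix of lagged history predictors."""

    X: np.ndarray
    y: np.ndarray
    M: int
    regressor_blocks: tuple[str, ...]
    session_index: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.y):
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != self.M * len(self.regressor_blocks):
            raise ValueError("column count does not match M * number of blocks")

    def block(self, name: str) -> np.ndarray:
        i = self.regressor_blocks.index(name)
        return self.X[:, i * self.M : (i + 1) * self.M]


@dataclass
class RegressionFit:
    b_reward: np.ndarray
    b_choice: np.ndarray
    intercept: float
    lam: float
    lambda_grid: np.ndarray
    cv_deviance: np.ndarray
    M: int
    extra_blocks: dict[str, np.ndarray] = field(default_factory=dict)

    def coefficients(self, name: str) -> np.ndarray:
        if name == "reward":
            return self.b_reward
        if name == "choice":
            return self.b_choice
        return self.extra_blocks[name]


def _lag_columns(x: np.ndarray, M: int) -> np.ndarray:
    """Rows t = M..T-1 (0-based) with columns [x(t-1), ..., x(t-M)]."""
    T = len(x)
    return np.column_stack([x[M - m : T - m] for m in range(1, M + 1)])


def _per_trial_vectors(sess: SessionRecord) -> dict[str, np.ndarray]:
    c = sess.choices.astype(float)
    r = sess.rewards.astype(float)
    r_right = r * c
    r_left = r * (1.0 - c)
    return {
        "reward": r_right - r_left,
        "choice": c,
        "unsigned_reward": r_right + r_left,
        "reward_right": r_right,
        "reward_left": r_left,
        "noreward_right": (1.0 - r) * c,
        "noreward_left": (1.0 - r) * (1.0 - c),
    }


def _build(sessions: list[SessionRecord], M: int, blocks: tuple[str, ...]) -> LagDesign:
    if M < 1:
        raise ValueError("lag count M must be >= 1")
    xs, ys, idx = [], [], []
    for k, sess in enumerate(sessions):
        if len(sess) <= M:
            warnings.warn(
                f"session {k} has {len(sess)} trials <= M={M}; skipped", RuntimeWarning
            )
            continue
        vecs = _per_trial_vectors(sess)
        cols = [_lag_columns(vecs[name], M) for name in blocks]
        xs.append(np.concatenate(cols, axis=1))
        ys.append(sess.choices[M:].astype(float))
        idx.append(np.full(len(sess) - M, k))
    if not xs:
        raise ValueError("no session is longer than the lag count M")
    return LagDesign(
        X=np.concatenate(xs, axis=0),
        y=np.concatenate(ys),
        M=M,
        regressor_blocks=blocks,
        session_index=np.concatenate(idx),
    )


def build_design(sessions: list[SessionRecord], M: int = 15) -> LagDesign:
    """Basic design: M signed-reward lags then M choice lags per usable trial.

    The first M trials of every session are excluded, so no row mixes
    lags across a session boundary.
    """
    return _build(sessions, M, BASIC_BLOCKS)


def build_extended_design(sessions: list[SessionRecord], M: int = 30) -> LagDesign:
    """Extended design with six regressor blocks.

    Block order: unsigned rewards, choices, right rewards, left
    rewards, right no-rewards, left no-rewards.  For every trial
    exactly one of {reward_right, reward_left, noreward_right,
    noreward_left} is 1.
    """
    return _build(sessions, M, EXTENDED_BLOCKS)


def default_lambda_grid() -> np.ndarray:
    return np.logspace(-4, 1, 50)


def _binomial_deviance(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _contiguous_folds(n: int, folds: int, rng: np.random.Generator | None) -> np.ndarray:
    """Fold labels as contiguous row blocks, rotated by a seeded offset.

    Contiguous blocks (rather than shuffled trials) limit leakage from
    the serial correlation of behavioral data.
    """
    offset = int(rng.integers(n)) if rng is not None else 0
    edges = np.linspace(0, n, folds + 1).astype(int)
    labels = np.empty(n, dtype=int)
    for k in range(folds):
        labels[edges[k] : edges[k + 1]] = k
    return np.roll(labels, offset)


def _fit_at_lambda(
    X: np.ndarray, y: np.ndarray, lam: float, coef0=None, intercept0=None
) -> LogisticRegression:
    # C = 1/(n*lam) maps sklearn's objective onto mean deviance + lam * penalty
    # with the fixed 0.25*L2 + 0.5*L1 mixing (l1_ratio = 0.5).
    model = LogisticRegression(
        penalty="elasticnet",
        solver="saga",
        l1_ratio=0.5,
        C=1.0 / (len(y) * lam),
        max_iter=2000,
        tol=1e-5,
        warm_start=True,
    )
    if coef0 is not None:
        model.coef_ = coef0.copy()
        model.intercept_ = intercept0.copy()
        model.classes_ = np.array([0.0, 1.0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, y)
    return model


def fit_elastic_net(
    design: LagDesign,
    lambda_grid: np.ndarray | None = None,
    folds: int = 5,
    rng: np.random.Generator | None = None,
) -> RegressionFit:
    """Cross-validated elastic-net logistic regression on a lag design.

    The intercept is never penalized.  Raises if the response contains
    a single class (e.g. an all-left session set).
    """
    y = design.y
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"response contains a single class ({classes.tolist()}); "
            "the regression is undefined for these sessions"
        )
    grid = default_lambda_grid() if lambda_grid is None else np.asarray(lambda_grid, float)
    order = np.argsort(grid)[::-1]  # descending lambda for warm starts
    labels = _contiguous_folds(len(y), folds, rng)

    cv_dev = np.zeros(len(grid))
    for k in range(folds):
        train, test = labels != k, labels == k
        coef0 = intercept0 = None
        for j in order:
            model = _fit_at_lambda(design.X[train], y[train], grid[j], coef0, intercept0)
            coef0, intercept0 = model.coef_, model.intercept_
            p = model.predict_proba(design.X[test])[:, 1]
            cv_dev[j] += _binomial_deviance(y[test], p) / folds

    best = int(np.argmin(cv_dev))
    final = _fit_at_lambda(design.X, y, grid[best])
    coefs = final.coef_.ravel()
    M = design.M
    blocks = {
        name: coefs[i * M : (i + 1) * M] for i, name in enumerate(design.regressor_blocks)
    }
    b_reward = blocks.pop("reward", blocks.get("unsigned_reward", np.zeros(M)))
    b_choice = blocks.pop("choice")
    return RegressionFit(
        b_reward=b_reward,
        b_choice=b_choice,
        intercept=float(final.intercept_[0]),
        lam=float(grid[best]),
        lambda_grid=grid,
        cv_deviance=cv_dev,
        M=M,
        extra_blocks=blocks,
    )


@dataclass
class DecayFit:
    """Exponential-decay parameterization of fitted lag coefficients."""

    alpha: float
    tau_f: float
    tau_s: float
    phi: float
    vartheta: float
    degenerate: bool = False


def reward_decay_curve(alpha: float, M: int) -> np.ndarray:
    """b_R,m = alpha * (1 - alpha)^(m-1), m = 1..M."""
    m = np.arange(1, M + 1)
    return alpha * (1.0 - alpha) ** (m - 1)


def choice_decay_curve(
    phi: float, tau_f: float, vartheta: float, tau_s: float, M: int
) -> np.ndarray:
    """b_C,m = phi (1-tau_f) tau_f^(m-1) + vartheta (1-tau_s) tau_s^(m-1)."""
    m = np.arange(1, M + 1)
    return phi * (1.0 - tau_f) * tau_f ** (m - 1) + vartheta * (1.0 - tau_s) * tau_s ** (
        m - 1
    )


def fit_decay_model(fit: RegressionFit) -> DecayFit:
    """Least-squares exponential-decay fit to the lagged coefficients.

    The reward coefficients are fit by a single exponential in the
    learning rate alpha; the choice coefficients by the sum of two
    scaled exponentials (fast and slow).  A flat, all-zero choice
    curve is unidentifiable and returned as a flagged degenerate fit.
    The two choice components are ordered so that tau_f >= tau_s.
    """
    b_r, b_c = np.asarray(fit.b_reward, float), np.asarray(fit.b_choice, float)
    if not (np.isfinite(b_r).all() and np.isfinite(b_c).all()):
        raise ValueError("non-finite regression coefficients")
    if len(b_r) < 5 or len(b_c) < 5:
        raise ValueError("need at least 5 lags to fit the decay model")
    M = len(b_r)

    res = optimize.minimize_scalar(
        lambda a: np.sum((reward_decay_curve(a, M) - b_r) ** 2),
        bounds=(0.0, 1.0),
        method="bounded",
    )
    alpha = float(res.x)

    if np.max(np.abs(b_c)) < 1e-12:
        return DecayFit(alpha=alpha, tau_f=0.0, tau_s=0.0, phi=0.0, vartheta=0.0,
                        degenerate=True)

    def residual(theta):
        phi, tf, vth, ts = theta
        return choice_decay_curve(phi, tf, vth, ts, M) - b_c

    scale = float(np.max(np.abs(b_c))) * 4.0
    best, best_cost = None, np.inf
    taus = (0.05, 0.2, 0.4, 0.6, 0.8, 0.95)
    for tf0 in taus:
        for ts0 in taus:
            sol = optimize.least_squares(
                residual,
                x0=[-scale / 2, tf0, scale / 2, ts0],
                bounds=([-np.inf, 0.0, -np.inf, 0.0], [np.inf, 1.0, np.inf, 1.0]),
                xtol=1e-14, ftol=1e-14, gtol=1e-14,
            )
            if sol.cost < best_cost:
                best, best_cost = sol.x, sol.cost
    phi, tau_f, vartheta, tau_s = map(float, best)
    if tau_f < tau_s:  # canonical ordering of the two components
        phi, tau_f, vartheta, tau_s = vartheta, tau_s, phi, tau_f
    return DecayFit(alpha=alpha, tau_f=tau_f, tau_s=tau_s, phi=phi, vartheta=vartheta)


def condition_correlation(
    per_session_fits: list[RegressionFit],
    covariate: np.ndarray,
    which: str = "choice",
) -> tuple[float, float, np.ndarray]:
    """Pearson correlation of lag-1 coefficients with a per-session covariate.

    Returns (r, p, tercile means of the lag-1 coefficient with sessions
    sorted by the covariate) — the session-sorting analysis used to ask
    whether volatility, set-probability difference, or reward rate
    drives the history effects.
    """
    if len(per_session_fits) < 3:
        raise ValueError("need at least 3 sessions")
    cov = np.asarray(covariate, dtype=float)
    if len(cov) != len(per_session_fits):
        raise ValueError("one covariate value per session required")
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant; correlation undefined")
    lag1 = np.array([f.coefficients(which)[0] for f in per_session_fits])
    r, p = stats.pearsonr(cov, lag1)
    order = np.argsort(cov)
    terciles = np.array([g.mean() for g in np.array_split(lag1[order], 3)])
    return float(r), float(p), terciles
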