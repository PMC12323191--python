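"""Gaussian-process Bayesian optimization of a black-box training objective.

The surrogate is a GP with a squared-exponential ARD kernel and an
observation-noise term, maintained on the unit cube; integer and categorical
dimensions are handled by continuous relaxation plus rounding.  The
acquisition is expected improvement (minimization), maximized over seeded
quasi-random candidate draws.  Everything is deterministic given the seed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, qmc

logger = logging.getLogger(__name__)

__all__ = [
    "Real",
    "Integer",
    "Categorical",
    "SearchSpace",
    "BOState",
    "gp_posterior",
    "expected_improvement",
    "optimize",
]


@dataclass(frozen=True)
class Real:
    name: str
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not (np.isfinite(self.low) and np.isfinite(self.high) and self.low < self.high):
            raise ValueError(f"{self.name}: bounds must be finite with low < high")
        if self.log and self.low <= 0:
            raise ValueError(f"{self.name}: log scale requires positive bounds")

    def from_unit(self, u: float) -> float:
        if self.log:
            return float(np.exp(np.log(self.low) + u * (np.log(self.high) - np.log(self.low))))
        return float(self.low + u * (self.high - self.low))


@dataclass(frozen=True)
class Integer:
    name: str
    low: int
    high: int

    def __post_init__(self):
        if self.low >= self.high:
            raise ValueError(f"{self.name}: bounds must satisfy low < high")

    def from_unit(self, u: float) -> int:
        return int(np.clip(round(self.low + u * (self.high - self.low)), self.low, self.high))

    @property
    def choices(self):
        return list(range(self.low, self.high + 1))


@dataclass(frozen=True)
class Categorical:
    name: str
    choices: tuple

    def __post_init__(self):
        if len(self.choices) == 0:
            raise ValueError(f"{self.name}: choices must be non-empty")

    def from_unit(self, u: float) -> object:
        idx = min(int(u * len(self.choices)), len(self.choices) - 1)
        return self.choices[idx]


@dataclass(frozen=True)
class SearchSpace:
    """Named, typed hyperparameter dimensions."""

    dimensions: tuple

    @property
    def names(self):
        return [d.name for d in self.dimensions]

    def from_unit(self, u: np.ndarray) -> dict:
        return {d.name: d.from_unit(float(ui)) for d, ui in zip(self.dimensions, u)}

    def finite_grid(self):
        """All points if every dimension is discrete, else None."""
        axes = []
        for d in self.dimensions:
            if isinstance(d, Categorical):
                axes.append(list(d.choices))
            elif isinstance(d, Integer):
                axes.append(d.choices)
            else:
                return None
        return [dict(zip(self.names, combo)) for combo in itertools.product(*axes)]


@dataclass
class BOState:
    """Observation history and GP surrogate configuration.

    X_unit holds the unit-cube coordinates of evaluated points, y their
    objective values; length_scale / amplitude / noise parameterize the
    squared-exponential kernel.  The incumbent is the running minimum.
    """

    X_unit: list = field(default_factory=list)
    y: list = field(default_factory=list)
    points: list = field(default_factory=list)
    failed: list = field(default_factory=list)
    length_scale: float | np.ndarray = 0.25
    amplitude: float = 1.0
    noise: float = 1e-6
    seed: int = 0

    @property
    def incumbent(self):
        if not self.y:
            return None
        i = int(np.argmin(self.y))
        return self.points[i], float(self.y[i])

    def record(self, u, point, value):
        self.X_unit.append(np.asarray(u, float))
        self.points.append(point)
        self.y.append(float(value))


def _se_kernel(A, B, length_scale, amplitude):
    A = np.atleast_2d(A) / length_scale
    B = np.atleast_2d(B) / length_scale
    d2 = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * A @ B.T
    )
    return amplitude * np.exp(-0.5 * np.maximum(d2, 0.0))


def gp_posterior(state: BOState, query: np.ndarray):
    """Predictive mean and variance of the GP at unit-cube query points.

    With zero observations returns the prior (mean 0, variance = amplitude).
    Ill-conditioned covariances get jitter (logged); variance is clipped at 0.
    """
    Q = np.atleast_2d(np.asarray(query, float))
    if not state.y:
        return np.zeros(Q.shape[0]), np.full(Q.shape[0], state.amplitude)
    X = np.vstack(state.X_unit)
    y = np.asarray(state.y, float)
    y_mean = y.mean()
    K = _se_kernel(X, X, state.length_scale, state.amplitude)
    K[np.diag_indices_from(K)] += state.noise
    for attempt in range(4):
        try:
            L = np.linalg.cholesky(K)
            break
        except np.linalg.LinAlgError:
            jit = state.amplitude * 10.0 ** (-8 + 2 * attempt)
            logger.warning("GP covariance ill-conditioned; jitter %.1e", jit)
            K[np.diag_indices_from(K)] += jit
    else:
        raise np.linalg.LinAlgError("GP covariance not positive definite after jitter")
    Ks = _se_kernel(Q, X, state.length_scale, state.amplitude)
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, y - y_mean))
    mean = Ks @ alpha + y_mean
    v = np.linalg.solve(L, Ks.T)
    var = state.amplitude - np.sum(v**2, axis=0)
    return mean, np.maximum(var, 0.0)


def expected_improvement(state: BOState, query: np.ndarray) -> np.ndarray:
    """EI(x) = E[max(0, y_best - Y(x))] under the GP posterior (minimization)."""
    inc = state.incumbent
    if inc is None:
        raise ValueError("expected_improvement requires at least one observation")
    y_best = inc[1]
    mean, var = gp_posterior(state, query)
    sigma = np.sqrt(var)
    imp = y_best - mean
    ei = np.where(sigma > 0, 0.0, np.maximum(imp, 0.0))
    pos = sigma > 0
    if np.any(pos):
        z = imp[pos] / sigma[pos]
        ei = ei.astype(float)
        ei[pos] = imp[pos] * norm.cdf(z) + sigma[pos] * norm.pdf(z)
    return np.maximum(ei, 0.0)


@dataclass(frozen=True)
class OptimizeResult:
    best_point: dict
    best_value: float
    state: BOState


def optimize(
    objective,
    space: SearchSpace,
    budget: int = 25,
    n_init: int = 5,
    seed: int = 0,
    n_candidates: int = 256,
) -> OptimizeResult:
    """Minimize a black-box objective over the search space.

    n_init seeded quasi-random (Sobol) evaluations, then budget - n_init
    rounds of fit-posterior -> maximize EI over candidate draws -> evaluate.
    A purely discrete space no larger than the budget is searched
    exhaustively.  Failed evaluations are logged and excluded from the
    surrogate.  The incumbent trajectory is non-increasing by construction.
    """
    if not budget >= n_init >= 1:
        raise ValueError("require budget >= n_init >= 1")
    ndim = len(space.dimensions)
    state = BOState(seed=seed)
    grid = space.finite_grid()
    rng = np.random.default_rng(seed)

    def evaluate(u, point):
        try:
            val = float(objective(point))
        except Exception as exc:  # noqa: BLE001 - failed points are data
            logger.warning("objective failed at %s: %s", point, exc)
            state.failed.append((point, str(exc)))
            return
        state.record(u, point, val)

    if grid is not None and len(grid) <= budget:
        for point in grid:
            evaluate(np.full(ndim, 0.5), point)
    else:
        sobol = qmc.Sobol(ndim, scramble=True, seed=seed)
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.filterwarnings("ignore", message=".*balance properties.*")
            init = sobol.random(n_init)
        for u in init:
            evaluate(u, space.from_unit(u))
        while len(state.y) + len(state.failed) < budget:
            if state.y:
                yarr = np.asarray(state.y, float)
                state.amplitude = float(np.var(yarr)) or 1.0
                cand = rng.random((n_candidates, ndim))
                ei = expected_improvement(state, cand)
                u = cand[int(np.argmax(ei))]
            else:
                u = rng.random(ndim)
            evaluate(u, space.from_unit(u))
    inc = state.incumbent
    if inc is None:
        raise RuntimeError("every objective evaluation failed")
    return OptimizeResult(best_point=inc[0], best_value=inc[1], state=state)


def default_search_space() -> SearchSpace:
    """Default hyperparameter space for the fusion model."""
    return SearchSpace(
        dimensions=(
            Real("C", 0.1, 100.0, log=True),
            Real("epsilon", 0.001, 0.5, log=True),
            Real("gamma", 1e-3, 1.0, log=True),
            Real("learning_rate", 1e-4, 1e-2, log=True),
            Real("structure_weight", 0.05, 1.0, log=True),
            Categorical("n_heads", (1, 2, 4)),
            Categorical("n_layers", (1, 2, 3)),
            Categorical("model_dim", (32, 64, 128)),
        )
    )
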