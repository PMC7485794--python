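"""Extreme learning machine regression and particle-swarm optimisation of it.

An ELM is a single-hidden-layer network whose input weights and hidden
biases are random and never trained; only the output weights are solved, by
least squares against the hidden-layer activations.  PSO-ELM replaces the
random input layer with one optimised by a particle swarm: each particle
encodes a full set of input weights and biases, its fitness is the RMSE of
the analytically refit ELM on a validation set, and the swarm follows the
standard inertia / cognitive / social velocity update.  A velocity-position
coefficient ``m`` scales the position step (``x <- x + m * v``), letting the
swarm move conservatively even with large velocities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "ElmModel",
    "PsoConfig",
    "PsoTrace",
    "elm_fit",
    "elm_predict",
    "pso_minimize",
    "pso_elm_fit",
    "inertia_at",
    "save_model",
    "load_model",
]

_ACTIVATIONS = {
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "tanh": np.tanh,
}


@dataclass
class ElmModel:
    """Random-hidden-layer regressor with analytically solved output weights."""

    input_weights: np.ndarray  # hidden x input
    hidden_biases: np.ndarray  # hidden
    output_weights: np.ndarray  # hidden
    activation: str = "sigmoid"

    @property
    def input_dim(self) -> int:
        return self.input_weights.shape[1]

    @property
    def hidden_count(self) -> int:
        return self.input_weights.shape[0]


@dataclass(frozen=True)
class PsoConfig:
    """Swarm hyperparameters.

    ``w_schedule`` is either a single inertia weight or a ``(start, end)``
    pair interpolated linearly across iterations (the conventional
    "0.9~0.3" decreasing schedule).  ``m`` scales the position update.
    """

    pop: int = 50
    w_schedule: float | tuple[float, float] = (0.9, 0.3)
    c1: float = 1.65
    c2: float = 2.8
    m: float = 0.2
    iterations: int = 100
    seed: int = 0
    bounds: tuple[float, float] = (-1.0, 1.0)
    v_max_frac: float = 0.5

    def __post_init__(self):
        if self.pop < 1:
            raise ConfigurationError("pop: must be >= 1")
        if self.iterations < 1:
            raise ConfigurationError("iterations: must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ConfigurationError("c1/c2: learning factors must be > 0")
        if self.m <= 0:
            raise ConfigurationError("m: velocity-position coefficient must be > 0")
        if self.bounds[0] >= self.bounds[1]:
            raise ConfigurationError("bounds: lower bound must be < upper bound")


@dataclass
class PsoTrace:
    """Global-best fitness per iteration (non-increasing) and the final best."""

    gbest_fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float


def inertia_at(cfg: PsoConfig, t: float) -> float:
    """Inertia weight at (possibly fractional) iteration t in [0, iterations-1]."""
    if isinstance(cfg.w_schedule, (int, float)):
        return float(cfg.w_schedule)
    w_start, w_end = cfg.w_schedule
    if cfg.iterations == 1:
        return float(w_start)
    return float(w_start + (w_end - w_start) * t / (cfg.iterations - 1))


def elm_fit(
    X: np.ndarray,
    y: np.ndarray,
    hidden_count: int,
    seed: int = 0,
    activation: str = "sigmoid",
) -> ElmModel:
    """Fit an ELM: random input layer on [-1, 1], pseudoinverse output weights."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ConfigurationError("X/y: expected samples x features matrix and aligned targets")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ConfigurationError("X/y: inputs must be finite")
    if hidden_count < 1:
        raise ConfigurationError("hidden_count: must be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(hidden_count, X.shape[1]))
    b = rng.uniform(-1.0, 1.0, size=hidden_count)
    model = ElmModel(input_weights=W, hidden_biases=b, output_weights=np.zeros(hidden_count),
                     activation=activation)
    return _solve_output_weights(model, X, y)


def _hidden_matrix(model: ElmModel, X: np.ndarray) -> np.ndarray:
    act = _ACTIVATIONS[model.activation]
    return act(X @ model.input_weights.T + model.hidden_biases)


def _solve_output_weights(model: ElmModel, X: np.ndarray, y: np.ndarray) -> ElmModel:
    H = _hidden_matrix(model, X)
    model.output_weights = np.linalg.pinv(H) @ y
    return model


def elm_predict(model: ElmModel, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ConfigurationError(
            f"X: expected {model.input_dim} features, got {X.shape[1] if X.ndim == 2 else 'non-matrix'}"
        )
    return _hidden_matrix(model, X) @ model.output_weights


def pso_minimize(
    fitness,
    dim: int,
    cfg: PsoConfig,
    init_positions: np.ndarray | None = None,
) -> PsoTrace:
    """Global-best particle swarm minimisation over a box.

    Velocity update: ``v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x)``,
    clamped to ``v_max = v_max_frac * (hi - lo)``; position update
    ``x <- x + m v``, clipped to the bounds.  ``init_positions`` seeds the
    swarm (e.g. with a known starting point); remaining particles are
    uniform over the box.
    """
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.bounds
    x = rng.uniform(lo, hi, size=(cfg.pop, dim))
    if init_positions is not None:
        init_positions = np.atleast_2d(np.asarray(init_positions, dtype=float))
        x[: init_positions.shape[0]] = init_positions
    v = np.zeros_like(x)
    v_max = cfg.v_max_frac * (hi - lo)

    def evaluate(position, particle):
        val = float(fitness(position))
        if not np.isfinite(val):
            raise ConfigurationError(f"non-finite fitness for particle {particle}")
        return val

    pbest = x.copy()
    pbest_fit = np.array([evaluate(x[i], i) for i in range(cfg.pop)])
    g = int(np.argmin(pbest_fit))
    gbest = pbest[g].copy()
    gbest_fit = float(pbest_fit[g])
    trace = [gbest_fit]

    for t in range(cfg.iterations):
        w = inertia_at(cfg, t)
        r1 = rng.uniform(size=(cfg.pop, dim))
        r2 = rng.uniform(size=(cfg.pop, dim))
        v = w * v + cfg.c1 * r1 * (pbest - x) + cfg.c2 * r2 * (gbest - x)
        v = np.clip(v, -v_max, v_max)
        x = np.clip(x + cfg.m * v, lo, hi)
        for i in range(cfg.pop):
            f = evaluate(x[i], i)
            if f < pbest_fit[i]:
                pbest_fit[i] = f
                pbest[i] = x[i]
                if f < gbest_fit:
                    gbest_fit = f
                    gbest = x[i].copy()
        trace.append(gbest_fit)

    return PsoTrace(
        gbest_fitness=np.array(trace), best_position=gbest, best_fitness=gbest_fit
    )


def _decode_particle(position: np.ndarray, hidden_count: int, input_dim: int,
                     activation: str) -> ElmModel:
    W = position[: hidden_count * input_dim].reshape(hidden_count, input_dim)
    b = position[hidden_count * input_dim:]
    return ElmModel(input_weights=W.copy(), hidden_biases=b.copy(),
                    output_weights=np.zeros(hidden_count), activation=activation)


def pso_elm_fit(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hidden_count: int,
    cfg: PsoConfig,
    activation: str = "sigmoid",
    fitness_on: str = "validation",
    init_positions: np.ndarray | None = None,
) -> tuple[ElmModel, PsoTrace]:
    """PSO over ELM input weights and hidden biases.

    Each particle encodes the input-weight matrix followed by the bias
    vector; its fitness is the RMSE (on the validation set by default, or
    the training set with ``fitness_on='training'``) of the ELM whose output
    weights are refit analytically on the training data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    if X_val.shape[0] == 0:
        raise ConfigurationError("X_val: validation set must be non-empty")
    if fitness_on not in ("validation", "training"):
        raise ConfigurationError("fitness_on: must be 'validation' or 'training'")
    Xf, yf = (X_val, y_val) if fitness_on == "validation" else (X, y)
    input_dim = X.shape[1]
    dim = hidden_count * (input_dim + 1)

    def fitness(position):
        model = _decode_particle(position, hidden_count, input_dim, activation)
        _solve_output_weights(model, X, y)
        resid = yf - elm_predict(model, Xf)
        return np.sqrt(np.mean(resid**2))

    trace = pso_minimize(fitness, dim, cfg, init_positions=init_positions)
    model = _decode_particle(trace.best_position, hidden_count, input_dim, activation)
    _solve_output_weights(model, X, y)
    return model, trace


def save_model(model: ElmModel, path: str | Path, extra: dict | None = None) -> None:
    """Serialise an ELM (weights, activation) as JSON."""
    payload = {
        "input_weights": model.input_weights.tolist(),
        "hidden_biases": model.hidden_biases.tolist(),
        "output_weights": model.output_weights.tolist(),
        "activation": model.activation,
    }
    if extra:
        payload["extra"] = extra
    Path(path).write_text(json.dumps(payload, indent=2))


def load_model(path: str | Path) -> ElmModel:
    payload = json.loads(Path(path).read_text())
    return ElmModel(
        input_weights=np.array(payload["input_weights"], dtype=float),
        hidden_biases=np.array(payload["hidden_biases"], dtype=float),
        output_weights=np.array(payload["output_weights"], dtype=float),
        activation=payload["activation"],
    )
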