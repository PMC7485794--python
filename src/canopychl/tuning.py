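"""Orthogonal-array (L25) tuning of the PSO hyperparameters.

Five PSO parameters — population size, inertia-weight schedule, the two
learning factors, and the velocity-position coefficient — each take five
levels.  A full factorial would need 5^5 runs; the L25(5^5) orthogonal array
covers them in 25 runs such that every (factor, level) appears exactly five
times and every ordered pair of factors sees all 25 level combinations
exactly once.  Marginal analysis sums the validation R^2 of the five runs at
each (level, factor) cell — W[i][j] — and picks, per factor, the level with
the largest sum.

The array uses the Galois-field construction: writing run ``r = 5a + b``
(a, b in 0..4), the level indices of the five factors are
``(a, b, a+b, 2a+b, 3a+b) mod 5``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .inversion import PsoConfig, elm_predict, pso_elm_fit

__all__ = [
    "FACTORS",
    "DEFAULT_LEVELS",
    "REFERENCE_RUN_R2",
    "OrthogonalDesign",
    "MarginalTable",
    "build_l25_design",
    "marginal_analysis",
    "run_orthogonal_experiment",
]

FACTORS = ("pop", "w", "c1", "c2", "m")

#: Candidate levels for each PSO parameter; the ``w`` pairs are linear
#: start->end inertia schedules.
DEFAULT_LEVELS: dict[str, list] = {
    "pop": [40, 50, 60, 70, 80],
    "w": [0.3, 0.9, 1.5, (0.9, 0.3), (0.3, 1.5)],
    "c1": [1.1, 1.3, 1.65, 2.8, 3.5],
    "c2": [1.1, 1.3, 1.65, 2.8, 3.5],
    "m": [0.02, 0.06, 0.2, 0.6, 1.0],
}

#: Validation R^2 reported for a published 25-run L25 tuning experiment of a
#: PSO-ELM chlorophyll inversion model on field data, in run order of the
#: design above.  Used as the worked example for marginal analysis; the
#: underlying field spectra are not available.
REFERENCE_RUN_R2 = (
    0.721, 0.763, 0.753, 0.773, 0.772,
    0.773, 0.758, 0.759, 0.757, 0.773,
    0.761, 0.765, 0.721, 0.773, 0.746,
    0.739, 0.779, 0.687, 0.773, 0.773,
    0.773, 0.762, 0.733, 0.760, 0.760,
)


@dataclass
class OrthogonalDesign:
    """25 x 5 table of level indices plus the level values per factor."""

    factors: tuple[str, ...]
    levels: dict[str, list]
    runs: np.ndarray  # 25 x 5 int level indices

    @property
    def n_runs(self) -> int:
        return self.runs.shape[0]

    def run_parameters(self, r: int) -> dict:
        """Concrete parameter values of run ``r``."""
        return {
            f: self.levels[f][self.runs[r, j]] for j, f in enumerate(self.factors)
        }


@dataclass
class MarginalTable:
    """W[i][j] = sum of run R^2 where factor j sits at level i; argmax per factor."""

    W: np.ndarray  # 5 levels x 5 factors
    best_level: dict[str, int]
    best_values: dict[str, object]


def build_l25_design(levels: dict[str, list] | None = None) -> OrthogonalDesign:
    """Standard L25(5^5) array via the Galois-field generator."""
    levels = dict(DEFAULT_LEVELS if levels is None else levels)
    if tuple(levels.keys()) != FACTORS:
        raise ConfigurationError(f"levels: expected factors {FACTORS} in order")
    if any(len(v) != 5 for v in levels.values()):
        raise ConfigurationError("levels: every factor needs exactly 5 levels")
    runs = np.empty((25, 5), dtype=int)
    for r in range(25):
        a, b = divmod(r, 5)
        runs[r] = [a, b, (a + b) % 5, (2 * a + b) % 5, (3 * a + b) % 5]
    return OrthogonalDesign(factors=FACTORS, levels=levels, runs=runs)


def marginal_analysis(design: OrthogonalDesign, r2: np.ndarray) -> MarginalTable:
    """Per-factor marginal sums of run R^2 and the maximising level."""
    r2 = np.asarray(r2, dtype=float)
    if r2.shape != (design.n_runs,):
        raise ConfigurationError(f"r2: expected {design.n_runs} values aligned to runs")
    if not np.all(np.isfinite(r2)):
        raise ConfigurationError("r2: all values must be finite")
    W = np.zeros((5, 5))
    for j in range(5):
        for i in range(5):
            W[i, j] = r2[design.runs[:, j] == i].sum()
    best_level: dict[str, int] = {}
    best_values: dict[str, object] = {}
    for j, f in enumerate(design.factors):
        col = W[:, j]
        i = int(np.argmax(col))
        if np.sum(col == col[i]) > 1:
            warnings.warn(f"marginal tie for factor '{f}'; choosing lowest level index")
        best_level[f] = i
        best_values[f] = design.levels[f][i]
    return MarginalTable(W=W, best_level=best_level, best_values=best_values)


def run_seed(master_seed: int, run_index: int) -> int:
    """Deterministic per-run seed derived from the master seed."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(run_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def run_orthogonal_experiment(
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    design: OrthogonalDesign,
    hidden_count: int = 20,
    iterations: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Train PSO-ELM at each design run's parameter levels; return the 25
    validation R^2 values (run seeds derived deterministically from ``seed``)."""
    from .metrics import r2_score  # local import to avoid a cycle

    out = np.empty(design.n_runs)
    for r in range(design.n_runs):
        params = design.run_parameters(r)
        cfg = PsoConfig(
            pop=int(params["pop"]),
            w_schedule=params["w"],
            c1=float(params["c1"]),
            c2=float(params["c2"]),
            m=float(params["m"]),
            iterations=iterations,
            seed=run_seed(seed, r),
        )
        model, _ = pso_elm_fit(X, y, X_val, y_val, hidden_count, cfg)
        out[r] = r2_score(y_val, elm_predict(model, X_val))
    return out
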