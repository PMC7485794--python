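"""Successive projections algorithm (SPA) and MLR subset refinement.

SPA is a forward wavelength selector that minimises collinearity: starting
from the column of the calibration matrix with the largest l2 norm, each
iteration projects every unselected column into the null space of the most
recently selected vector's residual and picks the column with the largest
residual norm.  The selected wavelengths are then refined by exhaustive
multiple-linear-regression subset search, keeping the subset with the
smallest cross-validated RMSE.

Cross-validated (rather than training) RMSE makes the refinement meaningful:
training RMSE never increases with subset size and would always keep every
candidate, whereas CV-RMSE can prefer a parsimonious subset.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import KFold

from .calibration import SpectrumSet
from .exceptions import ConfigurationError

__all__ = ["SpaResult", "spa_select", "spa_select_trace", "mlr_refine", "subset_cv_rmse"]

# residual norms below this floor are treated as exactly collinear
_RESIDUAL_FLOOR = 1e-12
# subsets whose CV-RMSE is within this tolerance of the optimum tie on
# cardinality, then lexicographic index order
_TIE_ABS = 1e-9
_TIE_REL = 1e-6


@dataclass
class SpaResult:
    """Outcome of SPA selection plus MLR refinement."""

    selected_wavelengths: list[float]
    selected_indices: list[int]
    refined_subset: list[float]
    refined_indices: list[int]
    refined_rmse: float
    history: list[dict] = field(default_factory=list)


def spa_select_trace(X_cal: np.ndarray, n_select: int) -> tuple[list[int], list[dict]]:
    """SPA selection returning the ordered index list and per-iteration history.

    History entries record the selected index and the residual norm at
    selection time; residual norms are non-increasing per retained column
    because orthogonal projection is non-expansive.
    """
    X = np.asarray(X_cal, dtype=float)
    if X.ndim != 2:
        raise ConfigurationError("X_cal: expected a 2-D matrix")
    m, j = X.shape
    if not 1 <= n_select <= min(m, j):
        raise ConfigurationError(
            f"n_select: must lie in [1, min(M, J)] = [1, {min(m, j)}]"
        )
    if np.all(np.linalg.norm(X, axis=0) < _RESIDUAL_FLOOR):
        raise ConfigurationError("X_cal: all columns are numerically zero")

    residuals = X.copy()  # current y_j for every column
    unselected = np.ones(j, dtype=bool)
    selected: list[int] = []
    history: list[dict] = []
    for _ in range(n_select):
        norms = np.linalg.norm(residuals, axis=0)
        norms[~unselected] = -1.0
        a_k = int(np.argmax(norms))
        if norms[a_k] < _RESIDUAL_FLOOR:
            warnings.warn(
                f"all residuals below numerical floor after {len(selected)} "
                f"selections; returning a shorter list"
            )
            break
        z = residuals[:, a_k].copy()
        selected.append(a_k)
        unselected[a_k] = False
        history.append({"index": a_k, "residual_norm": float(norms[a_k])})
        # project remaining residuals into the null space of z
        coeff = (z @ residuals) / (z @ z)
        residuals = residuals - np.outer(z, coeff)
    return selected, history


def spa_select(X_cal: np.ndarray, n_select: int) -> list[int]:
    """Ordered SPA-selected column indices (see :func:`spa_select_trace`)."""
    return spa_select_trace(X_cal, n_select)[0]


def _ols_rmse(X: np.ndarray, y: np.ndarray, Xt: np.ndarray, yt: np.ndarray) -> float:
    """Fit y ~ X + intercept by least squares; RMSE on (Xt, yt)."""
    A = np.column_stack([np.ones(len(X)), X])
    At = np.column_stack([np.ones(len(Xt)), Xt])
    if len(X) <= A.shape[1]:
        return np.inf
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        return np.inf  # singular design within this fold
    resid = yt - At @ coef
    return float(np.sqrt(np.mean(resid**2)))


def subset_cv_rmse(
    X: np.ndarray, y: np.ndarray, columns, n_folds: int = 5, seed: int = 0
) -> float:
    """K-fold cross-validated RMSE of an OLS fit on the given columns."""
    cols = list(columns)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = []
    for train, test in kf.split(X):
        errs.append(_ols_rmse(X[np.ix_(train, cols)], y[train], X[np.ix_(test, cols)], y[test]))
    return float(np.mean(errs))


def mlr_refine(
    s: SpectrumSet,
    chl: np.ndarray,
    candidate_indices,
    n_folds: int = 5,
    seed: int = 0,
) -> SpaResult:
    """Exhaustive MLR subset search over SPA candidates, by smallest CV-RMSE.

    Every nonempty subset of the candidates is scored by K-fold
    cross-validated RMSE of an ordinary-least-squares fit (intercept
    included).  Near-ties are resolved in favour of smaller subsets, then
    lexicographic index order.
    """
    candidates = sorted(int(i) for i in candidate_indices)
    if not 1 <= len(candidates) <= 15:
        raise ConfigurationError("candidate_indices: need between 1 and 15 candidates")
    chl = np.asarray(chl, dtype=float)
    if chl.shape != (s.n_samples,):
        raise ConfigurationError("chl: length must equal sample count")
    X = s.values
    best_subset: tuple[int, ...] | None = None
    best_rmse = np.inf
    for size in range(1, len(candidates) + 1):
        for subset in itertools.combinations(candidates, size):
            rmse = subset_cv_rmse(X, chl, subset, n_folds=n_folds, seed=seed)
            if not np.isfinite(rmse):
                continue
            tol = 0.0 if not np.isfinite(best_rmse) else max(_TIE_ABS, _TIE_REL * best_rmse)
            if rmse < best_rmse - tol:
                best_rmse = rmse
                best_subset = subset
            # ties: earlier (smaller, lexicographically first) subset wins
    if best_subset is None:
        raise ConfigurationError("mlr_refine: every candidate subset was singular")
    centers = s.grid.centers
    return SpaResult(
        selected_wavelengths=[float(centers[i]) for i in candidates],
        selected_indices=candidates,
        refined_subset=[float(centers[i]) for i in best_subset],
        refined_indices=list(best_subset),
        refined_rmse=float(best_rmse),
    )
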