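"""Regression accuracy metrics used throughout: R^2 and RMSE (mg/L)."""

from __future__ import annotations

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["r2_score", "rmse"]


def _aligned(y_true, y_pred):
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ConfigurationError("y_true/y_pred: expected aligned 1-D vectors")
    return y_true, y_pred


def r2_score(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    y_true, y_pred = _aligned(y_true, y_pred)
    if y_true.size < 2:
        raise ConfigurationError("r2_score: need at least 2 observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ConfigurationError("r2_score: y_true is constant")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error, in the units of the target (mg/L here)."""
    y_true, y_pred = _aligned(y_true, y_pred)
    if y_true.size < 1:
        raise ConfigurationError("rmse: need at least 1 observation")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
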