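"""Wet-chemistry ground truth and dataset bookkeeping.

Chlorophyll concentration of a leaf extract is computed from optical
densities at 663 and 645 nm by the standard two-wavelength formula

    Chl (mg/L) = 5.134 * OD663 + 20.436 * OD645.

This module also summarises chlorophyll distributions (max/min/mean/SD and
coefficient of variation) and splits a dataset into modeling and validation
subsets, stratified by chlorophyll quintile so both subsets span the range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import SpectrumSet
from .exceptions import ConfigurationError

__all__ = [
    "OdPair",
    "ChlStats",
    "chl_from_od",
    "cv_percent",
    "summarize_chl",
    "split_dataset",
    "read_od_table",
]

_OD663_COEF = 5.134
_OD645_COEF = 20.436


@dataclass(frozen=True)
class OdPair:
    """Absorbances of the pigment extract at 663 and 645 nm."""

    od663: float
    od645: float

    def __post_init__(self):
        if self.od663 < 0 or self.od645 < 0:
            raise ConfigurationError("od663/od645: optical densities must be >= 0")


@dataclass(frozen=True)
class ChlStats:
    n: int
    max: float
    min: float
    mean: float
    sd: float
    cv_percent: float


def chl_from_od(od: OdPair) -> float:
    """Chlorophyll (mg/L) from the 663/645 nm optical-density pair."""
    return _OD663_COEF * od.od663 + _OD645_COEF * od.od645


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100*SD/mean, rounded to 2 decimals for reporting."""
    if mean <= 0:
        raise ConfigurationError("mean: CV defined only for positive mean")
    return round(100.0 * sd / mean, 2)


def summarize_chl(values) -> ChlStats:
    """Summary statistics of a chlorophyll vector (sample SD, n-1 denominator)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ConfigurationError("summarize_chl: need at least 2 values")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    cv = 0.0 if sd == 0 else cv_percent(mean, sd)
    return ChlStats(
        n=int(values.size),
        max=round(float(values.max()), 2),
        min=round(float(values.min()), 2),
        mean=round(mean, 2),
        sd=round(sd, 2),
        cv_percent=cv,
    )


def split_dataset(
    s: SpectrumSet, frac_model: float = 0.84, seed: int = 0, n_strata: int = 5
) -> tuple[SpectrumSet, SpectrumSet]:
    """Partition samples into modeling and validation sets.

    The modeling set holds ``round(frac_model * n)`` samples; allocation is
    stratified by chlorophyll quantile bin (largest-remainder rounding per
    bin) so both subsets cover the full concentration range.  Falls back to a
    simple random split with a warning when the data are too small to
    stratify.
    """
    if not 0 < frac_model < 1:
        raise ConfigurationError("frac_model: must be strictly between 0 and 1")
    if s.chl is None:
        raise ConfigurationError("split_dataset: spectrum set has no chlorophyll targets")
    n = s.n_samples
    n_model = int(round(frac_model * n))
    if n_model == 0 or n_model == n:
        raise ConfigurationError("frac_model: split leaves one subset empty")
    rng = np.random.default_rng(seed)

    if n < 2 * n_strata:
        warnings.warn("too few samples to stratify; using a simple random split")
        perm = rng.permutation(n)
        return s.select_samples(np.sort(perm[:n_model])), s.select_samples(
            np.sort(perm[n_model:])
        )

    # quantile-bin stratification on chlorophyll
    edges = np.quantile(s.chl, np.linspace(0, 1, n_strata + 1))
    bins = np.clip(np.searchsorted(edges, s.chl, side="right") - 1, 0, n_strata - 1)
    model_idx: list[int] = []
    # largest-remainder allocation of n_model across strata
    counts = np.array([(bins == b).sum() for b in range(n_strata)])
    quotas = frac_model * counts
    base = np.floor(quotas).astype(int)
    short = n_model - base.sum()
    order = np.argsort(-(quotas - base))
    take = base.copy()
    for b in order[: max(short, 0)]:
        take[b] += 1
    for b in range(n_strata):
        members = np.flatnonzero(bins == b)
        members = rng.permutation(members)
        model_idx.extend(members[: take[b]].tolist())
    model_idx = np.sort(np.array(model_idx, dtype=int))
    val_mask = np.ones(n, dtype=bool)
    val_mask[model_idx] = False
    val_idx = np.flatnonzero(val_mask)
    return s.select_samples(model_idx), s.select_samples(val_idx)


def read_od_table(path, sep: str = ",") -> np.ndarray:
    """Read a delimited table with ``od663`` and ``od645`` columns; returns
    the chlorophyll vector (mg/L) computed row by row."""
    df = pd.read_csv(path, sep=sep)
    for col in ("od663", "od645"):
        if col not in df.columns:
            raise ConfigurationError(f"OD table missing column '{col}'")
    return np.array(
        [chl_from_od(OdPair(r.od663, r.od645)) for r in df.itertuples(index=False)]
    )
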