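"""Single-band association screening between reflectance and chlorophyll.

Three complementary dependence measures are computed per wavelength:

* Pearson's product-moment correlation (linear association, in [-1, 1]);
* distance correlation, the classical (biased) V-statistic estimator built
  from doubly centred pairwise-distance matrices — zero only under
  independence in the population version, in [0, 1];
* the maximal information coefficient (MIC), estimated by an exhaustive
  search over grid shapes with total cell count bounded by ``n**0.6``: one
  axis is equipartitioned into quantile bins and the other axis's cut points
  are optimised by dynamic programming to maximise mutual information; the
  score is normalised by ``log2(min(rows, cols))`` and maximised over shapes
  and both orientations.  This is a desk-scale approximation of the full
  MIC search, adequate for ranking bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .calibration import SpectrumSet, WavelengthGrid
from .exceptions import ConfigurationError

__all__ = [
    "ScreeningResult",
    "pearson_per_band",
    "dcor_per_band",
    "mic_per_band",
    "distance_correlation",
    "mic",
    "grid_mutual_information",
    "screen_bands",
]


@dataclass
class ScreeningResult:
    grid: WavelengthGrid
    pearson: np.ndarray
    dcor: np.ndarray
    mic: np.ndarray

    def peak_band(self, method: str) -> float:
        """Wavelength (nm) where |association| is largest for the given method."""
        curve = {"pearson": np.abs(self.pearson), "dcor": self.dcor, "mic": self.mic}[
            method
        ]
        return float(self.grid.centers[int(np.argmax(curve))])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "wavelength_nm": self.grid.centers,
                "pearson": self.pearson,
                "dcor": self.dcor,
                "mic": self.mic,
            }
        )


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(np.sum(xc**2))
    sy = np.sqrt(np.sum(yc**2))
    if sx == 0 or sy == 0:
        warnings.warn("constant variable in Pearson correlation; reporting 0")
        return 0.0
    return float(np.dot(xc, yc) / (sx * sy))


def pearson_per_band(s: SpectrumSet, chl: np.ndarray) -> np.ndarray:
    chl = np.asarray(chl, dtype=float)
    if s.n_samples < 3:
        raise ConfigurationError("pearson_per_band: need at least 3 samples")
    if np.ptp(chl) == 0:
        raise ConfigurationError("pearson_per_band: chlorophyll vector is constant")
    return np.array([_pearson(s.values[:, j], chl) for j in range(s.n_bands)])


def _centered_distances(x: np.ndarray) -> np.ndarray:
    d = np.abs(x[:, None] - x[None, :])
    return d - d.mean(axis=0, keepdims=True) - d.mean(axis=1, keepdims=True) + d.mean()


def distance_correlation(x, y) -> float:
    """Classical (biased) sample distance correlation of two scalar variables."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ConfigurationError("distance_correlation: need aligned vectors, n >= 4")
    a = _centered_distances(x)
    b = _centered_distances(y)
    dcov2 = (a * b).mean()
    dvarx = (a * a).mean()
    dvary = (b * b).mean()
    denom = np.sqrt(dvarx * dvary)
    if denom <= 0:
        return 0.0
    return float(np.sqrt(max(dcov2, 0.0) / denom))


def dcor_per_band(s: SpectrumSet, chl: np.ndarray) -> np.ndarray:
    chl = np.asarray(chl, dtype=float)
    if s.n_samples < 4:
        raise ConfigurationError("dcor_per_band: need at least 4 samples")
    b = _centered_distances(chl)
    dvary = (b * b).mean()
    out = np.empty(s.n_bands)
    for j in range(s.n_bands):
        a = _centered_distances(s.values[:, j])
        dvarx = (a * a).mean()
        denom = np.sqrt(dvarx * dvary)
        out[j] = 0.0 if denom <= 0 else np.sqrt(max((a * b).mean(), 0.0) / denom)
    return out


def grid_mutual_information(counts: np.ndarray) -> float:
    """Mutual information (bits) of a joint count table."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    if n <= 0:
        return 0.0
    p = counts / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (px * py))
    return float(np.nansum(terms))


def _equipartition_labels(y: np.ndarray, c: int) -> np.ndarray:
    """Quantile-bin labels 0..c-1; ties share a bin."""
    edges = np.quantile(y, np.linspace(0, 1, c + 1)[1:-1])
    return np.searchsorted(edges, y, side="right")


def _xlogx(a: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        v = a * np.log2(a)
    return np.nan_to_num(v, nan=0.0, neginf=0.0)


def _best_mi_by_rows(x: np.ndarray, labels: np.ndarray, c: int, r_max: int) -> dict[int, float]:
    """Max MI (bits) over partitions of x into exactly r contiguous bins, for
    every r in 2..r_max, with the other axis fixed to the given c-bin labels.

    Row cut points are restricted to boundaries between distinct x values.
    The optimisation is a max-plus dynamic programme over a precomputed
    (cut, cut) row-score matrix, one vectorised reduction per added row.
    """
    n = x.size
    order = np.argsort(x, kind="stable")
    ls = labels[order]
    xs = x[order]
    distinct = np.flatnonzero(np.diff(xs) != 0) + 1
    positions = np.concatenate(([0], distinct, [n]))
    m = positions.size
    # prefix counts of each label at every candidate cut position
    onehot = np.zeros((n + 1, c))
    np.add.at(onehot[1:], (np.arange(n), ls), 1.0)
    prefix = np.cumsum(onehot, axis=0)[positions]  # m x c

    # score[s, t]: contribution of a row spanning cut s..t (s < t)
    cnt = prefix[None, :, :] - prefix[:, None, :]
    score = _xlogx(cnt).sum(axis=2) - _xlogx(cnt.sum(axis=2))
    score[np.tril_indices(m)] = -np.inf  # rows must be non-empty, forward

    const = (-_xlogx(prefix[m - 1]).sum()) / n + np.log2(n)
    dp = np.full(m, -np.inf)
    dp[0] = 0.0
    out: dict[int, float] = {}
    for r in range(1, r_max + 1):
        dp = (dp[:, None] + score).max(axis=0)
        if r >= 2 and np.isfinite(dp[m - 1]):
            out[r] = float(dp[m - 1] / n + const)
    return out


def mic(x, y, alpha: float = 0.6) -> float:
    """Maximal information coefficient of two scalar variables (bounded-grid
    equipartition-plus-DP approximation, cell bound ``n**alpha``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ConfigurationError("mic: vectors must be aligned")
    n = x.size
    if n < 10:
        raise ConfigurationError("mic: estimator unreliable below n = 10")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0
    bound = n**alpha
    best = 0.0
    for a, b in ((x, y), (y, x)):
        c = 2
        while 2 * c <= bound:
            labels = _equipartition_labels(b, c)
            r_max = int(bound // c)
            for r, val in _best_mi_by_rows(a, labels, c, r_max).items():
                best = max(best, val / np.log2(min(r, c)))
            c += 1
    return float(min(best, 1.0))


def mic_per_band(s: SpectrumSet, chl: np.ndarray, alpha: float = 0.6) -> np.ndarray:
    chl = np.asarray(chl, dtype=float)
    if s.n_samples < 10:
        raise ConfigurationError("mic_per_band: need at least 10 samples")
    return np.array([mic(s.values[:, j], chl, alpha=alpha) for j in range(s.n_bands)])


def screen_bands(s: SpectrumSet, chl: np.ndarray | None = None) -> ScreeningResult:
    """Run all three per-band association measures."""
    if chl is None:
        chl = s.chl
    if chl is None:
        raise ConfigurationError("screen_bands: no chlorophyll vector available")
    return ScreeningResult(
        grid=s.grid,
        pearson=pearson_per_band(s, chl),
        dcor=dcor_per_band(s, chl),
        mic=mic_per_band(s, chl),
    )
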