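"""Wavelength grids, spectrum containers, and radiometric calibration.

A push-broom hyperspectral imager delivers digital numbers (DN) on a fixed
wavelength grid.  This module provides the grid convention used throughout the
package, the two-point ("black-white") DN-to-reflectance correction against
dark and white reference panels, boundary-band removal, interval cropping, and
region-of-interest averaging of image cubes.

Grid convention
---------------
A grid from ``start`` to ``end`` at ``step`` nm holds ``floor((end-start)/step)``
bands; band *k* is centred at ``start + (k + 0.5) * step``.  For 400-1000 nm at
2.35 nm this yields 255 bands; dropping one band at each boundary leaves 253
effective bands.  This convention is normative for the whole package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, DegenerateCalibrationError

__all__ = [
    "WavelengthGrid",
    "CalibrationPair",
    "SpectrumSet",
    "make_grid",
    "drop_boundary_bands",
    "calibrate_reflectance",
    "crop_interval",
    "roi_mean_spectrum",
]

# tolerance absorbing float error in (end-start)/step when the ratio is integral
_GRID_EPS = 1e-9


@dataclass(frozen=True)
class WavelengthGrid:
    """Ordered band centres (nm) with the nominal sampling step."""

    centers: np.ndarray
    step: float

    def __post_init__(self):
        centers = np.asarray(self.centers, dtype=float)
        if centers.ndim != 1 or centers.size == 0:
            raise ConfigurationError("centers: expected a non-empty 1-D array")
        if centers.size > 1 and not np.all(np.diff(centers) > 0):
            raise ConfigurationError("centers: must be strictly increasing")
        if self.step <= 0:
            raise ConfigurationError("step: must be positive")
        object.__setattr__(self, "centers", centers)

    @property
    def n_bands(self) -> int:
        return int(self.centers.size)

    def __len__(self) -> int:
        return self.n_bands


@dataclass(frozen=True)
class CalibrationPair:
    """Dark/white panel DN readings and their known reflectivities.

    The panels anchor the affine DN->reflectance map: ``dn_dark`` maps to
    ``rho_dark`` and ``dn_white`` to ``rho_white``.
    """

    dn_dark: float
    dn_white: float
    rho_dark: float = 0.0
    rho_white: float = 1.0

    def __post_init__(self):
        if self.dn_dark == self.dn_white:
            raise DegenerateCalibrationError(
                "dark and white panel DN values coincide; calibration undefined"
            )
        if not (0.0 <= self.rho_dark < self.rho_white <= 1.0):
            raise ConfigurationError(
                "rho_dark/rho_white: need 0 <= rho_dark < rho_white <= 1"
            )


@dataclass
class SpectrumSet:
    """Per-sample spectra on a shared grid, optionally with chlorophyll targets.

    ``values`` is samples x bands; ``kind`` flags whether entries are raw
    sensor DN or reflectance in [0, 1].
    """

    grid: WavelengthGrid
    values: np.ndarray
    sample_ids: list[str] = field(default_factory=list)
    chl: np.ndarray | None = None
    kind: str = "reflectance"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("values: expected samples x bands matrix")
        if self.values.shape[1] != self.grid.n_bands:
            raise ConfigurationError(
                f"values: {self.values.shape[1]} columns but grid has "
                f"{self.grid.n_bands} bands"
            )
        if not self.sample_ids:
            self.sample_ids = [f"s{i:04d}" for i in range(self.values.shape[0])]
        if len(self.sample_ids) != self.values.shape[0]:
            raise ConfigurationError("sample_ids: length must equal sample count")
        if self.chl is not None:
            self.chl = np.asarray(self.chl, dtype=float)
            if self.chl.shape != (self.values.shape[0],):
                raise ConfigurationError("chl: length must equal sample count")
        if self.kind not in ("reflectance", "dn"):
            raise ConfigurationError("kind: must be 'reflectance' or 'dn'")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.values.shape[1]

    def select_bands(self, indices) -> "SpectrumSet":
        """Restrict to a subset of bands, keeping sample metadata."""
        indices = np.asarray(indices, dtype=int)
        grid = WavelengthGrid(self.grid.centers[indices], self.grid.step)
        return SpectrumSet(
            grid=grid,
            values=self.values[:, indices],
            sample_ids=list(self.sample_ids),
            chl=None if self.chl is None else self.chl.copy(),
            kind=self.kind,
        )

    def select_samples(self, indices) -> "SpectrumSet":
        indices = np.asarray(indices, dtype=int)
        return SpectrumSet(
            grid=self.grid,
            values=self.values[indices],
            sample_ids=[self.sample_ids[i] for i in indices],
            chl=None if self.chl is None else self.chl[indices],
            kind=self.kind,
        )


def make_grid(start: float, end: float, step: float) -> WavelengthGrid:
    """Build the uniform band grid covering [start, end] nm.

    Band count is ``floor((end - start) / step)`` and band *k* is centred at
    ``start + (k + 0.5) * step``; e.g. 400-1000 nm at 2.35 nm gives 255 bands
    with the first centre at 401.175 nm.
    """
    if step <= 0:
        raise ConfigurationError("step: must be positive")
    if end <= start:
        raise ConfigurationError("end: must exceed start")
    count = int(math.floor((end - start) / step + _GRID_EPS))
    if count < 1:
        raise ConfigurationError("grid: interval shorter than one step")
    centers = start + (np.arange(count) + 0.5) * step
    return WavelengthGrid(centers=centers, step=float(step))


def drop_boundary_bands(s: SpectrumSet, n_each_side: int = 1) -> SpectrumSet:
    """Remove the outermost bands, where push-broom sensors are least reliable."""
    if n_each_side < 0:
        raise ConfigurationError("n_each_side: must be >= 0")
    if n_each_side == 0:
        return s
    if s.n_bands <= 2 * n_each_side:
        raise ConfigurationError(
            f"cannot drop {n_each_side} bands per side from {s.n_bands} bands"
        )
    keep = np.arange(n_each_side, s.n_bands - n_each_side)
    return s.select_bands(keep)


def calibrate_reflectance(dn: SpectrumSet, cal: CalibrationPair) -> SpectrumSet:
    """Two-point black-white correction of a DN spectrum set.

    rho_t = (DN_t - DN_1) / (DN_2 - DN_1) * (rho_2 - rho_1) + rho_1,
    where panel 1 is the dark reference and panel 2 the white reference.
    """
    scale = (cal.rho_white - cal.rho_dark) / (cal.dn_white - cal.dn_dark)
    rho = (dn.values - cal.dn_dark) * scale + cal.rho_dark
    out = replace_values(dn, rho)
    out.kind = "reflectance"
    return out


def replace_values(s: SpectrumSet, values: np.ndarray) -> SpectrumSet:
    """Copy a spectrum set with new values on the same grid."""
    return SpectrumSet(
        grid=s.grid,
        values=np.asarray(values, dtype=float),
        sample_ids=list(s.sample_ids),
        chl=None if s.chl is None else s.chl.copy(),
        kind=s.kind,
    )


def crop_interval(s: SpectrumSet, lo: float, hi: float) -> SpectrumSet:
    """Keep bands whose centres lie in the closed interval [lo, hi] nm."""
    if lo >= hi:
        raise ConfigurationError("crop: lo must be < hi")
    keep = np.flatnonzero((s.grid.centers >= lo) & (s.grid.centers <= hi))
    if keep.size == 0:
        raise ConfigurationError(f"crop: no band centres inside [{lo}, {hi}] nm")
    return s.select_bands(keep)


def roi_mean_spectrum(cube: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Average an image cube (lines x samples x bands) over a 0/1 pixel mask.

    Returns the per-band arithmetic mean over the selected pixels — one
    spectrum per region of interest.
    """
    cube = np.asarray(cube, dtype=float)
    mask = np.asarray(mask)
    if cube.ndim != 3:
        raise ConfigurationError("cube: expected lines x samples x bands array")
    if mask.shape != cube.shape[:2]:
        raise ConfigurationError("mask: shape must match cube spatial dimensions")
    sel = mask.astype(bool)
    if not sel.any():
        raise ConfigurationError("mask: selects no pixels")
    return cube[sel].mean(axis=0)
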