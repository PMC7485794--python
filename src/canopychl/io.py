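"""File interfaces: delimited spectra tables and a minimal ENVI cube reader.

The spectra table is plain delimited text with one row per sample, columns
``wavelength_nm_<centre>`` for each band and an optional ``chl_mg_per_L``
ground-truth column.  The ENVI reader handles the classic text header plus a
raw binary payload in any of the three standard interleaves (bsq, bil, bip);
it covers exactly what ROI extraction needs, not the full format zoo.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import SpectrumSet, WavelengthGrid
from .exceptions import ConfigurationError

__all__ = [
    "write_spectra_table",
    "read_spectra_table",
    "read_envi_cube",
    "write_envi_cube",
    "read_mask",
    "write_mask",
]

_WL_PREFIX = "wavelength_nm_"
_CHL_COLUMN = "chl_mg_per_L"

# ENVI numeric data-type codes -> numpy dtypes (subset in common use)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
}


def write_spectra_table(s: SpectrumSet, path: str | Path, sep: str = ",") -> None:
    """Write a spectrum set as a delimited table with one column per band."""
    cols = {f"{_WL_PREFIX}{c:.4f}": s.values[:, i] for i, c in enumerate(s.grid.centers)}
    df = pd.DataFrame(cols, index=pd.Index(s.sample_ids, name="sample_id"))
    if s.chl is not None:
        df[_CHL_COLUMN] = s.chl
    df.to_csv(path, sep=sep)


def read_spectra_table(path: str | Path, sep: str = ",", kind: str = "reflectance") -> SpectrumSet:
    """Read a delimited spectra table back into a :class:`SpectrumSet`.

    The nominal grid step is inferred from the median spacing of the
    wavelength columns.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    wl_cols = [c for c in df.columns if c.startswith(_WL_PREFIX)]
    if not wl_cols:
        raise ConfigurationError(f"no '{_WL_PREFIX}*' columns found in {path}")
    centers = np.array([float(c[len(_WL_PREFIX):]) for c in wl_cols])
    order = np.argsort(centers)
    centers = centers[order]
    values = df[wl_cols].to_numpy(dtype=float)[:, order]
    step = float(np.median(np.diff(centers))) if centers.size > 1 else 1.0
    chl = df[_CHL_COLUMN].to_numpy(dtype=float) if _CHL_COLUMN in df.columns else None
    return SpectrumSet(
        grid=WavelengthGrid(centers=centers, step=step),
        values=values,
        sample_ids=[str(i) for i in df.index],
        chl=chl,
        kind=kind,
    )


def _parse_envi_header(text: str) -> dict:
    """Parse ``key = value`` lines, folding ``{...}`` blocks (possibly multi-line)."""
    # join brace blocks onto one line
    text = re.sub(r"\{[^}]*\}", lambda m: m.group(0).replace("\n", " "), text)
    header: dict = {}
    for line in text.splitlines():
        if "=" not in line:
            continue
        key, _, value = line.partition("=")
        header[key.strip().lower()] = value.strip()
    return header


def read_envi_cube(header_path: str | Path) -> tuple[np.ndarray, np.ndarray | None]:
    """Read an ENVI-style cube given its text header.

    Returns ``(cube, wavelengths)`` with the cube as lines x samples x bands
    (band-interleave resolved) and wavelengths in nm when the header lists
    them, else ``None``.  The binary payload is looked up next to the header
    (same stem, or the header path without its ``.hdr`` suffix).
    """
    header_path = Path(header_path)
    text = header_path.read_text()
    if not text.lstrip().lower().startswith("envi"):
        raise ConfigurationError(f"{header_path}: missing ENVI magic line")
    hdr = _parse_envi_header(text)
    try:
        samples = int(hdr["samples"])
        lines = int(hdr["lines"])
        bands = int(hdr["bands"])
        dtype_code = int(hdr["data type"])
        interleave = hdr["interleave"].lower()
    except KeyError as exc:
        raise ConfigurationError(f"{header_path}: header missing field {exc}") from exc
    if dtype_code not in _ENVI_DTYPES:
        raise ConfigurationError(f"unsupported ENVI data type {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(hdr.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")

    data_path = header_path.with_suffix("")
    if not data_path.exists():
        candidates = [p for p in header_path.parent.glob(header_path.stem + ".*")
                      if p != header_path and p.suffix.lower() != ".hdr"]
        if not candidates:
            raise ConfigurationError(f"no binary payload found for {header_path}")
        data_path = candidates[0]
    raw = np.fromfile(data_path, dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ConfigurationError(
            f"{data_path}: has {raw.size} elements, header implies {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ConfigurationError(f"unsupported interleave '{interleave}'")

    wavelengths = None
    if "wavelength" in hdr:
        inner = hdr["wavelength"].strip().lstrip("{").rstrip("}")
        wavelengths = np.array([float(tok) for tok in inner.split(",") if tok.strip()])
        if wavelengths.size != bands:
            raise ConfigurationError("wavelength list length does not match band count")
    return cube.astype(float), wavelengths


def write_envi_cube(
    cube: np.ndarray,
    header_path: str | Path,
    interleave: str = "bil",
    wavelengths: np.ndarray | None = None,
    dtype_code: int = 4,
) -> None:
    """Write a lines x samples x bands cube as ENVI header + raw binary."""
    header_path = Path(header_path)
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ConfigurationError("cube: expected lines x samples x bands array")
    lines, samples, bands = cube.shape
    dtype = _ENVI_DTYPES[dtype_code]
    if interleave == "bsq":
        raw = cube.transpose(2, 0, 1)
    elif interleave == "bil":
        raw = cube.transpose(0, 2, 1)
    elif interleave == "bip":
        raw = cube
    else:
        raise ConfigurationError(f"unsupported interleave '{interleave}'")
    np.ascontiguousarray(raw, dtype=dtype).tofile(header_path.with_suffix(""))
    parts = [
        "ENVI",
        f"samples = {samples}",
        f"lines = {lines}",
        f"bands = {bands}",
        "header offset = 0",
        "file type = ENVI Standard",
        f"data type = {dtype_code}",
        f"interleave = {interleave}",
        "byte order = 0",
    ]
    if wavelengths is not None:
        wl = ", ".join(f"{w:.4f}" for w in np.asarray(wavelengths))
        parts.append("wavelength = { " + wl + " }")
    header_path.write_text("\n".join(parts) + "\n")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/1 region-of-interest mask stored as delimited integers."""
    return np.loadtxt(path, dtype=int).astype(bool)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(mask, dtype=int), fmt="%d")
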