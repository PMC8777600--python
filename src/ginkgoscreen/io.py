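"""Plain-text I/O for spectra and correlation maps.

Spectrum files are two-column CSV (wavelength_nm, absorbance) with an
optional single header line; JCAMP-DX files are converted to the same
container when the optional ``jcamp`` reader is installed. Correlation maps
are CSV matrices whose first row carries the nu2 (reference-axis)
wavelengths and whose first column carries the nu1 (sample-axis)
wavelengths, preceded by ``#``-comment metadata lines.

All writers use 17-significant-digit formatting so a write/read round trip
reproduces values to better than 1e-12 relative error.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Union

import numpy as np

from .cos2t2d import ASYNCHRONOUS, SYNCHRONOUS, CorrelationMap
from .spectral import GridError, Spectrum, WavelengthGrid

__all__ = [
    "SpectrumParseError",
    "MapFormatError",
    "read_spectrum",
    "write_spectrum",
    "read_map",
    "write_map",
]

PathLike = Union[str, os.PathLike]

_FMT = "%.17g"


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed."""


class MapFormatError(ValueError):
    """A correlation-map file is malformed."""


def _grid_from_wavelengths(wl: np.ndarray, origin: str) -> WavelengthGrid:
    """Build a uniform grid from an ascending wavelength vector."""
    steps = np.diff(wl)
    step = float(steps[0])
    if step <= 0 or not np.allclose(steps, step, rtol=0, atol=1e-6 * max(step, 1.0)):
        raise GridError(
            f"{origin}: wavelengths are not on a uniform grid "
            "(uniform spacing is required; resample externally first)"
        )
    return WavelengthGrid(float(wl[0]), float(wl[-1]), step)


def read_spectrum(
    path: PathLike,
    wavelength_col: int = 0,
    absorbance_col: int = 1,
    label: str | None = None,
) -> Spectrum:
    """Read a spectrum from a two-column text/CSV file.

    Rows may be comma- or whitespace-separated. A single non-numeric header
    line at the top is skipped; any later non-numeric row is a parse error
    naming the offending line. Wavelengths must be strictly monotone
    (descending input is reversed to ascending) and uniformly spaced.
    """
    path = Path(path)
    if path.suffix.lower() in (".jdx", ".dx", ".jcamp"):
        return _read_jcamp(path, label)
    wl: list[float] = []
    ab: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split(",") if "," in line else line.split()
            try:
                w = float(tokens[wavelength_col])
                a = float(tokens[absorbance_col])
            except (ValueError, IndexError):
                if lineno == 1 and not wl:
                    continue  # header line
                raise SpectrumParseError(
                    f"{path}: non-numeric data on line {lineno}: {line!r}"
                ) from None
            wl.append(w)
            ab.append(a)
    if len(wl) < 2:
        raise SpectrumParseError(f"{path}: fewer than two data rows")

    wl_arr = np.asarray(wl)
    ab_arr = np.asarray(ab)
    diffs = np.diff(wl_arr)
    if np.any(diffs == 0):
        raise SpectrumParseError(f"{path}: duplicate wavelengths present")
    if np.all(diffs < 0):
        wl_arr = wl_arr[::-1]
        ab_arr = ab_arr[::-1]
    elif not np.all(diffs > 0):
        raise SpectrumParseError(f"{path}: wavelengths are not strictly monotone")

    grid = _grid_from_wavelengths(wl_arr, str(path))
    return Spectrum(grid, ab_arr, label if label is not None else path.stem)


def _read_jcamp(path: Path, label: str | None) -> Spectrum:
    try:
        import jcamp  # optional dependency
    except ImportError:
        raise SpectrumParseError(
            f"{path}: JCAMP-DX input requires the optional 'jcamp' package"
        ) from None
    data = jcamp.jcamp_readfile(str(path))
    wl = np.asarray(data["x"], dtype=float)
    ab = np.asarray(data["y"], dtype=float)
    order = np.argsort(wl)
    wl, ab = wl[order], ab[order]
    grid = _grid_from_wavelengths(wl, str(path))
    return Spectrum(grid, ab, label if label is not None else path.stem)


def write_spectrum(s: Spectrum, path: PathLike) -> None:
    """Write a spectrum as two-column CSV with a header line."""
    with open(path, "w") as fh:
        fh.write("wavelength_nm,absorbance\n")
        for w, a in zip(s.grid.wavelengths, s.absorbance):
            fh.write(f"{_FMT % w},{_FMT % a}\n")


def write_map(corr_map: CorrelationMap, path: PathLike) -> None:
    """Write a correlation map as a self-describing CSV matrix.

    Layout: ``#`` metadata lines (kind and trace labels), then a first row
    holding the nu2 wavelengths, then one row per nu1 wavelength with the
    map values.
    """
    wl = corr_map.grid.wavelengths
    with open(path, "w") as fh:
        fh.write(f"# kind={corr_map.kind}\n")
        fh.write(f"# sample={corr_map.sample_label}\n")
        fh.write(f"# reference={corr_map.reference_label}\n")
        fh.write("nu1\\nu2," + ",".join(_FMT % w for w in wl) + "\n")
        for i, w1 in enumerate(wl):
            row = ",".join(_FMT % v for v in corr_map.values[i])
            fh.write(f"{_FMT % w1},{row}\n")


def read_map(path: PathLike, kind: str | None = None) -> CorrelationMap:
    """Read a correlation map written by :func:`write_map`.

    ``kind`` overrides (or supplies, for files lacking metadata) the map
    kind; ragged rows or a mismatch between the axis lengths and the matrix
    body raise :class:`MapFormatError`.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, _, value = line.lstrip("# ").partition("=")
                    meta[key.strip()] = value.strip()
                continue
            rows.append(line.split(","))
    if len(rows) < 2:
        raise MapFormatError(f"{path}: no matrix body found")

    header, body = rows[0], rows[1:]
    try:
        nu2 = np.asarray([float(t) for t in header[1:]])
    except ValueError:
        raise MapFormatError(f"{path}: non-numeric nu2 axis row") from None
    p = nu2.size
    if len(body) != p:
        raise MapFormatError(
            f"{path}: matrix has {len(body)} rows but the nu2 axis lists {p} "
            "wavelengths (square map required)"
        )
    nu1 = np.empty(p)
    values = np.empty((p, p))
    for i, tokens in enumerate(body):
        if len(tokens) != p + 1:
            raise MapFormatError(
                f"{path}: row {i + 2} has {len(tokens)} fields, expected {p + 1}"
            )
        try:
            nu1[i] = float(tokens[0])
            values[i] = [float(t) for t in tokens[1:]]
        except ValueError:
            raise MapFormatError(f"{path}: non-numeric value in row {i + 2}") from None
    if not np.allclose(nu1, nu2, rtol=0, atol=1e-9):
        raise MapFormatError(f"{path}: nu1 and nu2 axes differ; expected a shared grid")

    grid = _grid_from_wavelengths(nu1, str(path))
    map_kind = kind or meta.get("kind")
    if map_kind not in (SYNCHRONOUS, ASYNCHRONOUS):
        raise MapFormatError(
            f"{path}: map kind missing or unknown ({map_kind!r}); pass kind= explicitly"
        )
    return CorrelationMap(
        map_kind,
        grid,
        values,
        sample_label=meta.get("sample", ""),
        reference_label=meta.get("reference", ""),
    )
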