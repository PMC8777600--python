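"""Wavelength grids and absorbance-spectrum containers.

UV-Vis absorbance spectra live on uniform wavelength grids. The analysis
grid used throughout the screening pipeline spans 245-410 nm at 1 nm
resolution (166 points, both endpoints sampled), covering the two flavonoid
absorption bands: band II (benzoyl, ~240-280 nm) and band I (cinnamoyl,
~320-385 nm).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridError",
    "GridMismatchError",
    "RangeError",
    "WavelengthGrid",
    "Spectrum",
    "SpectrumPair",
    "DEFAULT_GRID",
    "resample",
]


class GridError(ValueError):
    """Invalid wavelength-grid specification."""


class GridMismatchError(GridError):
    """Two spectra or maps that must share a grid do not."""


class RangeError(GridError):
    """Requested wavelengths fall outside the data's wavelength range."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform, inclusive wavelength grid in nanometres.

    Both ``start`` and ``stop`` are sampled, so the number of points is
    ``(stop - start) / step + 1``.
    """

    start: float = 245.0
    stop: float = 410.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if not self.start < self.stop:
            raise GridError(f"grid start ({self.start}) must be < stop ({self.stop})")
        if self.step <= 0:
            raise GridError(f"grid step must be positive, got {self.step}")
        n = (self.stop - self.start) / self.step
        if abs(n - round(n)) > 1e-9:
            raise GridError(
                f"grid span {self.stop - self.start} nm is not an integer "
                f"multiple of step {self.step} nm"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    @property
    def wavelengths(self) -> np.ndarray:
        """The sampled wavelengths, ascending, endpoints included."""
        return self.start + self.step * np.arange(self.n_points)

    def __contains__(self, wavelength: float) -> bool:
        if wavelength < self.start - 1e-9 or wavelength > self.stop + 1e-9:
            return False
        k = (wavelength - self.start) / self.step
        return abs(k - round(k)) <= 1e-9


#: 245-410 nm at 1 nm: the pipeline's analysis grid (166 points).
DEFAULT_GRID = WavelengthGrid(245.0, 410.0, 1.0)


@dataclass
class Spectrum:
    """A single absorbance spectrum on a uniform wavelength grid.

    Absorbance is in dimensionless absorbance units (AU). Negative values
    are allowed (baseline noise); non-finite values are not.
    """

    grid: WavelengthGrid
    absorbance: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 1:
            raise ValueError(f"absorbance must be 1-D, got shape {a.shape}")
        if a.size != self.grid.n_points:
            raise ValueError(
                f"absorbance length {a.size} does not match grid point "
                f"count {self.grid.n_points}"
            )
        if not np.all(np.isfinite(a)):
            raise ValueError("absorbance contains non-finite values")
        self.absorbance = a

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.wavelengths

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.grid, factor * self.absorbance, self.label)


@dataclass
class SpectrumPair:
    """The two extracts of one product: 80% methanol and water.

    The dual-solvent design exploits aglycone solubility: quercetin and
    kaempferol dissolve well in methanol but poorly in water, so an
    adulterated product shows band-I intensity in the methanolic extract
    that is weak or absent in the aqueous one.
    """

    methanol: Spectrum
    water: Spectrum
    product_id: str = ""

    def __post_init__(self) -> None:
        if self.methanol.grid != self.water.grid:
            raise GridMismatchError(
                f"extract spectra of {self.product_id!r} are on different grids"
            )

    @property
    def grid(self) -> WavelengthGrid:
        return self.methanol.grid


def resample(s: Spectrum, grid: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``grid``.

    The target grid must lie within the source wavelength range: no
    extrapolation is ever performed. Values at wavelengths shared between
    the two grids are passed through unchanged.
    """
    src = s.grid.wavelengths
    tgt = grid.wavelengths
    if tgt[0] < src[0] - 1e-9 or tgt[-1] > src[-1] + 1e-9:
        raise RangeError(
            f"target grid {grid.start}-{grid.stop} nm extends beyond the "
            f"source range {s.grid.start}-{s.grid.stop} nm; refusing to "
            "extrapolate"
        )
    values = np.interp(tgt, src, s.absorbance)
    return Spectrum(grid, values, s.label)
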