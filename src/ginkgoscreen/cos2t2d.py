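"""Two-trace two-dimensional correlation spectroscopy (2T2D COS).

A pair of spectra — one *sample* spectrum s(nu) and one *reference*
spectrum r(nu) — is compared by constructing two p x p correlation maps
over all wavelength pairs (nu1, nu2):

    synchronous   Phi(nu1, nu2) = 1/2 [ s(nu1) s(nu2) + r(nu1) r(nu2) ]
    asynchronous  Psi(nu1, nu2) = 1/2 [ s(nu1) r(nu2) - r(nu1) s(nu2) ]

No perturbation series is needed: two traces suffice. The asynchronous map
is antisymmetric with a zero diagonal and vanishes identically whenever the
two spectra are proportional, so its cross peaks flag genuine differences in
relative band content — exactly what adulteration of a ginkgo extract with
cheap flavonols produces.

Three ways of pairing the spectra of a supplement cohort are supported:

* series A — methanolic extract vs. the same product's aqueous extract
  (exploits the poor water solubility of flavonol aglycones);
* series B — methanolic extract vs. an authentic ginkgo leaf-extract
  reference spectrum;
* series C — methanolic extract vs. the average of the three adulterant
  standards (rutin, quercetin, kaempferol), each scaled to unit area first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

from .spectral import GridMismatchError, Spectrum, WavelengthGrid

if TYPE_CHECKING:  # pragma: no cover
    from .synth import CohortDataset

__all__ = [
    "SYNCHRONOUS",
    "ASYNCHRONOUS",
    "MapKindError",
    "NormalizationError",
    "SeriesConfigurationError",
    "CorrelationMap",
    "MapStack",
    "CrossPeak",
    "synchronous_map",
    "asynchronous_map",
    "averaged_adulterant_reference",
    "build_series",
    "detect_cross_peaks",
]

SYNCHRONOUS = "synchronous"
ASYNCHRONOUS = "asynchronous"


class MapKindError(TypeError):
    """An operation received a correlation map of the wrong kind."""


class NormalizationError(ValueError):
    """A spectrum could not be scaled to unit area."""


class SeriesConfigurationError(ValueError):
    """A series build is missing its required reference input."""


@dataclass
class CorrelationMap:
    """A p x p synchronous or asynchronous 2T2D correlation map.

    Rows index nu1 (the sample axis), columns index nu2 (the reference
    axis); values are in AU^2.
    """

    kind: str
    grid: WavelengthGrid
    values: np.ndarray
    sample_label: str = ""
    reference_label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in (SYNCHRONOUS, ASYNCHRONOUS):
            raise MapKindError(f"unknown map kind {self.kind!r}")
        v = np.asarray(self.values, dtype=float)
        p = self.grid.n_points
        if v.shape != (p, p):
            raise ValueError(f"map shape {v.shape} does not match grid ({p}x{p})")
        self.values = v

    @property
    def n_points(self) -> int:
        return self.grid.n_points


@dataclass
class MapStack:
    """An ordered stack of correlation maps sharing one grid and kind.

    This is the three-way array (samples x nu1 x nu2) consumed by
    multiway PCA.
    """

    maps: list[CorrelationMap]
    sample_ids: list[str]
    series: str = ""

    def __post_init__(self) -> None:
        if not self.maps:
            raise ValueError("map stack is empty")
        if len(self.maps) != len(self.sample_ids):
            raise ValueError("number of maps and sample ids differ")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample ids are not unique")
        first = self.maps[0]
        for m in self.maps[1:]:
            if m.kind != first.kind:
                raise ValueError("maps in a stack must share one kind")
            if m.grid != first.grid:
                raise GridMismatchError("maps in a stack must share one grid")

    def __len__(self) -> int:
        return len(self.maps)

    @property
    def grid(self) -> WavelengthGrid:
        return self.maps[0].grid

    @property
    def kind(self) -> str:
        return self.maps[0].kind

    def as_array(self) -> np.ndarray:
        """The stack as an (n, p, p) array."""
        return np.stack([m.values for m in self.maps])


@dataclass(frozen=True)
class CrossPeak:
    """An off-diagonal local extremum of an asynchronous map.

    ``sign`` is +1 or -1, the sign of Psi at the peak; ``magnitude`` is
    |Psi| there. Only upper-triangle peaks (nu2 > nu1) are reported — the
    lower triangle holds their antisymmetric mirror images.
    """

    nu1: float
    nu2: float
    magnitude: float
    sign: int


def _check_same_grid(s: Spectrum, r: Spectrum) -> None:
    if s.grid != r.grid:
        raise GridMismatchError(
            "sample and reference spectra are on different grids; "
            "resample onto a common grid first"
        )


def synchronous_map(s: Spectrum, r: Spectrum) -> CorrelationMap:
    """Phi(nu1, nu2) = 1/2 [s(nu1) s(nu2) + r(nu1) r(nu2)] — symmetric."""
    _check_same_grid(s, r)
    values = 0.5 * (np.outer(s.absorbance, s.absorbance) + np.outer(r.absorbance, r.absorbance))
    return CorrelationMap(SYNCHRONOUS, s.grid, values, s.label, r.label)


def asynchronous_map(s: Spectrum, r: Spectrum) -> CorrelationMap:
    """Psi(nu1, nu2) = 1/2 [s(nu1) r(nu2) - r(nu1) s(nu2)] — antisymmetric.

    Psi vanishes identically when s and r are proportional, and its zero
    diagonal is exact by construction.
    """
    _check_same_grid(s, r)
    values = 0.5 * (np.outer(s.absorbance, r.absorbance) - np.outer(r.absorbance, s.absorbance))
    return CorrelationMap(ASYNCHRONOUS, s.grid, values, s.label, r.label)


def averaged_adulterant_reference(adulterants: Sequence[Spectrum]) -> Spectrum:
    """Average adulterant standards into one reference spectrum.

    Each input is first scaled to unit area (trapezoid-free sum x step),
    then the pointwise arithmetic mean is taken. The pre-scaling makes the
    average invariant to the (unknown, arbitrary) standard concentrations,
    so no single compound dominates the reference.
    """
    if len(adulterants) < 2:
        raise ValueError("need at least two adulterant spectra to average")
    grid = adulterants[0].grid
    scaled = []
    for sp in adulterants:
        if sp.grid != grid:
            raise GridMismatchError("adulterant spectra are on different grids")
        area = float(np.sum(sp.absorbance) * grid.step)
        if area <= 0:
            raise NormalizationError(
                f"spectrum {sp.label!r} has nonpositive total area ({area:g}); "
                "cannot scale to unit area"
            )
        scaled.append(sp.absorbance / area)
    mean = np.mean(scaled, axis=0)
    label = "mean(" + ",".join(sp.label or "?" for sp in adulterants) + ")"
    return Spectrum(grid, mean, label)


def build_series(cohort: "CohortDataset", series: str) -> MapStack:
    """Assemble one asynchronous map per product for series A, B or C.

    The sample spectrum is always the product's 80% methanolic extract;
    the reference depends on the series (see module docstring).
    """
    if series not in ("A", "B", "C"):
        raise SeriesConfigurationError(f"unknown series {series!r}; expected A, B or C")
    if series == "B" and cohort.reference_extract is None:
        raise SeriesConfigurationError(
            "series B requires the authentic ginkgo reference-extract spectrum"
        )
    if series == "C":
        if not cohort.adulterant_spectra:
            raise SeriesConfigurationError(
                "series C requires the adulterant standard spectra"
            )
        names = sorted(cohort.adulterant_spectra)
        reference = averaged_adulterant_reference(
            [cohort.adulterant_spectra[n] for n in names]
        )

    maps: list[CorrelationMap] = []
    ids: list[str] = []
    for product in cohort.products:
        s = product.spectra.methanol
        if series == "A":
            r = product.spectra.water
        elif series == "B":
            r = cohort.reference_extract
        else:
            r = reference
        maps.append(asynchronous_map(s, r))
        ids.append(product.product_id)
    return MapStack(maps, ids, series)


def detect_cross_peaks(
    corr_map: CorrelationMap,
    rel_threshold: float = 0.10,
    min_offdiag: float = 5.0,
    merge_radius: float = 4.0,
) -> list[CrossPeak]:
    """Locate cross peaks of an asynchronous map.

    A cross peak is a grid point that is an 8-neighbour local maximum of
    |Psi| with

    * |Psi| >= ``rel_threshold`` x max|Psi| over the map,
    * |nu1 - nu2| >= ``min_offdiag`` nm (diagonal ridge excluded),
    * nu2 > nu1 (upper triangle; lower-triangle peaks are mirror images).

    Peaks closer than ``merge_radius`` nm (Chebyshev distance in the
    (nu1, nu2) plane) are merged keeping the largest; among exact ties the
    lexicographically lowest (nu1, nu2) wins, so a flat plateau reports its
    lowest corner. The result is sorted by descending magnitude.
    """
    if corr_map.kind != ASYNCHRONOUS:
        raise MapKindError("cross-peak detection operates on asynchronous maps")
    if not 0.0 < rel_threshold < 1.0:
        raise ValueError("rel_threshold must lie strictly between 0 and 1")

    mag = np.abs(corr_map.values)
    vmax = float(mag.max())
    if vmax == 0.0:
        return []

    # 8-neighbour local maxima (plateau points all qualify).
    from scipy.ndimage import maximum_filter

    neighborhood_max = maximum_filter(mag, size=3, mode="constant", cval=-np.inf)
    is_peak = mag >= neighborhood_max

    wl = corr_map.grid.wavelengths
    nu1 = wl[:, None]
    nu2 = wl[None, :]
    is_peak &= mag >= rel_threshold * vmax
    is_peak &= np.abs(nu1 - nu2) >= min_offdiag - 1e-9
    is_peak &= nu2 > nu1

    ii, jj = np.nonzero(is_peak)
    # Descending magnitude; ties broken toward the lexicographically lowest
    # (nu1, nu2) so plateaus resolve deterministically.
    order = np.lexsort((jj, ii, -mag[ii, jj]))
    accepted: list[tuple[int, int]] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        too_close = any(
            max(abs(wl[i] - wl[ai]), abs(wl[j] - wl[aj])) < merge_radius - 1e-9
            for ai, aj in accepted
        )
        if not too_close:
            accepted.append((i, j))

    return [
        CrossPeak(
            nu1=float(wl[i]),
            nu2=float(wl[j]),
            magnitude=float(mag[i, j]),
            sign=1 if corr_map.values[i, j] > 0 else -1,
        )
        for i, j in accepted
    ]
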