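"""Synthetic UV-Vis cohorts of (possibly adulterated) ginkgo supplements.

The screening method rests on a small set of spectroscopic facts about
flavonols dissolved in 80% methanol vs. water:

* each flavonol shows two absorption bands — band II (benzoyl, 240-280 nm)
  and band I (cinnamoyl, 320-385 nm) — with maxima at 257/355 nm for rutin,
  255/368 nm for quercetin and 265/365 nm for kaempferol;
* absorbances of the components of a mixture add;
* the aglycones quercetin and kaempferol dissolve well in methanol but
  poorly in water, while rutin (a glycoside) and the ginkgo leaf-extract
  matrix extract comparably in both solvents.

This module emulates exactly those facts and nothing more. Components are
sums of Gaussian bands, extracts are noisy nonnegative linear mixtures
scaled by solvent-dependent extraction fractions, and cohorts are drawn
from archetype presets (rutin-adulterated, quercetin-adulterated,
quercetin+kaempferol-adulterated, ginkgo-free, authentic) with lognormal
amount jitter. The generator also emits the ground-truth flavonol
percentage table that the HCA stage consumes, plus the reference-extract
and adulterant standard spectra the correlation series need.

The published 20-product flavonol table ships as a packaged fixture
(:func:`load_table1`); the raw study spectra were never deposited, which is
what this generator stands in for.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .hca import FlavonolTable
from .spectral import DEFAULT_GRID, Spectrum, SpectrumPair, WavelengthGrid

__all__ = [
    "CompositionError",
    "EmptyCohortError",
    "ComponentBandModel",
    "SupplementComposition",
    "ProductRecord",
    "CohortDataset",
    "CohortConfig",
    "DEFAULT_LIBRARY",
    "ARCHETYPES",
    "ARCHETYPE_PRESETS",
    "METHANOL80",
    "WATER",
    "component_spectrum",
    "simulate_extract",
    "simulate_cohort",
    "load_table1",
]

METHANOL80 = "methanol80"
WATER = "water"
_SOLVENTS = (METHANOL80, WATER)


class CompositionError(KeyError):
    """A composition references a component absent from the band library."""


class EmptyCohortError(ValueError):
    """A cohort request with no products at all."""


@dataclass(frozen=True)
class ComponentBandModel:
    """Gaussian band model of one mixture component.

    ``bands`` is a tuple of (center_nm, sigma_nm, height_AU) triples;
    ``f_methanol``/``f_water`` are the fractions of the component carried
    into the 80% methanol and aqueous extracts (solubility surrogates).
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]
    f_methanol: float
    f_water: float

    def __post_init__(self) -> None:
        for center, sigma, height in self.bands:
            if not 200.0 <= center <= 500.0:
                raise ValueError(f"{self.name}: band center {center} nm outside 200-500 nm")
            if sigma <= 0 or height <= 0:
                raise ValueError(f"{self.name}: band widths and heights must be positive")
        for f in (self.f_methanol, self.f_water):
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{self.name}: extraction fractions must lie in [0, 1]")

    def fraction(self, solvent: str) -> float:
        if solvent == METHANOL80:
            return self.f_methanol
        if solvent == WATER:
            return self.f_water
        raise ValueError(f"unknown solvent {solvent!r}; expected one of {_SOLVENTS}")


#: Default component library. Band maxima follow the flavonol literature
#: (rutin 257/355 nm, quercetin 255/368 nm, kaempferol 265/365 nm); widths,
#: height ratios, the ginkgo-matrix model and the extraction fractions are
#: generator choices, not measured quantities (see docs/methods.md). The
#: ginkgo matrix is a deliberately non-physical stand-in: a
#: flavonol-glycoside-like band pair plus a broad short-wavelength shoulder.
DEFAULT_LIBRARY: dict[str, ComponentBandModel] = {
    "rutin": ComponentBandModel(
        "rutin", ((257.0, 12.0, 1.0), (355.0, 18.0, 1.0)), f_methanol=0.9, f_water=0.5
    ),
    "quercetin": ComponentBandModel(
        "quercetin", ((255.0, 12.0, 1.0), (368.0, 18.0, 1.0)), f_methanol=0.95, f_water=0.10
    ),
    "kaempferol": ComponentBandModel(
        "kaempferol", ((265.0, 12.0, 1.0), (365.0, 18.0, 0.9)), f_methanol=0.95, f_water=0.10
    ),
    "ginkgo_matrix": ComponentBandModel(
        "ginkgo_matrix",
        ((265.0, 12.0, 1.0), (350.0, 18.0, 1.0), (255.0, 25.0, 0.6)),
        f_methanol=0.9,
        f_water=0.9,
    ),
    "foreign_matrix": ComponentBandModel(
        "foreign_matrix", ((272.0, 14.0, 1.0), (338.0, 20.0, 0.9)), f_methanol=0.9, f_water=0.85
    ),
}

ARCHETYPES = (
    "authentic",
    "rutin_adulterated",
    "quercetin_adulterated",
    "quercetin_kaempferol_adulterated",
    "no_ginkgo",
)

#: Mean component amounts per archetype (arbitrary concentration units).
#: Adulterant-to-matrix ratios are large, mirroring the adulteration levels
#: implied by chromatographic peak-area percentages dominated by one
#: flavonol.
ARCHETYPE_PRESETS: dict[str, dict[str, float]] = {
    "authentic": {"ginkgo_matrix": 1.0},
    "rutin_adulterated": {"ginkgo_matrix": 1.0, "rutin": 6.0},
    "quercetin_adulterated": {"ginkgo_matrix": 1.0, "quercetin": 5.0},
    "quercetin_kaempferol_adulterated": {
        "ginkgo_matrix": 1.0,
        "quercetin": 3.0,
        "kaempferol": 3.0,
    },
    "no_ginkgo": {"foreign_matrix": 1.0},
}


@dataclass(frozen=True)
class SupplementComposition:
    """Ground-truth component amounts of one simulated product."""

    amounts: dict[str, float]
    archetype: str = ""

    def __post_init__(self) -> None:
        if self.archetype and self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        if any(a < 0 for a in self.amounts.values()):
            raise ValueError("component amounts must be nonnegative")
        if not any(a > 0 for a in self.amounts.values()):
            raise ValueError("composition needs at least one positive amount")


@dataclass
class ProductRecord:
    """One simulated product: id, ground truth, and its two extract spectra."""

    product_id: str
    composition: SupplementComposition
    spectra: SpectrumPair


@dataclass
class CohortDataset:
    """A complete simulated study: products plus the series references."""

    products: list[ProductRecord]
    reference_extract: Spectrum
    adulterant_spectra: dict[str, Spectrum]
    flavonol_table: FlavonolTable
    seed: int

    @property
    def product_ids(self) -> list[str]:
        return [p.product_id for p in self.products]

    @property
    def archetypes(self) -> list[str]:
        return [p.composition.archetype for p in self.products]


@dataclass(frozen=True)
class CohortConfig:
    """Tunable study conditions of the generator.

    ``noise_sigma`` is the standard deviation of the additive iid Gaussian
    absorbance noise (AU); ``jitter`` the lognormal sigma of per-product
    relative amount variation (0.15 = roughly +/-15%).
    """

    noise_sigma: float = 0.002
    jitter: float = 0.15
    grid: WavelengthGrid = DEFAULT_GRID
    presets: dict[str, dict[str, float]] = field(
        default_factory=lambda: dict(ARCHETYPE_PRESETS)
    )


def component_spectrum(model: ComponentBandModel, grid: WavelengthGrid) -> Spectrum:
    """Noise-free pure-component spectrum: a sum of Gaussian bands,

    A(nu) = sum_b height_b * exp(-(nu - center_b)^2 / (2 sigma_b^2)).
    """
    nu = grid.wavelengths
    a = np.zeros_like(nu)
    for center, sigma, height in model.bands:
        a += height * np.exp(-((nu - center) ** 2) / (2.0 * sigma**2))
    return Spectrum(grid, a, model.name)


def _mixture(
    composition: SupplementComposition,
    library: dict[str, ComponentBandModel],
    solvent: str,
    grid: WavelengthGrid,
) -> np.ndarray:
    total = np.zeros(grid.n_points)
    for name, amount in composition.amounts.items():
        if name not in library:
            raise CompositionError(
                f"component {name!r} not found in the band library "
                f"(available: {sorted(library)})"
            )
        model = library[name]
        total += amount * model.fraction(solvent) * component_spectrum(model, grid).absorbance
    return total


def simulate_extract(
    composition: SupplementComposition,
    library: dict[str, ComponentBandModel] | None = None,
    solvent: str = METHANOL80,
    noise_sigma: float = 0.0,
    seed: int | np.random.Generator | None = None,
    grid: WavelengthGrid = DEFAULT_GRID,
    label: str = "",
) -> Spectrum:
    """Simulate one extract spectrum of a multicomponent product.

    A(nu) = sum_c amount_c * f_solvent(c) * component_c(nu) + eps(nu),
    with eps iid Gaussian(0, noise_sigma^2). Reproducible for a fixed seed.
    """
    library = DEFAULT_LIBRARY if library is None else library
    values = _mixture(composition, library, solvent, grid)
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, grid.n_points)
    return Spectrum(grid, values, label or f"{composition.archetype or 'mixture'}:{solvent}")


def _flavonol_percentages(composition: SupplementComposition) -> np.ndarray:
    """Ground-truth %R/%Q/%K: each flavonol amount over the total amount."""
    total = sum(composition.amounts.values())
    return np.array(
        [100.0 * composition.amounts.get(c, 0.0) / total for c in ("rutin", "quercetin", "kaempferol")]
    )


def simulate_cohort(
    n_per_archetype: dict[str, int],
    config: CohortConfig | None = None,
    seed: int = 0,
    library: dict[str, ComponentBandModel] | None = None,
) -> CohortDataset:
    """Simulate a labelled supplement cohort.

    Products are generated archetype by archetype in the canonical
    :data:`ARCHETYPES` order, so archetype labels depend only on the counts,
    never on the seed. Each product draws from an independent child RNG
    seeded by (root seed, product index): enlarging the cohort does not
    reshuffle earlier products, and regeneration from the same seed is
    bit-identical.
    """
    config = config or CohortConfig()
    library = DEFAULT_LIBRARY if library is None else library
    for archetype, count in n_per_archetype.items():
        if archetype not in config.presets:
            raise ValueError(f"unknown archetype {archetype!r}")
        if count < 0:
            raise ValueError(f"negative count for archetype {archetype!r}")
    if sum(n_per_archetype.values()) == 0:
        raise EmptyCohortError("cohort has no products")

    grid = config.grid
    products: list[ProductRecord] = []
    percentages: list[np.ndarray] = []
    index = 0
    for archetype in ARCHETYPES:
        count = n_per_archetype.get(archetype, 0)
        preset = config.presets.get(archetype, ARCHETYPE_PRESETS.get(archetype, {}))
        for _ in range(count):
            rng = np.random.default_rng(np.random.SeedSequence((seed, index)))
            if config.jitter > 0:
                amounts = {
                    name: mean * float(np.exp(rng.normal(0.0, config.jitter)))
                    for name, mean in preset.items()
                }
            else:
                amounts = dict(preset)
            composition = SupplementComposition(amounts, archetype)
            product_id = f"P{index + 1:02d}"
            meoh = simulate_extract(
                composition, library, METHANOL80, config.noise_sigma, rng, grid,
                label=f"{product_id}:meoh",
            )
            water = simulate_extract(
                composition, library, WATER, config.noise_sigma, rng, grid,
                label=f"{product_id}:water",
            )
            products.append(
                ProductRecord(product_id, composition, SpectrumPair(meoh, water, product_id))
            )
            percentages.append(_flavonol_percentages(composition))
            index += 1

    reference = simulate_extract(
        SupplementComposition({"ginkgo_matrix": 1.0}, "authentic"),
        library, METHANOL80, 0.0, None, grid, label="GB-XRM",
    )
    adulterants = {
        name: simulate_extract(
            SupplementComposition({name: 1.0}), library, METHANOL80, 0.0, None, grid,
            label=name,
        )
        for name in ("rutin", "quercetin", "kaempferol")
    }
    table = FlavonolTable([p.product_id for p in products], np.array(percentages))
    return CohortDataset(products, reference, adulterants, table, seed)


def load_table1() -> FlavonolTable:
    """Load the packaged 20-product chromatographic flavonol table (S1-S20)."""
    resource = importlib.resources.files("ginkgoscreen").joinpath(
        "data/table1_flavonols.csv"
    )
    try:
        with resource.open() as fh:
            df = pd.read_csv(fh, index_col=0)
    except FileNotFoundError:  # pragma: no cover - packaging defect
        raise RuntimeError(
            "packaged flavonol table is missing; reinstall the package"
        ) from None
    if df.shape != (20, 3):
        raise RuntimeError(f"packaged flavonol table is corrupt (shape {df.shape})")
    return FlavonolTable.from_frame(df)
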