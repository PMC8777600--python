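"""End-to-end screening runs: simulate -> correlate -> peaks / MPCA; HCA.

A run is described by a flat key/value configuration (see
:class:`RunConfig`), executes its stages in order, writes every
intermediate artifact as plain text, and finishes with a JSON manifest
recording the configuration, the seed, and a SHA-256 checksum of every
output file — re-running the same configuration is bit-identical, which the
manifest makes checkable without parsing any artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np

from . import io as gio
from .cos2t2d import build_series, detect_cross_peaks
from .hca import cluster_flavonols
from .mpca import cross_validate, fit_stack, unfold
from .synth import ARCHETYPES, CohortConfig, CohortDataset, simulate_cohort

__all__ = ["ConfigurationError", "RunConfig", "run_pipeline", "write_cohort"]

log = logging.getLogger("ginkgoscreen")


class ConfigurationError(ValueError):
    """An invalid or incomplete run configuration."""


@dataclass
class RunConfig:
    """Flat configuration of a full screening run.

    ``counts`` maps archetype name to product count. ``series`` lists which
    correlation series to build (subset of A/B/C). MPCA and peak-detector
    settings mirror the corresponding function defaults.
    """

    seed: int = 0
    simulate: bool = True
    spectra_dir: str = ""  # file mode: directory of <id>_meoh.csv / <id>_water.csv
    reference_path: str = ""  # file mode: authentic reference spectrum (series B)
    adulterant_dir: str = ""  # file mode: adulterant standard spectra (series C)
    counts: dict[str, int] = field(
        default_factory=lambda: {
            "rutin_adulterated": 4,
            "quercetin_adulterated": 4,
            "no_ginkgo": 4,
        }
    )
    noise_sigma: float = 0.002
    jitter: float = 0.15
    series: tuple[str, ...] = ("A", "B")
    peaks_threshold: float = 0.10
    peaks_min_offdiag: float = 5.0
    peaks_merge_radius: float = 4.0
    mpca_components: int = 3
    cv_splits: int = 0  # 0 disables cross-validation
    cv_per_blind: int = 2
    cv_order: str = "blocked"
    scale_offset: float = 1e-5
    hca_k: int = 4

    def validate(self) -> None:
        for s in self.series:
            if s not in ("A", "B", "C"):
                raise ConfigurationError(f"unknown series {s!r}")
        if self.simulate:
            if not self.counts or sum(self.counts.values()) == 0:
                raise ConfigurationError("cohort counts are empty")
            for a in self.counts:
                if a not in ARCHETYPES:
                    raise ConfigurationError(f"unknown archetype {a!r}")
            n = sum(self.counts.values())
            if self.cv_splits and n < self.cv_splits:
                raise ConfigurationError(
                    f"cv_splits={self.cv_splits} exceeds the cohort size {n}"
                )
        else:
            if not self.spectra_dir:
                raise ConfigurationError("file mode requires spectra_dir")
            if "B" in self.series and not self.reference_path:
                raise ConfigurationError(
                    "series B requires a reference spectrum: set reference_path "
                    "or enable simulation"
                )
            if "C" in self.series and not self.adulterant_dir:
                raise ConfigurationError(
                    "series C requires adulterant standard spectra: set "
                    "adulterant_dir or enable simulation"
                )

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Parse a flat ``key = value`` / ``key: value`` text config."""
        values: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            sep = "=" if "=" in line else ":"
            if sep not in line:
                raise ConfigurationError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition(sep)
            values[key.strip()] = value.strip()
        kwargs: dict = {}
        known = {f.name: f for f in fields(cls)}
        counts: dict[str, int] = {}
        for key, value in values.items():
            if key.startswith("count."):
                counts[key.removeprefix("count.")] = int(value)
            elif key == "series":
                kwargs["series"] = tuple(t.strip() for t in value.split(",") if t.strip())
            elif key in known:
                if key in ("seed", "mpca_components", "cv_splits", "cv_per_blind", "hca_k"):
                    kwargs[key] = int(value)
                elif key == "simulate":
                    kwargs[key] = value.lower() in ("1", "true", "yes", "on")
                elif key in ("cv_order", "spectra_dir", "reference_path", "adulterant_dir"):
                    kwargs[key] = value
                else:
                    kwargs[key] = float(value)
            else:
                raise ConfigurationError(f"unknown configuration key {key!r}")
        if counts:
            kwargs["counts"] = counts
        return cls(**kwargs)

    def to_flat_dict(self) -> dict:
        d = asdict(self)
        d["series"] = ",".join(self.series)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_cohort(cohort: CohortDataset, out_dir: str | Path) -> list[Path]:
    """Write a cohort's spectra, labels and flavonol table as CSV files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for product in cohort.products:
        for suffix, spectrum in (
            ("meoh", product.spectra.methanol),
            ("water", product.spectra.water),
        ):
            path = out / f"{product.product_id}_{suffix}.csv"
            gio.write_spectrum(spectrum, path)
            written.append(path)
    path = out / "reference_extract.csv"
    gio.write_spectrum(cohort.reference_extract, path)
    written.append(path)
    for name, spectrum in sorted(cohort.adulterant_spectra.items()):
        path = out / f"adulterant_{name}.csv"
        gio.write_spectrum(spectrum, path)
        written.append(path)
    labels = out / "labels.csv"
    with open(labels, "w") as fh:
        fh.write("product_id,archetype\n")
        for product in cohort.products:
            fh.write(f"{product.product_id},{product.composition.archetype}\n")
    written.append(labels)
    table = out / "flavonols.csv"
    cohort.flavonol_table.to_frame().rename_axis("product_id").to_csv(table)
    written.append(table)
    return written


def load_cohort(
    spectra_dir: str | Path,
    reference_path: str | Path | None = None,
    adulterant_dir: str | Path | None = None,
) -> CohortDataset:
    """Assemble a cohort from measured spectrum files.

    ``spectra_dir`` must hold one ``<id>_meoh.csv`` and one
    ``<id>_water.csv`` per product; all spectra are resampled onto the
    default 245-410 nm analysis grid. ``adulterant_dir`` holds one CSV per
    adulterant standard, named after the compound. No flavonol table is
    available in file mode.
    """
    from .spectral import DEFAULT_GRID, SpectrumPair, resample
    from .synth import ProductRecord, SupplementComposition

    spectra_dir = Path(spectra_dir)
    meoh_files = sorted(spectra_dir.glob("*_meoh.csv"))
    if not meoh_files:
        raise ConfigurationError(f"no *_meoh.csv spectra found in {spectra_dir}")
    products: list[ProductRecord] = []
    for meoh_path in meoh_files:
        pid = meoh_path.name.removesuffix("_meoh.csv")
        water_path = spectra_dir / f"{pid}_water.csv"
        if not water_path.exists():
            raise ConfigurationError(f"missing aqueous-extract spectrum {water_path}")
        meoh = resample(gio.read_spectrum(meoh_path), DEFAULT_GRID)
        water = resample(gio.read_spectrum(water_path), DEFAULT_GRID)
        # File mode carries no ground truth; a unit placeholder composition
        # keeps the container contract satisfied.
        composition = SupplementComposition({"ginkgo_matrix": 1.0})
        products.append(ProductRecord(pid, composition, SpectrumPair(meoh, water, pid)))
    reference = None
    if reference_path:
        reference = resample(gio.read_spectrum(reference_path), DEFAULT_GRID)
    adulterants: dict[str, Spectrum] = {}
    if adulterant_dir:
        for path in sorted(Path(adulterant_dir).glob("*.csv")):
            adulterants[path.stem] = resample(gio.read_spectrum(path), DEFAULT_GRID)
    from .hca import FlavonolTable

    placeholder = FlavonolTable(
        [p.product_id for p in products],
        np.zeros((len(products), 3)),
    )
    return CohortDataset(products, reference, adulterants, placeholder, seed=-1)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute a full screening run; returns the manifest dictionary."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if config.simulate:
        log.info(
            "simulate: %d products, seed %d", sum(config.counts.values()), config.seed
        )
        cohort = simulate_cohort(
            config.counts,
            CohortConfig(noise_sigma=config.noise_sigma, jitter=config.jitter),
            seed=config.seed,
        )
        written += write_cohort(cohort, out / "cohort")
    else:
        log.info("loading measured spectra from %s", config.spectra_dir)
        cohort = load_cohort(
            config.spectra_dir,
            config.reference_path or None,
            config.adulterant_dir or None,
        )

    for series in config.series:
        stack = build_series(cohort, series)
        series_dir = out / f"series_{series}"
        series_dir.mkdir(exist_ok=True)
        for pid, corr_map in zip(stack.sample_ids, stack.maps):
            path = series_dir / f"{pid}_async.csv"
            gio.write_map(corr_map, path)
            written.append(path)
        log.info("series %s: %d asynchronous maps", series, len(stack))

        peaks_path = series_dir / "peaks.csv"
        with open(peaks_path, "w") as fh:
            fh.write("product_id,nu1_nm,nu2_nm,magnitude,sign\n")
            for pid, corr_map in zip(stack.sample_ids, stack.maps):
                for pk in detect_cross_peaks(
                    corr_map,
                    rel_threshold=config.peaks_threshold,
                    min_offdiag=config.peaks_min_offdiag,
                    merge_radius=config.peaks_merge_radius,
                ):
                    sign = "+" if pk.sign > 0 else "-"
                    fh.write(f"{pid},{pk.nu1:g},{pk.nu2:g},{pk.magnitude:.10e},{sign}\n")
        written.append(peaks_path)

        n = len(stack)
        if config.mpca_components <= n - 1:
            model = fit_stack(stack, config.mpca_components, offset=config.scale_offset)
            written += _write_mpca(model, stack, series_dir, config)
        else:
            log.info("series %s: too few samples for MPCA, skipped", series)

    if config.simulate and len(cohort.products) >= max(2, config.hca_k):
        written += _write_hca(cohort, out, config)
    elif config.simulate:
        log.info("hca: fewer products than clusters requested, skipped")

    manifest = {
        "config": config.to_flat_dict(),
        "seed": config.seed,
        "outputs": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(written)
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    log.info("wrote %d artifacts and manifest to %s", len(written), out)
    return manifest


def _write_hca(cohort: CohortDataset, out: Path, config: RunConfig) -> list[Path]:
    written: list[Path] = []
    dend, partition = cluster_flavonols(cohort.flavonol_table, k=config.hca_k)
    hca_dir = out / "hca"
    hca_dir.mkdir(exist_ok=True)
    merges = hca_dir / "merges.csv"
    with open(merges, "w") as fh:
        fh.write("cluster_a,cluster_b,height,new_size\n")
        for a, b, h, size in dend.merges:
            fh.write(f"{a},{b},{h:.12g},{size}\n")
    written.append(merges)
    part_path = hca_dir / "partition.csv"
    with open(part_path, "w") as fh:
        fh.write("product_id,cluster\n")
        for pid, lab in zip(partition.product_ids, partition.labels):
            fh.write(f"{pid},{lab}\n")
    written.append(part_path)
    return written


def _write_mpca(model, stack, series_dir: Path, config: RunConfig) -> list[Path]:
    written: list[Path] = []
    scores_path = series_dir / "mpca_scores.csv"
    with open(scores_path, "w") as fh:
        fh.write("product_id," + ",".join(f"PC{i+1}" for i in range(model.n_components)) + "\n")
        for pid, row in zip(stack.sample_ids, model.scores):
            fh.write(pid + "," + ",".join(f"{v:.12g}" for v in row) + "\n")
    written.append(scores_path)

    summary_path = series_dir / "mpca_summary.csv"
    rmsecv = None
    if config.cv_splits:
        rmsecv = cross_validate(
            unfold(stack),
            model.n_components,
            n_splits=config.cv_splits,
            per_blind=config.cv_per_blind,
            order=config.cv_order,
            offset=config.scale_offset,
        ).rmsecv_per_k
    with open(summary_path, "w") as fh:
        fh.write("component,explained_variance_pct,cumulative_pct,rmsec,rmsecv\n")
        cumulative = model.cumulative_variance_pct
        for i in range(model.n_components):
            cv = f"{rmsecv[i]:.12g}" if rmsecv is not None else ""
            fh.write(
                f"{i+1},{model.explained_variance_pct[i]:.12g},"
                f"{cumulative[i]:.12g},{model.rmsec_per_k[i]:.12g},{cv}\n"
            )
    written.append(summary_path)

    for i in range(model.n_components):
        from .cos2t2d import CorrelationMap

        loading = CorrelationMap(
            stack.kind, stack.grid, model.loading_map(i),
            sample_label=f"loading PC{i+1}", reference_label="",
        )
        path = series_dir / f"mpca_loading_pc{i+1}.csv"
        gio.write_map(loading, path)
        written.append(path)
    return written
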