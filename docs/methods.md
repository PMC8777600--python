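# Methods

## Scope and data model

The package screens herbal products for flavonol adulteration from UV-Vis
absorbance spectra of two extracts per product (80% methanol and water).
All analysis happens on a uniform wavelength grid; the default analysis
grid spans 245–410 nm at 1 nm with both endpoints sampled (166 points).
Spectra are dimensionless absorbance (AU); negative baseline-noise values
are allowed and no absorbance floor or ceiling is enforced, since dilution
factors of real extracts are unknown. File readers accept two-column
CSV/whitespace text (optional single header line) and require strictly
monotone, uniformly spaced wavelengths — a spectrum container with
start/stop/step semantics cannot faithfully hold irregular samplings, so
irregular files are rejected rather than silently regularized. Resampling
onto the analysis grid is piecewise-linear and never extrapolates: UV-Vis
bands at 1 nm are smooth enough that linear interpolation is innocuous,
whereas padding outside the measured range would fabricate data.

## Two-trace correlation maps

For sample s(ν) and reference r(ν) on one grid,

* synchronous: Φ(ν₁,ν₂) = ½[s(ν₁)s(ν₂) + r(ν₁)r(ν₂)] (symmetric),
* asynchronous: Ψ(ν₁,ν₂) = ½[s(ν₁)r(ν₂) − r(ν₁)s(ν₂)] (antisymmetric,
  zero diagonal, identically zero for proportional traces).

Maps are computed on raw (resampled) absorbances, not on normalized
spectra: the defining products are bilinear in the traces, and the
concentration scale they inherit is removed later by per-sample
normalization in the MPCA preprocessing. Rows index ν₁ (sample axis) and
columns ν₂ (reference axis); this axis convention is fixed by the package
and stated in the map file header. Both map kinds are exposed, but the
screening pipeline consumes only asynchronous maps — difference
information is what adulteration produces.

Three series pair the traces: A (methanol vs. water extract of the same
product), B (methanol extract vs. authentic leaf-extract reference), C
(methanol extract vs. the mean of the rutin/quercetin/kaempferol standard
spectra). For series C each standard is scaled to unit area (sum × step)
before averaging; standard concentrations are arbitrary, and without the
pre-scaling one compound could dominate the mean.

## Cross-peak detection

A cross peak is an 8-neighbour local maximum of |Ψ| that (i) reaches at
least `rel_threshold` (default 0.10) of the map's global |Ψ| maximum,
(ii) lies at least `min_offdiag` (default 5 nm) off the diagonal, and
(iii) sits in the upper triangle ν₂ > ν₁ (the lower triangle holds the
antisymmetric mirrors). Peaks closer than `merge_radius` (default 4 nm,
Chebyshev distance) are merged keeping the largest; exact ties resolve to
the lexicographically lowest (ν₁, ν₂), so plateaus report their lowest
corner deterministically. The three thresholds are detector conventions,
not physical constants; they are exposed as CLI flags and the detector is
validated against an exhaustive brute-force scan in the test suite.

## Synthetic cohorts

The generator emulates exactly the facts the method exploits:

* **Band shapes.** Each component is a sum of Gaussian bands. Flavonol
  band centers follow the literature maxima — rutin 257/355 nm, quercetin
  255/368 nm, kaempferol 265/365 nm — with σ = 12 nm (band II) and 18 nm
  (band I) and band-I:band-II height ratios 1.0/1.0/0.9. Widths and
  ratios are not tabulated anywhere at this resolution; they were chosen
  once to give broad, strongly overlapping bands typical of flavonoid
  UV-Vis spectra.
* **Matrix models.** The authentic ginkgo matrix is a deliberately
  non-physical stand-in: a glycoside-like band pair at 265/350 nm plus a
  broad 255 nm shoulder (σ 25, height 0.6). A distinct "foreign matrix"
  (272/338 nm) represents products made from a different plant extract.
  Only their qualitative distinctness from the three adulterants matters.
* **Solvents.** Extraction fractions encode solubility: glycosides and
  matrices 0.9 in both solvents (rutin 0.9/0.5), the aglycones 0.95
  (methanol) vs. 0.10 (water). The magnitudes are plausible inventions;
  the *ordering* (aglycones nearly insoluble in water) is the modelled
  fact.
* **Mixing and noise.** A(ν) = Σ_c amount_c · f_solvent(c) ·
  component_c(ν) + ε, with ε iid Gaussian (default σ = 0.002 AU, a
  realistic photometric noise floor for a double-beam instrument).
* **Cohorts.** Archetype presets set mean amounts (matrix 1.0 plus rutin
  6.0, quercetin 5.0, or quercetin 3.0 + kaempferol 3.0; ginkgo-free
  products carry the foreign matrix alone), mirroring peak-area tables in
  which the adulterant dominates. Per-product amounts get ±15% lognormal
  jitter. Seeding is hierarchical: each product's RNG derives from
  (root seed, product index), so enlarging a cohort never reshuffles
  earlier products, and regeneration is bit-identical.
* **Flavonol table.** %R/%Q/%K are computed from the ground-truth amounts
  (flavonol amount over total amount × 100), not from simulated
  chromatograms — chromatography simulation is out of scope.

What the generator does **not** emulate: molar absorptivities,
pH/solvatochromic band shifts, baseline drift and scatter, instrument
bandwidth, or intra-archetype composition diversity beyond amount jitter.
Passing tests therefore demonstrate that the algorithms behave correctly
on data with the assumed structure (additive bands, solvent contrast,
distinct matrices), not that the screen has any particular sensitivity or
specificity on real supplements.

## Multiway PCA

The map stack (n × p × p) is unfolded row-major to n × p² and refolded
losslessly. Preprocessing is rows first, then columns: (1) each sample row
is divided by its Euclidean norm (zero-norm rows are left unchanged and
flagged), which makes scores invariant to scaling any input map by a
positive constant; (2) each column is mean-centered and divided by
(standard deviation + offset), std with the n−1 denominator and additive
offset default 10⁻⁵ guarding near-constant columns. The row-then-column
order is a package convention, fixed and documented here because the two
orders do not commute.

Decomposition is economy SVD of the preprocessed matrix (for an unfolded
array, multiway PCA is definitionally ordinary PCA of the unfolding; the
test suite computes both paths). Scores are U·S, loadings the right
singular vectors with a deterministic sign convention (each loading
flipped so its largest-magnitude element is positive). Explained variance
per component is σᵢ²/Σσ². RMSEC(k) = √(Σ residual²/(n·p²)) for the rank-k
reconstruction; RMSECV uses venetian blinds: fold of sample i is
⌊i/per_blind⌋ mod n_splits ("blocked", the default; a strict interleave
i mod n_splits is available), preprocessing and SVD refit per training
fold, held-out rows preprocessed with the training parameters (each row
normalized by its own norm, then the stored column center/scale) and
reconstructed from 1..k components. Both error measures are in
preprocessed (unitless) coordinates and pool all n·p² matrix entries.
Projection of new maps applies the stored preprocessing rule and the
loading basis; projecting the training stack reproduces the training
scores.

## Hierarchical clustering of flavonol tables

Tables are mean-centered per column (no further standardization — all
three columns share percentage units), then clustered with Ward's
minimum-variance criterion on Euclidean distances via SciPy's linkage;
heights follow the distance ("ward.D2") convention with monotone merge
order. Flat partitions cut the tree into exactly k clusters and are
relabelled 1..k in first-seen row order for determinism; k = 4 is the
default reading for ginkgo supplement tables (rutin-dominant, quercetin-
dominant, mixed quercetin/kaempferol, low-flavonol). The implementation is
checked against a brute-force Ward oracle that recomputes within-cluster
sums of squares at every step. The number of clusters is an explicit
argument rather than a height threshold, since peak-area tables are small
and the analyst chooses k.

## Pipeline and reproducibility

`run_pipeline` executes simulate → correlation series → peak tables +
MPCA → HCA, writing every intermediate as plain text and finishing with a
JSON manifest of SHA-256 content checksums; identical config and seed
give identical checksums. A file mode consumes measured spectra
(`<id>_meoh.csv`/`<id>_water.csv`) instead of simulating; it requires an
explicit reference spectrum for series B and adulterant standards for
series C, and validates this before any computation. HCA is skipped
(logged) when fewer products than clusters are available, and MPCA when
the stack has fewer than components + 1 samples.

## Numerical conventions and limitations

* Map text files carry 17 significant digits; write/read round trips are
  exact to < 10⁻¹² relative error.
* Grid equality is exact on (start, stop, step); spectra on different
  grids must be resampled explicitly — no silent alignment.
* The acceptance script exercises desk-scale problems (166-point grids,
  single-product simulations, the 20-row packaged table), which complete
  in seconds.
* On real products, quercetin- and kaempferol-adulterated samples are
  hard to distinguish from each other (their band-I maxima differ by
  3 nm, well within band overlap); the generator reproduces this — both
  archetypes put their dominant series-A cross peak in the same
  365–380 nm window.
* The published 20-product flavonol table is shipped for clustering
  exactly as printed (two decimals); partitions derived from it can
  differ near cluster boundaries from partitions of higher-precision
  source data.
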