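"""Synchronous/asynchronous 2T2D maps, series assembly, cross-peak detection."""

import numpy as np
import pytest

from ginkgoscreen import (
    CohortConfig,
    Spectrum,
    WavelengthGrid,
    asynchronous_map,
    averaged_adulterant_reference,
    build_series,
    detect_cross_peaks,
    simulate_cohort,
    synchronous_map,
)
from ginkgoscreen.cos2t2d import (
    CorrelationMap,
    MapKindError,
    MapStack,
    NormalizationError,
    SeriesConfigurationError,
)
from ginkgoscreen.spectral import DEFAULT_GRID, GridMismatchError

from conftest import random_spectrum

TWO_POINT = WavelengthGrid(300, 301, 1)


def spec2(a, b, grid=TWO_POINT, label=""):
    return Spectrum(grid, [a, b], label)


class TestSynchronousMap:
    def test_hand_computed_two_point_example(self):
        s = r = spec2(1.0, 2.0)
        phi = synchronous_map(s, r).values
        np.testing.assert_array_equal(phi, [[1.0, 2.0], [2.0, 4.0]])

    def test_equal_traces_collapse_to_outer_product(self, rng):
        s = random_spectrum(rng)
        phi = synchronous_map(s, s).values
        np.testing.assert_allclose(phi, np.outer(s.absorbance, s.absorbance))

    def test_diagonal_nonnegative_and_symmetric(self, rng):
        phi = synchronous_map(random_spectrum(rng), random_spectrum(rng)).values
        assert np.all(np.diag(phi) >= 0)
        assert np.max(np.abs(phi - phi.T)) <= 1e-12 * np.max(np.abs(phi))

    def test_swap_invariance(self, rng):
        s, r = random_spectrum(rng), random_spectrum(rng)
        np.testing.assert_array_equal(
            synchronous_map(s, r).values, synchronous_map(r, s).values
        )


class TestAsynchronousMap:
    def test_hand_computed_two_point_example(self):
        psi = asynchronous_map(spec2(1.0, 0.0), spec2(0.0, 1.0)).values
        np.testing.assert_array_equal(psi, [[0.0, 0.5], [-0.5, 0.0]])

    def test_proportional_traces_give_zero_map(self, rng):
        s = random_spectrum(rng)
        psi = asynchronous_map(s, s.scaled(3.7)).values
        assert np.max(np.abs(psi)) <= 1e-12

    def test_antisymmetry_with_zero_diagonal(self, rng):
        psi = asynchronous_map(random_spectrum(rng), random_spectrum(rng)).values
        assert np.max(np.abs(psi + psi.T)) <= 1e-12 * np.max(np.abs(psi))
        assert np.max(np.abs(np.diag(psi))) == 0.0

    def test_bilinear_scaling(self, rng):
        s, r = random_spectrum(rng), random_spectrum(rng)
        base = asynchronous_map(s, r).values
        scaled = asynchronous_map(s.scaled(2.5), r.scaled(0.4)).values
        np.testing.assert_allclose(
            scaled, 2.5 * 0.4 * base, rtol=0, atol=1e-12 * np.max(np.abs(base))
        )

    def test_swap_negates(self, rng):
        s, r = random_spectrum(rng), random_spectrum(rng)
        np.testing.assert_array_equal(
            asynchronous_map(r, s).values, -asynchronous_map(s, r).values
        )

    def test_grid_mismatch_rejected(self, rng):
        s = random_spectrum(rng)
        r = random_spectrum(rng, WavelengthGrid(245, 410, 5))
        with pytest.raises(GridMismatchError):
            asynchronous_map(s, r)


class TestAveragedAdulterantReference:
    def test_mean_of_identical_spectra_is_the_unit_area_spectrum(self, rng):
        s = Spectrum(DEFAULT_GRID, np.abs(rng.normal(1, 0.1, 166)))
        out = averaged_adulterant_reference([s, s, s])
        expected = s.absorbance / (s.absorbance.sum() * DEFAULT_GRID.step)
        np.testing.assert_allclose(out.absorbance, expected)

    def test_disjoint_equal_area_bands_average_to_half_height(self):
        grid = DEFAULT_GRID
        wl = grid.wavelengths
        a = np.where(np.abs(wl - 260) <= 2, 1.0, 0.0)
        b = np.where(np.abs(wl - 380) <= 2, 1.0, 0.0)
        out = averaged_adulterant_reference([Spectrum(grid, a), Spectrum(grid, b)])
        unit_a = a / (a.sum() * grid.step)
        unit_b = b / (b.sum() * grid.step)
        np.testing.assert_allclose(out.absorbance, 0.5 * unit_a + 0.5 * unit_b)

    def test_scale_invariance(self, rng):
        spectra = [Spectrum(DEFAULT_GRID, np.abs(rng.normal(1, 0.2, 166))) for _ in range(3)]
        scaled = [s.scaled(c) for s, c in zip(spectra, (0.2, 5.0, 17.0))]
        np.testing.assert_allclose(
            averaged_adulterant_reference(spectra).absorbance,
            averaged_adulterant_reference(scaled).absorbance,
            rtol=1e-12,
        )

    def test_nonpositive_area_rejected(self):
        flat = Spectrum(DEFAULT_GRID, np.zeros(166))
        ok = Spectrum(DEFAULT_GRID, np.ones(166))
        with pytest.raises(NormalizationError):
            averaged_adulterant_reference([ok, flat])


class TestBuildSeries:
    def test_series_a_authentic_map_is_zero(self, noise_free_cohort):
        stack = build_series(noise_free_cohort, "A")
        idx = noise_free_cohort.archetypes.index("authentic")
        assert np.max(np.abs(stack.maps[idx].values)) <= 1e-15

    def test_series_b_authentic_map_is_zero(self, noise_free_cohort):
        stack = build_series(noise_free_cohort, "B")
        idx = noise_free_cohort.archetypes.index("authentic")
        assert np.max(np.abs(stack.maps[idx].values)) <= 1e-15

    def test_series_c_shares_one_reference_label(self, noise_free_cohort):
        stack = build_series(noise_free_cohort, "C")
        assert len(stack) == len(noise_free_cohort.products)
        labels = {m.reference_label for m in stack.maps}
        assert len(labels) == 1

    def test_series_b_without_reference_rejected(self, noise_free_cohort):
        import dataclasses

        crippled = dataclasses.replace(noise_free_cohort, reference_extract=None)
        with pytest.raises(SeriesConfigurationError):
            build_series(crippled, "B")

    def test_noise_free_peak_counts_by_archetype(self, noise_free_cohort):
        """Series A: authentic products show no cross peaks, every
        aglycone-adulterated product at least one."""
        stack = build_series(noise_free_cohort, "A")
        for arch, corr_map in zip(noise_free_cohort.archetypes, stack.maps):
            n = len(detect_cross_peaks(corr_map))
            if arch == "authentic":
                assert n == 0
            if arch in ("quercetin_adulterated", "quercetin_kaempferol_adulterated"):
                assert n >= 1


def brute_force_peaks(values, wl, rel_threshold, min_offdiag, merge_radius):
    """Literal re-statement of the peak definition, as nested loops."""
    mag = np.abs(values)
    vmax = mag.max()
    if vmax == 0:
        return []
    p = len(wl)
    candidates = []
    for i in range(p):
        for j in range(p):
            if not wl[j] > wl[i]:
                continue
            if abs(wl[i] - wl[j]) < min_offdiag - 1e-9:
                continue
            if mag[i, j] < rel_threshold * vmax:
                continue
            is_max = True
            for di in (-1, 0, 1):
                for dj in (-1, 0, 1):
                    if di == dj == 0:
                        continue
                    ii, jj = i + di, j + dj
                    if 0 <= ii < p and 0 <= jj < p and mag[ii, jj] > mag[i, j]:
                        is_max = False
            if is_max:
                candidates.append((i, j))
    candidates.sort(key=lambda t: (-mag[t], t[0], t[1]))
    accepted = []
    for i, j in candidates:
        if all(
            max(abs(wl[i] - wl[a]), abs(wl[j] - wl[b])) >= merge_radius - 1e-9
            for a, b in accepted
        ):
            accepted.append((i, j))
    return [(wl[i], wl[j], mag[i, j]) for i, j in accepted]


class TestDetectCrossPeaks:
    def test_zero_map_gives_no_peaks(self):
        m = CorrelationMap("asynchronous", TWO_POINT, np.zeros((2, 2)))
        assert detect_cross_peaks(m) == []

    def test_synchronous_map_rejected(self, rng):
        m = synchronous_map(random_spectrum(rng), random_spectrum(rng))
        with pytest.raises(MapKindError):
            detect_cross_peaks(m)

    def test_two_disjoint_bands_give_one_peak_at_band_coordinates(self):
        wl = DEFAULT_GRID.wavelengths
        s = Spectrum(DEFAULT_GRID, np.exp(-((wl - 300.0) ** 2) / (2 * 10.0**2)))
        r = Spectrum(DEFAULT_GRID, np.exp(-((wl - 360.0) ** 2) / (2 * 10.0**2)))
        peaks = detect_cross_peaks(asynchronous_map(s, r))
        assert len(peaks) == 1
        assert (peaks[0].nu1, peaks[0].nu2) == (300.0, 360.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_brute_force_scan_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        grid = WavelengthGrid(245, 294, 1)  # 50x50
        raw = rng.normal(0, 1, (50, 50))
        values = 0.5 * (raw - raw.T)  # antisymmetric like a real map
        m = CorrelationMap("asynchronous", grid, values)
        got = [(p.nu1, p.nu2, p.magnitude) for p in detect_cross_peaks(m)]
        expected = brute_force_peaks(values, grid.wavelengths, 0.10, 5.0, 4.0)
        assert got == pytest.approx(expected)

    def test_sorted_by_descending_magnitude(self, recovery_cohort):
        stack = build_series(recovery_cohort, "A")
        for m in stack.maps:
            mags = [p.magnitude for p in detect_cross_peaks(m)]
            assert mags == sorted(mags, reverse=True)


class TestMapStack:
    def test_duplicate_ids_rejected(self, rng):
        m = asynchronous_map(random_spectrum(rng), random_spectrum(rng))
        with pytest.raises(ValueError):
            MapStack([m, m], ["a", "a"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            MapStack([], [])
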