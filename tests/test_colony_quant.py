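"""Grid fitting, density/area extraction and diploid-area normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mythscreen import colony_quant as cq
from mythscreen import synth
from mythscreen.colony_quant import (
    LowSignalError,
    fit_grid,
    measure_area,
    measure_density,
    minmax_normalize,
    normalize_densities,
)


def _center_errors(grid, truth_centers):
    return np.hypot(*(grid.centers - truth_centers).transpose(2, 0, 1))


class TestFitGrid:
    def test_jitter_free_centers_within_one_pixel(self):
        rng = np.random.default_rng(1)
        dens = rng.uniform(5e4, 2e5, size=(8, 12))
        img = synth.render_plate(dens, pitch=40, radius=10, background=3000.0)
        truth, _ = synth.grid_centers(8, 12, 40)
        grid = fit_grid(img, 8, 12)
        assert _center_errors(grid, truth).max() < 1.0

    def test_jittered_centers_within_three_pixels(self):
        rng = np.random.default_rng(2)
        dens = rng.uniform(5e4, 2e5, size=(8, 12))
        offsets = rng.normal(0.0, 2.0, size=(8, 12, 2))
        img = synth.render_plate(
            dens, pitch=40, radius=10, background=3000.0, offsets=offsets, noise_sd=20.0, seed=3
        )
        truth, _ = synth.grid_centers(8, 12, 40)
        grid = fit_grid(img, 8, 12)
        assert _center_errors(grid, truth + offsets).max() < 3.0

    def test_sparse_plate_with_gradient(self):
        """~10% occupied quadruplicate plate: lattice still within a pixel."""
        rng = np.random.default_rng(7)
        mask96 = rng.random((8, 12)) < 0.10
        dens = np.kron(mask96, np.ones((2, 2))) * 1e5 + np.kron(~mask96, np.ones((2, 2))) * 1500.0
        img = synth.render_plate(
            dens, pitch=24, radius=7, background=3000.0, gradient_amplitude=300.0,
            noise_sd=20.0, seed=7,
        )
        truth, _ = synth.grid_centers(16, 24, 24)
        grid = fit_grid(img, 16, 24)
        assert _center_errors(grid, truth).max() < 1.0

    def test_blank_image_raises_low_signal(self):
        with pytest.raises(LowSignalError):
            fit_grid(np.full((300, 300), 1000.0), 8, 12)

    def test_manual_override_bypasses_detection(self):
        img = np.full((300, 300), 1000.0)
        grid = fit_grid(img, 4, 4, origin=(50.0, 50.0), pitch=40.0)
        assert grid.centers[0, 0] == pytest.approx((50.0, 50.0))
        assert grid.centers[3, 3] == pytest.approx((170.0, 170.0))


class TestMeasureDensity:
    def test_blank_plate_measures_zero(self):
        img = np.full((300, 300), 2000.0)
        grid = fit_grid(img, 4, 4, origin=(60.0, 60.0), pitch=40.0)
        assert (measure_density(img, grid)["raw_density"] == 0).all()

    def test_single_colony_within_five_percent(self):
        dens = np.zeros((8, 12))
        dens[3, 5] = 1e5
        img = synth.render_plate(dens, pitch=24, radius=7, background=3000.0)
        grid = fit_grid(img, 8, 12, origin=(24.0, 24.0), pitch=24.0)
        tab = measure_density(img, grid)
        got = tab.loc[(tab.row == 4) & (tab.col == 6), "raw_density"].iloc[0]
        assert got == pytest.approx(1e5, rel=0.05)

    def test_gradient_largely_cancelled_by_local_background(self):
        """10%-of-background gradient: measured density within 7% of truth."""
        dens = np.zeros((8, 12))
        dens[3, 5] = 1e5
        img = synth.render_plate(
            dens, pitch=24, radius=7, background=3000.0, gradient_amplitude=300.0
        )
        grid = fit_grid(img, 8, 12, origin=(24.0, 24.0), pitch=24.0)
        tab = measure_density(img, grid)
        got = tab.loc[(tab.row == 4) & (tab.col == 6), "raw_density"].iloc[0]
        assert got == pytest.approx(1e5, rel=0.07)

    def test_intensity_scaling_scales_densities(self):
        """Densities are linear in pixel intensity (background subtracted)."""
        rng = np.random.default_rng(4)
        dens = rng.uniform(2e4, 4e5, size=(8, 12))
        img = synth.render_plate(dens, pitch=24, radius=7, background=3000.0)
        grid = fit_grid(img, 8, 12)
        d1 = measure_density(img, grid)["raw_density"].to_numpy()
        d2 = measure_density(3.0 * img, grid)["raw_density"].to_numpy()
        np.testing.assert_allclose(d2, 3.0 * d1, rtol=1e-6)

    def test_translation_changes_densities_under_two_percent(self):
        rng = np.random.default_rng(5)
        dens = rng.uniform(2e4, 4e5, size=(8, 12))
        img = synth.render_plate(
            dens, pitch=24, radius=7, background=3000.0, noise_sd=20.0, seed=6
        )
        d1 = measure_density(img, fit_grid(img, 8, 12))["raw_density"].to_numpy()
        shifted = np.roll(np.roll(img, 5, axis=0), 9, axis=1)
        d2 = measure_density(shifted, fit_grid(shifted, 8, 12))["raw_density"].to_numpy()
        assert np.max(np.abs(d2 - d1) / d1) < 0.02

    def test_measured_tracks_truth_on_full_screen(self, screen, screen_results):
        """Pearson between measured raw densities and generator truth ≥ 0.99."""
        _, spots, _ = screen_results
        merged = screen.truth.merge(
            spots, left_on=["plate", "row384", "col384"], right_on=["plate", "row", "col"]
        )
        assert len(merged) == len(screen.truth)
        r = np.corrcoef(merged["true_density"], merged["raw_density"])[0, 1]
        assert r >= 0.99


class TestMeasureArea:
    def test_blank_plate_zero_area(self):
        img = np.full((500, 700), 1000.0)
        grid = fit_grid(img, 8, 12, origin=(48.0, 48.0), pitch=48.0)
        assert (measure_area(img, grid)["diploid_area"] == 0).all()

    def test_disc_area_within_ten_percent(self):
        img = synth._render_variable_radius_plate(
            np.full((8, 12), 10.0), 48, amplitude=2000.0, shoulder_sigma=0.3,
            background=3000.0, gradient_amplitude=0.0, noise_sd=0.0, seed=0,
        )
        grid = fit_grid(img, 8, 12)
        areas = measure_area(img, grid)["diploid_area"]
        assert np.allclose(areas, np.pi * 100.0, rtol=0.10)

    def test_missing_colony_nearly_empty(self):
        radii = np.full((8, 12), 10.0)
        radii[4, 7] = 0.0
        img = synth._render_variable_radius_plate(
            radii, 48, 2000.0, 0.5, 3000.0, 0.0, 10.0, seed=1
        )
        grid = fit_grid(img, 8, 12)
        tab = measure_area(img, grid)
        gap = tab.loc[(tab.row == 5) & (tab.col == 8), "diploid_area"].iloc[0]
        assert gap < 0.05 * tab["diploid_area"].median()


class TestMinMaxNormalize:
    def test_formula(self):
        np.testing.assert_allclose(minmax_normalize([2, 4, 6]), [0.0, 0.5, 1.0])

    def test_degenerate_all_equal_maps_to_one(self):
        np.testing.assert_allclose(minmax_normalize([5, 5, 5]), [1.0, 1.0, 1.0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            minmax_normalize([])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 1e6), min_size=2, max_size=30))
    def test_range_and_extrema(self, values):
        out = minmax_normalize(values)
        assert np.all((out >= 0.0) & (out <= 1.0))
        if max(values) > min(values):
            assert out.min() == 0.0 and out.max() == 1.0


class TestNormalizeDensities:
    @staticmethod
    def _tables(raw_density, area_norm):
        raw = pd.DataFrame(
            {"plate": [1], "row": [1], "col": [1], "prey": ["p"], "raw_density": [raw_density]}
        )
        areas = pd.DataFrame(
            {"plate": [1], "row": [1], "col": [1], "diploid_area": [100], "area_norm": [area_norm]}
        )
        return raw, areas

    def test_division_by_area_norm(self):
        out = normalize_densities(*self._tables(10.0, 0.5))
        assert out["normalized_density"].iloc[0] == pytest.approx(20.0)
        assert out["qc_flag"].iloc[0] == "ok"

    def test_vanishing_area_flags_failed_mating(self):
        out = normalize_densities(*self._tables(10.0, 0.0))
        assert out["qc_flag"].iloc[0] == "failed_mating"
        assert np.isnan(out["normalized_density"].iloc[0])

    def test_zero_density_stays_zero(self):
        out = normalize_densities(*self._tables(0.0, 1.0))
        assert out["normalized_density"].iloc[0] == 0.0

    def test_misaligned_tables_rejected(self):
        raw, areas = self._tables(10.0, 0.5)
        areas["plate"] = 2
        with pytest.raises(ValueError, match="no matching diploid well"):
            normalize_densities(raw, areas)

    def test_epsilon_bounds(self):
        raw, areas = self._tables(10.0, 0.5)
        with pytest.raises(ValueError):
            normalize_densities(raw, areas, epsilon=0.0)
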