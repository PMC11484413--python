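"""Aperture/intensity rasterization and area-overlap downsampling."""

import numpy as np
import pytest

from vmatqa.feature_map import (
    build_grid,
    downsample_fraction,
    featurize_plan,
    intensity_from_aperture,
    overlap_matrix,
    rasterize_aperture,
)
from vmatqa.plan_model import ControlPoint, MachineSpec, VMATPlan
from vmatqa.synth_data import SimConfig, simulate_regular_plan


def brute_force_raster(cp, grid):
    """Per-pixel point-in-rectangle oracle."""
    out = np.zeros(grid.shape, dtype=np.uint8)
    for p, (lo, hi) in enumerate(grid.row_of_pair):
        for i in range(lo, hi):
            for j in range(grid.n_position_index):
                x = -grid.field_height / 2 + (j + 0.5) * grid.resolution
                if cp.left_positions[p] < x < cp.right_positions[p]:
                    out[i, j] = 1
    return out


def random_cp(machine, rng, grid_aligned=False):
    n = machine.n_leaf_pairs
    half = machine.field_height / 2
    left = rng.uniform(-half, half, n)
    right = left + rng.uniform(0, half - left)
    if grid_aligned:
        left, right = np.round(left), np.round(right)
    return ControlPoint(
        gantry_angle=0.0,
        left_positions=left,
        right_positions=right,
        dose=float(rng.uniform(0.5, 5.0)),
    )


class TestBuildGrid:
    def test_fine_resolution_worked_examples(self):
        machine = MachineSpec(40, (7.5,) * 40, 300.0, 400.0, 5.0)
        grid = build_grid(machine, 0.1)
        assert grid.n_leaf_index == 3000
        assert grid.n_position_index == 4000

    def test_degenerate_one_pixel_axis(self):
        machine = MachineSpec(1, (10.0,), 10.0, 10.0, 5.0)
        grid = build_grid(machine, 10.0)
        assert grid.shape == (1, 1)

    def test_row_partition_covers_rows_exactly(self, machine):
        grid = build_grid(machine, 1.0)
        rows = sorted(r for lo, hi in grid.row_of_pair for r in range(lo, hi))
        assert rows == list(range(grid.n_leaf_index))

    def test_invalid_resolution(self, machine):
        with pytest.raises(ValueError, match="resolution"):
            build_grid(machine, -1.0)
        with pytest.raises(ValueError, match="divide"):
            build_grid(machine, 3.0)


class TestRasterize:
    def test_closed_pairs_give_empty_map(self, small_machine):
        grid = build_grid(small_machine, 1.0)
        cp = ControlPoint(0.0, np.zeros(4), np.zeros(4), 1.0)
        assert rasterize_aperture(cp, grid).values.sum() == 0

    def test_single_open_pair_pixel_count(self, small_machine):
        # one 10 mm-wide pair open from -5 to +5 at 1 mm: 10 rows x 10 cols
        grid = build_grid(small_machine, 1.0)
        left = np.zeros(4)
        right = np.zeros(4)
        left[2], right[2] = -5.0, 5.0
        cp = ControlPoint(0.0, left, right, 1.0)
        a = rasterize_aperture(cp, grid)
        assert a.values.sum() == 100
        np.testing.assert_array_equal(a.values, brute_force_raster(cp, grid))

    def test_matches_bruteforce_oracle_on_random_cps(self, small_machine, rng):
        grid = build_grid(small_machine, 2.0)
        for _ in range(100):
            cp = random_cp(small_machine, rng)
            got = rasterize_aperture(cp, grid).values
            np.testing.assert_array_equal(got, brute_force_raster(cp, grid))
            assert set(np.unique(got)) <= {0, 1}

    def test_bank_grid_mismatch(self, small_machine, machine):
        grid = build_grid(machine, 1.0)
        cp = ControlPoint(0.0, np.zeros(4), np.ones(4), 1.0)
        with pytest.raises(ValueError, match="pairs"):
            rasterize_aperture(cp, grid)


class TestIntensity:
    def test_zero_dose_annihilates(self, small_machine, rng):
        grid = build_grid(small_machine, 1.0)
        a = rasterize_aperture(random_cp(small_machine, rng), grid)
        assert intensity_from_aperture(a, 0.0).values.sum() == 0

    def test_single_pixel_product(self):
        from vmatqa.feature_map import ApertureMap

        vals = np.zeros((6, 8), dtype=np.uint8)
        vals[3, 4] = 1
        out = intensity_from_aperture(ApertureMap(values=vals), 2.0).values
        assert out[3, 4] == 2.0 and out.sum() == 2.0

    def test_constant_map(self):
        from vmatqa.feature_map import ApertureMap

        out = intensity_from_aperture(
            ApertureMap(values=np.ones((2, 2), dtype=np.uint8)), 1.5
        ).values
        np.testing.assert_allclose(out, 1.5)

    def test_negative_dose_rejected(self):
        from vmatqa.feature_map import ApertureMap

        with pytest.raises(ValueError, match="dose"):
            intensity_from_aperture(ApertureMap(values=np.zeros((2, 2), np.uint8)), -1.0)


class TestDownsampling:
    def test_overlap_matrix_is_row_stochastic_and_mass_preserving(self):
        for n_src, n_tgt in [(400, 64), (10, 10), (9, 4)]:
            m = overlap_matrix(n_src, n_tgt)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            np.testing.assert_allclose(m.sum(axis=0), n_tgt / n_src, atol=1e-12)

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="target larger"):
            overlap_matrix(10, 20)

    def test_mean_conservation_any_factor(self, rng):
        values = rng.random((40, 60))
        for shape in [(40, 60), (20, 30), (8, 12), (7, 9)]:
            ds = downsample_fraction(values, shape)
            assert np.mean(ds) == pytest.approx(np.mean(values), abs=1e-9)


class TestFeaturizePlan:
    def test_two_arc_plan_gives_180_maps(self, machine, sim_plan):
        grid = build_grid(machine, 2.0)
        ft = featurize_plan(sim_plan, grid, (64, 64))
        assert ft.n_control_points == 180
        assert ft.apertures.shape == (180, 64, 64)
        assert ft.intensities.shape == (180, 64, 64)
        assert ft.doses.shape == (180,)

    def test_identity_downsample_matches_rasterizer(self, small_machine, rng):
        grid = build_grid(small_machine, 2.0)
        cp = random_cp(small_machine, rng)
        plan = VMATPlan("x", [[cp]], machine=small_machine)
        ft = featurize_plan(plan, grid, grid.shape)
        np.testing.assert_array_equal(
            ft.apertures[0], rasterize_aperture(cp, grid).values
        )
        np.testing.assert_allclose(
            ft.intensities[0],
            rasterize_aperture(cp, grid).values * cp.dose,
            atol=1e-5,
        )

    def test_downsampled_intensity_mean_matches_analytic_area(self, small_machine, rng):
        # grid-aligned leaves: open-area fraction is exact from the intervals
        grid = build_grid(small_machine, 1.0)
        for _ in range(5):
            cp = random_cp(small_machine, rng, grid_aligned=True)
            plan = VMATPlan("x", [[cp]], machine=small_machine)
            ft = featurize_plan(plan, grid, (20, 30))
            open_len = np.clip(
                cp.right_positions - cp.left_positions, 0.0, None
            )
            frac = float(
                np.sum(open_len * np.array(small_machine.leaf_widths))
                / (small_machine.field_width * small_machine.field_height)
            )
            assert np.mean(ft.intensities[0]) == pytest.approx(
                cp.dose * frac, abs=1e-6
            )

    def test_equivalent_to_rasterize_then_downsample(self, machine, sim_plan):
        grid = build_grid(machine, 1.0)
        ft = featurize_plan(sim_plan, grid, (64, 64))
        for k in (0, 57, 179):
            cp = list(sim_plan.control_points())[k]
            full = rasterize_aperture(cp, grid).values
            cov = downsample_fraction(full.astype(float), (64, 64))
            np.testing.assert_array_equal(ft.apertures[k], (cov >= 0.5).astype(np.uint8))
            np.testing.assert_allclose(ft.intensities[k], cov * cp.dose, atol=1e-4)

    def test_widening_gap_never_loses_pixels(self, small_machine, rng):
        grid = build_grid(small_machine, 1.0)
        for _ in range(10):
            cp = random_cp(small_machine, rng)
            wider = ControlPoint(
                0.0,
                cp.left_positions - rng.uniform(0, 5, 4),
                cp.right_positions + rng.uniform(0, 5, 4),
                cp.dose,
            )
            a0 = rasterize_aperture(cp, grid).values
            a1 = rasterize_aperture(wider, grid).values
            assert np.all(a1 >= a0)

    def test_deterministic(self, machine, sim_plan):
        grid = build_grid(machine, 2.0)
        f1 = featurize_plan(sim_plan, grid, (64, 64))
        f2 = featurize_plan(sim_plan, grid, (64, 64))
        assert np.array_equal(f1.apertures, f2.apertures)
        assert np.array_equal(f1.intensities, f2.intensities)

    def test_target_larger_than_grid_rejected(self, small_machine, sim_plan):
        grid = build_grid(small_machine, 10.0)
        with pytest.raises(ValueError, match="exceeds"):
            featurize_plan(sim_plan, grid, (64, 64))


class TestPersistence:
    def test_hdf5_roundtrip(self, machine, sim_plan, tmp_path):
        from vmatqa.feature_map import load_feature_tensors, save_feature_tensors

        grid = build_grid(machine, 2.0)
        ft = featurize_plan(sim_plan, grid, (64, 64))
        path = tmp_path / "f.h5"
        save_feature_tensors([ft], path, grid_meta={"resolution_mm": 2.0})
        (back,) = load_feature_tensors(path)
        assert back.plan_id == ft.plan_id and back.label == ft.label
        np.testing.assert_array_equal(back.apertures, ft.apertures)
        np.testing.assert_array_equal(back.intensities, ft.intensities)
        np.testing.assert_array_equal(back.doses, ft.doses)
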