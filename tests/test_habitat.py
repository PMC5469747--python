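import math

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from finmove.grids import GridSpec
from finmove.habitat import (
    HabitatConfig,
    HabitatStack,
    build_habitat_stack,
    daily_positions,
    detect_fronts,
    distance_to_habitat,
    habitat_area_fraction,
    habitat_frequency,
    habitat_mask,
    haversine_km,
    metric_gradient_log,
)
from finmove.simulate import FrontSpec, simulate_scene


def small_grid(nx=60, ny=40):
    return GridSpec(lon0=4.0, lat0=40.0, dlon=0.05, dlat=0.05, nx=nx, ny=ny)


def stack_from_masks(grid, masks, days=None):
    masks = np.asarray(masks, bool)
    days = days if days is not None else list(range(len(masks)))
    return HabitatStack(grid=grid, days=list(days), masks=masks)


class TestDetectFronts:
    def test_constant_field_no_fronts(self):
        grid = small_grid()
        assert not detect_fronts(np.full(grid.shape, 0.2), grid).any()

    def test_log_gradient_scale_invariance(self):
        grid = small_grid()
        scene = simulate_scene(grid, front=FrontSpec(lon=5.0, width_deg=0.3))
        m1 = detect_fronts(scene.chla[0], grid)
        m2 = detect_fronts(2.0 * scene.chla[0], grid)
        assert np.array_equal(m1, m2)

    def test_front_band_contains_max_gradient_line(self):
        grid = small_grid()
        scene = simulate_scene(grid, front=FrontSpec(lon=5.0, width_deg=0.2))
        mask = detect_fronts(scene.chla[0], grid)
        col = int(np.argmin(np.abs(grid.lon_centers - 5.0)))
        assert mask[:, col].all()

    def test_small_grid_is_error(self):
        grid = GridSpec(lon0=0, lat0=0, dlon=1, dlat=1, nx=2, ny=2)
        with pytest.raises(ValueError):
            detect_fronts(np.ones((2, 2)), grid)

    def test_monotone_in_threshold(self):
        grid = small_grid()
        scene = simulate_scene(grid, front=FrontSpec(lon=5.0, width_deg=0.3))
        loose = detect_fronts(scene.chla[0], grid, HabitatConfig(gradient_threshold=0.2))
        tight = detect_fronts(scene.chla[0], grid, HabitatConfig(gradient_threshold=0.8))
        assert loose.sum() >= tight.sum()
        assert np.all(loose | ~tight)


class TestHabitatMask:
    def test_shallow_water_everywhere_empty(self):
        grid = small_grid()
        chla = np.full(grid.shape, 0.2)
        fronts = np.ones(grid.shape, bool)
        depth = np.full(grid.shape, 100.0)
        assert not habitat_mask(chla, fronts, depth).any()

    def test_constructed_intersection(self):
        grid = small_grid(nx=10, ny=8)
        chla = np.full(grid.shape, 0.2)
        chla[:, 6:] = 0.9  # too green east
        fronts = np.zeros(grid.shape, bool)
        fronts[:, 3:8] = True
        depth = np.full(grid.shape, 500.0)
        depth[:2] = 50.0  # shallow south rows
        expected = np.zeros(grid.shape, bool)
        expected[2:, 3:6] = True
        assert np.array_equal(habitat_mask(chla, fronts, depth), expected)

    def test_high_chl_front_cells_unsuitable(self):
        grid = small_grid(nx=6, ny=6)
        chla = np.full(grid.shape, 0.6)  # above the 0.5 mg m^-3 bound
        fronts = np.ones(grid.shape, bool)
        depth = np.full(grid.shape, 1000.0)
        assert not habitat_mask(chla, fronts, depth).any()

    def test_mismatched_grids_error(self):
        with pytest.raises(ValueError):
            habitat_mask(np.ones((3, 3)), np.ones((4, 4), bool), np.ones((3, 3)))


class TestHabitatFrequency:
    def test_identical_masks_give_zero_or_one(self):
        grid = small_grid(nx=8, ny=5)
        m = np.zeros(grid.shape, bool)
        m[2, 3] = True
        stack = stack_from_masks(grid, [m, m, m])
        f = habitat_frequency(stack, [0, 1, 2])
        assert set(np.unique(f)) <= {0.0, 1.0}

    def test_half_of_window(self):
        grid = small_grid(nx=4, ny=4)
        m1 = np.zeros(grid.shape, bool)
        m1[1, 1] = True
        stack = stack_from_masks(grid, [m1, np.zeros(grid.shape, bool)] * 15)
        f = habitat_frequency(stack, list(range(30)))
        assert f[1, 1] == pytest.approx(0.5)

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(6)
        grid = small_grid(nx=7, ny=6)
        masks = rng.random((10, *grid.shape)) < 0.3
        stack = stack_from_masks(grid, masks)
        window = [1, 4, 7, 9]
        f = habitat_frequency(stack, window)
        for r in range(grid.ny):
            for c in range(grid.nx):
                assert f[r, c] == pytest.approx(
                    sum(masks[d][r, c] for d in window) / len(window)
                )

    def test_missing_day_listed(self):
        grid = small_grid(nx=4, ny=4)
        stack = stack_from_masks(grid, [np.zeros(grid.shape, bool)], days=[5])
        with pytest.raises(KeyError, match="99"):
            habitat_frequency(stack, [5, 99])


class TestHabitatAreaFraction:
    def test_fully_suitable_region(self):
        grid = small_grid(nx=10, ny=10)
        region = box(grid.lon0, grid.lat0, grid.lon0 + 0.3, grid.lat0 + 0.3)
        assert habitat_area_fraction(np.ones(grid.shape, bool), region, grid) == pytest.approx(100.0)

    def test_half_suitable_region(self):
        grid = small_grid(nx=10, ny=4)
        mask = np.zeros(grid.shape, bool)
        mask[:2, :] = True  # southern half of each column
        region = box(grid.lon0, grid.lat0, grid.lon0 + 10 * grid.dlon, grid.lat0 + 4 * grid.dlat)
        # rows differ slightly in area (cos lat); compare against cell accounting
        areas = grid.cell_areas_km2()
        expected = 100.0 * areas[:2].sum() / areas.sum()
        assert habitat_area_fraction(mask, region, grid) == pytest.approx(expected)

    def test_random_mask_matches_cell_accounting(self):
        rng = np.random.default_rng(12)
        grid = small_grid(nx=12, ny=9)
        mask = rng.random(grid.shape) < 0.4
        region = box(4.1, 40.05, 4.4, 40.3)
        LON, LAT = grid.center_mesh()
        inside = (LON > 4.1) & (LON < 4.4) & (LAT > 40.05) & (LAT < 40.3)
        areas = grid.cell_areas_km2()
        expected = 100.0 * areas[inside & mask].sum() / areas[inside].sum()
        assert habitat_area_fraction(mask, region, grid) == pytest.approx(expected)

    def test_empty_intersection_error(self):
        grid = small_grid(nx=4, ny=4)
        with pytest.raises(ValueError):
            habitat_area_fraction(np.ones(grid.shape, bool), box(50, 50, 51, 51), grid)


class TestDistanceToHabitat:
    def _stack_single(self, grid, suitable_cells, day=0):
        m = np.zeros(grid.shape, bool)
        for r, c in suitable_cells:
            m[r, c] = True
        return stack_from_masks(grid, [m], days=[day])

    def _positions(self, rows):
        return pd.DataFrame(rows, columns=["ptt", "day", "lon", "lat"])

    def test_on_suitable_cell_is_zero(self):
        grid = small_grid()
        stack = self._stack_single(grid, [(5, 5)])
        pos = self._positions([("w1", 0, grid.lon_centers[5], grid.lat_centers[5])])
        res = distance_to_habitat(pos, stack)
        assert res.distances_km.iloc[0] == 0.0

    def test_one_degree_of_latitude(self):
        grid = GridSpec(lon0=7.95, lat0=40.95, dlon=0.1, dlat=0.1, nx=1, ny=11)
        stack = self._stack_single(grid, [(10, 0)])  # sole suitable cell at 42.0°N
        pos = self._positions([("w1", 0, 8.0, 41.0)])
        res = distance_to_habitat(pos, stack)
        assert res.distances_km.iloc[0] == pytest.approx(111.19, abs=0.01)

    def test_matches_exhaustive_scan(self):
        rng = np.random.default_rng(3)
        grid = small_grid(nx=25, ny=20)
        mask = rng.random(grid.shape) < 0.05
        stack = stack_from_masks(grid, [mask], days=[0])
        LON, LAT = grid.center_mesh()
        pos = self._positions(
            [("w", 0, rng.uniform(4, 7), rng.uniform(40, 42)) for _ in range(100)]
        )
        res = distance_to_habitat(pos, stack)

        def oracle(lon, lat):
            # independent spherical law-of-cosines distance, full scan;
            # a position whose own cell is suitable scores 0 by contract
            r0 = int((lat - grid.lat0) // grid.dlat)
            c0 = int((lon - grid.lon0) // grid.dlon)
            if 0 <= r0 < grid.ny and 0 <= c0 < grid.nx and mask[r0, c0]:
                return 0.0
            best = math.inf
            for r in range(grid.ny):
                for c in range(grid.nx):
                    if not mask[r, c]:
                        continue
                    p1, p2 = math.radians(lat), math.radians(LAT[r, c])
                    dl = math.radians(LON[r, c] - lon)
                    cosd = min(1.0, math.sin(p1) * math.sin(p2) + math.cos(p1) * math.cos(p2) * math.cos(dl))
                    best = min(best, 6371.0 * math.acos(cosd))
            return best

        for i, row in enumerate(pos.itertuples(index=False)):
            assert res.distances_km.iloc[i] == pytest.approx(oracle(row.lon, row.lat), abs=1e-6)

    def test_empty_day_excluded_but_counted(self):
        grid = small_grid(nx=5, ny=5)
        stack = stack_from_masks(grid, [np.zeros(grid.shape, bool)], days=[0])
        pos = self._positions([("w1", 0, 4.1, 40.1)])
        res = distance_to_habitat(pos, stack)
        assert math.isnan(res.distances_km.iloc[0])
        assert res.n_excluded_empty_days == 1

    def test_lipschitz_under_position_shift(self):
        grid = small_grid()
        stack = self._stack_single(grid, [(20, 30)])
        base = self._positions([("w1", 0, 5.0, 40.5)])
        moved = self._positions([("w1", 0, 5.0, 40.5 + 0.1)])  # ~11.1 km shift
        d0 = distance_to_habitat(base, stack).distances_km.iloc[0]
        d1 = distance_to_habitat(moved, stack).distances_km.iloc[0]
        shift = haversine_km(5.0, 40.5, 5.0, 40.6)
        assert abs(d1 - d0) <= shift + 1e-9

    def test_fraction_strictly_below_threshold(self):
        grid = small_grid()
        stack = self._stack_single(grid, [(10, 10)])
        lon0, lat0 = grid.lon_centers[10], grid.lat_centers[10]
        pos = self._positions(
            [("a", 0, lon0, lat0), ("b", 0, lon0, lat0 + 0.05), ("c", 0, lon0, lat0 + 1.0)]
        )
        res = distance_to_habitat(pos, stack, threshold_km=7.0)
        assert res.fraction_within == pytest.approx(2 / 3)


class TestDailyPositions:
    def test_daily_mean_per_platform(self):
        df = pd.DataFrame(
            {
                "ptt": ["w1"] * 3 + ["w2"],
                "time": pd.to_datetime(
                    ["2012-09-01 03:00", "2012-09-01 15:00", "2012-09-02 06:00", "2012-09-01 12:00"]
                ),
                "lon": [8.0, 9.0, 10.0, 5.0],
                "lat": [42.0, 43.0, 44.0, 40.0],
            }
        )
        out = daily_positions(df)
        assert len(out) == 3
        row = out[(out.ptt == "w1") & (out.day == pd.Timestamp("2012-09-01").date())]
        assert row.lon.iloc[0] == pytest.approx(8.5)


class TestBuildStack:
    def test_pipeline_scene_stack(self):
        grid = small_grid()
        scene = simulate_scene(grid, front=FrontSpec(lon=5.0, width_deg=0.2), n_days=3)
        stack = build_habitat_stack(scene.chla, scene.depth, grid, days=[0, 1, 2], sea=~scene.land)
        assert stack.masks.shape == (3, grid.ny, grid.nx)
        assert not (stack.masks & scene.land[None]).any()  # suitable ⇒ sea
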