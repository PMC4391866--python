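"""Conversion, indicator scoring, travel time and HI composition tests."""

import networkx as nx
import numpy as np
import pytest

from pnvgap.rasterstack_io import GridSpec, Raster
from pnvgap.protection_coverage import PNVMap
from pnvgap.human_influence import (
    FrictionModel,
    HIConfig,
    IndicatorStack,
    LivestockModel,
    accessibility_index,
    build_friction,
    compose_hi,
    compute_human_influence,
    conversion_score,
    livestock_pressure_index,
    population_density_index,
    travel_time,
    vegetation_transformation_index,
)


def _r(g, vals, mask=None):
    return Raster(g, np.asarray(vals, dtype=float), mask)


class TestConversionScore:
    def test_urban_dominates_cropland(self):
        g = GridSpec(1, 1, 1.0)
        out = conversion_score(_r(g, [[0.1]]), _r(g, [[1]]), _r(g, [[0]]))
        assert out.values[0, 0] == 100.0

    def test_cropland_percentage_passthrough(self):
        g = GridSpec(1, 2, 1.0)
        out = conversion_score(_r(g, [[0.30, 0.0]]), _r(g, [[0, 0]]), _r(g, [[0, 0]]))
        assert out.values[0, 0] == pytest.approx(30.0)
        assert out.values[0, 1] == 0.0

    def test_road_cells_score_100(self):
        g = GridSpec(1, 1, 1.0)
        assert conversion_score(_r(g, [[0.0]]), _r(g, [[0]]), _r(g, [[1]])).values[0, 0] == 100.0

    def test_cropland_out_of_range_fails(self):
        g = GridSpec(1, 1, 1.0)
        with pytest.raises(ValueError):
            conversion_score(_r(g, [[1.5]]), _r(g, [[0]]), _r(g, [[0]]))


class TestVti:
    def _one_cell(self, pnv_level, luc_levels):
        g = GridSpec(1, 1, 1.0)
        phys = _r(g, [[pnv_level]])
        lucs = [_r(g, [[lv]]) for lv in luc_levels]
        return vegetation_transformation_index(phys, lucs).values[0, 0]

    def test_three_steps_below_scores_75(self):
        assert self._one_cell(1, [4, 4, 4, 4]) == 75.0

    def test_unchanged_physiognomy_scores_0(self):
        assert self._one_cell(3, [3, 3, 3, 3]) == 0.0

    def test_mean_over_maps(self):
        assert self._one_cell(1, [1, 2, 3, 4]) == pytest.approx((0 + 25 + 50 + 75) / 4)

    def test_five_steps_capped_at_100(self):
        assert self._one_cell(1, [6, 6, 6, 6]) == 100.0

    def test_luc_above_pnv_scores_0(self):
        assert self._one_cell(4, [1, 2, 3, 4]) == 0.0

    def test_invalid_level_fails(self):
        with pytest.raises(ValueError):
            self._one_cell(1, [7, 1, 1, 1])


class TestHpi:
    @pytest.mark.parametrize("density,score", [(0, 0), (10, 50), (20, 100), (35, 100)])
    def test_linear_saturating_rule(self, density, score):
        g = GridSpec(1, 1, 1.0)
        assert population_density_index(_r(g, [[density]])).values[0, 0] == score

    def test_negative_density_fails(self):
        g = GridSpec(1, 1, 1.0)
        with pytest.raises(ValueError):
            population_density_index(_r(g, [[-1.0]]))


class TestTravelTime:
    def test_destination_cell_is_zero_hours(self):
        g = GridSpec(1, 3, 1000.0)
        f = FrictionModel(_r(g, [[5.0, 5.0, 5.0]]),
                          np.zeros((1, 3), bool),
                          np.array([[True, False, False]]))
        assert travel_time(f).values[0, 0] == 0.0

    def test_uniform_speed_straight_line(self):
        # 5 cells of 1 km at 5 km/h from the destination -> 1.0 h
        g = GridSpec(1, 6, 1000.0)
        f = FrictionModel(_r(g, np.full((1, 6), 5.0)),
                          np.zeros((1, 6), bool),
                          np.array([[True] + [False] * 5]))
        hours = travel_time(f)
        assert hours.values[0, 5] == pytest.approx(1.0)

    def test_no_destination_fails(self):
        g = GridSpec(2, 2, 1000.0)
        f = FrictionModel(_r(g, np.full((2, 2), 4.0)), np.zeros((2, 2), bool), np.zeros((2, 2), bool))
        with pytest.raises(ValueError):
            travel_time(f)

    def _nx_oracle(self, speed, barrier, dest, cell_km):
        nr, nc = speed.shape
        G = nx.Graph()
        for i in range(nr):
            for j in range(nc):
                if not barrier[i, j]:
                    G.add_node((i, j))
        for i in range(nr):
            for j in range(nc):
                if barrier[i, j]:
                    continue
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        ni, nj = i + di, j + dj
                        if (di, dj) == (0, 0) or not (0 <= ni < nr and 0 <= nj < nc):
                            continue
                        if barrier[ni, nj]:
                            continue
                        dist = cell_km * (np.sqrt(2) if di and dj else 1.0)
                        w = dist * 0.5 * (1 / speed[i, j] + 1 / speed[ni, nj])
                        G.add_edge((i, j), (ni, nj), weight=w)
        lengths = {}
        for (i, j), d in nx.multi_source_dijkstra_path_length(
                G, [tuple(t) for t in np.argwhere(dest & ~barrier)]).items():
            lengths[(i, j)] = d
        out = np.full((nr, nc), np.inf)
        for (i, j), d in lengths.items():
            out[i, j] = d
        return out

    def test_river_detour_matches_dijkstra_oracle(self):
        # vertical river wall with one gap forces a detour
        nr = nc = 15
        g = GridSpec(nr, nc, 1000.0)
        barrier = np.zeros((nr, nc), bool)
        barrier[:, 7] = True
        barrier[10, 7] = False  # the gap
        speed = np.full((nr, nc), 5.0)
        dest = np.zeros((nr, nc), bool)
        dest[2, 2] = True
        hours = travel_time(FrictionModel(_r(g, speed), barrier, dest))
        exp = self._nx_oracle(speed, barrier, dest, 1.0)
        np.testing.assert_allclose(hours.values[~barrier], exp[~barrier])
        assert np.isinf(hours.values[barrier]).all()
        # crossing must route through the gap: longer than the unobstructed line
        direct = np.sqrt((2 - 2) ** 2 + (12 - 2) ** 2) / 5.0
        assert hours.values[2, 12] > direct

    def test_random_friction_grids_match_dijkstra_oracle(self, rng):
        for _ in range(3):
            nr, nc = rng.integers(5, 20, size=2)
            g = GridSpec(int(nr), int(nc), 1000.0)
            speed = rng.uniform(1, 60, size=(nr, nc))
            barrier = rng.random((nr, nc)) < 0.15
            dest = np.zeros((nr, nc), bool)
            dest[rng.integers(nr), rng.integers(nc)] = True
            if (dest & barrier).any():
                continue
            hours = travel_time(FrictionModel(_r(g, speed), barrier, dest))
            exp = self._nx_oracle(speed, barrier, dest, 1.0)
            np.testing.assert_allclose(hours.values[~barrier], exp[~barrier])


class TestAi:
    @pytest.mark.parametrize("hours,score", [(0, 100), (3, 50), (6, 0), (8, 0)])
    def test_linear_rule(self, hours, score):
        g = GridSpec(1, 1, 1.0)
        assert accessibility_index(_r(g, [[hours]])).values[0, 0] == score

    def test_unreachable_scores_zero(self):
        g = GridSpec(1, 1, 1.0)
        assert accessibility_index(_r(g, [[np.inf]])).values[0, 0] == 0.0


class TestLpi:
    def _model(self, g, cattle, avail):
        return LivestockModel({"cattle": _r(g, cattle)}, {"cattle": 6.25}, _r(g, avail))

    def test_no_livestock_scores_zero(self):
        g = GridSpec(1, 1, 1.0)
        assert livestock_pressure_index(self._model(g, [[0.0]], [[100.0]])).values[0, 0] == 0.0

    def test_half_ratio_scores_50(self):
        g = GridSpec(1, 1, 1.0)
        # requirement 8 * 6.25 = 50 against availability 100 -> ratio 0.5
        assert livestock_pressure_index(self._model(g, [[8.0]], [[100.0]])).values[0, 0] == 50.0

    def test_ratio_above_one_capped_at_100(self):
        g = GridSpec(1, 1, 1.0)
        out = livestock_pressure_index(self._model(g, [[27.2]], [[100.0]]))  # ratio 1.7
        assert out.values[0, 0] == 100.0

    def test_nonpositive_availability_fails(self):
        g = GridSpec(1, 1, 1.0)
        with pytest.raises(ValueError):
            livestock_pressure_index(self._model(g, [[1.0]], [[0.0]]))

    def test_literal_one_minus_variant(self):
        g = GridSpec(1, 1, 1.0)
        out = livestock_pressure_index(self._model(g, [[8.0]], [[100.0]]), literal_one_minus=True)
        assert out.values[0, 0] == 50.0  # 1 - 0.5 = 0.5


class TestComposeHi:
    def _stack(self, g, v):
        r = _r(g, np.full(g.shape, float(v)))
        return IndicatorStack(r, r.copy(), r.copy(), r.copy())

    def test_fully_converted_cell_is_100(self):
        g = GridSpec(1, 1, 1.0)
        out = compose_hi(_r(g, [[100.0]]), self._stack(g, 3.0))
        assert out.hi.values[0, 0] == 100.0

    def test_no_conversion_passes_indicator_mean(self):
        g = GridSpec(1, 1, 1.0)
        assert compose_hi(_r(g, [[0.0]]), self._stack(g, 50.0)).hi.values[0, 0] == 50.0

    def test_partial_conversion_arithmetic(self):
        g = GridSpec(1, 1, 1.0)
        out = compose_hi(_r(g, [[40.0]]), self._stack(g, 50.0))
        assert out.hi.values[0, 0] == pytest.approx(70.0)  # 40 + 50 * 0.6

    def test_out_of_range_conversion_fails(self):
        g = GridSpec(1, 1, 1.0)
        with pytest.raises(ValueError):
            compose_hi(_r(g, [[120.0]]), self._stack(g, 0.0))

    def test_hi_bounds_and_monotonicity(self, rng):
        g = GridSpec(10, 10, 1.0)
        conv = _r(g, rng.uniform(0, 100, g.shape))
        base = IndicatorStack(*[_r(g, rng.uniform(0, 100, g.shape)) for _ in range(4)])
        hi = compose_hi(conv, base).hi.values
        assert (hi >= conv.values - 1e-12).all() and (hi <= 100 + 1e-12).all()
        bumped = IndicatorStack(_r(g, np.minimum(base.vti.values + 10, 100)),
                                base.hpi, base.ai, base.lpi)
        hi2 = compose_hi(conv, bumped).hi.values
        assert (hi2 >= hi - 1e-12).all()


class TestPipeline:
    def test_pristine_landscape_has_zero_hi(self):
        from pnvgap.synthetic_landscape import LandscapeConfig, generate

        cfg = LandscapeConfig(seed=3, grid=GridSpec(40, 40), degradation_strength=0,
                              cropland_intensity=0, pop_peak=0,
                              livestock_mean_density=0, n_pa=10)
        ls = generate(cfg)
        _, _, _, res = compute_human_influence(
            ls.pnv, ls.luc_maps, ls.cropland_fraction, ls.urban_mask, ls.road_mask,
            ls.river_mask, ls.population, ls.livestock, ls.feed_availability)
        assert (res.hi.values == 0).all()

    def test_planted_indicator_means_recovered(self, small_landscape):
        ls = small_landscape
        _, ind, _, res = compute_human_influence(
            ls.pnv, ls.luc_maps, ls.cropland_fraction, ls.urban_mask, ls.road_mask,
            ls.river_mask, ls.population, ls.livestock, ls.feed_availability)
        from scipy.stats import norm

        zs = []
        for code, rec in ls.truth["per_pnv"].items():
            row = res.hi_pnv[res.hi_pnv.pnv_code == int(code)].iloc[0]
            np.testing.assert_allclose(row["conversion_mean"], rec["converted_mean_pct"], rtol=1e-10)
            np.testing.assert_allclose(row["hpi_mean"], rec["hpi_mean"], rtol=1e-10)
            np.testing.assert_allclose(row["lpi_mean"], rec["lpi_mean"], rtol=1e-10)
            diff = row["vti_mean"] - rec["vti_expected_mean"]
            if rec["vti_mean_se"] == 0:  # no degradation headroom in this PNV
                assert abs(diff) < 1e-12
                continue
            zs.append(diff / rec["vti_mean_se"])
        # 2 SE per comparison, adjusted for the simultaneous comparisons
        zs = np.asarray(zs)
        assert np.max(np.abs(zs)) <= norm.ppf(1 - 0.025 / zs.size)

    def test_bridge_allows_crossing_river(self, small_landscape):
        ls = small_landscape
        f = build_friction(ls.grid, ls.road_mask, ls.river_mask, ls.population, config=HIConfig())
        crossing = ls.river_mask.values.astype(bool) & ls.road_mask.values.astype(bool)
        if crossing.any():
            assert not f.barrier_mask[crossing].any()
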