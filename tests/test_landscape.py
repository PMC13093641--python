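"""Resistance surfaces, least-cost paths, geographic and climate distances."""

import itertools

import numpy as np
import pandas as pd
import pytest

from demogscape.landscape import (Raster, ResistanceConfig,
                                  combine_resistance, env_dissimilarity,
                                  great_circle_distance, landuse_resistance,
                                  least_cost_distance, select_uncorrelated_vars,
                                  slope_resistance)
from demogscape.stats import DistanceMatrix


def brute_force_least_cost(values, cell_size, start, goal):
    """Exhaustive enumeration over simple paths on a small 8-connected
    lattice; the independent oracle for Dijkstra."""
    nrow, ncol = values.shape
    best = [np.inf]

    def step(cur, visited, cost):
        if cost >= best[0]:
            return
        if cur == goal:
            best[0] = cost
            return
        r, c = cur
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if dr == dc == 0:
                continue
            nr, nc = r + dr, c + dc
            if not (0 <= nr < nrow and 0 <= nc < ncol):
                continue
            if (nr, nc) in visited:
                continue
            fac = np.sqrt(2) if dr and dc else 1.0
            w = 0.5 * (values[r, c] + values[nr, nc]) * cell_size * fac
            step((nr, nc), visited | {(nr, nc)}, cost + w)

    step(start, {start}, 0.0)
    return best[0]


class TestSlopeReclassification:
    @pytest.mark.parametrize("deg,expected", [
        (0, 1.0), (5, 1.0), (10, 1.0), (15, 1.5), (25, 1.5), (40, 1.5),
        (45, 4.0), (55, 4.0), (60, 4.0), (65, 6.0), (75, 6.0), (80, 6.0),
        (81, 10.0), (85, 10.0), (90, 10.0)])
    def test_band_values(self, deg, expected):
        r = Raster(np.array([[float(deg)]]), 100.0)
        assert slope_resistance(r).values[0, 0] == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            slope_resistance(Raster(np.array([[95.0]]), 100.0))

    def test_nodata_propagates(self):
        r = Raster(np.array([[5.0, -9999.0]]), 100.0)
        out = slope_resistance(r)
        assert out.values[0, 1] == -9999.0


class TestLanduseReclassification:
    @pytest.mark.parametrize("code,expected", [
        (1, 1.0), (2, 2.0), (3, 2.0), (4, 3.0), (5, 5.0), (6, 10.0)])
    def test_published_table(self, code, expected):
        r = Raster(np.array([[float(code)]]), 100.0)
        assert landuse_resistance(r).values[0, 0] == expected

    def test_unknown_code_named_in_error(self):
        with pytest.raises(ValueError, match="99"):
            landuse_resistance(Raster(np.array([[99.0]]), 100.0))


class TestCombine:
    def test_rules(self):
        a = Raster(np.array([[1.5]]), 50.0)
        b = Raster(np.array([[3.0]]), 50.0)
        assert combine_resistance(a, b).values[0, 0] == 4.5
        assert combine_resistance(a, b, "sum").values[0, 0] == 4.5
        assert combine_resistance(a, b, "max").values[0, 0] == 3.0

    def test_identity_surface(self):
        ones = Raster(np.ones((3, 3)), 10.0)
        for rule in ("product", "max"):
            assert (combine_resistance(ones, ones, rule).values == 1).all()

    def test_misaligned_rejected(self):
        with pytest.raises(ValueError):
            combine_resistance(Raster(np.ones((2, 2)), 10.0),
                               Raster(np.ones((3, 3)), 10.0))


class TestLeastCost:
    def test_same_cell_zero(self):
        r = Raster(np.ones((3, 3)), 100.0)
        d = least_cost_distance(r, [(1, 1), (1, 1)])
        assert d.values[0, 1] == 0

    def test_uniform_row(self):
        r = Raster(np.ones((1, 4)), 100.0)
        d = least_cost_distance(r, [(0, 0), (0, 3)])
        assert d.values[0, 1] == pytest.approx(300.0)

    @pytest.mark.parametrize("seed,shape", [(0, (3, 3)), (1, (3, 3)),
                                            (2, (4, 4)), (3, (4, 4))])
    def test_matches_exhaustive_enumeration(self, seed, shape):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(1, 10, size=shape)
        r = Raster(vals, 100.0)
        start, goal = (0, 0), (shape[0] - 1, shape[1] - 1)
        d = least_cost_distance(r, [start, goal])
        expected = brute_force_least_cost(vals, 100.0, start, goal)
        assert d.values[0, 1] == pytest.approx(expected)

    def test_detour_around_costly_column(self):
        vals = np.ones((3, 3))
        vals[:, 1] = 1000.0
        r = Raster(vals, 100.0)
        d = least_cost_distance(r, [(1, 0), (1, 2)])
        expected = brute_force_least_cost(vals, 100.0, (1, 0), (1, 2))
        assert d.values[0, 1] == pytest.approx(expected)

    def test_triangle_inequality_and_lower_bound(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 8, size=(6, 6))
        r = Raster(vals, 100.0)
        pts = [(0, 0), (5, 5), (0, 5), (3, 2)]
        d = least_cost_distance(r, pts).values
        for i, j, k in itertools.permutations(range(4), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9
        # lower bound: chebyshev lattice distance x min resistance
        for i, j in itertools.combinations(range(4), 2):
            cheb = max(abs(pts[i][0] - pts[j][0]),
                       abs(pts[i][1] - pts[j][1]))
            assert d[i, j] >= cheb * 100.0 * vals.min() - 1e-9

    def test_unreachable_pair_is_error(self):
        vals = np.ones((3, 3))
        vals[:, 1] = -9999.0
        r = Raster(vals, 100.0)
        with pytest.raises(ValueError, match="not connected"):
            least_cost_distance(r, [(1, 0), (1, 2)])

    def test_nodata_point_is_error(self):
        vals = np.ones((2, 2))
        vals[0, 0] = -9999.0
        with pytest.raises(ValueError, match="nodata"):
            least_cost_distance(Raster(vals, 100.0), [(0, 0), (1, 1)])


class TestAsciiGrid:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        r = Raster(rng.uniform(0, 50, size=(5, 7)), 250.0, (12.5, -3.25))
        r.to_ascii(tmp_path / "g.asc")
        back = Raster.from_ascii(tmp_path / "g.asc")
        assert back.shape == r.shape
        assert back.cell_size == r.cell_size
        assert back.origin == r.origin
        assert np.allclose(back.values, r.values, rtol=1e-6)


class TestGreatCircle:
    def test_identical_zero(self):
        d = great_circle_distance([(121.0, 23.5), (121.0, 23.5)])
        assert d.values[0, 1] == 0

    def test_one_degree_meridian(self):
        d = great_circle_distance([(0.0, 0.0), (0.0, 1.0)])
        assert d.values[0, 1] == pytest.approx(111_195, rel=1e-4)

    def test_invalid_latitude(self):
        with pytest.raises(ValueError):
            great_circle_distance([(0.0, 95.0), (0.0, 0.0)])


class TestEnvDissimilarity:
    def test_identical_rows_zero(self):
        df = pd.DataFrame({"bio7": [5.0, 5.0, 8.0]}, index=list("abc"))
        d = env_dissimilarity(df, metric="euclidean")
        assert d.values[0, 1] == pytest.approx(0.0)

    def test_euclidean_in_sd_units(self):
        v = np.array([1.0, 3.0, 5.0, 7.0])
        df = pd.DataFrame({"bio7": v}, index=list("abcd"))
        d = env_dissimilarity(df, metric="euclidean")
        sd = v.std()
        for i, j in itertools.combinations(range(4), 2):
            assert d.values[i, j] == pytest.approx(abs(v[i] - v[j]) / sd)

    def test_variable_order_invariance(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((5, 3)), columns=["a", "b", "c"])
        d1 = env_dissimilarity(df).values
        d2 = env_dissimilarity(df[["c", "a", "b"]]).values
        assert np.allclose(d1, d2)

    def test_constant_variable_dropped_with_warning(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [0.0, 1.0, 2.0]})
        with pytest.warns(UserWarning, match="constant"):
            d = env_dissimilarity(df, metric="euclidean")
        assert d.values[0, 2] > 0


class TestVariableSelection:
    def _genetic(self, v):
        m = np.abs(np.subtract.outer(v, v)).astype(float)
        return DistanceMatrix([str(i) for i in range(len(v))], m)

    def test_duplicate_variable_one_kept(self):
        rng = np.random.default_rng(2)
        x = rng.random(8)
        df = pd.DataFrame({"a": x, "b": x})
        kept = select_uncorrelated_vars(df, self._genetic(x))
        assert len(kept) == 1

    def test_keeps_more_genetic_correlated(self):
        rng = np.random.default_rng(3)
        sig = np.linspace(0, 1, 10)
        a = sig + rng.normal(0, 0.05, 10)
        b = a + rng.normal(0, 0.12, 10)     # correlated with a, noisier
        assert abs(np.corrcoef(a, b)[0, 1]) > 0.7
        kept = select_uncorrelated_vars(pd.DataFrame({"a": a, "b": b}),
                                        self._genetic(sig))
        assert kept == ["a"]

    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(40, 3)), columns=["a", "b", "c"])
        gd = self._genetic(rng.random(40))
        assert select_uncorrelated_vars(df, gd) == ["a", "b", "c"]
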