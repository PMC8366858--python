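"""Raster slope, shore distance, IDW, standardization, design matrix."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString

from scoterhab.covariates import (
    CovariateTable,
    LINEAR_COVARIATES,
    DESIGN_COLUMNS,
    build_design_matrix,
    destandardize,
    distance_to_shore,
    idw_surface,
    average_survey_window,
    pairwise_collinearity,
    standardize,
)
from scoterhab.raster import RasterGrid, compute_slope, read_ascii_grid, write_ascii_grid


class TestRaster:
    def test_ascii_roundtrip(self, tmp_path, rng):
        r = RasterGrid(xll=10.0, yll=-5.0, cellsize=250.0,
                       values=rng.normal(size=(6, 4)).round(4))
        write_ascii_grid(tmp_path / "g.asc", r)
        back = read_ascii_grid(tmp_path / "g.asc")
        assert back.xll == r.xll and back.yll == r.yll and back.cellsize == r.cellsize
        np.testing.assert_allclose(back.values, r.values, rtol=1e-5)

    def test_nearest_sample(self):
        vals = np.arange(12, dtype=float).reshape(3, 4)
        r = RasterGrid(xll=0, yll=0, cellsize=100, values=vals)
        # (50, 50) is the center of the bottom-left cell = row 2, col 0
        assert r.sample(50, 50) == vals[2, 0]
        assert r.sample(350, 250) == vals[0, 3]


class TestSlope:
    def test_flat_field_zero(self):
        r = RasterGrid(0, 0, 100, np.full((5, 5), -12.0))
        assert np.all(compute_slope(r).values == 0)

    def test_analytic_plane(self):
        # depth drops 1 m per 100 m of easting -> slope atan(1/100) everywhere
        x = np.arange(8) * 100.0
        vals = np.tile(-x / 100.0, (6, 1))
        r = RasterGrid(0, 0, 100.0, vals)
        s = compute_slope(r)
        expected = np.degrees(np.arctan(1 / 100))
        np.testing.assert_allclose(s.values, expected, rtol=1e-12)

    def test_range_and_small_raster_rejected(self, rng):
        r = RasterGrid(0, 0, 50.0, rng.normal(0, 30, size=(10, 10)))
        s = compute_slope(r).values
        assert np.all((s >= 0) & (s < 90))
        with pytest.raises(ValueError):
            compute_slope(RasterGrid(0, 0, 50.0, np.zeros((1, 5))))


class TestDistanceToShore:
    def test_point_on_vertex(self):
        shore = LineString([(0, 0), (0, 5000)])
        assert distance_to_shore([(0, 0)], shore)[0] == 0.0

    def test_perpendicular(self):
        shore = LineString([(0, -1e5), (0, 1e5)])
        assert distance_to_shore([(3000.0, 123.0)], shore)[0] == pytest.approx(3.0)

    def test_brute_force_oracle(self, rng):
        verts = np.column_stack(
            [rng.normal(0, 800, 30), np.linspace(0, 50_000, 30)]
        )
        shore = LineString(verts)
        pts = np.column_stack(
            [rng.uniform(500, 20_000, 100), rng.uniform(0, 50_000, 100)]
        )

        def seg_dist(p, a, b):
            ab = b - a
            t = np.clip(np.dot(p - a, ab) / np.dot(ab, ab), 0, 1)
            return np.linalg.norm(p - (a + t * ab))

        got = distance_to_shore(pts, shore)
        for p, g in zip(pts, got):
            brute = min(
                seg_dist(p, verts[i], verts[i + 1]) for i in range(len(verts) - 1)
            )
            assert g == pytest.approx(brute / 1000.0, rel=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            distance_to_shore([(0, 0)], [])


class TestIDW:
    def test_coincident_target_returns_buoy_value(self):
        obs = np.array([[0.0, 0.0], [1000.0, 0.0]])
        vals = np.array([4.0, 8.0])
        out = idw_surface(obs, vals, np.array([[1000.0, 0.0]]))
        assert out[0] == 8.0

    @pytest.mark.parametrize("power", [0.5, 1.0, 2.0, 4.0])
    def test_equidistant_symmetry(self, power):
        obs = np.array([[-500.0, 0.0], [500.0, 0.0]])
        out = idw_surface(obs, np.array([4.0, 8.0]), np.array([[0.0, 700.0]]), power)
        assert out[0] == pytest.approx(6.0)

    def test_formula_oracle(self, rng):
        obs = rng.uniform(0, 10_000, (5, 2))
        vals = rng.uniform(2, 12, 5)
        tgt = rng.uniform(0, 10_000, (10, 2))
        got = idw_surface(obs, vals, tgt, power=2.0)
        for t, g in zip(tgt, got):
            d = np.linalg.norm(obs - t, axis=1)
            w = d**-2.0
            assert g == pytest.approx((w * vals).sum() / w.sum(), rel=1e-12)

    def test_bounded_by_observations(self, rng):
        obs = rng.uniform(0, 5000, (8, 2))
        vals = rng.uniform(-3, 9, 8)
        got = idw_surface(obs, vals, rng.uniform(0, 5000, (50, 2)))
        assert got.min() >= vals.min() - 1e-12
        assert got.max() <= vals.max() + 1e-12

    def test_missing_handling(self):
        obs = np.array([[0.0, 0.0], [1000.0, 0.0]])
        out = idw_surface(obs, np.array([np.nan, 8.0]), np.array([[200.0, 0.0]]))
        assert out[0] == 8.0
        with pytest.raises(ValueError, match="missing"):
            idw_surface(obs, np.array([np.nan, np.nan]), np.array([[0.0, 0.0]]))


class TestSurveyWindow:
    def test_idempotent_mean(self):
        s = np.array([1.0, 2.0, 3.0])
        out = average_survey_window({"a": s, "b": s, "c": s}, ["a", "b", "c"])
        np.testing.assert_array_equal(out, s)

    def test_two_dates(self):
        out = average_survey_window(
            {"a": np.array([2.0]), "b": np.array([4.0])}, ["a", "b"]
        )
        assert out[0] == 3.0

    def test_arithmetic_oracle(self, rng):
        surfaces = {f"d{i}": rng.normal(size=7) for i in range(5)}
        out = average_survey_window(surfaces, list(surfaces))
        np.testing.assert_allclose(out, sum(surfaces.values()) / 5, rtol=1e-12)

    def test_missing_date_error(self):
        with pytest.raises(ValueError, match="d2"):
            average_survey_window({"d1": np.zeros(3)}, ["d1", "d2"])


def toy_table(rng, n=50):
    df = pd.DataFrame({c: rng.normal(size=n) for c in LINEAR_COVARIATES})
    df["cell_id"] = [f"c{i}" for i in range(n)]
    df["year"] = 2009
    df["count"] = rng.integers(0, 5, n)
    return CovariateTable(data=df)


class TestStandardize:
    def test_basic_arithmetic(self):
        df = pd.DataFrame({c: [1.0, 2.0, 3.0] for c in LINEAR_COVARIATES})
        t = standardize(CovariateTable(data=df))
        np.testing.assert_allclose(t.data["bathy_z"], [-1, 0, 1])

    def test_mean_sd_and_roundtrip(self, rng):
        t = standardize(toy_table(rng))
        for c in LINEAR_COVARIATES:
            z = t.data[c + "_z"]
            assert abs(z.mean()) < 1e-10 and abs(z.std(ddof=1) - 1) < 1e-10
            back = destandardize(t, c, z)
            np.testing.assert_allclose(back, t.data[c], rtol=1e-10, atol=1e-10)

    def test_idempotent_with_stored_constants(self, rng):
        t = standardize(toy_table(rng))
        z1 = t.data[[c + "_z" for c in LINEAR_COVARIATES]].copy()
        t2 = standardize(t)  # constants reused
        z2 = t2.data[[c + "_z" for c in LINEAR_COVARIATES]]
        assert z1.equals(z2)

    def test_zero_variance_rejected(self, rng):
        t = toy_table(rng)
        t.data["wind"] = 5.0
        with pytest.raises(ValueError, match="wind"):
            standardize(t)


class TestCollinearity:
    def test_identity_and_sign(self, rng):
        t = toy_table(rng, n=200)
        t.data["slope"] = -t.data["bathy"]
        r = pairwise_collinearity(t)
        assert r.loc["bathy", "bathy"] == 1.0
        assert r.loc["bathy", "slope"] == pytest.approx(1.0)

    def test_independent_columns_near_zero(self, rng):
        t = toy_table(rng, n=10_000)
        r = pairwise_collinearity(t)
        off = r.to_numpy()[~np.eye(len(LINEAR_COVARIATES), dtype=bool)]
        assert off.max() < 0.05

    def test_warning_and_constant_error(self, rng):
        t = toy_table(rng, n=200)
        t.data["dist"] = t.data["bathy"] * 0.95 + rng.normal(0, 0.1, 200)
        with pytest.warns(UserWarning):
            pairwise_collinearity(t)
        t.data["dist"] = 1.0
        with pytest.raises(ValueError):
            pairwise_collinearity(t)


class TestDesignMatrix:
    def test_fourteen_named_columns(self, rng):
        d = build_design_matrix(standardize(toy_table(rng)))
        assert d.X.shape[1] == 14
        assert d.columns == DESIGN_COLUMNS

    def test_zero_row(self, rng):
        t = standardize(toy_table(rng))
        for c in LINEAR_COVARIATES:
            t.data.loc[0, c + "_z"] = 0.0
        d = build_design_matrix(t)
        np.testing.assert_array_equal(d.X[0], [1.0] + [0.0] * 13)

    def test_higher_order_columns_reconstruct(self, rng):
        t = standardize(toy_table(rng))
        d = build_design_matrix(t)
        cols = {c: d.X[:, i] for i, c in enumerate(d.columns)}
        np.testing.assert_allclose(cols["nao_x_bathy"], cols["nao"] * cols["bathy"])
        np.testing.assert_allclose(cols["nao_x_dist"], cols["nao"] * cols["dist"])
        np.testing.assert_allclose(cols["bathy2"], cols["bathy"] ** 2)
        np.testing.assert_allclose(cols["wave2"], cols["wave"] ** 2)

    def test_row_mismatch_rejected(self, rng):
        t = standardize(toy_table(rng))
        with pytest.raises(ValueError, match="mismatch"):
            build_design_matrix(t, counts=np.zeros(3))

    def test_unstandardized_rejected(self, rng):
        with pytest.raises(ValueError, match="standardized"):
            build_design_matrix(toy_table(rng))
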