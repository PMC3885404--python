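"""Point ingest: reading, run deduplication, DEM, height normalization."""

import numpy as np
import pandas as pd
import pytest

from rockveg.grids import GridSpec, HeightRaster, read_ascii_grid, write_ascii_grid
from rockveg.points import (
    PointIngestError,
    build_dem,
    dedup_runs,
    normalize_heights,
    read_points,
    validate_points,
    write_points,
)


class TestReadPoints:
    def test_valid_csv_identity(self, toy_points, tmp_path):
        path = tmp_path / "pts.csv"
        toy_points.to_csv(path, index=False)
        out = read_points(path)
        assert len(out) == 5
        pd.testing.assert_frame_equal(
            out[["x", "y", "z"]], toy_points[["x", "y", "z"]]
        )

    def test_invalid_return_number_rejected_with_warning(self, toy_points):
        bad = toy_points.copy()
        bad.loc[2, "return_number"] = 5
        with pytest.warns(UserWarning, match="rejected 1"):
            out = validate_points(bad)
        assert len(out) == 4

    def test_nonfinite_coordinate_rejected(self, toy_points):
        bad = toy_points.copy()
        bad.loc[0, "x"] = np.nan
        with pytest.warns(UserWarning):
            out = validate_points(bad)
        assert len(out) == 4

    def test_missing_column_fatal_names_column(self, toy_points, tmp_path):
        path = tmp_path / "pts.csv"
        toy_points.drop(columns=["scan_angle"]).to_csv(path, index=False)
        with pytest.raises(PointIngestError, match="scan_angle"):
            read_points(path)

    def test_csv_round_trip(self, small_cloud, tmp_path):
        path = tmp_path / "cloud.csv"
        write_points(small_cloud, path)
        back = read_points(path)
        np.testing.assert_allclose(back["x"], small_cloud["x"])
        np.testing.assert_allclose(back["z"], small_cloud["z"])
        assert (back["run_id"] == small_cloud["run_id"]).all()


def _brute_force_dedup(points, cell_size=4.0):
    """Per-cell winner-run oracle: smallest mean |scan angle|, then run id."""
    grid = GridSpec.from_bounds(
        points["x"].min(), points["y"].min(), points["x"].max(), points["y"].max(), cell_size
    )
    keep = np.zeros(len(points), dtype=bool)
    i, j = grid.cell_index(points["x"].to_numpy(), points["y"].to_numpy())
    for cell in set(zip(i, j)):
        mask = (i == cell[0]) & (j == cell[1])
        sub = points.loc[mask]
        stats = sub.groupby("run_id")["scan_angle"].apply(lambda s: s.abs().mean())
        winner = stats.sort_index().sort_values(kind="stable").index[0]
        keep |= mask & (points["run_id"] == winner).to_numpy()
    return points.loc[keep].reset_index(drop=True)


class TestDedupRuns:
    def test_smaller_mean_angle_wins(self):
        pts = pd.DataFrame(
            {
                "x": [1.0, 2.0, 1.5, 2.5],
                "y": [1.0, 2.0, 1.5, 2.5],
                "z": 0.0,
                "return_number": 1,
                "intensity": 0.0,
                "scan_angle": [5.0, 5.0, 12.0, 12.0],
                "run_id": ["A", "A", "B", "B"],
                "is_ground": True,
            }
        )
        out = dedup_runs(pts, 4.0)
        assert set(out["run_id"]) == {"A"}
        assert len(out) == 2

    def test_single_run_cell_unchanged(self, toy_points):
        one_run = toy_points.assign(run_id="A")
        out = dedup_runs(one_run, 4.0)
        assert len(out) == len(one_run)

    def test_tie_keeps_smaller_run_id(self):
        pts = pd.DataFrame(
            {
                "x": [1.0, 2.0],
                "y": [1.0, 1.0],
                "z": 0.0,
                "return_number": 1,
                "intensity": 0.0,
                "scan_angle": [7.0, -7.0],
                "run_id": ["B", "A"],
                "is_ground": True,
            }
        )
        out = dedup_runs(pts, 4.0)
        assert set(out["run_id"]) == {"A"}

    def test_matches_brute_force_oracle_and_idempotent(self, small_cloud):
        sub = small_cloud.iloc[:4000]
        out = dedup_runs(sub, 4.0)
        oracle = _brute_force_dedup(sub, 4.0)
        assert len(out) <= len(sub)
        merged = out.sort_values(["x", "y", "z"]).reset_index(drop=True)
        expect = oracle.sort_values(["x", "y", "z"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(merged, expect)
        again = dedup_runs(out, 4.0)
        assert len(again) == len(out)

    def test_empty_input(self):
        empty = pd.DataFrame(columns=["x", "y", "z", "scan_angle", "run_id"])
        assert len(dedup_runs(empty)) == 0


def _barycentric_oracle(xy, z, q):
    """Interpolate z at q by walking every triangle of the Delaunay mesh."""
    from scipy.spatial import Delaunay

    tri = Delaunay(xy)
    out = np.full(len(q), np.nan)
    for t in tri.simplices:
        A = np.c_[xy[t].T, ]
        for k, p in enumerate(q):
            T = np.vstack([xy[t].T, np.ones(3)])
            try:
                lam = np.linalg.solve(T, np.array([p[0], p[1], 1.0]))
            except np.linalg.LinAlgError:
                continue
            if (lam >= -1e-9).all():
                out[k] = lam @ z[t]
    return out


class TestBuildDem:
    def test_exact_on_plane(self):
        rng = np.random.default_rng(0)
        pts = pd.DataFrame(
            {
                "x": rng.uniform(0, 20, 50),
                "y": rng.uniform(0, 20, 50),
                "is_ground": True,
            }
        )
        pts["z"] = 2 + 0.1 * pts["x"]
        dem = build_dem(pts, cell_size=2.0)
        cx, _ = dem.grid.centers()
        inside = ~dem.extrapolated
        np.testing.assert_allclose(dem.values[inside], (2 + 0.1 * cx)[inside], atol=1e-9)

    def test_cell_center_on_ground_point(self):
        # point exactly at a cell center of the snapped 2 m grid
        pts = pd.DataFrame(
            {
                "x": [1.0, 9.0, 1.0, 9.0],
                "y": [1.0, 1.0, 9.0, 9.0],
                "z": [4.0, 8.0, 6.0, 10.0],
                "is_ground": True,
            }
        )
        dem = build_dem(pts, cell_size=2.0)
        assert dem.sample([1.0 + 1e-9], [1.0 + 1e-9])[0] == pytest.approx(4.0, abs=1e-9)

    def test_interior_matches_barycentric_oracle(self):
        rng = np.random.default_rng(1)
        xy = rng.uniform(0, 30, (60, 2))
        z = rng.uniform(0, 5, 60)
        pts = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "z": z, "is_ground": True})
        dem = build_dem(pts, cell_size=2.0)
        cx, cy = dem.grid.centers()
        inside = ~dem.extrapolated
        q = np.c_[cx[inside], cy[inside]]
        oracle = _barycentric_oracle(xy, z, q)
        ok = ~np.isnan(oracle)
        np.testing.assert_allclose(dem.values[inside][ok], oracle[ok], atol=1e-9)

    def test_too_few_ground_points_fatal(self, toy_points):
        two = toy_points.iloc[:2].assign(is_ground=True)
        with pytest.raises(PointIngestError):
            build_dem(two)

    def test_collinear_ground_fatal(self):
        pts = pd.DataFrame(
            {"x": [0.0, 1.0, 2.0], "y": [0.0, 1.0, 2.0], "z": 1.0, "is_ground": True}
        )
        with pytest.raises(PointIngestError):
            build_dem(pts)


class TestNormalizeHeights:
    @pytest.fixture()
    def flat_dem(self):
        grid = GridSpec(0, 0, 2.0, 5, 5)
        return HeightRaster(grid, np.full((5, 5), 2.4))

    def test_height_above_ground(self, flat_dem):
        pts = pd.DataFrame(
            {"x": [3.0], "y": [3.0], "z": [12.4], "is_ground": [False]}
        )
        out, clamped = normalize_heights(pts, flat_dem)
        assert out["height"].iloc[0] == pytest.approx(10.0)
        assert clamped == 0

    def test_ground_point_height_zero(self, flat_dem):
        pts = pd.DataFrame({"x": [3.0], "y": [3.0], "z": [2.4], "is_ground": [True]})
        out, _ = normalize_heights(pts, flat_dem)
        assert out["height"].iloc[0] == 0.0

    def test_below_dem_clamped_and_counted(self, flat_dem):
        pts = pd.DataFrame(
            {"x": [3.0, 5.0], "y": [3.0, 5.0], "z": [2.1, 3.4], "is_ground": False}
        )
        out, clamped = normalize_heights(pts, flat_dem)
        assert out["height"].iloc[0] == 0.0
        assert clamped == 1
        assert (out["height"] >= 0).all()

    def test_point_outside_dem_dropped_with_warning(self, flat_dem):
        pts = pd.DataFrame(
            {"x": [3.0, 99.0], "y": [3.0, 99.0], "z": [5.0, 5.0], "is_ground": False}
        )
        with pytest.warns(UserWarning, match="outside"):
            out, _ = normalize_heights(pts, flat_dem)
        assert len(out) == 1


def test_ascii_grid_round_trip(tmp_path):
    grid = GridSpec(10.0, 20.0, 2.0, 4, 3)
    values = np.arange(12, dtype=float).reshape(3, 4)
    write_ascii_grid(HeightRaster(grid, values), tmp_path / "r.asc")
    back = read_ascii_grid(tmp_path / "r.asc")
    assert back.grid == grid
    np.testing.assert_allclose(back.values, values)
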