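"""Point-cloud I/O, normalization, clipping, thinning and density accounting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lidar_agb as la
from lidar_agb.pointcloud import DemRaster, NormalizedPointCloud, RawPointCloud


def make_cloud(x, y, h, cls=None):
    x = np.asarray(x, float)
    cls = np.full(x.size, 5) if cls is None else np.asarray(cls)
    return NormalizedPointCloud(x, np.asarray(y, float), np.asarray(h, float), cls)


# ---------------------------------------------------------------------------
# I/O


class TestCsvIO:
    def test_three_line_csv(self, tmp_path):
        p = tmp_path / "pts.csv"
        p.write_text("x,y,z,class\n1.0,2.0,3.0,5\n4.0,5.0,6.0,2\n7.0,8.0,9.0,5\n")
        cloud = la.read_point_cloud(p, "xyz-csv")
        assert len(cloud) == 3
        np.testing.assert_array_equal(cloud.x, [1.0, 4.0, 7.0])
        np.testing.assert_array_equal(cloud.classification, [5, 2, 5])

    def test_round_trip_preserves_coordinates(self, tmp_path, rng):
        raw = RawPointCloud(rng.uniform(0, 100, 50), rng.uniform(0, 100, 50),
                            rng.uniform(0, 40, 50), np.full(50, 5))
        la.write_point_cloud_csv(raw, tmp_path / "c.csv")
        back = la.read_point_cloud(tmp_path / "c.csv")
        np.testing.assert_allclose(back.x, raw.x)
        np.testing.assert_allclose(back.z, raw.z)
        assert len(back) == 50

    def test_empty_file_warns_not_raises(self, tmp_path):
        p = tmp_path / "empty.csv"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            cloud = la.read_point_cloud(p)
        assert len(cloud) == 0

    def test_malformed_record_names_row(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("x,y,z,class\n1.0,2.0,3.0,5\n4.0,,6.0,2\n")
        with pytest.raises(ValueError, match="row 2"):
            la.read_point_cloud(p)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown point-cloud format"):
            la.read_point_cloud(tmp_path / "x.bin", "laz")


# ---------------------------------------------------------------------------
# Normalization


class TestNormalize:
    def test_flat_zero_dem_is_identity(self, rng):
        raw = RawPointCloud(rng.uniform(1, 9, 30), rng.uniform(1, 9, 30),
                            rng.uniform(0, 30, 30), np.full(30, 5))
        dem = DemRaster.flat(0, 0, 10, 10)
        norm = la.normalize_heights(raw, dem)
        np.testing.assert_allclose(norm.h, raw.z)

    def test_constant_dem_subtracts(self):
        raw = RawPointCloud([5.0], [5.0], [112.4], [5])
        dem = DemRaster.flat(0, 0, 10, 10, elevation=100.0)
        norm = la.normalize_heights(raw, dem)
        assert norm.h[0] == pytest.approx(12.4)

    def test_tilted_plane_bilinear_exact(self, rng):
        # bilinear interpolation reproduces a planar surface exactly
        p, q, r = 50.0, 0.3, -0.2
        n = 24
        xs = np.arange(n) + 0.5
        gx, gy = np.meshgrid(xs, xs)
        dem = DemRaster(0, 0, 1.0, p + q * gx + r * gy)
        x = rng.uniform(1, n - 1, 20)
        y = rng.uniform(1, n - 1, 20)
        z = rng.uniform(100, 140, 20)
        raw = RawPointCloud(x, y, z, np.full(20, 5))
        norm = la.normalize_heights(raw, dem, low_clamp=np.inf)
        np.testing.assert_allclose(norm.h, z - (p + q * x + r * y), atol=1e-9)

    def test_outside_extent_raises_with_count(self):
        raw = RawPointCloud([5.0, 50.0, 60.0], [5.0, 5.0, 5.0],
                            [1.0, 1.0, 1.0], [5, 5, 5])
        dem = DemRaster.flat(0, 0, 10, 10)
        with pytest.raises(ValueError, match="2 returns"):
            la.normalize_heights(raw, dem)

    def test_nodata_cells_drop_returns(self):
        grid = np.zeros((10, 10))
        grid[4:6, 4:6] = -9999.0
        dem = DemRaster(0, 0, 1.0, grid)
        raw = RawPointCloud([5.0, 1.0], [5.0, 1.0], [3.0, 4.0], [5, 5])
        with pytest.warns(UserWarning, match="nodata"):
            norm = la.normalize_heights(raw, dem)
        assert len(norm) == 1 and norm.h[0] == pytest.approx(4.0)

    def test_subground_clamp_and_drop(self):
        raw = RawPointCloud([1, 2, 3.0], [1, 1, 1.0], [-0.3, -2.0, 5.0],
                            [2, 2, 5])
        dem = DemRaster.flat(0, 0, 10, 10)
        with pytest.warns(UserWarning, match="below ground"):
            norm = la.normalize_heights(raw, dem)
        # -0.3 clamped to 0; -2.0 dropped; 5.0 untouched
        np.testing.assert_allclose(np.sort(norm.h), [0.0, 5.0])


# ---------------------------------------------------------------------------
# Clipping


class TestClip:
    def test_boundary_return_retained(self):
        geom = la.PlotGeometry(0, 0, "circle", 10.0)
        cloud = make_cloud([10.0], [0.0], [5.0])
        assert len(la.clip_to_plot(cloud, geom)) == 1

    def test_009_ha_circle_radius_matches_field_convention(self):
        geom = la.PlotGeometry.from_area(0, 0, "circle", 0.09)
        assert geom.dimension == pytest.approx(16.9, abs=0.05)
        assert geom.area_ha == pytest.approx(0.09, abs=1e-12)

    @pytest.mark.parametrize("shape,dim", [("circle", 13.0), ("square", 22.0)])
    def test_membership_matches_brute_force(self, shape, dim, rng):
        geom = la.PlotGeometry(50.0, 50.0, shape, dim)
        x = rng.uniform(20, 80, 100)
        y = rng.uniform(20, 80, 100)
        cloud = make_cloud(x, y, np.zeros(100))
        kept = la.clip_to_plot(cloud, geom)
        if shape == "circle":
            expect = [(xi - 50) ** 2 + (yi - 50) ** 2 <= dim**2
                      for xi, yi in zip(x, y)]
        else:
            expect = [abs(xi - 50) <= dim / 2 and abs(yi - 50) <= dim / 2
                      for xi, yi in zip(x, y)]
        assert len(kept) == sum(expect)
        np.testing.assert_array_equal(np.sort(kept.x), np.sort(x[np.array(expect)]))

    def test_clip_normalize_commute_on_flat_dem(self, rng):
        x, y = rng.uniform(1, 19, 200), rng.uniform(1, 19, 200)
        z = rng.uniform(8, 30, 200)  # keep every return above the 7 m ground
        raw = RawPointCloud(x, y, z, np.full(200, 5))
        dem = DemRaster.flat(0, 0, 20, 20, elevation=7.0)
        geom = la.PlotGeometry(10, 10, "circle", 6.0)
        a = la.clip_to_plot(la.normalize_heights(raw, dem), geom)
        norm_then = la.normalize_heights(
            RawPointCloud(*[v[geom.contains(x, y)] for v in (x, y, z)],
                          np.full(int(geom.contains(x, y).sum()), 5)), dem)
        np.testing.assert_allclose(np.sort(a.h), np.sort(norm_then.h))


# ---------------------------------------------------------------------------
# Thinning and density


class TestThin:
    def setup_method(self):
        r = np.random.default_rng(7)
        self.geom = la.PlotGeometry(5, 5, "square", 10.0)  # 100 m2
        self.cloud = make_cloud(r.uniform(0, 10, 1000), r.uniform(0, 10, 1000),
                                r.uniform(0, 30, 1000))

    def test_exact_keep_count(self):
        thinned = la.thin_to_density(self.cloud, self.geom, 5.0, seed=1)
        assert len(thinned) == 500
        assert la.point_density(thinned, self.geom) == pytest.approx(5.0)

    def test_subset_with_identical_fields(self):
        thinned = la.thin_to_density(self.cloud, self.geom, 3.0, seed=2)
        original = {(x, y, h) for x, y, h in
                    zip(self.cloud.x, self.cloud.y, self.cloud.h)}
        assert all((x, y, h) in original for x, y, h in
                   zip(thinned.x, thinned.y, thinned.h))

    def test_target_at_or_above_current_is_noop(self):
        with pytest.warns(UserWarning, match="unchanged"):
            out = la.thin_to_density(self.cloud, self.geom, 50.0, seed=3)
        assert len(out) == 1000
        np.testing.assert_array_equal(out.h, self.cloud.h)

    def test_seed_determinism_and_variation(self):
        a = la.thin_to_density(self.cloud, self.geom, 5.0, seed=9)
        b = la.thin_to_density(self.cloud, self.geom, 5.0, seed=9)
        np.testing.assert_array_equal(a.x, b.x)
        differing = 0
        for s in range(10):
            c = la.thin_to_density(self.cloud, self.geom, 5.0, seed=100 + s)
            d = la.thin_to_density(self.cloud, self.geom, 5.0, seed=200 + s)
            differing += not np.array_equal(c.x, d.x)
        assert differing == 10

    def test_lineage_recorded(self):
        t = la.thin_to_density(self.cloud, self.geom, 5.0, seed=4)
        assert t.provenance["thinned_to"] == 5.0
        assert t.provenance["thin_seed"] == 4

    @given(target=st.floats(0.5, 9.5), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_thinning_count_contract_property(self, target, seed):
        n_keep = int(np.round(target * self.geom.area_m2))
        thinned = la.thin_to_density(self.cloud, self.geom, target, seed=seed)
        assert len(thinned) == min(n_keep, 1000)

    def test_density_examples(self):
        assert la.point_density(self.cloud, self.geom) == pytest.approx(10.0)
        empty = make_cloud([], [], [])
        assert la.point_density(empty, self.geom) == 0.0

    def test_synthetic_density_is_exact(self):
        cfg = la.StandConfig(extent_x=30, extent_y=30, seed=5)
        cloud = la.sample_returns(la.simulate_stand(cfg), cfg)
        geom = la.PlotGeometry(15, 15, "square", 30.0)
        assert la.point_density(cloud, geom) == pytest.approx(20.0)
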