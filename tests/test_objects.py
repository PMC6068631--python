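import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenocloud.cloud import PointCloud
from phenocloud.exceptions import EmptySegmentError, InvalidConfigError
from phenocloud.objects import (
    Measurement,
    RectRegion,
    TrimSpec,
    crop_rectangle,
    measure_height,
    measure_object,
    measure_xy,
    slice_extents,
    trimmed_histogram_mean,
    zero_bottom,
)
from phenocloud.scene import NoiseModel, ObjectSpec, make_object_cloud


def brute_force_slices(xyz, width, min_points):
    """Independent O(n^2) oracle for slice_extents."""
    z = xyz[:, 2]
    idx = np.floor((z - z.min()) / width).astype(int)
    out = {}
    for u in sorted(set(idx)):
        members = xyz[idx == u]
        if len(members) < min_points:
            continue
        dim_x = max(abs(a[0] - b[0]) for a in members for b in members)
        dim_y = max(abs(a[1] - b[1]) for a in members for b in members)
        out[u] = (dim_x, dim_y)
    return out


class TestCropRectangle:
    def test_full_bbox_is_identity(self, clean_cuboid):
        xyz = clean_cuboid.xyz
        region = RectRegion(
            xyz[:, 0].min(), xyz[:, 0].max(), xyz[:, 1].min(), xyz[:, 1].max()
        )
        out = crop_rectangle(clean_cuboid, region)
        np.testing.assert_array_equal(out.xyz, xyz)

    def test_region_outside_raises(self, clean_cuboid):
        with pytest.raises(EmptySegmentError):
            crop_rectangle(clean_cuboid, RectRegion(1e4, 2e4, 1e4, 2e4))

    def test_hand_listed_points_against_linear_scan(self):
        pts = np.array(
            [
                [0, 0, 0], [1, 1, 0], [2, 2, 0], [3, 3, 0], [4, 4, 0],
                [5, 5, 0], [-1, 2, 0], [2, -1, 0], [10, 10, 0], [1.5, 2.5, 0],
            ],
            dtype=float,
        )
        region = RectRegion(1.0, 3.0, 1.0, 3.0)
        out = crop_rectangle(PointCloud(pts), region)
        expected = [
            p for p in pts
            if region.x_min <= p[0] <= region.x_max and region.y_min <= p[1] <= region.y_max
        ]
        assert len(expected) == 4
        np.testing.assert_array_equal(out.xyz, np.array(expected))

    def test_bounds_are_closed(self):
        pts = np.array([[1.0, 1.0, 0.0], [3.0, 3.0, 0.0]])
        out = crop_rectangle(PointCloud(pts), RectRegion(1.0, 3.0, 1.0, 3.0))
        assert len(out) == 2

    def test_degenerate_region_rejected(self):
        with pytest.raises(InvalidConfigError):
            RectRegion(3.0, 1.0, 0.0, 1.0)


class TestZeroBottom:
    def test_min_subtraction(self):
        z = np.arange(5.0, 11.0)
        cloud = PointCloud(np.column_stack([np.zeros(6), np.zeros(6), z]))
        out = zero_bottom(cloud, bottom_percentile=0.0)
        np.testing.assert_allclose(out.xyz[:, 2], z - 5.0)

    def test_idempotent_at_percentile_zero(self):
        rng = np.random.default_rng(0)
        cloud = PointCloud(rng.uniform(-5, 5, (100, 3)))
        once = zero_bottom(cloud, 0.0)
        twice = zero_bottom(once, 0.0)
        np.testing.assert_allclose(once.xyz, twice.xyz)

    def test_robust_to_underfloor_noise(self):
        z = np.concatenate([np.full(1000, 50.0), np.full(10, 45.0)])
        cloud = PointCloud(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]))
        out = zero_bottom(cloud, bottom_percentile=1.0)
        bulk = np.median(out.xyz[:, 2])
        assert abs(bulk) < 0.5

    def test_empty_cloud_raises(self):
        with pytest.raises(EmptySegmentError):
            zero_bottom(PointCloud(np.empty((0, 3))))


class TestTrimmedHistogramMean:
    def test_hand_enumerated_bins(self):
        # one value per bin of width 0.95 over [0.5, 19.5]; retained bins
        # 5..14 hold the values 5.5..14.5
        values = np.arange(0.5, 20.0, 1.0)
        assert trimmed_histogram_mean(values) == pytest.approx(10.0)

    def test_constant_values(self):
        assert trimmed_histogram_mean(np.full(50, 3.7)) == pytest.approx(3.7)

    def test_outliers_in_top_bins_are_trimmed(self, rng):
        values = np.concatenate([150 + rng.uniform(-0.5, 0.5, 100), np.full(3, 200.0)])
        assert abs(trimmed_histogram_mean(values) - 150.0) < 0.5

    def test_empty_raises(self):
        with pytest.raises(EmptySegmentError):
            trimmed_histogram_mean([])

    def test_invalid_trim_spec(self):
        with pytest.raises(InvalidConfigError):
            TrimSpec(n_bins=10, trim_low_bins=5, trim_high_bins=5)

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=200).map(np.array)
    )
    def test_result_within_range(self, values):
        result = trimmed_histogram_mean(values)
        assert values.min() - 1e-9 <= result <= values.max() + 1e-9


class TestMeasureHeight:
    def test_noise_free_cuboid(self, clean_cuboid_with_bed):
        height, n = measure_height(zero_bottom(clean_cuboid_with_bed, 0.0))
        assert height == pytest.approx(150.0, abs=1e-6)
        assert n > 0

    def test_jittered_cuboid_20_seeds(self):
        spec = ObjectSpec("cuboid", (100.0, 80.0, 150.0))
        noise = NoiseModel(density_pts_per_mm2=0.8, jitter_sd_mm=0.5)
        devs = []
        for seed in range(20):
            cloud = make_object_cloud(spec, noise, seed=seed)
            height, _ = measure_height(cloud)
            devs.append(abs(height - 150.0))
        assert np.mean(devs) < 0.5

    def test_outlier_robustness(self):
        spec = ObjectSpec("cuboid", (100.0, 80.0, 150.0))
        base = NoiseModel(density_pts_per_mm2=0.8, jitter_sd_mm=0.3)
        spiked = NoiseModel(
            density_pts_per_mm2=0.8, jitter_sd_mm=0.3,
            outlier_rate=0.02, outlier_offset_mm=50.0,
        )
        shifts = []
        for seed in range(5):
            h0, _ = measure_height(make_object_cloud(spec, base, seed=seed))
            h1, _ = measure_height(make_object_cloud(spec, spiked, seed=seed))
            shifts.append(abs(h1 - h0))
        assert max(shifts) < 1.0

    def test_center_region_empty_raises(self):
        # two distant clusters leave the bbox center empty
        xyz = np.vstack(
            [np.full((10, 3), 0.0), np.full((10, 3), 100.0)]
        ) + np.arange(20)[:, None] * 1e-3
        with pytest.raises(EmptySegmentError, match="center_fraction"):
            measure_height(PointCloud(xyz), center_fraction=0.1)


class TestSliceExtents:
    def test_noise_free_cuboid_slices(self, clean_cuboid):
        table = slice_extents(clean_cuboid)
        lateral = table[table["z_center"] < 149.0]
        np.testing.assert_allclose(lateral["dim_x"], 100.0, atol=1e-9)
        np.testing.assert_allclose(lateral["dim_y"], 80.0, atol=1e-9)

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 10_000))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(10, 200)
        xyz = rng.uniform(-50, 50, (n, 3))
        oracle = brute_force_slices(xyz, 5.0, 3)
        if not oracle:
            with pytest.raises(EmptySegmentError):
                slice_extents(PointCloud(xyz), slice_width_mm=5.0, min_points_per_slice=3)
            return
        table = slice_extents(PointCloud(xyz), slice_width_mm=5.0, min_points_per_slice=3)
        assert set(table["slice_index"]) == set(oracle)
        for row in table.itertuples():
            ox, oy = oracle[row.slice_index]
            assert row.dim_x == pytest.approx(ox, abs=1e-12)
            assert row.dim_y == pytest.approx(oy, abs=1e-12)

    def test_hemisphere_chords(self):
        spec = ObjectSpec("mushroom", (20.0, 50.0, 50.0))
        cloud = make_object_cloud(
            spec, NoiseModel(density_pts_per_mm2=3.0), seed=1, bed_margin_mm=0.0
        )
        table = slice_extents(cloud)
        cap = table[(table["z_center"] > 51) & (table["z_center"] < 50 + 0.6 * 50)]
        assert len(cap) > 10
        local = cap["z_center"].to_numpy() - 50.0
        expected = 2 * np.sqrt(50.0**2 - local**2)
        np.testing.assert_allclose(cap["dim_x"], expected, atol=1.0)

    def test_min_points_filter(self):
        z = np.concatenate([np.zeros(10), np.full(2, 7.5)])
        cloud = PointCloud(np.column_stack([z, z, z]))
        table = slice_extents(cloud, slice_width_mm=1.0, min_points_per_slice=5)
        assert list(table["slice_index"]) == [0]

    def test_all_slices_too_sparse_raises(self):
        cloud = PointCloud(np.random.default_rng(0).uniform(0, 100, (20, 3)))
        with pytest.raises(EmptySegmentError):
            slice_extents(cloud, slice_width_mm=0.01, min_points_per_slice=5)


class TestMeasureXY:
    def test_noise_free_cuboid_exact(self, clean_cuboid):
        dim_x, dim_y, n = measure_xy(clean_cuboid)
        assert dim_x == pytest.approx(100.0, abs=0.05)
        assert dim_y == pytest.approx(80.0, abs=0.05)
        assert n > 100

    def test_noise_free_cylinder(self):
        cloud = make_object_cloud(
            ObjectSpec("cylinder", (50.0, 150.0)), NoiseModel(density_pts_per_mm2=1.0),
            seed=3, bed_margin_mm=0.0,
        )
        dim_x, dim_y, _ = measure_xy(cloud)
        assert dim_x == pytest.approx(100.0, abs=1.0)
        assert dim_y == pytest.approx(100.0, abs=1.0)

    def test_mushroom_underestimates_cap_diameter(self):
        cloud = make_object_cloud(
            ObjectSpec("mushroom", (25.0, 90.0, 60.0)), NoiseModel(density_pts_per_mm2=1.0),
            seed=4, bed_margin_mm=0.0,
        )
        dim_x, dim_y, _ = measure_xy(cloud)
        assert dim_x < 120.0
        assert dim_y < 120.0

    def test_max_retained_reduction(self, clean_cuboid):
        dim_x, _, _ = measure_xy(clean_cuboid, reduction="max_retained")
        assert dim_x == pytest.approx(100.0, abs=0.1)

    def test_unknown_reduction(self, clean_cuboid):
        with pytest.raises(InvalidConfigError):
            measure_xy(clean_cuboid, reduction="median")


class TestMeasureObject:
    def test_noise_free_composite(self, clean_cuboid_with_bed):
        m = measure_object(clean_cuboid_with_bed)
        assert isinstance(m, Measurement)
        assert m.dim_x_mm == pytest.approx(100.0, abs=1.0)
        assert m.dim_y_mm == pytest.approx(80.0, abs=1.0)
        assert m.dim_z_mm == pytest.approx(150.0, abs=1.0)

    def test_empty_cloud_raises(self):
        with pytest.raises(EmptySegmentError):
            measure_object(PointCloud(np.empty((0, 3))))


class TestInvariances:
    def test_permutation_invariance(self, clean_cuboid):
        rng = np.random.default_rng(99)
        perm = rng.permutation(len(clean_cuboid))
        shuffled = clean_cuboid.select(perm)
        m1 = measure_object(clean_cuboid)
        m2 = measure_object(shuffled)
        assert m1.dim_x_mm == pytest.approx(m2.dim_x_mm, abs=1e-9)
        assert m1.dim_y_mm == pytest.approx(m2.dim_y_mm, abs=1e-9)
        assert m1.dim_z_mm == pytest.approx(m2.dim_z_mm, abs=1e-9)

    def test_translation_invariance(self, clean_cuboid):
        moved = clean_cuboid.translated(dx=1234.5, dy=-987.6, dz=55.5)
        m1 = measure_object(clean_cuboid)
        m2 = measure_object(moved)
        assert m1.dim_x_mm == pytest.approx(m2.dim_x_mm, abs=1e-6)
        assert m1.dim_y_mm == pytest.approx(m2.dim_y_mm, abs=1e-6)
        assert m1.dim_z_mm == pytest.approx(m2.dim_z_mm, abs=1e-6)
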