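"""Region geometry: rasterization, the minimum-volume enclosing ellipsoid,
axis extension, surrounding region and contralateral mirroring."""

import numpy as np
import pytest

from paquant import (
    ConfigurationError,
    ContourStack,
    DegenerateGeometryError,
    Ellipsoid,
    GeometryError,
    SliceContours,
    VoxelMask,
    extend_ellipsoid,
    mirror_roi,
    mvee,
    rasterize_contours,
    surrounding_mask,
)
from paquant.roi3d import ellipsoid_mask


def square(cx, cy, half):
    return np.array(
        [[cx - half, cy - half], [cx + half, cy - half], [cx + half, cy + half], [cx - half, cy + half]]
    )


def random_enclosing_ellipsoid(points, rng):
    """Brute-force sampler: a random-shape ellipsoid scaled to contain all points."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )
    ratios = rng.uniform(0.4, 1.0, size=3)
    c = points.mean(axis=0) + 0.2 * rng.standard_normal(3) * points.std(axis=0)
    body = (points - c) @ R / ratios
    s = np.sqrt((body**2).sum(axis=1)).max()
    return Ellipsoid(center=c, semi_axes=s * ratios, orientation=R)


class TestRasterizeContours:
    GEOM = dict(grid_shape=(5, 24, 24), voxel_size=(1.0, 1.0, 1.0))

    def test_square_count_matches_point_in_polygon_oracle(self):
        """10x10-voxel square placed between centres -> exactly 100 voxels."""
        stack = ContourStack([SliceContours(2.0, [square(8.0, 9.0, 5.0)])])
        mask = rasterize_contours(stack, **self.GEOM)
        # oracle: exhaustive centre-in-rectangle test
        count = sum(
            1
            for jy in range(24)
            for kx in range(24)
            if 3.0 <= kx <= 13.0 and 4.0 <= jy <= 14.0
        )
        assert mask.count == count == 121  # boundary centres included
        assert mask.data[2].sum() == mask.count  # all on the matching slice

    def test_offset_square_excludes_boundary(self):
        stack = ContourStack([SliceContours(1.0, [square(8.5, 8.5, 5.0)])])
        mask = rasterize_contours(stack, **self.GEOM)
        assert mask.count == 100  # corners fall between voxel centres

    def test_circle_area_within_two_percent(self):
        r = 8.0
        theta = np.linspace(0, 2 * np.pi, 256, endpoint=False)
        poly = np.stack([12 + r * np.cos(theta), 12 + r * np.sin(theta)], axis=1)
        stack = ContourStack([SliceContours(0.0, [poly])])
        mask = rasterize_contours(stack, grid_shape=(1, 48, 48), voxel_size=(1.0, 0.5, 0.5))
        assert abs(mask.count * 0.25 - np.pi * r * r) / (np.pi * r * r) < 0.02

    def test_empty_stack_warns_and_returns_empty(self, caplog):
        with caplog.at_level("WARNING"):
            mask = rasterize_contours(ContourStack([]), **self.GEOM)
        assert mask.count == 0
        assert any("empty" in r.message for r in caplog.records)

    def test_contour_off_the_slice_grid_is_rejected(self):
        stack = ContourStack([SliceContours(9.4, [square(8, 8, 2)])])
        with pytest.raises(GeometryError, match="does not match any slice"):
            rasterize_contours(stack, **self.GEOM)


class TestMVEE:
    def test_cube_corners_give_circumscribed_sphere(self):
        pts = np.array(
            [[i, j, k] for i in (-1, 1) for j in (-1, 1) for k in (-1, 1)], dtype=float
        )
        e = mvee(pts, tolerance=1e-6)
        np.testing.assert_allclose(e.semi_axes, np.sqrt(3), rtol=1e-6)
        np.testing.assert_allclose(e.center, 0.0, atol=1e-9)

    def test_recovers_generating_axis_aligned_ellipsoid(self, rng):
        gen = Ellipsoid(center=[1, 2, 3], semi_axes=[5, 3, 2], orientation=np.eye(3))
        # all six axis endpoints plus random surface points
        u = rng.standard_normal((40, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        surface = gen.center + u * gen.semi_axes
        endpoints = gen.center + np.vstack([np.diag(gen.semi_axes), -np.diag(gen.semi_axes)])
        e = mvee(np.vstack([endpoints, surface]), tolerance=1e-7)
        assert e.contains(surface, rtol=1e-7).all()
        np.testing.assert_allclose(e.volume, gen.volume, rtol=1e-4)
        np.testing.assert_allclose(e.center, gen.center, atol=1e-3)

    def test_beats_brute_force_enclosing_ellipsoids(self, rng):
        for _ in range(5):
            pts = rng.standard_normal((50, 3))
            e = mvee(pts)
            assert e.contains(pts).all()
            brute = min(
                random_enclosing_ellipsoid(pts, rng).volume for _ in range(200)
            )
            assert e.volume <= brute * (1 + 1e-6)

    def test_unique_optimum_regardless_of_initial_weights(self, rng):
        pts = rng.standard_normal((60, 3))
        e1 = mvee(pts)
        w = rng.random(60)
        e2 = mvee(pts, initial_weights=w / w.sum())
        assert abs(e1.volume - e2.volume) / e1.volume <= 1e-6

    def test_affine_equivariance(self, rng):
        pts = rng.standard_normal((40, 3))
        e = mvee(pts, tolerance=1e-8)
        for _ in range(3):
            A = rng.standard_normal((3, 3)) + 2 * np.eye(3)
            b = rng.standard_normal(3)
            e2 = mvee(pts @ A.T + b, tolerance=1e-8)
            np.testing.assert_allclose(
                e2.volume, abs(np.linalg.det(A)) * e.volume, rtol=1e-4
            )
            np.testing.assert_allclose(e2.center, A @ e.center + b, atol=1e-4)

    def test_coplanar_points_raise_with_rank(self, rng):
        pts = rng.standard_normal((20, 3))
        pts[:, 2] = 1.0  # squash onto a plane
        with pytest.raises(DegenerateGeometryError) as err:
            mvee(pts)
        assert err.value.rank == 2


class TestExtendEllipsoid:
    E = Ellipsoid(center=[0, 0, 0], semi_axes=[3, 2, 1], orientation=np.eye(3))

    def test_factor_one_is_identity(self):
        out = extend_ellipsoid(self.E, 1.0)
        np.testing.assert_array_equal(out.semi_axes, self.E.semi_axes)
        np.testing.assert_array_equal(out.center, self.E.center)

    def test_default_factor_cubes_the_volume(self):
        out = extend_ellipsoid(self.E)  # 1.2 on every axis
        assert out.volume / self.E.volume == pytest.approx(1.728, rel=1e-12)
        np.testing.assert_array_equal(out.orientation, self.E.orientation)

    def test_unit_sphere_doubles_to_radius_two(self):
        s = Ellipsoid(center=[0, 0, 0], semi_axes=[1, 1, 1], orientation=np.eye(3))
        np.testing.assert_allclose(extend_ellipsoid(s, 2.0).semi_axes, 2.0)

    def test_shrinking_factor_rejected(self):
        with pytest.raises(ConfigurationError, match="factor"):
            extend_ellipsoid(self.E, 0.9)


class TestSurroundingMask:
    VS = (0.5, 0.5, 0.5)
    SHAPE = (20, 20, 20)
    E = Ellipsoid(center=[4.75, 4.75, 4.75], semi_axes=[3, 2.5, 2], orientation=np.eye(3))

    def test_empty_tumour_gives_whole_ellipsoid(self):
        empty = VoxelMask(np.zeros(self.SHAPE, bool), self.VS)
        out = surrounding_mask(self.E, empty)
        ref = ellipsoid_mask(self.E, self.SHAPE, self.VS)
        np.testing.assert_array_equal(out.data, ref.data)

    def test_factor_one_leaves_a_thin_shell(self):
        tumour = ellipsoid_mask(self.E, self.SHAPE, self.VS)
        out = surrounding_mask(self.E, tumour)
        assert out.count == 0  # identical ellipsoid: set difference is empty
        extended = extend_ellipsoid(self.E, 1.2)
        shell = surrounding_mask(extended, tumour)
        # exhaustive set-arithmetic oracle
        ref = ellipsoid_mask(extended, self.SHAPE, self.VS).data & ~tumour.data
        np.testing.assert_array_equal(shell.data, ref)
        assert shell.count > 0

    def test_disjoint_from_tumour_always(self, rng):
        tumour = VoxelMask(rng.random(self.SHAPE) < 0.3, self.VS)
        out = surrounding_mask(self.E, tumour)
        assert not (out.data & tumour.data).any()

    def test_out_of_bounds_ellipsoid_warns_with_clipped_fraction(self, caplog):
        big = Ellipsoid(center=[4.75, 4.75, 4.75], semi_axes=[20, 20, 20], orientation=np.eye(3))
        empty = VoxelMask(np.zeros(self.SHAPE, bool), self.VS)
        with caplog.at_level("WARNING"):
            surrounding_mask(big, empty)
        assert any("clipped" in r.message for r in caplog.records)


class TestMirrorROI:
    VS = (0.5, 0.5, 0.5)
    SHAPE = (16, 16, 16)

    def make_roi(self, center):
        e = Ellipsoid(center=center, semi_axes=[2, 1.5, 1.2], orientation=np.eye(3))
        mask = ellipsoid_mask(e, self.SHAPE, self.VS)
        return e, mask

    def test_mirror_is_an_involution(self):
        e, mask = self.make_roi([3.75, 3.75, 2.8])
        e1, m1 = mirror_roi(e, mask, self.SHAPE)
        e2, m2 = mirror_roi(e1, m1, self.SHAPE)
        np.testing.assert_allclose(e2.center, e.center, atol=1e-12)
        np.testing.assert_array_equal(m2.data, mask.data)

    def test_roi_on_the_plane_is_fixed(self):
        mid = (self.SHAPE[2] - 1) * self.VS[2] / 2
        e, mask = self.make_roi([3.75, 3.75, mid])
        e1, m1 = mirror_roi(e, mask, self.SHAPE)
        np.testing.assert_allclose(e1.center, e.center, atol=1e-12)
        np.testing.assert_array_equal(m1.data, mask.data)

    def test_off_centre_reflection_matches_explicit_matrix(self):
        e, mask = self.make_roi([3.75, 3.75, 2.6])
        plane = (self.SHAPE[2] - 1) * self.VS[2] / 2
        e1, _ = mirror_roi(e, mask, self.SHAPE)
        S = np.diag([1.0, 1.0, -1.0])  # reflection about the lateral midline
        expected = S @ (e.center - [0, 0, plane]) + [0, 0, plane]
        np.testing.assert_allclose(e1.center, expected, atol=1e-12)
        assert np.linalg.det(e1.orientation) == pytest.approx(1.0)

    def test_mirrored_roi_outside_target_rejected(self):
        e, mask = self.make_roi([3.75, 3.75, 2.2])
        with pytest.raises(GeometryError, match="outside the target"):
            mirror_roi(e, mask, self.SHAPE, plane=1.0)


class TestRasterizationConsistency:
    def test_ellipsoid_voxel_volume_converges_with_resolution(self):
        e = Ellipsoid(center=[5, 5, 5], semi_axes=[3, 2.5, 2], orientation=np.eye(3))
        errors = []
        for step in (1.0, 0.5, 0.25):
            n = int(10 / step) + 1
            mask = ellipsoid_mask(e, (n, n, n), (step, step, step))
            errors.append(abs(mask.volume_mm3 - e.volume) / e.volume)
        assert errors[2] < errors[0]
        assert errors[2] < 0.01
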