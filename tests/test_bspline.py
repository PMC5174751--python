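"""Lattice geometry, basis functions, LUTs, interpolation and warping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ffdreg import (
    ConfigurationError,
    ControlPointMesh,
    DomainError,
    build_luts,
    cubic_bspline_weights,
    generate_phantom,
    interpolate_displacement,
    interpolate_displacement_naive,
    local_coordinates,
    make_geometry,
    warp_image,
)


class TestCubicBsplineWeights:
    def test_endpoint_weights(self):
        np.testing.assert_allclose(
            cubic_bspline_weights(0.0), [1 / 6, 2 / 3, 1 / 6, 0.0], atol=1e-15
        )

    def test_midpoint_weights(self):
        np.testing.assert_allclose(
            cubic_bspline_weights(0.5), [1 / 48, 23 / 48, 23 / 48, 1 / 48], atol=1e-15
        )

    @pytest.mark.parametrize("t", [-0.1, 1.0, 1.5, float("nan")])
    def test_domain_error_outside_unit_interval(self, t):
        with pytest.raises(DomainError):
            cubic_bspline_weights(t)

    @given(st.floats(min_value=0.0, max_value=1.0, exclude_max=True))
    @settings(max_examples=200, deadline=None)
    def test_partition_of_unity_and_range(self, t):
        w = cubic_bspline_weights(t)
        assert abs(w.sum() - 1.0) < 1e-12
        assert np.all(w >= 0.0) and np.all(w <= 1.0)


class TestGeometry:
    @pytest.mark.parametrize(
        "shape,spacing,regions,cps",
        [
            ((512, 512), (16, 16), (32, 32), (35, 35)),
            ((16, 16), (16, 16), (1, 1), (4, 4)),
            ((512, 512), (10, 10), (52, 52), (55, 55)),
            ((30, 40, 20), (8, 8, 8), (4, 5, 3), (7, 8, 6)),
        ],
    )
    def test_region_and_control_point_counts(self, shape, spacing, regions, cps):
        g = make_geometry(shape, spacing)
        assert g.regions == regions
        assert g.cp_counts == cps

    @pytest.mark.parametrize("spacing", [1, 0, 33])
    def test_invalid_spacing_rejected(self, spacing):
        with pytest.raises(ConfigurationError):
            make_geometry((32, 32), spacing)

    @pytest.mark.parametrize(
        "voxel,region,frac",
        [((0, 0), (0, 0), (0.0, 0.0)),
         ((17, 0), (1, 0), (1 / 16, 0.0)),
         ((511, 511), (31, 31), (15 / 16, 15 / 16))],
    )
    def test_local_coordinates(self, voxel, region, frac):
        g = make_geometry((512, 512), 16)
        reg, u = local_coordinates(voxel, g)
        assert reg == region
        np.testing.assert_allclose(u, frac, atol=1e-15)

    def test_local_coordinates_outside_image(self):
        g = make_geometry((32, 32), 8)
        with pytest.raises(DomainError):
            local_coordinates((32, 0), g)


class TestLUTs:
    def test_basis_product_rows_sum_to_one(self):
        g = make_geometry((30, 21), (7, 5))  # ragged last regions
        luts = build_luts(g, np.zeros((30, 21)))
        np.testing.assert_allclose(luts.basis_products.sum(axis=1), 1.0, atol=1e-12)

    def test_cp_indices_within_lattice(self):
        g = make_geometry((20, 20, 20), 6)
        luts = build_luts(g, np.zeros((20, 20, 20)))
        assert luts.cp_indices.min() >= 0
        assert luts.cp_indices.max() < g.n_control_points

    def test_constant_image_has_zero_gradient(self):
        g = make_geometry((16, 16), 4)
        luts = build_luts(g, np.full((16, 16), 7.0))
        assert np.all(luts.moving_gradient == 0.0)

    def test_linear_ramp_gradient_is_one_in_interior(self):
        g = make_geometry((16, 16), 4)
        img = np.arange(16, dtype=float)[:, None] * np.ones(16)
        luts = build_luts(g, img)
        np.testing.assert_allclose(luts.moving_gradient[1:-1, :, 0], 1.0)
        np.testing.assert_allclose(luts.moving_gradient[:, :, 1], 0.0)

    def test_shape_mismatch_rejected(self):
        g = make_geometry((16, 16), 4)
        with pytest.raises(ConfigurationError):
            build_luts(g, np.zeros((16, 17)))


class TestInterpolation:
    def test_zero_mesh_gives_zero_field(self):
        g = make_geometry((16, 16), 4)
        luts = build_luts(g, np.zeros((16, 16)))
        field = interpolate_displacement(ControlPointMesh.zeros(g), luts)
        assert np.all(field == 0.0)

    def test_uniform_mesh_gives_uniform_field(self):
        g = make_geometry((20, 12), (6, 4))
        luts = build_luts(g, np.zeros((20, 12)))
        coeffs = np.broadcast_to([2.5, -1.0], g.cp_counts + (2,)).copy()
        field = interpolate_displacement(ControlPointMesh(g, coeffs), luts)
        np.testing.assert_allclose(field[..., 0], 2.5, atol=1e-12)
        np.testing.assert_allclose(field[..., 1], -1.0, atol=1e-12)

    def test_lut_matches_naive_loop(self, small_setup):
        _, _, luts, mesh = small_setup
        lut_field = interpolate_displacement(mesh, luts)
        naive_field = interpolate_displacement_naive(mesh)
        np.testing.assert_allclose(lut_field, naive_field, atol=1e-10)

    def test_linearity(self, rng):
        g = make_geometry((24, 24), 6)
        luts = build_luts(g, np.zeros((24, 24)))
        c1 = rng.normal(size=g.cp_counts + (2,))
        c2 = rng.normal(size=g.cp_counts + (2,))
        a, b = 0.7, -1.3
        combo = interpolate_displacement(ControlPointMesh(g, a * c1 + b * c2), luts)
        sep = a * interpolate_displacement(ControlPointMesh(g, c1), luts) + \
            b * interpolate_displacement(ControlPointMesh(g, c2), luts)
        np.testing.assert_allclose(combo, sep, atol=1e-9)

    def test_locality_of_one_control_point(self):
        # perturbing one control point only touches voxels in its 4-region support
        g = make_geometry((32, 32), 8)
        luts = build_luts(g, np.zeros((32, 32)))
        base = interpolate_displacement(ControlPointMesh.zeros(g), luts)
        coeffs = np.zeros(g.cp_counts + (2,))
        cp = (3, 3)
        coeffs[cp + (0,)] = 1.0
        bumped = interpolate_displacement(ControlPointMesh(g, coeffs), luts)
        changed = np.any(bumped != base, axis=-1)
        # support regions of cp index c are regions c-3 .. c
        xs, ys = np.nonzero(changed)
        assert xs.size > 0
        for axis, idx in ((0, xs), (1, ys)):
            regions = idx // g.spacing[axis]
            assert regions.min() >= cp[axis] - 3
            assert regions.max() <= cp[axis]

    def test_geometry_mismatch_rejected(self, small_setup):
        _, _, luts, _ = small_setup
        other = make_geometry((32, 32), 4)
        with pytest.raises(ConfigurationError):
            interpolate_displacement(ControlPointMesh.zeros(other), luts)


class TestWarp:
    def test_zero_field_is_identity(self):
        img = generate_phantom((16, 16), seed=1)
        disp = np.zeros(img.shape + (2,))
        np.testing.assert_array_equal(warp_image(img, disp), img)

    def test_uniform_integer_shift_with_edge_clamp(self):
        row = np.array([0.0, 10.0, 20.0, 30.0])
        disp = np.ones((4, 1))
        np.testing.assert_allclose(warp_image(row, disp), [10, 20, 30, 30])

    def test_uniform_half_voxel_shift_interpolates(self):
        row = np.array([0.0, 10.0, 20.0, 30.0])
        disp = np.full((4, 1), 0.5)
        np.testing.assert_allclose(warp_image(row, disp), [5, 15, 25, 30])

    def test_non_finite_field_rejected(self):
        img = np.zeros((8, 8))
        disp = np.zeros((8, 8, 2))
        disp[0, 0, 0] = np.nan
        with pytest.raises(DomainError):
            warp_image(img, disp)
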