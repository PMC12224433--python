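"""Per-slice shape descriptors against closed-form and brute-force oracles."""

import math

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import cordmorph as cm
from cordmorph.errors import DegenerateInputError, UndefinedShapeError

from conftest import raster_ellipse, tube

PX = (0.8, 0.8)


class TestCenterline:
    def test_straight_cylinder_has_zero_angle(self):
        cl = cm.extract_centerline(tube(n_slices=20))
        assert np.all(cl.angle_deg < 0.5)
        assert np.allclose(np.linalg.norm(cl.tangent, axis=1), 1.0)

    def test_sheared_tube_angle_matches_closed_form(self):
        # centers advance 0.5 slice-thickness in AP per slice of equal mm
        seg = tube(n_slices=24, shear_ap=0.5)
        cl = cm.extract_centerline(seg)
        expected = math.degrees(math.atan(0.5))
        interior = slice(4, -4)
        assert np.allclose(cl.angle_deg[interior], expected, atol=1.0)
        assert np.allclose(cl.tilt_sag_deg[interior], expected, atol=1.0)
        assert np.all(cl.tilt_cor_deg[interior] < 1.0)

    def test_angle_agrees_with_least_squares_oracle(self):
        seg = tube(n_slices=24, shear_ap=0.3)
        cl = cm.extract_centerline(seg)
        # independent oracle: straight-line fit of the raw centroids
        zs = seg.nonempty_slices()
        cy = np.array([np.nonzero(seg.slice_mask(z))[1].mean() * 0.8 for z in zs])
        slope = np.linalg.lstsq(
            np.stack([zs * 0.8, np.ones_like(zs, float)], axis=1), cy, rcond=None
        )[0][0]
        oracle = math.degrees(math.atan(abs(slope)))
        assert np.median(cl.angle_deg) == pytest.approx(oracle, abs=1.0)
        assert oracle == pytest.approx(math.degrees(math.atan(0.3)), abs=0.5)

    def test_angle_bounds(self):
        cl = cm.extract_centerline(tube(n_slices=15, shear_ap=0.7))
        assert np.all((cl.angle_deg >= 0) & (cl.angle_deg < 90))

    def test_empty_and_thin_volumes_rejected(self):
        empty = cm.SegmentationVolume(np.zeros((8, 8, 8), bool), (1, 1, 1))
        with pytest.raises(DegenerateInputError):
            cm.extract_centerline(empty)
        with pytest.raises(DegenerateInputError):
            cm.extract_centerline(tube(n_slices=3), smoothing_degree=3)


class TestAreaAndDiameters:
    def test_circle_csa_matches_pi_r_squared(self):
        mask = raster_ellipse(5.0, 5.0)
        csa = cm.cross_sectional_area(mask, PX)
        assert csa == pytest.approx(math.pi * 25.0, rel=0.02)

    def test_zero_angle_correction_is_identity(self):
        mask = raster_ellipse(5.0, 5.0)
        assert cm.cross_sectional_area(mask, PX, 0.0) == pytest.approx(
            mask.sum() * 0.64, rel=1e-15
        )

    def test_cos_correction_scales_area(self):
        mask = raster_ellipse(5.0, 5.0)
        a0 = cm.cross_sectional_area(mask, PX, 0.0)
        assert cm.cross_sectional_area(mask, PX, 60.0) == pytest.approx(a0 / 2, rel=1e-12)

    def test_ellipse_diameters_match_analytic_extents(self):
        # semi-axes 6 mm (RL) x 4 mm (AP): AP diameter 8, transverse 12
        ap, tr = cm.ap_transverse_diameters(raster_ellipse(6.0, 4.0), PX)
        assert ap == pytest.approx(8.0, rel=0.02)
        assert tr == pytest.approx(12.0, rel=0.02)

    def test_diameters_swap_under_90_degree_rotation(self):
        ap1, tr1 = cm.ap_transverse_diameters(raster_ellipse(6.0, 4.0), PX)
        ap2, tr2 = cm.ap_transverse_diameters(raster_ellipse(4.0, 6.0), PX)
        assert ap2 == pytest.approx(tr1, rel=1e-9)
        assert tr2 == pytest.approx(ap1, rel=1e-9)

    def test_circle_diameters_equal(self):
        ap, tr = cm.ap_transverse_diameters(raster_ellipse(5.0, 5.0), PX)
        assert ap == pytest.approx(tr, rel=0.02)

    def test_anisotropic_pixels_respected(self):
        # same ellipse rendered with anisotropic pixels must give the same mm result
        iso = cm.ap_transverse_diameters(raster_ellipse(6.0, 4.0, px=0.5, n=64), (0.5, 0.5))
        mask = np.kron(raster_ellipse(6.0, 4.0, px=1.0, n=32), np.ones((1, 2), bool))
        aniso = cm.ap_transverse_diameters(mask, (1.0, 0.5))
        assert aniso[0] == pytest.approx(iso[0], rel=0.03)
        assert aniso[1] == pytest.approx(iso[1], rel=0.03)


class TestCompressionRatio:
    def test_example_value(self):
        assert cm.compression_ratio(8.0, 12.0) == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_equal_diameters_give_one(self):
        assert cm.compression_ratio(7.3, 7.3) == 1.0

    def test_exact_composition(self):
        for ap, tr in [(8.0, 12.0), (6.5, 10.1), (1.0, 3.0)]:
            assert cm.compression_ratio(ap, tr) * tr == pytest.approx(ap, rel=1e-15)

    def test_zero_transverse_rejected(self):
        with pytest.raises(UndefinedShapeError):
            cm.compression_ratio(8.0, 0.0)


class TestEccentricity:
    def test_centered_circle_is_circular(self):
        # grid-centred circle: 4-fold symmetry forces equal moments
        assert cm.eccentricity(raster_ellipse(5.0, 5.0, offset=(0, 0), n=41), PX) < 0.05

    def test_ellipse_closed_form(self):
        e = cm.eccentricity(raster_ellipse(6.0, 4.0), PX)
        assert e == pytest.approx(math.sqrt(1 - 16 / 36), abs=0.02)

    def test_invariant_under_uniform_scaling(self):
        e_coarse = cm.eccentricity(raster_ellipse(6.0, 4.0, px=0.8), PX)
        e_fine = cm.eccentricity(raster_ellipse(6.0, 4.0, px=0.4, n=80), (0.4, 0.4))
        assert e_fine == pytest.approx(e_coarse, abs=0.01)

    def test_in_range(self):
        e = cm.eccentricity(raster_ellipse(7.0, 3.0), PX)
        assert 0.0 <= e < 1.0


class TestSolidity:
    @staticmethod
    def _oracle(mask):
        """Brute-force: count grid centers inside the hull of positive pixel centers."""
        from matplotlib.path import Path

        pts = np.argwhere(mask).astype(float)
        hull = ConvexHull(pts)
        poly = Path(pts[hull.vertices])
        ii, jj = np.meshgrid(np.arange(mask.shape[0]), np.arange(mask.shape[1]), indexing="ij")
        grid = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        inside = poly.contains_points(grid, radius=1e-9) | poly.contains_points(grid, radius=-1e-9)
        return 100.0 * mask.sum() / inside.sum()

    def test_convex_shape_is_fully_solid(self):
        assert cm.solidity(raster_ellipse(6.0, 4.0)) >= 99.0

    def test_crescent_matches_hull_oracle_and_is_concave(self):
        crescent = raster_ellipse(6.0, 4.0) & ~raster_ellipse(5.0, 3.2, offset=(2.75, 0.25))
        s = cm.solidity(crescent)
        assert s < 100.0
        assert s == pytest.approx(self._oracle(crescent), abs=1.5)

    def test_indentation_monotonically_decreases_solidity(self):
        # rectangular notch of fixed width and growing depth: removed pixel
        # sets are nested, so solidity must fall strictly
        base = raster_ellipse(6.0, 4.0)
        n = base.shape[0]
        mouth = n // 2 - 6  # just outside the ellipse on the posterior side
        prev = cm.solidity(base)
        for depth in (4, 6, 8):
            notch = np.zeros_like(base)
            notch[n // 2 - 2 : n // 2 + 2, mouth : mouth + depth] = True
            s = cm.solidity(base & ~notch)
            assert s < prev
            prev = s


class TestInvariances:
    def test_translation_invariance_of_all_measures(self):
        mask = raster_ellipse(6.0, 4.0)
        shifted = np.roll(np.roll(mask, 3, axis=0), -2, axis=1)
        assert cm.cross_sectional_area(shifted, PX) == cm.cross_sectional_area(mask, PX)
        assert cm.ap_transverse_diameters(shifted, PX) == pytest.approx(
            cm.ap_transverse_diameters(mask, PX), rel=1e-12
        )
        assert cm.eccentricity(shifted, PX) == pytest.approx(cm.eccentricity(mask, PX), rel=1e-12)
        assert cm.solidity(shifted) == pytest.approx(cm.solidity(mask), rel=1e-12)

    def test_rotation90_invariance_of_csa_and_solidity(self):
        mask = raster_ellipse(6.0, 4.0)
        rot = np.rot90(mask)
        assert cm.cross_sectional_area(rot, PX) == cm.cross_sectional_area(mask, PX)
        assert cm.solidity(rot) == pytest.approx(cm.solidity(mask), rel=1e-12)


class TestDegenerateSlices:
    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedShapeError):
            cm.cross_sectional_area(np.zeros((5, 5), bool), PX)

    @pytest.mark.parametrize("pixels", [[(2, 2)], [(2, 2), (2, 3)], [(1, 1), (2, 2), (3, 3)]])
    def test_tiny_or_collinear_masks_rejected(self, pixels):
        mask = np.zeros((6, 6), bool)
        for i, j in pixels:
            mask[i, j] = True
        with pytest.raises(UndefinedShapeError):
            cm.eccentricity(mask, PX)
        with pytest.raises(UndefinedShapeError):
            cm.solidity(mask)

    def test_driver_excludes_undefined_slices(self):
        seg0 = tube(n_slices=12)
        vox = seg0.voxels.copy()
        vox[:, :, 5] = False
        vox[10, 10, 5] = True  # single-voxel slice
        seg = cm.SegmentationVolume(vox, seg0.voxel_size)
        res = cm.compute_slice_morphometrics(seg)
        assert 5 not in [m.slice_index for m in res]
        assert len(res) == 11

    def test_disconnected_components_measured_together(self):
        mask = raster_ellipse(3.0, 3.0, offset=(-8.0, 0.25)) | raster_ellipse(
            3.0, 3.0, offset=(8.0, 0.25)
        )
        csa = cm.cross_sectional_area(mask, PX)
        one = cm.cross_sectional_area(raster_ellipse(3.0, 3.0), PX)
        assert csa == pytest.approx(2 * one, rel=0.05)
        assert cm.solidity(mask) < 80.0  # hull spans the gap
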