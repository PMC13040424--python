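"""Biometry pipeline on phantoms with analytically known geometry."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cervimetry.biometry_core import (
    BiometryError,
    Centerline,
    CervicalBiometry,
    OsLandmarks,
    cervical_length,
    compartment_volumes,
    compute_biometry,
    extract_canal_centerline,
    locate_os_landmarks,
    os_diameter,
    utero_cervical_angle,
)
from cervimetry.phantom_gen import PhantomSpec, make_phantom
from cervimetry.volume_io import LabelVolume, UterineAxis

VOXEL = 0.8
TWO_VOXELS = 1.6


def _vol(voxels, spacing=(0.8, 0.8, 0.8)):
    return LabelVolume(voxels=np.asarray(voxels, dtype=np.int16),
                       affine=np.diag(list(spacing) + [1.0]))


class TestCenterline:
    def test_straight_tube_arc_length(self, straight_phantom):
        vol, _, axis = straight_phantom
        cl = extract_canal_centerline(vol, axis)
        assert cl.arc_length == pytest.approx(32.0, abs=TWO_VOXELS)

    def test_quarter_torus_arc_length(self, quarter_torus_phantom):
        vol, _, axis = quarter_torus_phantom
        cl = extract_canal_centerline(vol, axis)
        assert cl.arc_length == pytest.approx(math.pi * 20.0 / 2.0, rel=0.05)

    def test_points_inside_canal_region(self, quarter_torus_phantom):
        vol, _, axis = quarter_torus_phantom
        cl = extract_canal_centerline(vol, axis)
        canal = vol.world_coords(np.argwhere(vol.mask(3, 4)))
        from scipy.spatial import cKDTree
        d, _ = cKDTree(canal).query(cl.points)
        assert d.max() <= np.linalg.norm(vol.spacing)  # within 1 voxel diagonal

    def test_largest_component_wins(self, straight_phantom):
        # add a small disjoint canal blob; centerline must ignore it
        vol, _, axis = straight_phantom
        vox = vol.voxels.copy()
        vox[:4, :4, :4] = 0
        vox[:3, :3, :3] = 3
        vol2 = LabelVolume(voxels=vox, affine=vol.affine)
        cl = extract_canal_centerline(vol2, axis)
        assert cl.arc_length == pytest.approx(32.0, abs=TWO_VOXELS)

    def test_internal_os_end_nearer_uterine_axis(self, straight_phantom):
        vol, _, axis = straight_phantom
        cl = extract_canal_centerline(vol, axis)
        d_first = np.linalg.norm(cl.points[0] - axis.point_a)
        d_last = np.linalg.norm(cl.points[-1] - axis.point_a)
        assert d_first < d_last

    def test_no_canal_error(self):
        vox = np.zeros((10, 10, 10), dtype=np.int16)
        vox[4:6, 4:6, 4:6] = 1
        axis = UterineAxis(np.zeros(3), np.array([0, 0, 10.0]), "sidecar")
        with pytest.raises(BiometryError, match="extract_canal_centerline"):
            extract_canal_centerline(_vol(vox), axis)

    def test_canal_too_small_error_reports_count(self):
        vox = np.zeros((10, 10, 10), dtype=np.int16)
        vox[4:6, 4:6, 4:6] = 3  # 8 voxels < 20 minimum
        axis = UterineAxis(np.zeros(3), np.array([0, 0, 10.0]), "sidecar")
        with pytest.raises(BiometryError, match="8 voxels"):
            extract_canal_centerline(_vol(vox), axis)

    def test_centerline_validation(self):
        with pytest.raises(ValueError):
            Centerline(points=np.zeros((2, 3)))
        with pytest.raises(ValueError):
            Centerline(points=np.array([[0, 0, 0], [0, 0, 0], [0, 0, 1.0]]))


class TestLandmarksAndLength:
    def test_straight_centerline_midpoint(self):
        cl = Centerline(points=np.array(
            [[0, 0, 0], [0, 0, 10], [0, 0, 20], [0, 0, 32.0]]))
        lm = locate_os_landmarks(cl)
        assert np.allclose(lm.internal_os, [0, 0, 0])
        assert np.allclose(lm.external_os, [0, 0, 32])
        assert np.allclose(lm.canal_mid, [0, 0, 16])

    def test_bent_polyline_midpoint_at_vertex(self):
        # both segments have equal length, so half arc falls on the vertex
        cl = Centerline(points=np.array([[0, 0, 0], [0, 4, 8], [0, 0, 16.0]]))
        lm = locate_os_landmarks(cl)
        assert np.allclose(lm.canal_mid, [0, 4, 8])

    def test_collinear_landmarks_equal_lengths(self):
        lm = OsLandmarks(internal_os=np.array([0.0, 0, 0]),
                         external_os=np.array([0.0, 0, 30]),
                         canal_mid=np.array([0.0, 0, 15]))
        l2, l3 = cervical_length(lm)
        assert l2 == pytest.approx(l3)

    def test_curved_centerline_chord_formulas(self):
        # analytic arc: chords follow 2R sin(theta/2) / 4R sin(theta/4)
        rc, L = 20.0, math.pi * 20.0 / 2.0
        s = np.linspace(0, L, 400)
        pts = np.column_stack([rc * (1 - np.cos(s / rc)),
                               np.zeros_like(s), rc * np.sin(s / rc)])
        lm = locate_os_landmarks(Centerline(points=pts))
        l2, l3 = cervical_length(lm)
        assert l2 == pytest.approx(2 * rc * math.sin(L / (2 * rc)), abs=1e-3)
        assert l3 == pytest.approx(4 * rc * math.sin(L / (4 * rc)), abs=1e-3)

    def test_phantom_lengths_within_two_voxels(self, quarter_torus_phantom):
        vol, gt, axis = quarter_torus_phantom
        cl = extract_canal_centerline(vol, axis)
        l2, l3 = cervical_length(locate_os_landmarks(cl))
        assert l2 == pytest.approx(gt.length_2pt, abs=TWO_VOXELS)
        assert l3 == pytest.approx(gt.length_3pt, abs=TWO_VOXELS)
        assert l2 < l3 < cl.arc_length


class TestOsDiameter:
    def test_straight_tube_diameters(self, straight_phantom):
        vol, _, axis = straight_phantom
        cl = extract_canal_centerline(vol, axis)
        for which in ("internal", "external"):
            assert os_diameter(vol, cl, which) == pytest.approx(
                4.0, abs=TWO_VOXELS)

    def test_funnel_internal_larger_than_external(self):
        spec = PhantomSpec(canal_length=30.0, canal_radius_internal=4.0,
                           canal_radius_external=1.6)
        vol, _, axis = make_phantom(spec)
        cl = extract_canal_centerline(vol, axis)
        d_int = os_diameter(vol, cl, "internal")
        d_ext = os_diameter(vol, cl, "external")
        assert d_int > d_ext
        assert d_int == pytest.approx(8.0, abs=TWO_VOXELS)
        assert d_ext == pytest.approx(3.2, abs=TWO_VOXELS)

    def test_funnel_monotone_in_internal_radius(self):
        diams = []
        for r_int in (2.0, 3.0, 4.0):
            spec = PhantomSpec(canal_length=30.0, canal_radius_internal=r_int,
                               canal_radius_external=1.6)
            vol, _, axis = make_phantom(spec)
            cl = extract_canal_centerline(vol, axis)
            diams.append(os_diameter(vol, cl, "internal"))
        assert diams[0] < diams[1] < diams[2]

    def test_invalid_which(self, straight_phantom):
        vol, _, axis = straight_phantom
        cl = extract_canal_centerline(vol, axis)
        with pytest.raises(ValueError):
            os_diameter(vol, cl, "middle")

    def test_single_voxel_slab_at_most_voxel_diagonal(self):
        # a canal one voxel wide everywhere: Feret of the endpoint slab
        # cannot exceed the voxel diagonal
        vox = np.zeros((9, 9, 45), dtype=np.int16)
        vox[4, 4, 2:42] = 3
        vox[3:6, 3:6, 2:42] = np.where(
            vox[3:6, 3:6, 2:42] == 0, 2, vox[3:6, 3:6, 2:42])
        vol = _vol(vox)
        axis = UterineAxis(np.array([3.2, 3.2, -5.0]),
                           np.array([3.2, 3.2, -40.0]), "sidecar")
        cl = extract_canal_centerline(vol, axis)
        for which in ("internal", "external"):
            assert os_diameter(vol, cl, which) <= np.linalg.norm(vol.spacing)


class TestAngle:
    def test_antiparallel_is_180(self):
        lm = OsLandmarks(np.array([0.0, 0, 0]), np.array([0.0, 0, -30]),
                         np.array([0.0, 0, -15]))
        axis = UterineAxis(np.array([0.0, 0, 5]), np.array([0.0, 0, 40]), "sidecar")
        assert utero_cervical_angle(lm, axis) == pytest.approx(180.0)

    def test_perpendicular_is_90(self):
        lm = OsLandmarks(np.array([0.0, 0, 0]), np.array([30.0, 0, 0]),
                         np.array([15.0, 0, 0]))
        axis = UterineAxis(np.array([0.0, 0, 0]), np.array([0.0, 0, 40]), "sidecar")
        assert utero_cervical_angle(lm, axis) == pytest.approx(90.0)

    def test_phantom_angle_recovery(self):
        spec = PhantomSpec(utero_cervical_angle=120.0)
        vol, _, axis = make_phantom(spec)
        bio = compute_biometry(vol, axis)
        assert bio.utero_cervical_angle == pytest.approx(120.0, abs=2.0)

    def test_zero_length_cervical_line_errors(self):
        lm = OsLandmarks(np.zeros(3), np.zeros(3), np.zeros(3))
        axis = UterineAxis(np.zeros(3), np.array([0, 0, 1.0]), "sidecar")
        with pytest.raises(ValueError):
            utero_cervical_angle(lm, axis)


class TestVolumes:
    def test_thousand_stroma_voxels_exact(self):
        vox = np.zeros((10, 10, 10), dtype=np.int16)
        vox.ravel()[:1000] = 1
        total, stroma, canal, cyst = compartment_volumes(_vol(vox))
        assert stroma == pytest.approx(1000 * 0.512 / 1000.0)  # 0.512 cm^3
        assert (canal, cyst) == (0.0, 0.0)

    def test_partition_identity_exact(self, straight_phantom):
        vol, _, _ = straight_phantom
        total, stroma, canal, cyst = compartment_volumes(vol)
        assert total == stroma + canal + cyst  # exact in voxel counts

    def test_uterine_label_excluded(self, straight_phantom):
        vol, _, _ = straight_phantom
        total, *_ = compartment_volumes(vol)
        with_uterus = vol.mask(1, 2, 3, 4, 5).sum() * vol.voxel_volume_mm3 / 1000
        assert with_uterus > total  # label 5 present but not counted

    def test_straight_tube_canal_volume(self, straight_phantom):
        vol, gt, _ = straight_phantom
        _, _, canal, _ = compartment_volumes(vol)
        assert canal * 1000 == pytest.approx(math.pi * 4.0 * 32.0, rel=0.05)


class TestComputeBiometry:
    def test_full_panel_recovery(self, straight_phantom):
        vol, gt, axis = straight_phantom
        bio = compute_biometry(vol, axis)
        assert bio.length_2pt == pytest.approx(gt.length_2pt, abs=TWO_VOXELS)
        assert bio.length_3pt == pytest.approx(gt.length_3pt, abs=TWO_VOXELS)
        assert bio.internal_os_diameter == pytest.approx(4.0, abs=TWO_VOXELS)
        assert bio.external_os_diameter == pytest.approx(4.0, abs=TWO_VOXELS)
        assert bio.utero_cervical_angle == pytest.approx(140.0, abs=2.0)
        assert bio.canal_volume == pytest.approx(gt.canal_volume, rel=0.05)
        assert bio.meta["centerline_points"] >= 3

    def test_rigid_rotation_invariance(self):
        base = PhantomSpec(canal_length=30.0, canal_radius_internal=2.5,
                           canal_radius_external=2.0, curvature_radius=60.0,
                           utero_cervical_angle=120.0)
        vol0, _, ax0 = make_phantom(base)
        b0 = compute_biometry(vol0, ax0)
        volr, _, axr = make_phantom(
            dataclasses.replace(base, rotation=(30.0, 0.0, 0.0)))
        br = compute_biometry(volr, axr)
        assert br.total_volume == pytest.approx(b0.total_volume, rel=0.02)
        assert br.length_2pt == pytest.approx(b0.length_2pt, abs=TWO_VOXELS)
        assert br.internal_os_diameter == pytest.approx(
            b0.internal_os_diameter, abs=TWO_VOXELS)
        assert br.utero_cervical_angle == pytest.approx(
            b0.utero_cervical_angle, abs=2.0)

    def test_resolution_consistency(self):
        # halving the voxel size must not move measurements away from
        # analytic truth (beyond the dither noise floor on volumes)
        base = PhantomSpec(canal_length=30.0, canal_radius_internal=2.5,
                           canal_radius_external=2.0, curvature_radius=60.0,
                           utero_cervical_angle=120.0)
        vol_c, gt, ax_c = make_phantom(base)
        vol_f, _, ax_f = make_phantom(
            dataclasses.replace(base, spacing=(0.4, 0.4, 0.4)))
        bc = compute_biometry(vol_c, ax_c)
        bf = compute_biometry(vol_f, ax_f)
        fields = ["length_2pt", "length_3pt", "internal_os_diameter",
                  "external_os_diameter", "utero_cervical_angle"]
        for f in fields:
            truth = getattr(gt, f)
            assert abs(getattr(bf, f) - truth) <= abs(getattr(bc, f) - truth) + 1e-9
        truth = gt.canal_volume
        assert abs(bf.canal_volume - truth) <= (
            abs(bc.canal_volume - truth) + 0.005 * truth)

    def test_missing_canal_names_stage(self):
        vox = np.zeros((10, 10, 10), dtype=np.int16)
        vox[3:7, 3:7, 3:7] = 1
        axis = UterineAxis(np.zeros(3), np.array([0, 0, 10.0]), "sidecar")
        with pytest.raises(BiometryError, match="extract_canal_centerline"):
            compute_biometry(_vol(vox), axis)

    def test_panel_invariants_validated(self):
        with pytest.raises(ValueError):
            CervicalBiometry(-1, 1, 1, 1, 90, 1, 1, 0, 0)
        with pytest.raises(ValueError):
            CervicalBiometry(1, 1, 1, 1, 200, 1, 1, 0, 0)


coord = st.floats(min_value=-50.0, max_value=50.0,
                  allow_nan=False, allow_infinity=False)


class TestTriangleProperty:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(coord, coord, coord), min_size=3, max_size=20))
    def test_2pt_le_3pt_le_arc(self, raw):
        pts = np.asarray(raw, dtype=float)
        keep = np.concatenate(
            [[True], np.linalg.norm(np.diff(pts, axis=0), axis=1) > 1e-9])
        pts = pts[keep]
        if len(pts) < 3:
            return
        cl = Centerline(points=pts)
        l2, l3 = cervical_length(locate_os_landmarks(cl))
        assert l2 <= l3 + 1e-9
        assert l3 <= cl.arc_length + 1e-9
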