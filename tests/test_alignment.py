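"""Organ frame, three-rotation alignment and location/feature measures."""

import numpy as np
import pytest
import trimesh
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroshape import (
    LabeledVolume,
    NeuromastFrame,
    align_shape,
    compute_neuromast_frame,
    geometric_features,
    location_record,
    rotation1_angle,
)
from neuroshape.alignment import _projected_axis_angle, apply_rotation1
from neuroshape.core import rotation_x, rotation_y, rotation_z, wrap_angle_deg


def _ellipsoid(a, b, c):
    m = trimesh.creation.icosphere(subdivisions=3)
    m.vertices = m.vertices * np.array([a, b, c])
    return m


def _frame(cx=0.0, cy=0.0, r=10.0, polarity="parallel"):
    return NeuromastFrame(np.array([cx, cy, 0.0]), r, polarity)


class TestNeuromastFrame:
    def test_symmetric_pair(self):
        vol = np.zeros((4, 20, 40), dtype=np.int32)
        vol[1:3, 8:12, 4:8] = 1
        vol[1:3, 8:12, 32:36] = 2
        frame = compute_neuromast_frame(LabeledVolume(vol, (1, 1, 1)))
        assert frame.centroid_um[0] == pytest.approx(19.5)
        r_expect = abs(5.5 - 19.5)
        assert frame.max_radius_r == pytest.approx(r_expect)

    def test_coincident_cells_r_zero_warns(self):
        vol = np.zeros((4, 8, 8), dtype=np.int32)
        vol[1:3, 3:5, 3:5] = 1
        with pytest.warns(UserWarning):
            frame = compute_neuromast_frame(LabeledVolume(vol, (1, 1, 1)))
        assert frame.max_radius_r == 0.0

    def test_r_matches_bruteforce(self, ground_truth):
        frame = compute_neuromast_frame(ground_truth.cell_labels)
        cents = ground_truth.cell_labels.centroids_um()
        r_brute = max(
            np.hypot(c[0] - frame.centroid_um[0], c[1] - frame.centroid_um[1])
            for c in cents.values()
        )
        assert frame.max_radius_r == pytest.approx(r_brute)


class TestRotation1:
    @pytest.mark.parametrize(
        "offset,expect",
        [((1, 0), 0.0), ((0, 1), 90.0), ((-1, -1), -135.0), ((-1, 0), 180.0)],
    )
    def test_reference_angles(self, offset, expect):
        c = np.array([offset[0], offset[1], 0.0])
        assert rotation1_angle(c, _frame()) == pytest.approx(expect)

    def test_rotation_sends_radial_to_x(self):
        """After applying rotation 1 the recomputed angle is zero."""
        m = trimesh.creation.icosphere(subdivisions=2)
        m.apply_translation([-1.0, -1.0, 0.0])
        ang = rotation1_angle(m.center_mass, _frame())
        rotated = apply_rotation1(m, ang, about=np.zeros(3))
        ang2 = rotation1_angle(rotated.center_mass + [5, 0, 0],
                               _frame(cx=5.0))
        assert abs(ang2) < 1e-6 or ang2 == 0.0

    def test_zero_offset_flagged(self):
        with pytest.warns(UserWarning):
            assert rotation1_angle(np.zeros(3), _frame()) == 0.0


class TestAlignShape:
    def test_x_ellipsoid_cell_rotated_90(self):
        al = align_shape(_ellipsoid(3, 1, 1), "cell")
        assert abs(al.theta2) == pytest.approx(90.0, abs=1e-6)
        ang, _ = _projected_axis_angle(al.mesh.vertices, "xz")
        assert abs(ang) < 1.0

    def test_sphere_degenerate_path(self):
        al = align_shape(trimesh.creation.icosphere(subdivisions=2), "cell")
        assert al.theta2 == 0.0 and al.theta3 == 0.0
        assert "rotation2_degenerate" in al.flags

    def test_yz_axis_beyond_45_goes_to_y(self):
        """A 60-degree yz tilt must map the long axis to y, not z."""
        m = _ellipsoid(1, 1, 3)
        m.vertices = m.vertices @ rotation_x(60).T
        al = align_shape(m, "cell")
        ang, _ = _projected_axis_angle(al.mesh.vertices, "yz")
        assert abs(abs(ang) - 90.0) < 1.0  # parallel to y
        assert abs(al.theta3) <= 45.0

    def test_nucleus_rotation2_capped(self):
        m = _ellipsoid(1, 1, 3)
        m.vertices = m.vertices @ rotation_y(60).T
        al = align_shape(m, "nucleus")
        ang, _ = _projected_axis_angle(al.mesh.vertices, "xz")
        assert abs(abs(ang) - 90.0) < 1.0  # long axis on x
        assert abs(al.theta2) <= 45.0

    def test_cell_rotation2_uncapped(self):
        m = _ellipsoid(1, 1, 3)
        m.vertices = m.vertices @ rotation_y(60).T
        al = align_shape(m, "cell")
        ang, _ = _projected_axis_angle(al.mesh.vertices, "xz")
        assert abs(ang) < 1.0  # back on z despite the 60-degree tilt

    def test_alignment_idempotent(self):
        """Re-aligning an aligned, roughly upright cell is a no-op."""
        m = _ellipsoid(1.4, 1.1, 2.6)
        m.vertices = m.vertices @ (rotation_y(-25) @ rotation_x(15)).T
        first = align_shape(m, "cell")
        second = align_shape(first.mesh, "cell")
        assert abs(second.theta2) < 1.0 and abs(second.theta3) < 1.0


class TestLocationRecord:
    def test_farthest_cell_has_d_one(self):
        rec = location_record(np.array([10.0, 0, 0]), _frame(r=10.0))
        assert rec.d == pytest.approx(1.0)

    def test_perpendicular_90_maps_to_0(self):
        rec = location_record(np.array([0.0, 5.0, 0]),
                              _frame(r=10.0, polarity="perpendicular"))
        assert rec.o == pytest.approx(90.0)
        assert rec.a == pytest.approx(0.0)

    def test_perpendicular_wraps_across_minus_180(self):
        c = 5.0 * np.array([np.cos(np.radians(-135)), np.sin(np.radians(-135)), 0])
        rec = location_record(c, _frame(r=10.0, polarity="perpendicular"))
        assert rec.o == pytest.approx(-135.0)
        assert rec.a == pytest.approx(135.0)

    @given(st.floats(min_value=-179.999, max_value=180.0))
    @settings(max_examples=200, deadline=None)
    def test_adjustment_is_circular_isometry(self, o):
        """wrap(o - 90) is a bijection preserving circular distances."""
        a = wrap_angle_deg(o - 90.0)
        assert -180.0 < a <= 180.0
        o2 = wrap_angle_deg(o + 37.0)
        a2 = wrap_angle_deg(o2 - 90.0)

        def circ(x, y):
            return abs(wrap_angle_deg(x - y))

        assert circ(a, a2) == pytest.approx(circ(o, o2), abs=1e-9)


class TestGeometricFeatures:
    def test_axis_aligned_box(self):
        m = trimesh.creation.box(extents=(2.0, 3.0, 4.0))
        al = align_shape(m, "cell")
        # a box's projected long axes are already canonical; measure raw
        feats = geometric_features(
            type(al)(mesh=m, theta1=0, theta2=0, theta3=0, object_class="cell")
        )
        assert feats["width_um"] == pytest.approx(2.0)
        assert feats["depth_um"] == pytest.approx(3.0)
        assert feats["height_um"] == pytest.approx(4.0)
        assert feats["volume_um3"] == pytest.approx(24.0)

    def test_sphere_closed_forms(self):
        m = trimesh.creation.icosphere(subdivisions=4)
        m.apply_scale(5.0)
        al = align_shape(m, "cell")
        feats = geometric_features(al)
        assert feats["volume_um3"] == pytest.approx(4 / 3 * np.pi * 125, rel=0.05)
        assert feats["surface_area_um2"] == pytest.approx(100 * np.pi, rel=0.05)

    def test_features_invariant_to_organ_angle(self):
        """The same cell at different organ angles measures identically."""
        from neuroshape import make_cell_shape

        base = make_cell_shape("SC")
        results = []
        for ang in (0.0, 63.0, -120.0):
            m = base.copy()
            m.vertices = m.vertices @ rotation_z(ang).T
            m2 = apply_rotation1(m, ang)
            al = align_shape(m2, "cell")
            results.append(geometric_features(al))
        for key in ("width_um", "depth_um", "height_um", "volume_um3"):
            vals = [r[key] for r in results]
            assert max(vals) - min(vals) < 1e-6 * max(abs(v) for v in vals) + 1e-8

    def test_voxel_volume_path(self):
        m = trimesh.creation.box(extents=(2, 2, 2))
        al = align_shape(m, "cell")
        al.voxel_count = 1000
        al.voxel_volume_um3 = 0.008
        feats = geometric_features(al)
        assert feats["volume_um3"] == pytest.approx(8.0)
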