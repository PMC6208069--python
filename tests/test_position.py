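import numpy as np
import pytest
import trimesh
from scipy.spatial.transform import Rotation

from conftest import canonical_femur_landmarks, report_errors
from kneealign.frames import AnatomicFrame, build_femoral_frame
from kneealign.geometry import Plane, RigidTransform, TriangleMesh, random_transform
from kneealign.phantom import default_implants
from kneealign.position import (
    CaseInputs,
    ComponentPose,
    ImplantDefinition,
    alignment_angles,
    analyze_case,
    implant_pose_from_fiducials,
    placement_translations,
    resection_thickness,
)


@pytest.fixture
def femoral_implant():
    return default_implants("right")["femoral"]


@pytest.fixture
def canonical_frame():
    return build_femoral_frame(canonical_femur_landmarks("right"))


def pose(transform: RigidTransform) -> ComponentPose:
    return ComponentPose(transform, 0.0)


# ---------------------------------------------------------------------------
# implant pose from fiducials
# ---------------------------------------------------------------------------

class TestImplantPose:
    def test_identity_placement(self, femoral_implant):
        p = implant_pose_from_fiducials(femoral_implant, femoral_implant.fiducials)
        assert np.allclose(p.transform.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(p.transform.translation, 0.0, atol=1e-12)
        assert p.fit_rms < 1e-12

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_recovers_seeded_transform(self, femoral_implant, seed):
        rng = np.random.default_rng(seed)
        true = random_transform(rng)
        observed = {k: true.apply(v) for k, v in femoral_implant.fiducials.items()}
        p = implant_pose_from_fiducials(femoral_implant, observed)
        assert np.max(np.abs(p.transform.rotation - true.rotation)) < 1e-9
        assert np.max(np.abs(p.transform.translation - true.translation)) < 1e-9

    def test_noisy_fiducials_rotation_error_bounded(self, femoral_implant):
        """0.2 mm observation noise perturbs the fitted orientation by
        less than half a degree over 20 seeds."""
        worst = 0.0
        for seed in range(1, 21):
            rng = np.random.default_rng(seed)
            true = random_transform(rng, max_angle_deg=20, max_translation_mm=30)
            observed = {k: true.apply(v) + rng.normal(0, 0.2, 3)
                        for k, v in femoral_implant.fiducials.items()}
            p = implant_pose_from_fiducials(femoral_implant, observed)
            d = p.transform.rotation @ true.rotation.T
            worst = max(worst, np.degrees(np.linalg.norm(Rotation.from_matrix(d).as_rotvec())))
        assert worst <= 0.5

    def test_needs_three_matching_names(self, femoral_implant):
        observed = {"f1": (0, 0, 0), "f2": (1, 0, 0)}
        with pytest.raises(Exception, match="3 matching"):
            implant_pose_from_fiducials(femoral_implant, observed)


# ---------------------------------------------------------------------------
# angles and translations
# ---------------------------------------------------------------------------

class TestAlignmentAngles:
    def test_aligned_component_reads_zero(self, femoral_implant, canonical_frame):
        fe, vv, ie = alignment_angles(pose(RigidTransform.identity()),
                                      canonical_frame, femoral_implant)
        assert (fe, vv, ie) == pytest.approx((0, 0, 0), abs=1e-12)

    @pytest.mark.parametrize("angle", [1.0, 5.0, 12.0, 20.0])
    def test_single_axis_rotations_read_exactly(self, femoral_implant,
                                                canonical_frame, angle):
        """A rotation about one anatomic axis appears only in its own
        clinical angle, at exactly the rotation magnitude."""
        ml, ap, si = (canonical_frame.ml_axis, canonical_frame.ap_axis,
                      canonical_frame.si_axis)
        fe, vv, ie = alignment_angles(pose(RigidTransform.from_axis_angle(ml, angle)),
                                      canonical_frame, femoral_implant)
        assert fe == pytest.approx(angle, abs=1e-9)
        assert (vv, ie) == pytest.approx((0, 0), abs=1e-9)

        fe, vv, ie = alignment_angles(
            pose(RigidTransform.from_axis_angle(ap, -angle)),  # varus tilt
            canonical_frame, femoral_implant)
        assert vv == pytest.approx(angle, abs=1e-9)
        assert (fe, ie) == pytest.approx((0, 0), abs=1e-9)

        fe, vv, ie = alignment_angles(pose(RigidTransform.from_axis_angle(si, angle)),
                                      canonical_frame, femoral_implant)
        assert ie == pytest.approx(angle, abs=1e-9)
        assert (fe, vv) == pytest.approx((0, 0), abs=1e-9)

    def test_composed_rotation_cross_talk_bounded(self, femoral_implant,
                                                  canonical_frame):
        """3 deg about ML then 2 deg about SI: the projection angles read
        ~3 and ~2 with sub-0.05 deg cross-talk."""
        r_ml = RigidTransform.from_axis_angle(canonical_frame.ml_axis, 3.0)
        r_si = RigidTransform.from_axis_angle(canonical_frame.si_axis, 2.0)
        fe, vv, ie = alignment_angles(pose(r_ml.compose(r_si)),
                                      canonical_frame, femoral_implant)
        assert fe == pytest.approx(3.0, abs=0.05)
        assert ie == pytest.approx(2.0, abs=0.05)
        assert abs(vv) < 0.2

    def test_degenerate_projection_rejected(self, femoral_implant, canonical_frame):
        # component SI axis rotated onto the AP axis: no sagittal projection
        r = RigidTransform.from_axis_angle(canonical_frame.ml_axis, 90.0)
        with pytest.raises(Exception, match="VV"):
            alignment_angles(pose(r), canonical_frame, femoral_implant)


class TestPlacementTranslations:
    def test_origin_and_axis_aligned_offsets(self, femoral_implant, canonical_frame):
        at_origin = pose(RigidTransform(np.eye(3), canonical_frame.origin))
        assert placement_translations(at_origin, canonical_frame,
                                      femoral_implant) == pytest.approx((0, 0, 0))
        shifted = pose(RigidTransform(np.eye(3),
                                      canonical_frame.origin + 4 * canonical_frame.ap_axis))
        assert placement_translations(shifted, canonical_frame,
                                      femoral_implant) == pytest.approx((4, 0, 0))

    @pytest.mark.parametrize("seed", range(1, 11))
    def test_invariant_under_scene_motion(self, femoral_implant, canonical_frame, seed):
        rng = np.random.default_rng(seed)
        p = pose(RigidTransform(np.eye(3), (3.0, -2.0, 5.0)))
        base = placement_translations(p, canonical_frame, femoral_implant)
        g = random_transform(rng)
        moved_pose = pose(g.compose(p.transform))
        lm = canonical_femur_landmarks("right").transformed(g)
        moved = placement_translations(moved_pose, build_femoral_frame(lm),
                                       femoral_implant)
        assert np.allclose(moved, base, atol=1e-9)


# ---------------------------------------------------------------------------
# resections
# ---------------------------------------------------------------------------

def pole_sphere(subdivisions: int, radius: float = 25.0, centre=(-15.0, 0.0, 0.0)):
    """Sphere mesh with a vertex exactly at its inferior pole, so the
    distal extreme is analytic at every refinement level."""
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v0 = ico.vertices[0] / np.linalg.norm(ico.vertices[0])
    R, _ = Rotation.align_vectors([[0, 0, -1.0]], [v0])
    verts = radius * (np.asarray(ico.vertices) @ R.as_matrix().T) + np.asarray(centre)
    return TriangleMesh(verts, np.asarray(ico.faces))


class TestResectionThickness:
    frame = AnatomicFrame((0, 0, 0), (0, 1, 0), (1, 0, 0), (0, 0, 1),
                          "femur", "right")

    def test_plane_through_reference_vertex_is_zero(self):
        mesh = pole_sphere(3)
        plane = Plane((0, 0, -25.0), (0, 0, -1.0))
        assert resection_thickness(mesh, self.frame, plane,
                                   "distal_medial") == pytest.approx(0.0, abs=1e-12)

    def test_synthetic_condyle_nine_millimetres(self):
        mesh = pole_sphere(3)
        plane = Plane((0, 0, -16.0), (0, 0, -1.0))  # 9 mm above the pole
        assert resection_thickness(mesh, self.frame, plane,
                                   "distal_medial") == pytest.approx(9.0, abs=1e-6)

    def test_invariant_to_tessellation_density(self):
        plane = Plane((0, 0, -16.0), (0, 0, -1.0))
        values = [resection_thickness(pole_sphere(s), self.frame, plane, "distal_medial")
                  for s in (2, 3, 4)]
        assert max(values) - min(values) < 0.05

    def test_empty_region_rejected(self):
        mesh = pole_sphere(3, centre=(-30.0, 0.0, 0.0))
        plane = Plane((0, 0, -16.0), (0, 0, -1.0))
        with pytest.raises(Exception, match="no vertices"):
            # the whole sphere is medial of the sagittal plane
            resection_thickness(mesh, self.frame, plane, "distal_lateral")


# ---------------------------------------------------------------------------
# end-to-end case analysis
# ---------------------------------------------------------------------------

class TestAnalyzeCase:
    def test_zero_noise_identity_recovers_ground_truth(self, still_case):
        report = analyze_case(still_case.inputs)
        ea, et, er = report_errors(report, still_case.ground_truth)
        assert ea < 1e-6 and et < 1e-6 and er < 1e-6

    def test_zero_noise_ct_offset_recovered(self, offset_case):
        report = analyze_case(offset_case.inputs)
        ea, et, er = report_errors(report, offset_case.ground_truth)
        assert ea < 0.01 and et < 0.01 and er < 0.01

    def test_repeated_runs_are_identical(self, noisy_case):
        a = analyze_case(noisy_case.inputs)
        b = analyze_case(noisy_case.inputs)
        assert a.to_json() == b.to_json()

    def test_scene_equivariance(self, still_case):
        """Rigidly moving every post-operative input leaves all reported
        angles, translations and resections unchanged."""
        base = analyze_case(still_case.inputs)
        g = random_transform(np.random.default_rng(31), max_angle_deg=40,
                             max_translation_mm=60)
        moved = CaseInputs(
            preop_meshes=still_case.inputs.preop_meshes,
            landmarks=still_case.inputs.landmarks,
            postop_meshes={b: m.transformed(g)
                           for b, m in still_case.inputs.postop_meshes.items()},
            fiducials={c: {k: g.apply(v) for k, v in f.items()}
                       for c, f in still_case.inputs.fiducials.items()},
            implants=still_case.inputs.implants,
        )
        other = analyze_case(moved)
        for comp in ("femoral", "tibial"):
            m0, m1 = base.components[comp], other.components[comp]
            assert np.allclose([m0.fe, m0.vv, m0.ie, m0.ap, m0.ml, m0.si],
                               [m1.fe, m1.vv, m1.ie, m1.ap, m1.ml, m1.si], atol=1e-6)
        for k in base.resections:
            assert base.resections[k] == pytest.approx(other.resections[k], abs=1e-6)

    def test_report_serialisation_contains_conventions(self, still_case):
        report = analyze_case(still_case.inputs)
        doc = report.to_dict()
        assert "projection-angles" in doc["convention"]
        assert set(doc["resections"]) == {
            "distal_medial", "distal_lateral", "posterior_medial",
            "posterior_lateral", "plateau_medial", "plateau_lateral"}
        assert len(report.summary()) == 2


class TestImplantDefinition:
    def test_json_roundtrip(self, femoral_implant, tmp_path):
        p = tmp_path / "implant.json"
        femoral_implant.to_json(p)
        back = ImplantDefinition.from_json(p)
        assert back.name == femoral_implant.name
        for k in femoral_implant.fiducials:
            assert np.allclose(back.fiducials[k], femoral_implant.fiducials[k])
        for k, plane in femoral_implant.planes.items():
            assert np.allclose(back.planes[k].point, plane.point)
            assert np.allclose(back.planes[k].normal, plane.normal)

    def test_axes_must_be_orthonormal(self):
        with pytest.raises(ValueError, match="orthonormal"):
            ImplantDefinition("bad", "femoral",
                              {"a": (0, 0, 0), "b": (1, 0, 0), "c": (0, 1, 0)},
                              {"ap": (0, 1, 0), "ml": (0.5, 0.5, 0), "si": (0, 0, 1)},
                              {})
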