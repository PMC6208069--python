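"""Component pose, alignment angles, placement translations, resections.

The implant pose is recovered by paired-point (Kabsch) registration of
the implant definition's local fiducials onto the fiducial points
observed in the post-operative CT.  Alignment is reported as three
projection angles of the posed component axes in the bone's anatomic
frame — the three clinically named rotations rather than a sequential
Euler decomposition:

* FE (flexion/extension): component SI axis projected onto the sagittal
  (AP-SI) plane; positive = tilted posteriorly (flexion).
* VV (varus/valgus): component SI axis projected onto the coronal
  (ML-SI) plane; positive = tilted medially (varus).
* IE (internal/external): component ML axis projected onto the axial
  (AP-ML) plane; positive = rotated anterior-to-medial (internal).

Because the anatomic axes are anatomically signed (see
:mod:`kneealign.frames`), these definitions are mirror-consistent: the
same formulas give flexion/varus/internal positive on both sides.

Resection thickness is the signed plane-normal distance from the
pre-operative bone's regional extreme vertex to the posed resection
plane, positive on the removed-bone side — the surgical "resection
depth" reading.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import AnatomicFrame, build_frame
from .geometry import (
    DegenerateGeometryError,
    LandmarkSet,
    Plane,
    RigidTransform,
    TriangleMesh,
    as_point,
    signed_plane_distance,
)
from .registration import IcpParams, RegistrationResult, icp, kabsch

#: serialized convention tag embedded in every report
CONVENTION = ("projection-angles-v1: FE+ posterior tilt (flexion), "
              "VV+ medial tilt (varus), IE+ anterior-to-medial (internal); "
              "AP+ anterior, ML+ lateral, SI+ superior; "
              "resection = plane-normal distance, removed side positive")

FEMORAL_REGIONS = ("distal_medial", "distal_lateral", "posterior_medial", "posterior_lateral")
TIBIAL_REGIONS = ("plateau_medial", "plateau_lateral")
RESECTION_REGIONS = FEMORAL_REGIONS + TIBIAL_REGIONS

#: bone each component type attaches to
COMPONENT_BONE = {"femoral": "femur", "tibial": "tibia"}


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# implant definitions
# ---------------------------------------------------------------------------

@dataclass
class ImplantDefinition:
    """Parametric implant description in implant-local coordinates.

    Real prosthesis CAD is proprietary, so components are described by a
    definition file carrying the quantities the analysis needs: named
    registration fiducials, anatomic-labelled local axes, and the
    resection planes with normals oriented toward the removed bone.
    Vendor CAD-derived values drop into the same format.
    """

    name: str
    component: str  # 'femoral' | 'tibial'
    fiducials: dict = field(default_factory=dict)
    axes: dict = field(default_factory=dict)  # 'ap'/'ml'/'si' -> unit vectors
    planes: dict = field(default_factory=dict)  # name -> Plane

    def __post_init__(self):
        if self.component not in COMPONENT_BONE:
            raise ValueError(f"component must be 'femoral' or 'tibial', got {self.component!r}")
        self.fiducials = {str(k): as_point(v) for k, v in self.fiducials.items()}
        if len(self.fiducials) < 3:
            raise ValueError("implant definition needs at least 3 fiducials")
        ax = {k: as_point(v) for k, v in self.axes.items()}
        if set(ax) != {"ap", "ml", "si"}:
            raise ValueError("axes must define exactly ap, ml, si")
        M = np.column_stack([ax["ap"], ax["ml"], ax["si"]])
        if np.max(np.abs(M.T @ M - np.eye(3))) > 1e-9:
            raise ValueError("implant local axes are not orthonormal")
        self.axes = ax
        self.planes = {
            str(k): v if isinstance(v, Plane) else Plane(v["point"], v["normal"])
            for k, v in self.planes.items()
        }

    def to_json(self, path=None) -> str:
        doc = {
            "name": self.name,
            "component": self.component,
            "fiducials": {k: [float(c) for c in v] for k, v in sorted(self.fiducials.items())},
            "axes": {k: [float(c) for c in v] for k, v in sorted(self.axes.items())},
            "planes": {k: {"point": [float(c) for c in p.point],
                           "normal": [float(c) for c in p.normal]}
                       for k, p in sorted(self.planes.items())},
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source) -> "ImplantDefinition":
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        doc = json.loads(p.read_text() if p else str(source))
        return ImplantDefinition(doc["name"], doc["component"], doc["fiducials"],
                                 doc["axes"], doc["planes"])


@dataclass(frozen=True)
class ComponentPose:
    """Implant-local -> CT-frame transform with its fiducial fit rms."""

    transform: RigidTransform
    fit_rms: float


def implant_pose_from_fiducials(implant_def: ImplantDefinition,
                                observed_fiducials: dict) -> ComponentPose:
    """Kabsch fit of the implant's local fiducials onto the named points
    segmented from the post-operative CT."""
    common = sorted(set(implant_def.fiducials) & set(observed_fiducials))
    if len(common) < 3:
        raise DegenerateGeometryError(
            f"need >=3 matching fiducials, found {len(common)}: {common}")
    src = np.array([implant_def.fiducials[k] for k in common])
    dst = np.array([as_point(observed_fiducials[k]) for k in common])
    result = kabsch(src, dst)
    return ComponentPose(result.transform, result.rms_residual)


# ---------------------------------------------------------------------------
# angles and translations
# ---------------------------------------------------------------------------

def _projected_angle(y_comp: float, x_comp: float, what: str) -> float:
    """Signed angle (degrees) of a projected axis; errors if the
    projection collapses (axis parallel to the projection plane normal)."""
    if np.hypot(y_comp, x_comp) < 1e-9:
        raise DegenerateGeometryError(f"{what}: axis parallel to projection plane normal")
    return float(np.degrees(np.arctan2(y_comp, x_comp)))


def alignment_angles(pose: ComponentPose, frame: AnatomicFrame,
                     implant_def: ImplantDefinition) -> tuple[float, float, float]:
    """(FE, VV, IE) in degrees, signs as in the module docstring."""
    R = pose.transform.rotation
    c_si = R @ implant_def.axes["si"]
    c_ml = R @ implant_def.axes["ml"]
    # components of the posed axes along the anatomic directions
    a_si, m_si, s_si = c_si @ frame.ap_axis, c_si @ frame.ml_axis, c_si @ frame.si_axis
    a_ml, m_ml = c_ml @ frame.ap_axis, c_ml @ frame.ml_axis
    fe = _projected_angle(-a_si, s_si, "FE")
    vv = _projected_angle(-m_si, s_si, "VV")
    ie = _projected_angle(a_ml, m_ml, "IE")
    return fe, vv, ie


def placement_translations(pose: ComponentPose, frame: AnatomicFrame,
                           implant_def: ImplantDefinition) -> tuple[float, float, float]:
    """(AP, ML, SI) components in mm of the posed implant origin relative
    to the frame origin; anterior, lateral, superior positive."""
    v = pose.transform.translation - frame.origin
    return (float(v @ frame.ap_axis), float(v @ frame.ml_axis), float(v @ frame.si_axis))


# ---------------------------------------------------------------------------
# resections
# ---------------------------------------------------------------------------

def _region_reference_vertex(mesh: TriangleMesh, frame: AnatomicFrame, region: str) -> np.ndarray:
    """Regional extreme vertex of the (registered) pre-operative bone.

    Medial/lateral halves are split by the sagittal plane through the
    frame origin; distal regions take the minimum-SI vertex of their
    half, posterior regions the minimum-AP vertex, plateau regions the
    maximum-SI vertex.
    """
    if region not in RESECTION_REGIONS:
        raise ValueError(f"unknown region {region!r}; expected one of {RESECTION_REGIONS}")
    coords = frame.coords(mesh.vertices)  # columns: ap, ml, si
    half = coords[:, 1] < 0 if region.endswith("medial") else coords[:, 1] >= 0
    if not half.any():
        raise DegenerateGeometryError(f"no vertices in the {region} half-space")
    idx = np.flatnonzero(half)
    if region.startswith("distal"):
        pick = idx[np.argmin(coords[idx, 2])]
    elif region.startswith("posterior"):
        pick = idx[np.argmin(coords[idx, 0])]
    else:  # plateau
        pick = idx[np.argmax(coords[idx, 2])]
    return mesh.vertices[pick]


def resection_thickness(preop_mesh: TriangleMesh, frame: AnatomicFrame,
                        plane_in_ct: Plane, region: str) -> float:
    """Signed distance (mm) from the region's pre-operative extreme
    vertex to the resection plane; positive when the vertex lies on the
    removed-bone side of the plane."""
    v = _region_reference_vertex(preop_mesh, frame, region)
    return float(signed_plane_distance(plane_in_ct, v))


# ---------------------------------------------------------------------------
# end-to-end case analysis
# ---------------------------------------------------------------------------

@dataclass
class ComponentMeasurement:
    fe: float
    vv: float
    ie: float
    ap: float
    ml: float
    si: float
    fit_rms: float

    def to_dict(self) -> dict:
        return {k: float(getattr(self, k)) for k in ("fe", "vv", "ie", "ap", "ml", "si", "fit_rms")}


@dataclass
class CaseReport:
    """Everything the post-operative analysis of one knee produces."""

    components: dict  # 'femoral'/'tibial' -> ComponentMeasurement
    resections: dict  # region -> mm
    registrations: dict  # bone -> RegistrationResult (preop -> CT)
    frames: dict  # bone -> AnatomicFrame (in the CT frame)
    bone_transforms: dict  # bone -> RigidTransform preop -> CT
    poses: dict  # component -> ComponentPose
    convention: str = CONVENTION

    def to_dict(self) -> dict:
        return {
            "convention": self.convention,
            "components": {k: v.to_dict() for k, v in sorted(self.components.items())},
            "resections": {k: float(v) for k, v in sorted(self.resections.items())},
            "registrations": {
                bone: {
                    "rotation": [float(x) for x in r.transform.rotation.ravel()],
                    "translation": [float(x) for x in r.transform.translation],
                    "rms_residual": float(r.rms_residual),
                    "n_iterations": int(r.n_iterations),
                    "converged": bool(r.converged),
                }
                for bone, r in sorted(self.registrations.items())
            },
            "frames": {k: v.to_dict() for k, v in sorted(self.frames.items())},
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def summary(self) -> pd.DataFrame:
        """One row per component: angles (deg), translations (mm), fit rms."""
        rows = []
        for name, m in sorted(self.components.items()):
            rows.append({"component": name, "FE_deg": m.fe, "VV_deg": m.vv, "IE_deg": m.ie,
                         "AP_mm": m.ap, "ML_mm": m.ml, "SI_mm": m.si, "fit_rms_mm": m.fit_rms})
        return pd.DataFrame(rows)

    def resection_summary(self) -> pd.DataFrame:
        return pd.DataFrame([{"region": k, "thickness_mm": v}
                             for k, v in sorted(self.resections.items())])


@dataclass
class CaseInputs:
    """Bundle of one case's inputs, keyed by bone ('femur'/'tibia') and
    component ('femoral'/'tibial')."""

    preop_meshes: dict
    landmarks: dict
    postop_meshes: dict
    fiducials: dict
    implants: dict
    init_transforms: dict | None = None


#: coarse ICP stage used to absorb the unknown CT-frame offset before the
#: gated fine stage.  No trimming and no distance gate: the moving set is
#: the partial post-op surface, so every point has a true counterpart and
#: trimming would discard exactly the far-from-fit points (metaphyseal
#: flares) that carry the information about residual misalignment.
COARSE_ICP = IcpParams(max_iterations=200, tolerance=1e-7, trim_fraction=0.0,
                       max_correspondence_distance=np.inf)
#: short subsampled ICP used to score each multi-start candidate
COARSE_SEARCH = IcpParams(max_iterations=40, tolerance=1e-4, trim_fraction=0.0,
                          max_correspondence_distance=np.inf, subsample=800, seed=0)
#: multi-start grids over the bone's long axis: spin (deg) and slide (mm).
#: A long bone's surface constrains these two pose coordinates only
#: through its subtle asymmetries (cross-section eccentricity, bow,
#: metaphyseal flares), so ICP's basin of attraction is narrow there and
#: a local search from a single guess can settle in a spurious minimum.
LONG_AXIS_SPINS_DEG = np.arange(-12.0, 12.1, 3.0)
LONG_AXIS_SLIDES_MM = np.arange(-12.0, 12.1, 4.0)


def _long_axis_starts(dst_vertices: np.ndarray, init_inv: RigidTransform):
    """Candidate initialisations: ``init_inv`` perturbed by a grid of
    spins about, and slides along, the destination bone's principal
    (long) axis through its centroid."""
    centroid = dst_vertices.mean(axis=0)
    centred = dst_vertices - centroid
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis = vt[0]
    for delta in LONG_AXIS_SPINS_DEG:
        spin = RigidTransform.from_axis_angle(axis, float(delta))
        pivot = RigidTransform(spin.rotation, centroid - spin.rotation @ centroid)
        for slide in LONG_AXIS_SLIDES_MM:
            shift = RigidTransform(np.eye(3), slide * axis)
            yield shift.compose(pivot).compose(init_inv)


def register_bone(preop_mesh: TriangleMesh, postop_mesh,
                  init_transform: RigidTransform | None = None,
                  params: IcpParams | None = None,
                  coarse: bool = True) -> RegistrationResult:
    """Register a pre-operative bone into the post-operative CT frame.

    The *partial* post-operative surface is used as the moving set
    against the full pre-operative mesh (every moving point then has a
    true counterpart, so trimming only has to absorb noise), and the
    fitted transform is inverted to give preop -> CT.

    ICP itself is local; manual workflows bridge that with hand
    placement.  Here a deterministic coarse stage stands in: short
    subsampled ICP runs from a grid of rotations about the bone's long
    axis (the one rotation a shaft constrains weakly) pick the lowest-rms
    basin, a full coarse ICP refines it, and the gated fine stage
    finishes.  Capture range is ~12 deg about the long axis and several
    degrees / tens of mm elsewhere; beyond that, pass ``init_transform``.
    """
    params = params or IcpParams()
    post = postop_mesh.vertices if isinstance(postop_mesh, TriangleMesh) else postop_mesh
    init_inv = (init_transform or RigidTransform.identity()).inverse()
    if coarse:
        # iterate (multi-start search -> refine) until the rms stops
        # improving: one round can leave a residual offset that again
        # lies in the weakly-constrained spin/slide subspace, which the
        # re-centred grid of the next round then resolves
        prev_rms = np.inf
        for _ in range(3):
            best = None
            for start in _long_axis_starts(preop_mesh.vertices, init_inv):
                res = icp(post, preop_mesh.vertices, start, COARSE_SEARCH)
                if best is None or res.rms_residual < best.rms_residual:
                    best = res
            rough = icp(post, preop_mesh.vertices, best.transform, COARSE_ICP)
            init_inv = rough.transform
            if rough.rms_residual > prev_rms - 1e-3:
                break
            prev_rms = rough.rms_residual
    fine = icp(post, preop_mesh.vertices, init_inv, params)
    return RegistrationResult(fine.transform.inverse(), fine.rms_residual,
                              fine.n_iterations, fine.converged)


def analyze_case(inputs: CaseInputs, params: IcpParams | None = None) -> CaseReport:
    """Full post-operative pipeline for one knee.

    Stages: bone ICP registration -> landmark propagation into the CT
    frame -> anatomic frame construction -> implant pose from fiducials
    -> alignment angles, placement translations, and the six resection
    thicknesses.  Any stage failure is re-raised naming the stage.
    """
    registrations: dict = {}
    transforms: dict = {}
    frames: dict = {}
    meshes_ct: dict = {}
    for bone in ("femur", "tibia"):
        stage = f"registration[{bone}]"
        try:
            init = (inputs.init_transforms or {}).get(bone)
            reg = register_bone(inputs.preop_meshes[bone], inputs.postop_meshes[bone],
                                init, params)
        except Exception as exc:
            raise PipelineError(f"{stage}: {exc}") from exc
        registrations[bone] = reg
        transforms[bone] = reg.transform
        try:
            lm_ct = inputs.landmarks[bone].transformed(reg.transform)
            frames[bone] = build_frame(lm_ct)
        except Exception as exc:
            raise PipelineError(f"frames[{bone}]: {exc}") from exc
        meshes_ct[bone] = inputs.preop_meshes[bone].transformed(reg.transform)

    components: dict = {}
    resections: dict = {}
    poses: dict = {}
    for comp, implant in sorted(inputs.implants.items()):
        bone = COMPONENT_BONE[implant.component]
        frame = frames[bone]
        try:
            pose = implant_pose_from_fiducials(implant, inputs.fiducials[comp])
            fe, vv, ie = alignment_angles(pose, frame, implant)
            ap, ml, si = placement_translations(pose, frame, implant)
        except Exception as exc:
            raise PipelineError(f"component_pose[{comp}]: {exc}") from exc
        poses[comp] = pose
        components[comp] = ComponentMeasurement(fe, vv, ie, ap, ml, si, pose.fit_rms)
        regions = FEMORAL_REGIONS if implant.component == "femoral" else TIBIAL_REGIONS
        for region in regions:
            plane_name = region if implant.component == "femoral" else "plateau"
            try:
                plane_ct = implant.planes[plane_name].transformed(pose.transform)
                resections[region] = resection_thickness(meshes_ct[bone], frame,
                                                         plane_ct, region)
            except Exception as exc:
                raise PipelineError(f"resection[{region}]: {exc}") from exc
    return CaseReport(components, resections, registrations, frames, transforms, poses)
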