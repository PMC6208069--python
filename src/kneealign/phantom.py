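"""Parametric knee phantoms with analytically known ground truth.

The phantom stands in for segmented patient CT surfaces: the femur is a
shaft cylinder capped by two condylar spheres, the tibia a shaft
cylinder with a plateau ellipsoid.  Primitive geometry keeps every
landmark, axis, implant pose and resection depth analytic, so each
pipeline stage can be checked against exact ground truth.

``implant_and_scan`` emulates the post-operative scan: bone on the
removed side of each posed resection plane is cropped away, a
peri-implant band (CT metal-flare emulation, default 3 mm) is deleted,
the whole scene is moved by an unknown CT-frame offset, and Gaussian
jitter is added to surface vertices and implant fiducial observations.
All randomness flows through the spec seed.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh

from .frames import AnatomicFrame, build_frame
from .geometry import (
    DegenerateGeometryError,
    LandmarkSet,
    Plane,
    RigidTransform,
    TriangleMesh,
    signed_plane_distance,
)
from .position import (
    FEMORAL_REGIONS,
    TIBIAL_REGIONS,
    CaseInputs,
    ComponentPose,
    ImplantDefinition,
    alignment_angles,
    placement_translations,
    resection_thickness,
)


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, implant placement, and scan-noise parameters (mm / deg).

    Defaults describe a right knee with clinically typical resection
    depths (~6-10 mm), a 10 deg / 20 mm unknown CT-frame offset, 0.3 mm
    surface-vertex jitter (approximate segmentation uncertainty of a
    ~1 mm slice CT protocol) and 0.2 mm fiducial-observation jitter.
    """

    # femur geometry: elliptical, anteriorly bowed shaft and two unequal
    # condylar spheres (medial larger) — the asymmetries real bones have,
    # which also make the rigid pose observable from the surface alone
    femur_shaft_radii: tuple = (16.0, 13.0)
    femur_shaft_bow: float = 5.0
    femur_end_flare: tuple = ((0.8, 40.0), (0.4, 50.0))  # (knee, hip) metaphyses
    femur_shaft_top: float = 400.0
    femur_shaft_bottom: float = 10.0
    condyle_radius_medial: float = 21.0
    condyle_radius_lateral: float = 19.0
    condyle_offset_x: float = 24.0
    condyle_centre_z_medial: float = 19.0
    condyle_centre_z_lateral: float = 17.0
    # tibia geometry: triangular-prism-like shaft (3-lobed cross-section)
    tibia_shaft_radii: tuple = (13.0, 12.0)
    tibia_shaft_lobe: float = 0.12
    tibia_end_flare: tuple = ((0.5, 40.0), (0.9, 35.0))  # (ankle, plateau) metaphyses
    tibia_shaft_top: float = -25.0
    tibia_shaft_bottom: float = -380.0
    plateau_semi_axes: tuple = (30.0, 20.0, 10.0)
    plateau_centre_z: float = -20.0
    # discretisation
    n_theta: int = 40
    axial_spacing: float = 3.0
    sphere_subdivisions: int = 3
    # scan / noise model
    side: str = "right"
    noise_sd: float = 0.3
    fiducial_noise_sd: float = 0.2
    flare_band: float = 3.0
    ct_offset_deg: float = 10.0
    ct_offset_mm: float = 20.0
    ct_offset: RigidTransform | None = None  # explicit override
    seed: int = 1

    def __post_init__(self):
        if self.noise_sd < 0 or self.fiducial_noise_sd < 0:
            raise ValueError("noise standard deviations must be non-negative")
        for name in ("condyle_radius_medial", "condyle_radius_lateral",
                     "axial_spacing", "n_theta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if min(*self.femur_shaft_radii, *self.tibia_shaft_radii) <= 0:
            raise ValueError("shaft radii must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


# ---------------------------------------------------------------------------
# primitive meshing
# ---------------------------------------------------------------------------

def _shaft_grid(radii: tuple, z0: float, z1: float, n_theta: int,
                axial_spacing: float, bow_y: float = 0.0, lobe3: float = 0.0,
                end_flare: tuple = ((0.0, 1.0), (0.0, 1.0))) -> TriangleMesh:
    """Open tube with explicit axial rings (trimesh's cylinder has no
    axial subdivisions, which is too coarse for point-to-vertex ICP).

    ``radii`` gives an elliptical cross-section, ``bow_y`` a sagittal
    mid-shaft bow, ``lobe3`` a 3-lobed (triangular-prism-like)
    modulation, and ``end_flare`` = ((amp, length), (amp, length))
    exponential metaphyseal flares at the z0 and z1 ends.  Real long
    bones have all four features, and together they leave the shaft with
    no rigid-motion symmetry — every pose component is observable from
    the surface, as it must be for surface registration to be
    well-posed."""
    rx, ry = radii
    n_rows = max(2, int(np.ceil(abs(z1 - z0) / axial_spacing)) + 1)
    zs = np.linspace(z0, z1, n_rows)
    # aperiodic sampling: golden-ratio phase shift per ring and jittered
    # row heights.  A regular grid would be mapped onto itself by a
    # rotation of one theta step or a shift of one row — spurious exact
    # lattice alignments that no real segmentation mesh has and that
    # point-to-vertex registration would otherwise lock on to.
    golden = 0.381966
    if n_rows > 2:
        zs = zs + 0.35 * axial_spacing * np.sin(2 * np.pi * ((np.arange(n_rows) * golden) % 1.0))
        zs[0], zs[-1] = z0, z1
    base_thetas = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    (a0, l0), (a1, l1) = end_flare
    rows = []
    for r, z in enumerate(zs):
        thetas = base_thetas + 2 * np.pi * ((r * golden) % 1.0)
        scale = 1.0 + lobe3 * np.cos(3 * thetas)
        y_off = bow_y * np.sin(np.pi * (z - z0) / (z1 - z0))
        s = 1.0 + a0 * np.exp(-(z - z0) / l0) + a1 * np.exp(-(z1 - z) / l1)
        rows.append(np.column_stack([s * scale * rx * np.cos(thetas),
                                     s * scale * ry * np.sin(thetas) + y_off,
                                     np.full(n_theta, z)]))
    vertices = np.concatenate(rows)
    faces = []
    for r in range(n_rows - 1):
        base = r * n_theta
        for i in range(n_theta):
            j = (i + 1) % n_theta
            a, b = base + i, base + j
            c, d = a + n_theta, b + n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    return TriangleMesh(vertices, np.asarray(faces, dtype=np.int64))


def _ellipsoid(semi_axes, centre, subdivisions: int) -> TriangleMesh:
    ico = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    v = np.asarray(ico.vertices) * np.asarray(semi_axes, dtype=np.float64) + np.asarray(centre)
    return TriangleMesh(v, np.asarray(ico.faces, dtype=np.int64))


def _concatenate(meshes) -> TriangleMesh:
    verts, faces, offset = [], [], 0
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + offset)
        offset += m.n_vertices
    return TriangleMesh(np.concatenate(verts), np.concatenate(faces))


def _mirror_x(mesh: TriangleMesh) -> TriangleMesh:
    v = mesh.vertices.copy()
    v[:, 0] *= -1.0
    return TriangleMesh(v, mesh.faces[:, ::-1].copy())


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def _mirror_transform(t: RigidTransform) -> RigidTransform:
    return RigidTransform(_MIRROR @ t.rotation @ _MIRROR, _MIRROR @ t.translation)


# ---------------------------------------------------------------------------
# implant definitions (parametric stand-ins; vendor CAD drops into the
# same JSON format)
# ---------------------------------------------------------------------------

def default_implants(side: str = "right") -> dict[str, ImplantDefinition]:
    """Parametric femoral component and tibial tray (with keel) for the
    phantom, in implant-local mm.  Fiducial layouts mimic the point sets
    an engineer would pick on a segmented prosthesis: 8 points over the
    ~60 mm component envelope, including stem/keel points on the tray."""
    femoral = ImplantDefinition(
        name="phantom-femoral", component="femoral",
        fiducials={
            # extreme corners of the component envelope (posterior condyle
            # tips, anterior-flange top corners, distal anterior edges,
            # intercondylar notch): spread maximises pose conditioning
            "f1": (-30.0, -18.0, 2.0), "f2": (30.0, -18.0, 2.0),
            "f3": (-30.0, 12.0, 44.0), "f4": (30.0, 12.0, 44.0),
            "f5": (-30.0, 14.0, 4.0), "f6": (30.0, 14.0, 4.0),
            "f7": (0.0, -20.0, 30.0), "f8": (0.0, -20.0, 8.0),
        },
        axes={"ap": (0.0, 1.0, 0.0), "ml": (1.0, 0.0, 0.0), "si": (0.0, 0.0, 1.0)},
        planes={
            "distal_medial": Plane((-24.0, 0.0, 7.0), (0.0, 0.0, -1.0)),
            "distal_lateral": Plane((24.0, 0.0, 7.5), (0.0, 0.0, -1.0)),
            "posterior_medial": Plane((-24.0, -12.0, 18.0), (0.0, -1.0, 0.0)),
            "posterior_lateral": Plane((24.0, -11.5, 18.0), (0.0, -1.0, 0.0)),
        },
    )
    tibial = ImplantDefinition(
        name="phantom-tibial", component="tibial",
        fiducials={
            "t1": (-26.0, -12.0, -2.0), "t2": (26.0, -12.0, -2.0),
            "t3": (-24.0, 14.0, -2.0), "t4": (24.0, 14.0, -2.0),
            "t5": (0.0, -16.0, -4.0), "t6": (0.0, 16.0, -4.0),
            "t7": (0.0, 4.0, -35.0), "t8": (0.0, -4.0, -48.0),
        },
        axes={"ap": (0.0, 1.0, 0.0), "ml": (1.0, 0.0, 0.0), "si": (0.0, 0.0, 1.0)},
        planes={"plateau": Plane((0.0, 0.0, 0.0), (0.0, 0.0, 1.0))},
    )
    if side == "left":
        femoral, tibial = (_mirror_implant(femoral), _mirror_implant(tibial))
    return {"femoral": femoral, "tibial": tibial}


def _mirror_implant(idef: ImplantDefinition) -> ImplantDefinition:
    def mx(v):
        return (_MIRROR @ np.asarray(v, float))
    return ImplantDefinition(
        idef.name, idef.component,
        {k: mx(v) for k, v in idef.fiducials.items()},
        {k: mx(v) for k, v in idef.axes.items()},
        {k: Plane(mx(p.point), mx(p.normal)) for k, p in idef.planes.items()},
    )


def default_component_poses(side: str = "right") -> dict[str, RigidTransform]:
    """True implant poses (implant-local -> bone frame): clinically
    typical small rotations and offsets, and the tray seated 18 mm below
    the plateau apex."""
    fe2 = RigidTransform.from_axis_angle((1, 0, 0), 2.0)
    ie15 = RigidTransform.from_axis_angle((0, 0, 1), 1.5)
    femoral = RigidTransform(fe2.compose(ie15).rotation, (1.0, -0.5, 0.5))
    slope = RigidTransform.from_axis_angle((1, 0, 0), 3.0)
    ie_t = RigidTransform.from_axis_angle((0, 0, 1), -2.0)
    tibial = RigidTransform(slope.compose(ie_t).rotation, (0.5, 1.0, -18.0))
    if side == "left":
        femoral, tibial = _mirror_transform(femoral), _mirror_transform(tibial)
    return {"femoral": femoral, "tibial": tibial}


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class GroundTruth:
    """Everything the generator knows exactly, in the pre-operative bone
    frame (angles/resections are frame-invariant, so they compare
    directly against pipeline output computed in the CT frame)."""

    landmarks: dict
    frames: dict
    poses: dict  # component -> ComponentPose (implant-local -> bone frame)
    angles: dict  # component -> (fe, vv, ie) deg
    translations: dict  # component -> (ap, ml, si) mm
    resections: dict  # region -> mm
    ct_offset: RigidTransform
    n_vertices: dict  # bone -> declared pre-op vertex count
    implants: dict

    def verify(self, preop_meshes: dict) -> float:
        """Recompute angles/translations/resections from the stored poses
        and frames; return the maximum discrepancy (internal-consistency
        check, should be ~1e-12)."""
        worst = 0.0
        for comp, pose in self.poses.items():
            bone = "femur" if comp == "femoral" else "tibia"
            ang = alignment_angles(pose, self.frames[bone], self.implants[comp])
            tra = placement_translations(pose, self.frames[bone], self.implants[comp])
            worst = max(worst, *np.abs(np.array(ang) - np.array(self.angles[comp])),
                        *np.abs(np.array(tra) - np.array(self.translations[comp])))
            regions = FEMORAL_REGIONS if comp == "femoral" else TIBIAL_REGIONS
            for region in regions:
                pname = region if comp == "femoral" else "plateau"
                plane = self.implants[comp].planes[pname].transformed(pose.transform)
                r = resection_thickness(preop_meshes[bone], self.frames[bone], plane, region)
                worst = max(worst, abs(r - self.resections[region]))
        return float(worst)

    def to_json(self, path=None) -> str:
        doc = {
            "angles": {k: [float(x) for x in v] for k, v in sorted(self.angles.items())},
            "translations": {k: [float(x) for x in v] for k, v in sorted(self.translations.items())},
            "resections": {k: float(v) for k, v in sorted(self.resections.items())},
            "ct_offset": {"rotation": [float(x) for x in self.ct_offset.rotation.ravel()],
                          "translation": [float(x) for x in self.ct_offset.translation]},
            "n_vertices": {k: int(v) for k, v in sorted(self.n_vertices.items())},
            "frames": {k: v.to_dict() for k, v in sorted(self.frames.items())},
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    femur: TriangleMesh
    tibia: TriangleMesh
    landmarks: dict  # bone -> LandmarkSet
    spec: PhantomSpec

    @property
    def meshes(self) -> dict:
        return {"femur": self.femur, "tibia": self.tibia}


def generate_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Build the pre-operative bone surfaces and their landmark sets.

    Deterministic for a given spec (geometry carries no randomness; the
    seed only drives the scan-noise stage)."""
    spec = spec or PhantomSpec()
    shaft = _shaft_grid(spec.femur_shaft_radii, spec.femur_shaft_bottom,
                        spec.femur_shaft_top, spec.n_theta, spec.axial_spacing,
                        bow_y=spec.femur_shaft_bow, end_flare=spec.femur_end_flare)
    ox = spec.condyle_offset_x
    rm, rl = spec.condyle_radius_medial, spec.condyle_radius_lateral
    zm, zl = spec.condyle_centre_z_medial, spec.condyle_centre_z_lateral
    med = _ellipsoid((rm, rm, rm), (-ox, 0.0, zm), spec.sphere_subdivisions)
    lat = _ellipsoid((rl, rl, rl), (ox, 0.0, zl), spec.sphere_subdivisions)
    femur = _concatenate([shaft, med, lat])

    tib_shaft = _shaft_grid(spec.tibia_shaft_radii, spec.tibia_shaft_bottom,
                            spec.tibia_shaft_top, spec.n_theta, spec.axial_spacing,
                            lobe3=spec.tibia_shaft_lobe, end_flare=spec.tibia_end_flare)
    plateau = _ellipsoid(spec.plateau_semi_axes, (0.0, 0.0, spec.plateau_centre_z),
                         spec.sphere_subdivisions)
    tibia = _concatenate([tib_shaft, plateau])

    if min(femur.n_vertices, tibia.n_vertices) < 100:
        raise ValueError("mesh resolution too coarse to place landmarks (<100 vertices)")

    plateau_top = spec.plateau_centre_z + spec.plateau_semi_axes[2]
    lm_femur = LandmarkSet("femur", "right", {
        "hip_centre": (0.0, 0.0, spec.femur_shaft_top),
        "knee_centre": (0.0, 0.0, spec.femur_shaft_bottom),
        "medial_sulcus": (-(ox + rm), 0.0, zm),
        "lateral_epicondyle": (ox + rl, 0.0, zl),
    })
    lm_tibia = LandmarkSet("tibia", "right", {
        "medial_malleolus": (-20.0, 0.0, spec.tibia_shaft_bottom + 2.0),
        "lateral_malleolus": (20.0, 0.0, spec.tibia_shaft_bottom),
        "tubercle_medial_third": (-6.0, 22.0, spec.tibia_shaft_top - 3.0),
        "pcl_insertion": (0.0, -16.0, spec.tibia_shaft_top + 1.0),
        "plateau_centre": (0.0, 0.0, plateau_top - 2.0),
    })

    if spec.side == "left":
        femur, tibia = _mirror_x(femur), _mirror_x(tibia)
        lm_femur = LandmarkSet("femur", "left",
                               {k: _MIRROR @ v for k, v in lm_femur.landmarks.items()})
        lm_tibia = LandmarkSet("tibia", "left",
                               {k: _MIRROR @ v for k, v in lm_tibia.landmarks.items()})
    return Phantom(femur, tibia, {"femur": lm_femur, "tibia": lm_tibia}, spec)


#: implant-local z extent of the femoral component envelope; resection
#: crops and the flare band apply only below it so that the cuts stay in
#: the condylar zone instead of slicing the whole shaft
_FEMORAL_ZONE_Z = 45.0


def _femoral_crop_masks(verts_local: np.ndarray, implant: ImplantDefinition,
                        flare_band: float):
    """(removed-by-resection, flare-band) masks for femoral bone.

    Each distal/posterior plane governs its own medial or lateral half
    (split at implant-local x = 0, lateral = +x on the right)."""
    zone = verts_local[:, 2] < _FEMORAL_ZONE_Z
    x = verts_local[:, 0]
    lateral_positive = implant.axes["ml"][0] >= 0
    removed = np.zeros(len(verts_local), dtype=bool)
    near = np.zeros(len(verts_local), dtype=bool)
    for name, plane in implant.planes.items():
        is_lateral = name.endswith("lateral")
        if lateral_positive:
            half = x >= 0 if is_lateral else x < 0
        else:
            half = x < 0 if is_lateral else x >= 0
        d = signed_plane_distance(plane, verts_local)
        removed |= zone & half & (d > 0)
        near |= zone & half & (np.abs(d) < flare_band)
    return removed, near


def _tibial_crop_masks(verts_local: np.ndarray, implant: ImplantDefinition,
                       flare_band: float):
    plane = implant.planes["plateau"]
    d = signed_plane_distance(plane, verts_local)
    return d > 0, np.abs(d) < flare_band


def _crop_mesh(mesh: TriangleMesh, keep: np.ndarray) -> TriangleMesh:
    index = -np.ones(mesh.n_vertices, dtype=np.int64)
    kept = np.flatnonzero(keep)
    index[kept] = np.arange(len(kept))
    f = mesh.faces
    fkeep = keep[f].all(axis=1)
    return TriangleMesh(mesh.vertices[kept], index[f[fkeep]])


@dataclass
class PostOpScan:
    postop_meshes: dict  # bone -> TriangleMesh in the CT frame, noisy
    fiducial_observations: dict  # component -> {name: point in CT frame}
    ground_truth: GroundTruth


def _resolve_ct_offset(spec: PhantomSpec, rng: np.random.Generator) -> RigidTransform:
    if spec.ct_offset is not None:
        return spec.ct_offset
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return RigidTransform.from_axis_angle(axis, spec.ct_offset_deg,
                                          spec.ct_offset_mm * direction)


def implant_and_scan(phantom: Phantom,
                     implants: dict | None = None,
                     poses: dict | None = None) -> PostOpScan:
    """Emulate implantation plus the post-operative CT scan.

    Crops each pre-operative bone at its posed resection planes, deletes
    the peri-implant flare band, applies the CT-frame offset, and adds
    seeded Gaussian jitter to surface vertices and fiducial observations.
    """
    spec = phantom.spec
    implants = implants or default_implants(spec.side)
    poses = poses or default_component_poses(spec.side)
    rng = np.random.default_rng(spec.seed)
    ct = _resolve_ct_offset(spec, rng)

    frames = {bone: build_frame(lm) for bone, lm in phantom.landmarks.items()}
    gt_angles, gt_translations, gt_resections, gt_poses = {}, {}, {}, {}
    postop, observations = {}, {}
    for comp, implant in implants.items():
        bone = "femur" if implant.component == "femoral" else "tibia"
        pose = ComponentPose(poses[comp], 0.0)
        gt_poses[comp] = pose
        gt_angles[comp] = alignment_angles(pose, frames[bone], implant)
        gt_translations[comp] = placement_translations(pose, frames[bone], implant)
        mesh = phantom.meshes[bone]
        regions = FEMORAL_REGIONS if implant.component == "femoral" else TIBIAL_REGIONS
        for region in regions:
            pname = region if implant.component == "femoral" else "plateau"
            plane_bone = implant.planes[pname].transformed(pose.transform)
            gt_resections[region] = resection_thickness(mesh, frames[bone], plane_bone, region)

        verts_local = pose.transform.inverse().apply(mesh.vertices)
        if implant.component == "femoral":
            removed, near = _femoral_crop_masks(verts_local, implant, spec.flare_band)
        else:
            removed, near = _tibial_crop_masks(verts_local, implant, spec.flare_band)
        if not removed.any():
            raise DegenerateGeometryError(
                f"{comp} resection planes do not intersect the {bone}")
        cropped = _crop_mesh(mesh, ~(removed | near))
        scanned = cropped.transformed(ct)
        noisy = TriangleMesh(
            scanned.vertices + rng.normal(0.0, spec.noise_sd, scanned.vertices.shape),
            scanned.faces)
        postop[bone] = noisy

        pose_ct = ct.compose(pose.transform)
        observations[comp] = {
            name: pose_ct.apply(p) + rng.normal(0.0, spec.fiducial_noise_sd, 3)
            for name, p in sorted(implant.fiducials.items())
        }

    gt = GroundTruth(
        landmarks=phantom.landmarks, frames=frames, poses=gt_poses,
        angles=gt_angles, translations=gt_translations, resections=gt_resections,
        ct_offset=ct,
        n_vertices={"femur": phantom.femur.n_vertices, "tibia": phantom.tibia.n_vertices},
        implants=implants)
    return PostOpScan(postop, observations, gt)


@dataclass
class SimulatedCase:
    """A complete synthetic case: pipeline inputs plus ground truth."""

    inputs: CaseInputs
    ground_truth: GroundTruth
    phantom: Phantom


def simulate_case(spec: PhantomSpec | None = None) -> SimulatedCase:
    """One-call convenience: phantom -> implant -> scan -> CaseInputs."""
    spec = spec or PhantomSpec()
    phantom = generate_phantom(spec)
    implants = default_implants(spec.side)
    scan = implant_and_scan(phantom, implants)
    inputs = CaseInputs(
        preop_meshes=phantom.meshes,
        landmarks=phantom.landmarks,
        postop_meshes=scan.postop_meshes,
        fiducials=scan.fiducial_observations,
        implants=implants,
    )
    return SimulatedCase(inputs, scan.ground_truth, phantom)
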