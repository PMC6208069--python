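"""Geometric primitives shared by the whole toolkit.

All coordinates are millimetres in a right-handed Cartesian frame.  STL
files carry no unit metadata, so meshes read from disk are *taken* to be
in millimetres; this convention is asserted here once and relied on
everywhere else.

The module provides the three primitives every other stage is built on:
triangle surface meshes (bone and implant geometry), proper rigid
transforms (rotation + translation, reflections rejected), and named
anatomical landmark sets.
"""
from __future__ import annotations

import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: tolerance for orthonormality / unit-norm invariant checks
ORTHO_TOL = 1e-9
#: duplicate-vertex merge tolerance on STL read, in mm
MERGE_TOL = 1e-6


class StlParseError(ValueError):
    """Raised when an STL file is structurally malformed."""


class DegenerateGeometryError(ValueError):
    """Raised when an input configuration has no well-defined solution
    (collinear point sets, coincident landmarks, parallel axes, ...)."""


class LandmarkError(ValueError):
    """Raised when a landmark set is missing required names or two sets
    disagree on their name vocabulary."""


# ---------------------------------------------------------------------------
# array coercion helpers
# ---------------------------------------------------------------------------

def as_point(p) -> np.ndarray:
    """Coerce to a finite (3,) float64 point."""
    a = np.asarray(p, dtype=np.float64).reshape(3)
    if not np.all(np.isfinite(a)):
        raise ValueError(f"point has non-finite components: {a}")
    return a


def as_points(pts) -> np.ndarray:
    """Coerce to a finite (N, 3) float64 point array."""
    a = np.asarray(pts, dtype=np.float64)
    if a.ndim == 1:
        a = a.reshape(1, 3)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected an (N, 3) point array, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point array has non-finite entries")
    return a


def unit(v) -> np.ndarray:
    v = as_point(v)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise DegenerateGeometryError("cannot normalise a near-zero vector")
    return v / n


# ---------------------------------------------------------------------------
# rigid transforms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid transform ``p -> R @ p + t``.

    ``rotation`` must be orthonormal with determinant +1; reflections are
    rejected because a mirrored bone or implant is anatomical nonsense.
    """

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        t = as_point(self.translation)
        if not np.all(np.isfinite(R)):
            raise ValueError("rotation has non-finite entries")
        if np.max(np.abs(R.T @ R - np.eye(3))) > ORTHO_TOL:
            raise ValueError("rotation matrix is not orthonormal within 1e-9")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation matrix is a reflection (det < 0)")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    # -- constructors -------------------------------------------------------
    @staticmethod
    def identity() -> "RigidTransform":
        return RigidTransform(np.eye(3), np.zeros(3))

    @staticmethod
    def from_axis_angle(axis, angle_deg: float, translation=(0.0, 0.0, 0.0)) -> "RigidTransform":
        """Right-handed rotation of ``angle_deg`` about ``axis`` plus a translation."""
        from scipy.spatial.transform import Rotation

        ax = unit(axis)
        R = Rotation.from_rotvec(np.deg2rad(angle_deg) * ax).as_matrix()
        return RigidTransform(R, as_point(translation))

    @staticmethod
    def from_matrix(m) -> "RigidTransform":
        m = np.asarray(m, dtype=np.float64).reshape(4, 4)
        return RigidTransform(m[:3, :3], m[:3, 3])

    # -- algebra ------------------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    def apply(self, points) -> np.ndarray:
        """Apply to one point (3,) or a stack (N, 3)."""
        p = np.asarray(points, dtype=np.float64)
        single = p.ndim == 1
        out = as_points(p) @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, inner: "RigidTransform") -> "RigidTransform":
        """Return ``self ∘ inner`` (apply ``inner`` first)."""
        return RigidTransform(self.rotation @ inner.rotation,
                              self.rotation @ inner.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)


def apply_transform(transform: RigidTransform, points) -> np.ndarray:
    """Functional alias for :meth:`RigidTransform.apply`."""
    return transform.apply(points)


def compose(t_outer: RigidTransform, t_inner: RigidTransform) -> RigidTransform:
    return t_outer.compose(t_inner)


def invert(t: RigidTransform) -> RigidTransform:
    return t.inverse()


def random_transform(rng: np.random.Generator,
                     max_angle_deg: float = 180.0,
                     max_translation_mm: float = 100.0) -> RigidTransform:
    """A seeded random rigid transform (uniform axis, uniform magnitudes)."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = rng.uniform(-max_angle_deg, max_angle_deg)
    t = rng.uniform(-max_translation_mm, max_translation_mm, size=3)
    return RigidTransform.from_axis_angle(axis, angle, t)


# ---------------------------------------------------------------------------
# planes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Plane:
    """An oriented plane through ``point`` with unit ``normal``."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", as_point(self.point))
        object.__setattr__(self, "normal", unit(self.normal))

    def transformed(self, t: RigidTransform) -> "Plane":
        return Plane(t.apply(self.point), t.rotation @ self.normal)


def signed_plane_distance(plane: Plane, point) -> float | np.ndarray:
    """``normal · (point − plane.point)``; positive on the normal side.

    Accepts a single point or an (N, 3) stack.
    """
    p = np.asarray(point, dtype=np.float64)
    if p.ndim == 1:
        return float(np.dot(plane.normal, as_point(p) - plane.point))
    return (as_points(p) - plane.point) @ plane.normal


# ---------------------------------------------------------------------------
# triangle meshes + STL I/O
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """An indexed triangle surface in millimetres."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = as_points(self.vertices) if len(self.vertices) else np.zeros((0, 3))
        f = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(f):
            if f.min() < 0 or f.max() >= len(v):
                raise ValueError("face index out of range")
            if np.any((f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])):
                raise ValueError("face repeats a vertex index")
        self.vertices = v
        self.faces = f

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def transformed(self, t: RigidTransform) -> "TriangleMesh":
        return TriangleMesh(t.apply(self.vertices), self.faces.copy())

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    @staticmethod
    def from_trimesh(tm: trimesh.Trimesh) -> "TriangleMesh":
        return TriangleMesh(np.asarray(tm.vertices, dtype=np.float64),
                            np.asarray(tm.faces, dtype=np.int64))


def _merge_duplicate_vertices(vertices: np.ndarray, faces: np.ndarray,
                              tol: float = MERGE_TOL):
    """Weld vertices closer than ``tol`` (grid snap).  STL stores each facet
    independently, so welding is required before any mesh-level query."""
    if len(vertices) == 0:
        return vertices, faces
    key = np.round(vertices / tol).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    merged = vertices[first]
    remapped = inverse[faces] if len(faces) else faces
    return merged, remapped


def _drop_degenerate_faces(vertices: np.ndarray, faces: np.ndarray):
    if len(faces) == 0:
        return faces
    repeated = (faces[:, 0] == faces[:, 1]) | (faces[:, 1] == faces[:, 2]) | (faces[:, 0] == faces[:, 2])
    a = vertices[faces[:, 1]] - vertices[faces[:, 0]]
    b = vertices[faces[:, 2]] - vertices[faces[:, 0]]
    area2 = np.linalg.norm(np.cross(a, b), axis=1)
    bad = repeated | (area2 < 1e-12)
    if bad.any():
        log.warning("dropping %d degenerate (zero-area) faces on STL read", int(bad.sum()))
    return faces[~bad]


def _validate_binary_stl(path: Path) -> None:
    size = path.stat().st_size
    if size < 84:
        raise StlParseError(
            f"{path}: binary STL truncated at byte {size}; "
            "expected 80-byte header + uint32 facet count (84 bytes minimum)")
    with open(path, "rb") as fh:
        fh.seek(80)
        (n_facets,) = struct.unpack("<I", fh.read(4))
    expected = 84 + 50 * n_facets
    if size != expected:
        raise StlParseError(
            f"{path}: facet count {n_facets} at byte offset 80 implies "
            f"{expected} bytes, file has {size}")


def _looks_ascii(path: Path) -> bool:
    with open(path, "rb") as fh:
        head = fh.read(512)
    if not head.lstrip().startswith(b"solid"):
        return False
    # binary files may legally start with 'solid'; require a facet keyword
    return b"facet" in head or path.stat().st_size == len(head.lstrip())


def read_stl(path) -> TriangleMesh:
    """Read a binary or ASCII STL file (millimetres assumed).

    Duplicate vertices within 1e-6 mm are merged and zero-area faces
    dropped with a warning; malformed binary layouts raise
    :class:`StlParseError` naming the offending byte offset.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    if not _looks_ascii(path):
        _validate_binary_stl(path)
    try:
        tm = trimesh.load(str(path), file_type="stl", process=False)
    except Exception as exc:  # noqa: BLE001 - normalise parser failures
        raise StlParseError(f"{path}: unparseable STL ({exc})") from exc
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    faces = np.asarray(tm.faces, dtype=np.int64)
    vertices, faces = _merge_duplicate_vertices(vertices, faces)
    faces = _drop_degenerate_faces(vertices, faces)
    return TriangleMesh(vertices, faces)


def write_stl(mesh: TriangleMesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL.  ``dialect`` is ``binary`` (80-byte header,
    uint32 facet count, 50-byte records) or ``ascii``."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    if mesh.n_faces == 0:
        raise ValueError("refusing to write an STL with zero facets")
    tm = mesh.to_trimesh()
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(tm, file_obj=None, file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(data)


# ---------------------------------------------------------------------------
# landmark sets
# ---------------------------------------------------------------------------

#: controlled vocabulary of required landmark names per bone
REQUIRED_LANDMARKS = {
    "femur": ("hip_centre", "knee_centre", "medial_sulcus", "lateral_epicondyle"),
    "tibia": ("medial_malleolus", "lateral_malleolus", "tubercle_medial_third",
              "pcl_insertion", "plateau_centre"),
}


@dataclass
class LandmarkSet:
    """Named anatomical points for one bone, tagged with bone and side."""

    bone: str
    side: str
    landmarks: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bone not in REQUIRED_LANDMARKS:
            raise ValueError(f"bone must be 'femur' or 'tibia', got {self.bone!r}")
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        self.landmarks = {str(k): as_point(v) for k, v in self.landmarks.items()}
        missing = [n for n in REQUIRED_LANDMARKS[self.bone] if n not in self.landmarks]
        if missing:
            raise LandmarkError(f"{self.bone} landmark set missing required names: {missing}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.landmarks[name]

    @property
    def names(self):
        return sorted(self.landmarks)

    def transformed(self, t: RigidTransform) -> "LandmarkSet":
        return LandmarkSet(self.bone, self.side,
                           {k: t.apply(v) for k, v in self.landmarks.items()})

    # -- JSON interchange: {bone, side, landmarks: {name: [x, y, z]}} -------
    def to_json(self, path=None) -> str:
        doc = {"bone": self.bone, "side": self.side,
               "landmarks": {k: [float(c) for c in v] for k, v in sorted(self.landmarks.items())}}
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_json(source) -> "LandmarkSet":
        p = Path(source) if not str(source).lstrip().startswith("{") else None
        text = p.read_text() if p else str(source)
        doc = json.loads(text)
        return LandmarkSet(doc["bone"], doc["side"], doc["landmarks"])
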