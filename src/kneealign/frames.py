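"""Patient-specific anatomic coordinate frames from bony landmarks.

Femur: the mechanical (superior-inferior) axis runs from the knee centre
to the hip centre; the transepicondylar axis (medial sulcus to lateral
epicondyle) fixes the medio-lateral direction after orthogonalisation.

Tibia: the mechanical axis runs from the inter-malleolar midpoint to the
midpoint of the medial-third-of-tubercle and PCL-insertion landmarks;
the PCL-insertion-to-tubercle line fixes the antero-posterior direction.

The primary (SI) axis is kept exact and the secondary axis is projected
orthogonal to it (fixed Gram-Schmidt order); the third axis is a cross
product.  Axes are always anatomically signed — ml points medial->lateral,
ap posterior->anterior, si inferior->superior — so the handedness of the
(ml, ap, si) triple is +1 for right knees and -1 for left knees (a left
frame is the mirror image of a right frame).  All angle conventions
downstream are written in terms of these signed components, which makes
them mirror-consistent without per-side special cases.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DegenerateGeometryError, LandmarkSet, as_point, unit

#: cross-product norm below which two defining directions are treated as parallel
PARALLEL_TOL = 1e-6


def midpoint(a, b) -> np.ndarray:
    """Component-wise mean of two points."""
    return (as_point(a) + as_point(b)) / 2.0


@dataclass(frozen=True)
class AnatomicFrame:
    """Orthonormal anatomic axes + origin for one bone."""

    origin: np.ndarray
    ap_axis: np.ndarray
    ml_axis: np.ndarray
    si_axis: np.ndarray
    bone: str
    side: str

    def __post_init__(self):
        object.__setattr__(self, "origin", as_point(self.origin))
        for name in ("ap_axis", "ml_axis", "si_axis"):
            v = as_point(getattr(self, name))
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError(f"{name} is not unit length")
            object.__setattr__(self, name, v)
        g = np.array([
            [self.ap_axis @ self.ml_axis],
            [self.ap_axis @ self.si_axis],
            [self.ml_axis @ self.si_axis],
        ])
        if np.max(np.abs(g)) > 1e-9:
            raise ValueError("anatomic axes are not mutually orthogonal within 1e-9")

    @property
    def handedness(self) -> float:
        """det[ml, ap, si]: +1 for right knees, -1 for left (mirror) frames."""
        return float(np.linalg.det(np.column_stack([self.ml_axis, self.ap_axis, self.si_axis])))

    def coords(self, points) -> np.ndarray:
        """Express world points as (ap, ml, si) components about the origin."""
        p = np.atleast_2d(np.asarray(points, dtype=np.float64)) - self.origin
        out = np.column_stack([p @ self.ap_axis, p @ self.ml_axis, p @ self.si_axis])
        return out[0] if np.asarray(points).ndim == 1 else out

    def to_dict(self) -> dict:
        return {
            "bone": self.bone, "side": self.side,
            "origin": [float(x) for x in self.origin],
            "ap_axis": [float(x) for x in self.ap_axis],
            "ml_axis": [float(x) for x in self.ml_axis],
            "si_axis": [float(x) for x in self.si_axis],
        }


def _orthogonalised(secondary, primary) -> np.ndarray:
    """Component of ``secondary`` orthogonal to the unit ``primary`` axis."""
    s = as_point(secondary)
    if np.linalg.norm(np.cross(s, primary)) < PARALLEL_TOL * max(np.linalg.norm(s), 1.0):
        raise DegenerateGeometryError(
            "secondary axis is parallel to the mechanical axis; frame undefined")
    return unit(s - (s @ primary) * primary)


def build_femoral_frame(landmarks: LandmarkSet) -> AnatomicFrame:
    """Femoral frame: SI = knee->hip (exact), ML = orthogonalised
    transepicondylar axis (medial sulcus -> lateral epicondyle, hence
    already lateral-pointing), AP = SI x ML flipped on the left so it
    points anteriorly.  Origin: knee centre."""
    if landmarks.bone != "femur":
        raise ValueError(f"expected femur landmarks, got {landmarks.bone}")
    si = unit(landmarks["hip_centre"] - landmarks["knee_centre"])
    tea = landmarks["lateral_epicondyle"] - landmarks["medial_sulcus"]
    ml = _orthogonalised(tea, si)
    ap = np.cross(si, ml)
    if landmarks.side == "left":
        ap = -ap
    return AnatomicFrame(landmarks["knee_centre"], ap, ml, si,
                         bone="femur", side=landmarks.side)


def build_tibial_frame(landmarks: LandmarkSet) -> AnatomicFrame:
    """Tibial frame: SI = malleolar midpoint -> midpoint(tubercle medial
    third, PCL insertion) (exact), AP = orthogonalised PCL->tubercle line
    (tubercle is anterior), ML = AP x SI flipped on the left so it points
    laterally.  Origin: plateau centre."""
    if landmarks.bone != "tibia":
        raise ValueError(f"expected tibia landmarks, got {landmarks.bone}")
    proximal = midpoint(landmarks["tubercle_medial_third"], landmarks["pcl_insertion"])
    distal = midpoint(landmarks["medial_malleolus"], landmarks["lateral_malleolus"])
    si = unit(proximal - distal)
    ap_raw = landmarks["tubercle_medial_third"] - landmarks["pcl_insertion"]
    if np.linalg.norm(ap_raw) < PARALLEL_TOL:
        raise DegenerateGeometryError("tubercle and PCL landmarks coincide; AP axis undefined")
    ap = _orthogonalised(ap_raw, si)
    ml = np.cross(ap, si)
    if landmarks.side == "left":
        ml = -ml
    return AnatomicFrame(landmarks["plateau_centre"], ap, ml, si,
                         bone="tibia", side=landmarks.side)


def build_frame(landmarks: LandmarkSet) -> AnatomicFrame:
    """Dispatch on the landmark set's bone tag."""
    if landmarks.bone == "femur":
        return build_femoral_frame(landmarks)
    return build_tibial_frame(landmarks)
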