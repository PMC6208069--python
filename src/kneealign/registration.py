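"""Rigid registration: paired-point (Kabsch) and trimmed ICP.

Kabsch solves the closed-form least-squares rigid superposition of two
point sets in known correspondence (SVD with reflection guard); trimmed
ICP alternates k-d-tree nearest-neighbour correspondence with a Kabsch
update, discarding the worst ``trim_fraction`` of pairs and any pair
beyond ``max_correspondence_distance`` so that partial overlap — e.g. a
post-operative bone surface with the peri-implant flare region removed —
does not bias the fit.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .geometry import (
    DegenerateGeometryError,
    LandmarkError,
    RigidTransform,
    TriangleMesh,
    as_points,
)


class NoOverlapError(RuntimeError):
    """Raised when an ICP iteration rejects every correspondence."""


@dataclass(frozen=True)
class RegistrationResult:
    """Outcome of a rigid registration.

    ``rms_history`` holds the accepted-iteration rms sequence for ICP
    (starting at the rms under the initial transform); it is empty for
    closed-form fits.
    """

    transform: RigidTransform
    rms_residual: float
    n_iterations: int
    converged: bool
    rms_history: tuple = ()

    def __post_init__(self):
        if self.rms_residual < 0 or self.n_iterations < 0:
            raise ValueError("rms_residual and n_iterations must be non-negative")


@dataclass(frozen=True)
class IcpParams:
    """Tuning knobs for trimmed ICP.

    Defaults (100 iterations, 1e-6 mm rms tolerance, 10% trim, 10 mm
    correspondence gate) are chosen for flare-cropped partial-overlap
    knee surfaces; ``subsample``/``seed`` optionally draw a deterministic
    random subset of the moving points (default: use all points).
    """

    max_iterations: int = 100
    tolerance: float = 1e-6
    trim_fraction: float = 0.1
    max_correspondence_distance: float = 10.0
    subsample: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ValueError("trim_fraction must be in [0, 0.5)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


def kabsch(src_points, dst_points) -> RegistrationResult:
    """Least-squares rigid transform mapping ``src`` onto ``dst``.

    Minimises ``Σ |R·s + t − d|²`` over proper rotations via SVD of the
    cross-covariance; if the SVD yields a reflection the sign of the last
    singular vector is flipped (standard Kabsch correction).

    Raises
    ------
    DegenerateGeometryError
        Fewer than 3 pairs, mismatched counts, or a collinear source
        configuration (rotation about the line would be unconstrained).
    """
    src = as_points(src_points)
    dst = as_points(dst_points)
    if len(src) != len(dst):
        raise DegenerateGeometryError(
            f"point counts differ: {len(src)} vs {len(dst)}")
    if len(src) < 3:
        raise DegenerateGeometryError("need at least 3 point pairs")
    sc = src.mean(axis=0)
    dc = dst.mean(axis=0)
    s0 = src - sc
    d0 = dst - dc
    # collinearity: centred source must span a plane
    sing = np.linalg.svd(s0, compute_uv=False)
    if sing[1] < 1e-9 * max(sing[0], 1.0):
        raise DegenerateGeometryError("source points are collinear")
    H = s0.T @ d0
    U, _, Vt = np.linalg.svd(H)
    D = np.eye(3)
    if np.linalg.det(Vt.T @ U.T) < 0:
        D[2, 2] = -1.0
    R = Vt.T @ D @ U.T
    # re-orthonormalise to keep the RigidTransform invariant airtight
    Ru, _, Rvt = np.linalg.svd(R)
    R = Ru @ Rvt
    t = dc - R @ sc
    transform = RigidTransform(R, t)
    resid = transform.apply(src) - dst
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return RegistrationResult(transform, rms, 0, True)


def _trimmed_fit(src, dst, tree, transform, params):
    """One correspondence + trim pass; returns kept indices and matches."""
    moved = transform.apply(src)
    dist, idx = tree.query(moved, k=1)
    keep = np.flatnonzero(dist <= params.max_correspondence_distance)
    if len(keep) == 0:
        raise NoOverlapError(
            "all correspondences exceed max_correspondence_distance "
            f"({params.max_correspondence_distance} mm)")
    if params.trim_fraction > 0 and len(keep) > 3:
        n_keep = max(3, int(np.ceil(len(keep) * (1.0 - params.trim_fraction))))
        order = np.argsort(dist[keep], kind="stable")  # stable: ties by lowest index
        keep = keep[order[:n_keep]]
    return keep, idx[keep], dist[keep]


def icp(src, dst_points, init_transform: RigidTransform | None = None,
        params: IcpParams | None = None) -> RegistrationResult:
    """Trimmed iterative closest point.

    Parameters
    ----------
    src : TriangleMesh or (N, 3) array
        Moving geometry (vertices are used).
    dst_points : (M, 3) array or TriangleMesh
        Fixed point set, indexed once in a k-d tree.
    init_transform : RigidTransform, optional
        Initial guess; identity if omitted.  ICP is local — the caller is
        responsible for a sane initialisation (cf. the coarse stage used
        by :func:`kneealign.position.analyze_case`).
    params : IcpParams, optional

    The accepted-iteration rms sequence is non-increasing: a step that
    would raise the trimmed rms is rejected and iteration stops.
    """
    params = params or IcpParams()
    src_pts = src.vertices if isinstance(src, TriangleMesh) else as_points(src)
    dst = dst_points.vertices if isinstance(dst_points, TriangleMesh) else as_points(dst_points)
    if len(dst) == 0:
        raise ValueError("destination point set is empty")
    if params.subsample is not None and params.subsample < len(src_pts):
        rng = np.random.default_rng(params.seed)
        sel = np.sort(rng.choice(len(src_pts), size=params.subsample, replace=False))
        src_pts = src_pts[sel]
    transform = init_transform or RigidTransform.identity()
    tree = cKDTree(dst)

    keep, match, dist = _trimmed_fit(src_pts, dst, tree, transform, params)
    rms = float(np.sqrt(np.mean(dist**2)))
    history = [rms]
    converged = False
    n_iter = 0
    for n_iter in range(1, params.max_iterations + 1):
        try:
            step = kabsch(src_pts[keep], dst[match])
        except DegenerateGeometryError as exc:
            raise NoOverlapError(f"correspondence set degenerate: {exc}") from exc
        candidate = step.transform
        keep_new, match_new, dist_new = _trimmed_fit(src_pts, dst, tree, candidate, params)
        rms_new = float(np.sqrt(np.mean(dist_new**2)))
        if rms_new > rms + params.tolerance:
            converged = True  # monotonicity guard: reject the step, stop
            break
        improved = rms - rms_new
        transform, keep, match, rms = candidate, keep_new, match_new, rms_new
        history.append(rms)
        if improved < params.tolerance:
            converged = True
            break
    return RegistrationResult(transform, rms, n_iter, converged, tuple(history))


def landmark_qc(landmarks_a, landmarks_b, threshold_mm: float = 4.0) -> list[str]:
    """Names of landmarks whose two placements differ by more than
    ``threshold_mm`` (default 4 mm) — the review trigger used when two
    observers landmark the same bone independently."""
    a = landmarks_a.landmarks if hasattr(landmarks_a, "landmarks") else dict(landmarks_a)
    b = landmarks_b.landmarks if hasattr(landmarks_b, "landmarks") else dict(landmarks_b)
    if set(a) != set(b):
        diff = sorted(set(a) ^ set(b))
        raise LandmarkError(f"landmark name sets differ; symmetric difference: {diff}")
    flagged = []
    for name in sorted(a):
        d = float(np.linalg.norm(np.asarray(a[name], float) - np.asarray(b[name], float)))
        if d > threshold_mm:
            flagged.append(name)
    return flagged
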