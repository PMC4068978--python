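"""Rigid registration of dental-cast point clouds.

The measurement pipeline rests on three primitives: the closed-form optimal
rigid fit between paired point sets (Kabsch/SVD superposition), k-d-tree
nearest-neighbour correspondence, and trimmed iterative closest point (ICP)
for clouds without known correspondences.  Everything is point-to-point;
casts are metrically true so no scale is estimated, and reflections are
explicitly excluded (a tooth cannot mirror itself).

Units are millimetres throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError, DegeneracyError

__all__ = [
    "RigidTransform",
    "ICPParams",
    "kabsch",
    "nearest_neighbors",
    "icp",
    "merge_views",
    "compose",
    "invert",
]

_ORTHO_TOL = 1e-9


def _as_points(x, name: str = "points") -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ConfigurationError(f"{name} must be an (N, 3) array, got shape {a.shape}")
    if not np.isfinite(a).all():
        raise ConfigurationError(f"{name} contains non-finite coordinates")
    return a


@dataclass(frozen=True)
class RigidTransform:
    """A proper rigid motion x ↦ R x + t (rotation in SO(3), translation in mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        err = np.abs(R.T @ R - np.eye(3)).max()
        if err >= _ORTHO_TOL:
            raise ConfigurationError(
                f"rotation is not orthonormal (|R'R - I|_inf = {err:.3g})"
            )
        det = np.linalg.det(R)
        if abs(det - 1.0) >= _ORTHO_TOL:
            raise ConfigurationError(
                f"rotation must be proper (det = +1), got det = {det:.12g}"
            )
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix) -> "RigidTransform":
        """Build from a 4x4 row-major homogeneous matrix."""
        M = np.asarray(matrix, dtype=float)
        if M.shape != (4, 4):
            raise ConfigurationError(f"expected a 4x4 matrix, got shape {M.shape}")
        if not np.allclose(M[3], [0.0, 0.0, 0.0, 1.0], atol=1e-9):
            raise ConfigurationError("last row of a homogeneous matrix must be (0,0,0,1)")
        return cls(M[:3, :3], M[:3, 3])

    @property
    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix (row-major)."""
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points) -> np.ndarray:
        """Apply the motion to an (N, 3) array (or a single 3-vector)."""
        p = np.asarray(points, dtype=float)
        return p @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ICPParams:
    """Trimmed-ICP controls.

    trim_fraction is the fraction of worst-distance correspondences discarded
    at each iteration — robustness against partial overlap (gingiva, cast-base
    differences).  Iteration stops when the relative change of the trimmed RMS
    falls below rel_rms_tol or after max_iterations.
    """

    max_iterations: int = 100
    rel_rms_tol: float = 1e-8
    trim_fraction: float = 0.1
    min_points: int = 10

    def __post_init__(self):
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if not (0.0 <= self.trim_fraction < 0.5):
            raise ConfigurationError("trim_fraction must lie in [0, 0.5)")
        if self.rel_rms_tol <= 0:
            raise ConfigurationError("rel_rms_tol must be positive")
        if self.min_points < 3:
            raise ConfigurationError("min_points must be >= 3")


def kabsch(source, target) -> RigidTransform:
    """Least-squares rigid superposition of row-paired point sets.

    Returns the proper rigid motion minimising the mean squared distance of
    the transformed source to the target.  A reflection in the SVD solution is
    corrected by flipping the sign of the smallest singular direction.

    Raises DegeneracyError for fewer than 3 points or (near-)collinear input,
    where the rotation is not determined.
    """
    P = _as_points(source, "source")
    Q = _as_points(target, "target")
    if P.shape != Q.shape:
        raise ConfigurationError(
            f"source and target must be row-paired, got {P.shape} vs {Q.shape}"
        )
    if len(P) < 3:
        raise DegeneracyError(f"need >= 3 paired points, got {len(P)}")
    p_bar = P.mean(axis=0)
    q_bar = Q.mean(axis=0)
    H = (P - p_bar).T @ (Q - q_bar)
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 <=> collinear source or target: rotation about the line is free
    scale = max(S[0], np.linalg.norm(P - p_bar, axis=1).max(), 1.0)
    if S[1] <= 1e-12 * scale:
        raise DegeneracyError("cross-covariance is rank-deficient (collinear points)")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, q_bar - R @ p_bar)


def nearest_neighbors(reference, queries) -> tuple[np.ndarray, np.ndarray]:
    """Closest reference point for each query (Euclidean; ties -> lowest index).

    Returns (indices, distances).  Built on a k-d tree; exact-distance ties are
    resolved to the lowest reference index for reproducibility.
    """
    ref = _as_points(reference, "reference")
    if len(ref) == 0:
        raise DegeneracyError("reference cloud is empty")
    q = _as_points(queries, "queries")
    tree = cKDTree(ref)
    dist, idx = tree.query(q, k=1)
    # enforce the lowest-index tie rule: re-examine every query whose nearest
    # distance is attained by more than one reference point
    if len(ref) > 1:
        ball = tree.query_ball_point(q, dist * (1.0 + 1e-12) + 1e-300)
        for j, cands in enumerate(ball):
            if len(cands) > 1:
                d2 = np.linalg.norm(ref[cands] - q[j], axis=1)
                best = d2.min()
                idx[j] = min(c for c, dd in zip(cands, d2) if dd <= best * (1 + 1e-12))
                dist[j] = np.linalg.norm(ref[idx[j]] - q[j])
    return np.asarray(idx, dtype=int), np.asarray(dist, dtype=float)


def icp(
    source,
    target,
    init: RigidTransform | None = None,
    params: ICPParams | None = None,
    rms_history: list | None = None,
) -> tuple[RigidTransform, float, int]:
    """Trimmed point-to-point ICP aligning source onto target.

    Each iteration finds nearest-neighbour correspondences, discards the
    trim_fraction worst pairs, and re-solves the rigid fit on the survivors
    with kabsch().  Returns (transform, trimmed RMS in mm on the kept pairs,
    number of iterations).  The trimmed RMS is non-increasing; pass a list as
    rms_history to record it per iteration.
    """
    P = _as_points(source, "source")
    Q = _as_points(target, "target")
    params = params or ICPParams()
    if len(P) < params.min_points or len(Q) < params.min_points:
        raise DegeneracyError(
            f"both clouds need >= {params.min_points} points, got {len(P)}/{len(Q)}"
        )
    current = init if init is not None else RigidTransform.identity()
    n_keep = max(params.min_points, int(np.ceil((1.0 - params.trim_fraction) * len(P))))
    n_keep = min(n_keep, len(P))
    tree = cKDTree(Q)
    rms_prev = np.inf
    rms = np.inf
    n_iter = 0
    for n_iter in range(1, params.max_iterations + 1):
        moved = current.apply(P)
        dist, idx = tree.query(moved, k=1)
        keep = np.argsort(dist, kind="stable")[:n_keep]
        current = kabsch(P[keep], Q[idx[keep]])
        resid = current.apply(P[keep]) - Q[idx[keep]]
        rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
        if rms_history is not None:
            rms_history.append(rms)
        if rms < 1e-12:  # far below any physical residual: converged
            break
        if np.isfinite(rms_prev):
            if abs(rms_prev - rms) <= params.rel_rms_tol * rms_prev:
                break
        rms_prev = rms
    return current, rms, n_iter


def merge_views(views, view_transforms, refine: bool = False,
                params: ICPParams | None = None) -> np.ndarray:
    """Map each view by its transform and concatenate into one cloud.

    Emulates multi-angle scanning of a single cast: every view is expressed in
    the common frame via its (calibrated) transform; with refine=True each
    subsequent view is additionally ICP-polished against the union of the
    views merged so far.
    """
    if len(views) != len(view_transforms):
        raise ConfigurationError(
            f"got {len(views)} views but {len(view_transforms)} transforms"
        )
    if len(views) == 0:
        raise ConfigurationError("need at least one view")
    merged = _as_points(views[0], "view[0]")
    merged = view_transforms[0].apply(merged)
    for i, (view, T) in enumerate(zip(views[1:], view_transforms[1:]), start=1):
        placed = T.apply(_as_points(view, f"view[{i}]"))
        if refine:
            delta, _, _ = icp(placed, merged, params=params)
            placed = delta.apply(placed)
        merged = np.vstack([merged, placed])
    return merged


def compose(a: RigidTransform, b: RigidTransform) -> RigidTransform:
    """The motion applying b first, then a: (a ∘ b)(x) = a(b(x))."""
    return RigidTransform(a.rotation @ b.rotation,
                          a.rotation @ b.translation + a.translation)


def invert(a: RigidTransform) -> RigidTransform:
    """The inverse motion: invert(a) ∘ a = identity."""
    Rt = a.rotation.T
    return RigidTransform(Rt, -Rt @ a.translation)
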