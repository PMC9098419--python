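"""Rigid transforms and point-to-point iterative closest point (ICP).

Surface-distance comparisons between two bone models are only meaningful
site-specifically, so one point cloud is first registered to the other with
a rigid (rotation + translation) transform.  The least-squares core is the
closed-form cross-covariance (Kabsch/Umeyama) solution with reflection
rejection; ICP alternates nearest-neighbour correspondence (KD-tree) with
that closed-form fit, starting from a centroid pre-alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """A proper rigid motion ``p -> R @ p + t`` in mm coordinates."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if self.rotation.shape != (3, 3):
            raise ValueError("rotation must be 3x3")
        if np.linalg.norm(self.rotation.T @ self.rotation - np.eye(3)) > _ORTHO_TOL:
            raise ValueError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > _ORTHO_TOL:
            raise ValueError("rotation matrix must have determinant +1 (no reflections)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_euler_deg(cls, angles_deg: tuple[float, float, float],
                       translation: tuple[float, float, float] = (0.0, 0.0, 0.0)) -> "RigidTransform":
        """Build from intrinsic x-y-z Euler angles in degrees."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", angles_deg, degrees=True).as_matrix()
        return cls(R, np.asarray(translation, dtype=float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Map an ``(N, 3)`` array of points (or a single point)."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def is_identity(self, tol: float = 1e-12) -> bool:
        return (np.allclose(self.rotation, np.eye(3), atol=tol)
                and np.allclose(self.translation, 0.0, atol=tol))


@dataclass
class ICPResult:
    """Outcome of an ICP run: cumulative transform mapping source onto target."""

    transform: RigidTransform
    rms_residual: float
    iterations: int
    converged: bool
    rms_history: list[float] = field(default_factory=list)


def best_rigid_fit(source: np.ndarray, target: np.ndarray,
                   correspondences: np.ndarray | None = None) -> RigidTransform:
    """Least-squares rigid transform mapping corresponding source points onto
    target points (closed form via SVD of the cross-covariance).

    Parameters
    ----------
    source, target : (N, 3) arrays
        Point coordinates in mm.  If ``correspondences`` is given it is an
        ``(M, 2)`` array of (source index, target index) pairs; otherwise
        points correspond row-by-row.

    Raises
    ------
    ValueError
        Fewer than 3 pairs, or degenerate (collinear) configurations.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if correspondences is not None:
        pairs = np.asarray(correspondences, dtype=int)
        src = src[pairs[:, 0]]
        tgt = tgt[pairs[:, 1]]
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 3:
        raise ValueError("source and target must be matched (N, 3) arrays")
    if len(src) < 3:
        raise ValueError("need at least 3 correspondence pairs")
    mu_s = src.mean(axis=0)
    mu_t = tgt.mean(axis=0)
    H = (src - mu_s).T @ (tgt - mu_t)
    U, S, Vt = np.linalg.svd(H)
    # rank < 2 means the pairs are collinear: rotation about that line is free
    if np.sum(S > max(S[0], 1e-300) * 1e-9) < 2:
        raise ValueError("degenerate (collinear) correspondence pairs")
    D = np.eye(3)
    D[2, 2] = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidTransform(R, t)


def icp(source: np.ndarray, target: np.ndarray, max_iterations: int = 100,
        tol_mm: float = 1e-6) -> ICPResult:
    """Point-to-point ICP aligning ``source`` onto ``target``.

    Starts from a centroid pre-alignment, then alternates nearest-neighbour
    correspondence (KD-tree on the target) with :func:`best_rigid_fit` until
    the RMS residual changes by less than ``tol_mm`` or ``max_iterations``
    is reached.  Returns the cumulative rigid transform.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.ndim != 2 or tgt.ndim != 2 or src.shape[1] != 3 or tgt.shape[1] != 3:
        raise ValueError("point clouds must be (N, 3) arrays")
    if len(src) < 3 or len(tgt) < 3:
        raise ValueError("point clouds must contain at least 3 points")
    if not (np.all(np.isfinite(src)) and np.all(np.isfinite(tgt))):
        raise ValueError("point clouds contain non-finite coordinates")
    if tol_mm <= 0:
        raise ValueError("tol_mm must be positive")

    current = RigidTransform(np.eye(3), tgt.mean(axis=0) - src.mean(axis=0))
    tree = cKDTree(tgt)
    moved = current.apply(src)
    prev_rms = np.inf
    history: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        dists, idx = tree.query(moved)
        rms = float(np.sqrt(np.mean(dists**2)))
        history.append(rms)
        if abs(prev_rms - rms) < tol_mm:
            converged = True
            break
        step = best_rigid_fit(moved, tgt[idx])
        current = step.compose(current)
        moved = current.apply(src)
        prev_rms = rms
    dists, _ = tree.query(current.apply(src))
    final_rms = float(np.sqrt(np.mean(dists**2)))
    return ICPResult(transform=current, rms_residual=final_rms,
                     iterations=iteration, converged=converged,
                     rms_history=history)
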