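"""Rigid superimposition: 3-point initialization, global/per-tooth ICP best
fit, and landmark transfer.

The iterative best fit pairs each sampled moving vertex with its nearest
point on the fixed *surface* (closest point on candidate triangles, not
nearest vertex) and solves the orthogonal-Procrustes update in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .errors import (
    DegenerateConfigurationError,
    InvalidInputError,
    InvalidSegmentationError,
)
from .mesh_core import Landmark, ToothLabelMap, TriangleMesh, tooth_vertex_indices

_ORTHO_TOL = 1e-9


@dataclass
class RigidTransform:
    """Proper rigid motion ``x -> R x + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        R = self.rotation
        if R.shape != (3, 3) or self.translation.shape != (3,):
            raise InvalidInputError("rigid transform needs a 3x3 rotation and 3-vector")
        if np.abs(R @ R.T - np.eye(3)).max() > 1e-6 or abs(np.linalg.det(R) - 1) > 1e-6:
            raise InvalidInputError("rotation must be orthonormal with determinant +1")
        # Re-orthonormalize so long compositions stay within tolerance.
        u, _, vt = np.linalg.svd(R)
        self.rotation = u @ vt

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=np.float64)
        return pts @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform equivalent to applying ``other`` first, then self."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def to_json_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
        }

    @classmethod
    def from_json_dict(cls, d) -> "RigidTransform":
        return cls(np.asarray(d["rotation"]), np.asarray(d["translation"]))


@dataclass
class AlignmentResult:
    """Outcome of a best-fit run: transform, iteration count, final RMS (mm)."""

    transform: RigidTransform
    iterations: int
    rms_mm: float
    n_correspondences: int
    rms_history: list = field(default_factory=list)


def kabsch(source: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares proper rigid transform mapping ``source`` onto ``target``."""
    P = np.asarray(source, dtype=np.float64)
    Q = np.asarray(target, dtype=np.float64)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3 or len(P) < 3:
        raise InvalidInputError("kabsch needs two equal (n>=3, 3) point sets")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, qc - R @ pc)


def three_point_align(
    source_points: np.ndarray, target_points: np.ndarray
) -> RigidTransform:
    """Initial alignment from three corresponding anatomical points.

    Least-squares rigid fit (no scaling, no reflection); exact when the two
    triples are congruent.
    """
    src = np.asarray(source_points, dtype=np.float64)
    tgt = np.asarray(target_points, dtype=np.float64)
    if src.shape != (3, 3) or tgt.shape != (3, 3):
        raise InvalidInputError("three_point_align needs two ordered 3-point triples")
    for name, pts in (("source", src), ("target", tgt)):
        area2 = np.linalg.norm(np.cross(pts[1] - pts[0], pts[2] - pts[0]))
        scale = max(np.linalg.norm(pts[1] - pts[0]), np.linalg.norm(pts[2] - pts[0]), 1.0)
        if area2 < 1e-9 * scale**2:
            raise DegenerateConfigurationError(f"{name} points are collinear")
    return kabsch(src, tgt)


# ---------------------------------------------------------------------------
# Closest point on a triangulated surface
# ---------------------------------------------------------------------------


def _closest_point_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each triangle ``tri[i]`` to each ``points[i]`` (paired).

    Vectorized Ericson-style region classification; ``points`` (k, 3),
    ``tri`` (k, 3, 3) -> (k, 3).
    """
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, points - a
    d1 = np.einsum("ij,ij->i", ab, ap)
    d2 = np.einsum("ij,ij->i", ac, ap)
    bp = points - b
    d3 = np.einsum("ij,ij->i", ab, bp)
    d4 = np.einsum("ij,ij->i", ac, bp)
    cp = points - c
    d5 = np.einsum("ij,ij->i", ab, cp)
    d6 = np.einsum("ij,ij->i", ac, cp)

    out = np.empty_like(points)
    done = np.zeros(len(points), dtype=bool)

    m = (d1 <= 0) & (d2 <= 0)  # vertex A
    out[m] = a[m]
    done |= m
    m = ~done & (d3 >= 0) & (d4 <= d3)  # vertex B
    out[m] = b[m]
    done |= m
    m = ~done & (d6 >= 0) & (d5 <= d6)  # vertex C
    out[m] = c[m]
    done |= m

    vc = d1 * d4 - d3 * d2
    m = ~done & (vc <= 0) & (d1 >= 0) & (d3 <= 0)  # edge AB
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d1 / (d1 - d3)
    out[m] = a[m] + t[m, None] * ab[m]
    done |= m

    vb = d5 * d2 - d1 * d6
    m = ~done & (vb <= 0) & (d2 >= 0) & (d6 <= 0)  # edge AC
    with np.errstate(invalid="ignore", divide="ignore"):
        t = d2 / (d2 - d6)
    out[m] = a[m] + t[m, None] * ac[m]
    done |= m

    va = d3 * d6 - d5 * d4
    m = ~done & (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)  # edge BC
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
    out[m] = b[m] + t[m, None] * (c[m] - b[m])
    done |= m

    m = ~done  # interior
    with np.errstate(invalid="ignore", divide="ignore"):
        denom = va + vb + vc
        v = vb / denom
        w = vc / denom
    out[m] = a[m] + v[m, None] * ab[m] + w[m, None] * ac[m]
    return out


class SurfaceIndex:
    """Nearest point on a fixed triangulated surface, via a face-centroid tree.

    ``k`` candidate faces are examined per query; ties are broken toward the
    lowest face index for determinism.
    """

    def __init__(self, mesh: TriangleMesh, k: int = 8):
        self._tri = mesh.triangles()
        self._tree = cKDTree(self._tri.mean(axis=1))
        self._k = min(k, len(self._tri))

    def query(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (closest points (n,3), distances (n,))."""
        pts = np.asarray(points, dtype=np.float64)
        _, idx = self._tree.query(pts, k=self._k)
        idx = np.atleast_2d(idx)
        # Sorted candidate indices make argmin tie-breaks face-index order.
        idx = np.sort(idx, axis=1)
        k = idx.shape[1]
        rep = np.repeat(pts, k, axis=0)
        cand = _closest_point_on_triangles(rep, self._tri[idx.ravel()])
        d2 = ((cand - rep) ** 2).sum(axis=1).reshape(-1, k)
        best = d2.argmin(axis=1)
        rows = np.arange(len(pts))
        closest = cand.reshape(len(pts), k, 3)[rows, best]
        return closest, np.sqrt(d2[rows, best])


def _validate_mesh_pair(moving: TriangleMesh, fixed: TriangleMesh) -> None:
    for name, mesh in (("moving", moving), ("fixed", fixed)):
        if mesh is None or mesh.n_faces == 0:
            raise InvalidInputError(f"{name} mesh is empty")
        if not np.isfinite(mesh.vertices).all():
            raise InvalidInputError(f"{name} mesh has non-finite coordinates")


def _icp(
    moving_points: np.ndarray,
    surface: SurfaceIndex,
    init: RigidTransform,
    max_iterations: int,
    tol: float,
    trim_fraction: float,
) -> AlignmentResult:
    if max_iterations < 1:
        raise InvalidInputError("max_iterations must be >= 1")
    if not 0.0 <= trim_fraction < 1.0:
        raise InvalidInputError("trim_fraction must be in [0, 1)")
    T = init
    history: list[float] = []
    prev = np.inf
    n_kept = len(moving_points)
    for it in range(1, max_iterations + 1):
        q = T.apply(moving_points)
        closest, dist = surface.query(q)
        if trim_fraction > 0.0:
            n_kept = max(3, int(np.ceil(len(dist) * (1.0 - trim_fraction))))
            keep = np.argsort(dist, kind="stable")[:n_kept]
        else:
            keep = slice(None)
        rms = float(np.sqrt(np.mean(dist[keep] ** 2)))
        history.append(rms)
        T = kabsch(moving_points[keep], closest[keep])
        if prev - rms < tol:
            break
        prev = rms
    # Final RMS under the returned transform.
    q = T.apply(moving_points)
    _, dist = surface.query(q)
    if trim_fraction > 0.0:
        dist = np.sort(dist, kind="stable")[:n_kept]
    rms = float(np.sqrt(np.mean(dist**2)))
    history.append(rms)
    return AlignmentResult(
        transform=T,
        iterations=it,
        rms_mm=rms,
        n_correspondences=int(np.size(dist)),
        rms_history=history,
    )


def global_best_fit(
    moving: TriangleMesh,
    fixed: TriangleMesh,
    init: RigidTransform | None = None,
    max_iterations: int = 50,
    tol: float = 1e-7,
    sample_size: int = 5000,
    trim_fraction: float = 0.0,
    seed: int = 0,
    surface: SurfaceIndex | None = None,
) -> AlignmentResult:
    """Iterative closest-point refinement of ``init`` mapping moving onto fixed.

    A uniform random subsample of up to ``sample_size`` moving vertices (fixed
    ``seed``) is drawn once and reused across iterations, which keeps the RMS
    monotone non-increasing.  Hard cap ``max_iterations`` (default 50); early
    stop when the RMS improves by less than ``tol`` mm.
    """
    _validate_mesh_pair(moving, fixed)
    if init is None:
        init = RigidTransform.identity()
    pts = moving.vertices
    if len(pts) > sample_size:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=sample_size, replace=False)]
    if surface is None:
        surface = SurfaceIndex(fixed)
    return _icp(pts, surface, init, max_iterations, tol, trim_fraction)


def tooth_best_fit(
    tooth: int,
    source_mesh: TriangleMesh,
    source_labels: ToothLabelMap,
    target_mesh: TriangleMesh,
    init: RigidTransform,
    max_iterations: int = 50,
    tol: float = 1e-7,
    sample_size: int = 5000,
    trim_fraction: float = 0.0,
    seed: int = 0,
    surface: SurfaceIndex | None = None,
) -> AlignmentResult:
    """Surface best fit of one segmented tooth against the full target mesh.

    Captures the tooth's individual rigid motion between timepoints, starting
    from the global alignment ``init``.
    """
    _validate_mesh_pair(source_mesh, target_mesh)
    idx = tooth_vertex_indices(source_labels, tooth)
    if len(idx) < 10:
        raise InvalidSegmentationError(
            f"tooth {tooth} submesh has {len(idx)} vertices (< 10)"
        )
    pts = source_mesh.vertices[idx]
    if len(pts) > sample_size:
        rng = np.random.default_rng(seed)
        pts = pts[rng.choice(len(pts), size=sample_size, replace=False)]
    if surface is None:
        surface = SurfaceIndex(target_mesh)
    return _icp(pts, surface, init, max_iterations, tol, trim_fraction)


def suspect_fit(result: AlignmentResult, noise_sd_mm: float) -> bool:
    """Heuristic wrong-basin flag: final RMS far above the scan-noise floor."""
    return result.rms_mm > 5.0 * max(noise_sd_mm, 1e-3)


def transfer_landmarks(
    landmarks: list[Landmark], tooth_fit: AlignmentResult, target_frame: str
) -> list[Landmark]:
    """Map a tooth's landmarks through its best-fit transform into the target frame."""
    teeth = {lm.tooth for lm in landmarks}
    if len(teeth) != 1:
        raise InvalidInputError(
            f"landmarks span teeth {sorted(teeth)}; transfer expects exactly one tooth"
        )
    T = tooth_fit.transform
    return [
        Landmark(lm.tooth, lm.role, T.apply(lm.position[None, :])[0], target_frame)
        for lm in landmarks
    ]
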