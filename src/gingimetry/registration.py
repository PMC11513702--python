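"""Rigid superimposition of the post-operative cast onto the pre-operative one.

The alignment mirrors the metrology-software workflow: an automatic initial
alignment over the full arch, followed by refinement restricted to tooth
(non-gingival) surfaces -- the gingiva changed between timepoints, so
including it would bias the transform toward the soft-tissue displacement.

Refinement is point-to-plane ICP with staged correspondence rejection
(1.0 mm shrinking by 0.7 per stage to 0.2 mm).  Transforms are strictly rigid
(no scale): both casts are metric scans.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .mesh_io import Mesh, ToothAnnotation

RIGID_TOL = 1e-9

#: staged correspondence-rejection thresholds (mm)
REJECTION_START = 1.0
REJECTION_SHRINK = 0.7
REJECTION_FLOOR = 0.2

#: default ICP termination
MAX_ITERATIONS = 200
RELATIVE_TOL = 1e-6

#: moving points used per ICP stage (deterministic stride subsample)
MAX_ICP_POINTS = 4000


class AlignmentError(RuntimeError):
    """Coarse alignment impossible (degenerate geometry)."""


class RegistrationError(RuntimeError):
    """ICP refinement failed (too few surviving correspondences)."""


class TransformError(ValueError):
    """Matrix is not a valid rigid transform."""


# ---------------------------------------------------------------------------
# rigid-transform helpers
# ---------------------------------------------------------------------------


def validate_rigid(transform: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    """Check a 4x4 rigid transform (R orthonormal, det +1) and return it."""
    T = np.asarray(transform, dtype=np.float64)
    if T.shape != (4, 4):
        raise TransformError(f"expected 4x4 transform, got shape {T.shape}")
    R = T[:3, :3]
    if not np.allclose(R @ R.T, np.eye(3), atol=tol):
        raise TransformError("rotation block is not orthonormal")
    if np.linalg.det(R) < 0:
        raise TransformError("rotation block has negative determinant (reflection)")
    if not np.allclose(T[3], [0.0, 0.0, 0.0, 1.0], atol=tol):
        raise TransformError("last row must be [0, 0, 0, 1]")
    return T


def orthonormalize(transform: np.ndarray) -> np.ndarray:
    """Project the rotation block onto SO(3) via SVD (applied after updates)."""
    T = np.array(transform, dtype=np.float64)
    U, _, Vt = np.linalg.svd(T[:3, :3])
    R = U @ Vt
    if np.linalg.det(R) < 0:
        U[:, -1] *= -1
        R = U @ Vt
    T[:3, :3] = R
    return T


def make_transform(rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    T = np.eye(4)
    T[:3, :3] = rotation
    T[:3, 3] = translation
    return T


def invert_transform(transform: np.ndarray) -> np.ndarray:
    T = validate_rigid(transform)
    R, t = T[:3, :3], T[:3, 3]
    return make_transform(R.T, -R.T @ t)


def compose(*transforms: np.ndarray) -> np.ndarray:
    """Matrix composition: ``compose(A, B)`` applies B first, then A."""
    out = np.eye(4)
    for T in transforms:
        out = out @ T
    return orthonormalize(out)


def apply_transform(
    obj: Union[Mesh, np.ndarray], transform: np.ndarray
) -> Union[Mesh, np.ndarray]:
    """Apply a rigid transform to a Mesh or an (n, 3) point array (isometry)."""
    T = validate_rigid(transform)
    R, t = T[:3, :3], T[:3, 3]
    if isinstance(obj, Mesh):
        out = obj.copy()
        out.vertices = obj.vertices @ R.T + t
        if out.normals is not None:
            out.normals = obj.normals @ R.T
        return out
    pts = np.asarray(obj, dtype=np.float64)
    single = pts.ndim == 1
    pts = pts.reshape(-1, 3) @ R.T + t
    return pts[0] if single else pts


def rotation_angle_deg(transform_a: np.ndarray, transform_b: np.ndarray) -> float:
    """Angle (degrees) of the relative rotation between two rigid transforms."""
    R = transform_a[:3, :3] @ transform_b[:3, :3].T
    return float(np.degrees(np.abs(Rotation.from_matrix(R).magnitude())))


# ---------------------------------------------------------------------------
# registration result
# ---------------------------------------------------------------------------


@dataclass
class RegistrationResult:
    """Rigid transform mapping post-frame points into the pre-op frame."""

    transform: np.ndarray
    rms_residual: float
    n_correspondences: int
    converged: bool
    iterations: int
    #: point-to-plane RMS per accepted iteration, one list per rejection stage
    rms_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.transform = validate_rigid(self.transform)
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")
        if self.n_correspondences < 3:
            raise RegistrationError(
                f"need >= 3 correspondences, got {self.n_correspondences}"
            )


# ---------------------------------------------------------------------------
# coarse alignment (principal axes + centroid)
# ---------------------------------------------------------------------------


def _principal_frame(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    centroid = vertices.mean(axis=0)
    cov = np.cov((vertices - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if evals[0] <= 0 or evals[-1] / evals[0] < 1e-9:
        raise AlignmentError("degenerate geometry: rank-deficient covariance")
    if np.linalg.det(evecs) < 0:
        evecs[:, -1] *= -1
    return centroid, evecs


def _subsample(points: np.ndarray, n: int) -> np.ndarray:
    if len(points) <= n:
        return points
    step = max(1, len(points) // n)
    return points[::step][:n]


def coarse_align(moving: Mesh, fixed: Mesh) -> np.ndarray:
    """Initial rigid alignment from principal axes and centroids.

    The principal-axis decomposition leaves a 4-fold axis-sign ambiguity
    (sign flips of two axes preserving handedness); each candidate is scored
    by symmetric mean nearest-vertex distance on a subsample and the best one
    returned.
    """
    if moving.n_vertices < 3 or fixed.n_vertices < 3:
        raise AlignmentError("need at least 3 vertices in each mesh")
    c_m, E_m = _principal_frame(moving.vertices)
    c_f, E_f = _principal_frame(fixed.vertices)

    mov_s = _subsample(moving.vertices, 500)
    fix_s = _subsample(fixed.vertices, 500)
    tree_f = cKDTree(fix_s)

    best, best_score = None, np.inf
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])  # det +1
        R = E_f @ S @ E_m.T
        T = make_transform(R, c_f - R @ c_m)
        moved = mov_s @ R.T + T[:3, 3]
        d_fwd = tree_f.query(moved)[0].mean()
        d_bwd = cKDTree(moved).query(fix_s)[0].mean()
        score = 0.5 * (d_fwd + d_bwd)
        if score < best_score:
            best, best_score = T, score
    return orthonormalize(best)


# ---------------------------------------------------------------------------
# point-to-plane ICP refinement
# ---------------------------------------------------------------------------

MaskLike = Union[None, np.ndarray, Callable[[np.ndarray], np.ndarray]]


def _resolve_mask(moving: Mesh, mask: MaskLike) -> np.ndarray:
    if mask is None:
        return np.ones(moving.n_vertices, dtype=bool)
    if callable(mask):
        mask = mask(moving.vertices)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (moving.n_vertices,):
        raise ValueError("mask must be a boolean array over moving vertices")
    return mask


def crown_mask(
    annotations: Sequence[ToothAnnotation],
    radial_window: float = 3.5,
    margin_offset: float = 0.8,
    frame: str = "post",
) -> Callable[[np.ndarray], np.ndarray]:
    """Predicate selecting crown vertices: near a tooth in the plane
    orthogonal to its coronal axis, and coronal of its gingival margin by at
    least ``margin_offset`` mm.  ``frame`` chooses which margin polyline
    defines the tooth position ('post' for masking the moving post-op mesh).
    """

    def predicate(points: np.ndarray) -> np.ndarray:
        sel = np.zeros(len(points), dtype=bool)
        for ann in annotations:
            margin = ann.margin_post if frame == "post" else ann.margin_pre
            axis = ann.coronal_axis
            center = margin.mean(axis=0)
            rel = points - center
            axial = rel @ axis
            radial = np.linalg.norm(rel - np.outer(axial, axis), axis=1)
            margin_top = (margin @ axis).max() - center @ axis
            sel |= (radial <= radial_window) & (axial >= margin_top + margin_offset)
        return sel

    return predicate


def _closest_point_on_triangles(points: np.ndarray, v0, e1, e2) -> np.ndarray:
    """Closest point on each triangle (v0[i] + s*e1[i] + t*e2[i]) to points[i]
    (vectorised barycentric clamping, Ericson's region test)."""
    p = points - v0
    a = np.einsum("ij,ij->i", e1, e1)
    b = np.einsum("ij,ij->i", e1, e2)
    c = np.einsum("ij,ij->i", e2, e2)
    d = np.einsum("ij,ij->i", e1, p)
    e = np.einsum("ij,ij->i", e2, p)
    det = np.maximum(a * c - b * b, 1e-300)
    s = np.clip((c * d - b * e) / det, 0.0, 1.0)
    t = np.clip((a * e - b * d) / det, 0.0, 1.0)
    outside = s + t > 1.0
    if outside.any():
        # project onto the diagonal edge v1-v2
        dd = d[outside] - b[outside]
        ee = e[outside] - c[outside]
        denom = np.maximum(a[outside] - 2 * b[outside] + c[outside], 1e-300)
        ss = np.clip((dd - ee) / denom, 0.0, 1.0)
        s[outside] = ss
        t[outside] = 1.0 - ss
    # clamp to the two axis edges where needed
    s_edge = np.clip(d / np.maximum(a, 1e-300), 0.0, 1.0)
    t_edge = np.clip(e / np.maximum(c, 1e-300), 0.0, 1.0)
    cand_s = np.stack([s, s_edge, np.zeros_like(s)], axis=1)
    cand_t = np.stack([t, np.zeros_like(t), t_edge], axis=1)
    q = v0[:, None, :] + cand_s[..., None] * e1[:, None, :] + cand_t[..., None] * e2[:, None, :]
    d2 = ((q - points[:, None, :]) ** 2).sum(axis=2)
    best = np.argmin(d2, axis=1)
    return q[np.arange(len(points)), best]


class _SurfaceQuery:
    """Nearest point and face normal on a triangle mesh, via a centroid
    KD-tree shortlist followed by exact point-triangle projection."""

    def __init__(self, mesh: Mesh, k_candidates: int = 12):
        tri = mesh.vertices[mesh.faces]
        self.v0 = tri[:, 0]
        self.e1 = tri[:, 1] - tri[:, 0]
        self.e2 = tri[:, 2] - tri[:, 0]
        fn = np.cross(self.e1, self.e2)
        self.face_normals = fn / np.maximum(
            np.linalg.norm(fn, axis=1, keepdims=True), 1e-300
        )
        self.tree = cKDTree(tri.mean(axis=1))
        self.k = min(k_candidates, len(self.v0))

    def query(self, points: np.ndarray):
        _, idx = self.tree.query(points, k=self.k)
        if self.k == 1:
            idx = idx[:, None]
        n_pts = len(points)
        rep = np.repeat(points, self.k, axis=0)
        flat = idx.ravel()
        q = _closest_point_on_triangles(rep, self.v0[flat], self.e1[flat], self.e2[flat])
        d2 = ((q - rep) ** 2).sum(axis=1).reshape(n_pts, self.k)
        best = np.argmin(d2, axis=1)
        rows = np.arange(n_pts)
        face = idx[rows, best]
        closest = q.reshape(n_pts, self.k, 3)[rows, best]
        dist = np.sqrt(d2[rows, best])
        return dist, closest, self.face_normals[face]


def _collinear(points: np.ndarray) -> bool:
    if len(points) < 3:
        return True
    rel = points - points.mean(axis=0)
    s = np.linalg.svd(rel, compute_uv=False)
    return s[1] < 1e-9 * max(s[0], 1.0)


def icp_refine(
    moving: Mesh,
    fixed: Mesh,
    init: np.ndarray,
    mask: MaskLike = None,
    max_iterations: int = MAX_ITERATIONS,
    tol: float = RELATIVE_TOL,
    max_points: int = MAX_ICP_POINTS,
) -> RegistrationResult:
    """Point-to-plane ICP from ``init``, optionally restricted to ``mask``.

    Correspondences are nearest fixed vertices (paired with their area-weighted
    normals) in the early stages, switching to exact nearest points on the
    fixed surface (paired with face normals) in the final stage -- vertex
    shortcuts leave a curvature-dependent bias of order (edge length)^2 that
    the surface stage removes.  Pairs farther than the stage's rejection
    threshold are dropped.
    An update is accepted only if it does not increase the point-to-plane RMS,
    so the residual is non-increasing within each stage.  Terminates a stage
    on relative RMS change < ``tol``; ``max_iterations`` bounds the total.
    """
    init = validate_rigid(init)
    sel = _resolve_mask(moving, mask)
    pts_all = moving.vertices[sel]
    if len(pts_all) < 3 or _collinear(pts_all):
        raise RegistrationError("mask selects < 3 non-collinear moving vertices")
    pts = _subsample(pts_all, max_points)

    fixed_normals = fixed.normals if fixed.normals is not None else fixed.vertex_normals()
    tree = cKDTree(fixed.vertices)
    surface = _SurfaceQuery(fixed)

    thresholds = []
    thr = REJECTION_START
    while thr > REJECTION_FLOOR:
        thresholds.append(thr)
        thr *= REJECTION_SHRINK
    thresholds.append(REJECTION_FLOOR)

    T = init.copy()
    total_iters = 0
    converged = False
    history: list[list[float]] = []
    rms = np.inf
    n_corr = 0

    def _residuals(T_cur: np.ndarray, threshold: float, on_surface: bool):
        moved = pts @ T_cur[:3, :3].T + T_cur[:3, 3]
        if on_surface:
            dist, q_all, n_all = surface.query(moved)
            keep = dist <= threshold
            if keep.sum() < 3:
                raise RegistrationError(
                    f"< 3 correspondences survive rejection at {threshold:.3f} mm"
                )
            p, q, n = moved[keep], q_all[keep], n_all[keep]
        else:
            dist, idx = tree.query(moved)
            keep = dist <= threshold
            if keep.sum() < 3:
                raise RegistrationError(
                    f"< 3 correspondences survive rejection at {threshold:.3f} mm"
                )
            p = moved[keep]
            q = fixed.vertices[idx[keep]]
            n = fixed_normals[idx[keep]]
        r = np.einsum("ij,ij->i", p - q, n)
        return p, n, r, int(keep.sum())

    for threshold in thresholds:
        on_surface = threshold == thresholds[-1]
        stage_hist: list[float] = []
        p, n, r, n_corr = _residuals(T, threshold, on_surface)
        rms = float(np.sqrt(np.mean(r**2)))
        stage_hist.append(rms)
        while total_iters < max_iterations:
            # linearised point-to-plane solve: J = [p x n, n]
            J = np.hstack([np.cross(p, n), n])
            A = J.T @ J
            b = J.T @ r
            try:
                xi = np.linalg.solve(A, -b)
            except np.linalg.LinAlgError:
                break
            dT = make_transform(Rotation.from_rotvec(xi[:3]).as_matrix(), xi[3:])
            T_new = orthonormalize(dT @ T)
            total_iters += 1
            p2, n2, r2, n_corr2 = _residuals(T_new, threshold, on_surface)
            rms_new = float(np.sqrt(np.mean(r2**2)))
            if rms_new > rms + 1e-15:
                break  # reject the update, end this stage
            T, p, n, r, n_corr = T_new, p2, n2, r2, n_corr2
            rel_change = abs(rms - rms_new) / max(rms, 1e-30)
            rms = rms_new
            stage_hist.append(rms)
            if rel_change < tol or rms < 1e-12:
                converged = True
                break
        history.append(stage_hist)

    return RegistrationResult(
        transform=T,
        rms_residual=rms,
        n_correspondences=n_corr,
        converged=converged,
        iterations=total_iters,
        rms_history=history,
    )


def register(
    moving: Mesh,
    fixed: Mesh,
    annotations: Optional[Sequence[ToothAnnotation]] = None,
    use_mask: bool = True,
    **icp_kwargs,
) -> RegistrationResult:
    """Full-arch coarse alignment followed by (crown-masked) ICP refinement."""
    init = coarse_align(moving, fixed)
    mask = crown_mask(annotations) if (use_mask and annotations) else None
    return icp_refine(moving, fixed, init, mask=mask, **icp_kwargs)


# -- transform (de)serialisation: 12 numbers, row-major rotation then translation


def save_transform(transform: np.ndarray, path) -> None:
    T = validate_rigid(transform)
    flat = np.concatenate([T[:3, :3].ravel(), T[:3, 3]])
    np.savetxt(path, flat.reshape(1, -1), fmt="%.17g")


def load_transform(path) -> np.ndarray:
    flat = np.loadtxt(path).ravel()
    if flat.size != 12:
        raise TransformError(f"expected 12 numbers in {path}, got {flat.size}")
    T = make_transform(flat[:9].reshape(3, 3), flat[9:])
    return validate_rigid(orthonormalize(T), tol=1e-9)
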