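"""Per-tooth outcome metrics on superimposed pre-/post-operative casts.

CEJ-dependent metrics (classical, kept for comparability):

* recession depth -- axial distance between the deepest point of the gingival
  margin and the CEJ along the tooth axis; positive when the margin is apical
  to the CEJ, possibly negative post-operatively (margin beyond the CEJ);
* mRC -- per-tooth 100*(pre - post)/pre, averaged over teeth;
* cRC -- percentage of teeth whose post-op margin reaches or passes the CEJ.

CEJ-independent metrics (the workflow's point -- the CEJ is an unreliable
landmark, clinically undetectable in most cases):

* recession reduction -- distance between the deepest pre- and post-operative
  margin points (both in the pre-op frame after registration).  The classical
  two-point distance is unsigned; here the sign of the axial displacement
  component is attached so a worsened recession is representable.  Euclidean
  by default, with an axial-projection variant (``reduction="axial"``);
* gingival thickness gain -- signed buccal surface deviation sampled on the
  mid-tooth sagittal plane at axial offsets of up to +/-3 mm in 1 mm steps
  around the recession apex; the mean of the valid samples.  If any sample is
  invalid (ray misses, impression artifact) the measurement falls back to the
  single apex sample (``apex_only`` mode).

Ray-surface queries use a vectorised Moller-Trumbore intersector with a
per-tooth triangle prefilter; ties are broken deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import zlib
from scipy.spatial import cKDTree

from .mesh_io import Mesh, ToothAnnotation
from .registration import RegistrationResult, apply_transform

#: a deviation ray that misses the opposing surface within this distance (mm)
#: marks the sample invalid
RAY_MAX_DEVIATION = 3.0

#: how far outside the surface thickness probe rays start (mm)
PROBE_DISTANCE = 8.0


class LandmarkError(ValueError):
    """Empty or unusable landmark polyline."""


class MeasurementFailure(RuntimeError):
    """Thickness measurement impossible for a tooth (apex ray misses)."""


class CEJUnavailable(RuntimeError):
    """CEJ-dependent metric requested but no CEJ polyline annotated."""


@dataclass(frozen=True)
class MeasurementConfig:
    """Switches for the deliberately configurable conventions.

    ``reduction``: 'euclidean' (two-point distance with axial sign, default)
    or 'axial' (signed axial projection).  ``include_apex``: whether the
    offset-0 sample belongs to the thickness grid (7 points) or only the
    +/-1..3 mm offsets do (6 points); the apex sample is always measured for
    the fallback mode.
    """

    reduction: str = "euclidean"
    include_apex: bool = True
    max_offset: float = 3.0
    step: float = 1.0

    def offsets(self) -> np.ndarray:
        k = np.arange(-self.max_offset, self.max_offset + self.step / 2, self.step)
        if not self.include_apex:
            k = k[np.abs(k) > 1e-12]
        return k


@dataclass
class ToothMeasurementRecord:
    tooth_id: str
    recession_depth_pre: Optional[float]
    recession_depth_post: Optional[float]
    recession_reduction: float
    mrc_percent: Optional[float]
    complete_coverage: Optional[bool]
    thickness_gain: Optional[float]
    thickness_samples: list  # (offset mm, deviation mm or None)
    measurement_mode: str  # full_profile | apex_only | failed
    rater_id: str = "rater1"
    replicate_index: int = 0
    cej_available: bool = True
    # pass-through metadata for the statistical layer
    jaw: str = ""
    tooth_type: str = ""
    recession_type: str = ""
    artifact_flag: bool = False


# ---------------------------------------------------------------------------
# ray casting
# ---------------------------------------------------------------------------


class TriangleSoup:
    """Vectorised Moller-Trumbore ray intersector over a mesh's triangles."""

    def __init__(self, mesh: Mesh):
        tri = mesh.vertices[mesh.faces]
        self.v0 = tri[:, 0]
        self.e1 = tri[:, 1] - tri[:, 0]
        self.e2 = tri[:, 2] - tri[:, 0]
        self.centroids = tri.mean(axis=1)

    def subset_near(self, point: np.ndarray, radius: float) -> "TriangleSoup":
        keep = np.linalg.norm(self.centroids - point, axis=1) <= radius
        out = object.__new__(TriangleSoup)
        out.v0, out.e1, out.e2 = self.v0[keep], self.e1[keep], self.e2[keep]
        out.centroids = self.centroids[keep]
        return out

    def hits(self, origin: np.ndarray, direction: np.ndarray) -> np.ndarray:
        """Sorted ray parameters t > 1e-9 of all intersections."""
        if len(self.v0) == 0:
            return np.empty(0)
        d = np.asarray(direction, dtype=float)
        h = np.cross(d, self.e2)
        a = np.einsum("ij,ij->i", self.e1, h)
        ok = np.abs(a) > 1e-12
        f = np.zeros_like(a)
        f[ok] = 1.0 / a[ok]
        s = origin - self.v0
        u = f * np.einsum("ij,ij->i", s, h)
        q = np.cross(s, self.e1)
        v = f * (q @ d)
        t = f * np.einsum("ij,ij->i", self.e2, q)
        eps = 1e-9
        hit = ok & (u >= -eps) & (v >= -eps) & (u + v <= 1 + eps) & (t > eps)
        return np.sort(t[hit])


# ---------------------------------------------------------------------------
# landmark metrics
# ---------------------------------------------------------------------------


def deepest_recession_point(margin: np.ndarray, coronal_axis: np.ndarray) -> np.ndarray:
    """Most apical margin point (minimal coordinate along the coronal axis);
    ties broken by lowest point index."""
    margin = np.asarray(margin, dtype=float).reshape(-1, 3)
    if len(margin) == 0:
        raise LandmarkError("empty margin polyline")
    return margin[int(np.argmin(margin @ np.asarray(coronal_axis, dtype=float)))]


def recession_depth(
    margin_point: np.ndarray, cej: Optional[np.ndarray], coronal_axis: np.ndarray
) -> float:
    """Axial distance from the deepest margin point to the CEJ.

    The CEJ partner point is the one nearest in the plane orthogonal to the
    axis (avoids pairing with the contralateral CEJ arm); the returned value
    is its axial coordinate minus the margin point's -- positive when the
    margin sits apical to the CEJ.
    """
    if cej is None or len(cej) == 0:
        raise CEJUnavailable("CEJ-dependent metric unavailable: no CEJ polyline")
    axis = np.asarray(coronal_axis, dtype=float)
    cej = np.asarray(cej, dtype=float).reshape(-1, 3)
    p = np.asarray(margin_point, dtype=float)
    perp = cej - np.outer(cej @ axis, axis)
    p_perp = p - (p @ axis) * axis
    nearest = cej[int(np.argmin(np.linalg.norm(perp - p_perp, axis=1)))]
    return float((nearest - p) @ axis)


def recession_reduction(
    pre_point: np.ndarray,
    post_point: np.ndarray,
    coronal_axis: np.ndarray,
    mode: str = "euclidean",
) -> float:
    """Signed distance between the deepest pre- and post-op margin points.

    Both points must be in the common (pre-op) frame.  Positive means the
    post-op margin moved coronally (recession reduced).  The CEJ is never
    consulted.
    """
    delta = np.asarray(post_point, dtype=float) - np.asarray(pre_point, dtype=float)
    axial = float(delta @ np.asarray(coronal_axis, dtype=float))
    if mode == "axial":
        return axial
    if mode != "euclidean":
        raise ValueError(f"unknown reduction mode {mode!r}")
    dist = float(np.linalg.norm(delta))
    if dist == 0.0:
        return 0.0
    return dist if axial >= 0 else -dist


# ---------------------------------------------------------------------------
# cohort metrics
# ---------------------------------------------------------------------------


@dataclass
class RootCoverageSummary:
    mean: float
    sd: float
    per_tooth: list  # (tooth_id, mrc_percent)
    n_excluded: int


def mean_root_coverage(records: Sequence[ToothMeasurementRecord]) -> RootCoverageSummary:
    """Per-tooth mRC = 100*(pre - post)/pre and its mean +/- SD over teeth.

    Values may exceed 100 (margin beyond the CEJ) or be negative (worsening).
    Records without CEJ-dependent depths or with pre-depth = 0 are excluded
    (count reported).
    """
    per_tooth, n_excl = [], 0
    for r in records:
        if (
            not r.cej_available
            or r.recession_depth_pre is None
            or r.recession_depth_pre <= 0
        ):
            n_excl += 1
            continue
        mrc = 100.0 * (r.recession_depth_pre - r.recession_depth_post) / r.recession_depth_pre
        per_tooth.append((r.tooth_id, mrc))
    if n_excl:
        warnings.warn(f"mean_root_coverage: {n_excl} record(s) excluded", stacklevel=2)
    vals = np.array([m for _, m in per_tooth])
    if len(vals) == 0:
        return RootCoverageSummary(np.nan, np.nan, [], n_excl)
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return RootCoverageSummary(float(vals.mean()), sd, per_tooth, n_excl)


def complete_root_coverage(records: Sequence[ToothMeasurementRecord]) -> float:
    """cRC: 100 x (#teeth with post-op depth <= 0) / (#eligible teeth), to 2
    decimals.  Eligible = CEJ-dependent depths available."""
    eligible = [r for r in records if r.cej_available and r.recession_depth_post is not None]
    if not eligible:
        raise ValueError("no eligible records for complete root coverage")
    covered = sum(1 for r in eligible if r.recession_depth_post <= 0)
    return round(100.0 * covered / len(eligible), 2)


# ---------------------------------------------------------------------------
# thickness profile
# ---------------------------------------------------------------------------


def thickness_profile(
    pre: "Mesh | TriangleSoup",
    post_registered: "Mesh | TriangleSoup",
    apex_point: np.ndarray,
    coronal_axis: np.ndarray,
    buccal_normal: np.ndarray,
    config: MeasurementConfig = MeasurementConfig(),
):
    """Signed buccal deviation profile on the mid-tooth sagittal plane.

    Sample locations are points on the pre-op surface at axial offsets of
    ``config.offsets()`` mm from ``apex_point`` within the plane spanned by
    the coronal axis and the buccal normal; the deviation at each is the
    signed distance from the pre-op surface point to the post-op surface
    along the buccal normal (positive = outward gain).  Samples whose ray
    misses either surface within ``RAY_MAX_DEVIATION`` mm are invalid.

    Returns ``(samples, thickness_gain, measurement_mode)`` where samples is
    a list of (offset, deviation-or-None).  All samples valid ->
    ``full_profile`` with the mean; otherwise ``apex_only`` with the offset-0
    deviation.  An invalid offset-0 sample raises :class:`MeasurementFailure`.
    """
    soup_pre = pre if isinstance(pre, TriangleSoup) else TriangleSoup(pre)
    soup_post = (
        post_registered
        if isinstance(post_registered, TriangleSoup)
        else TriangleSoup(post_registered)
    )
    apex = np.asarray(apex_point, dtype=float)
    axis = np.asarray(coronal_axis, dtype=float)
    normal = np.asarray(buccal_normal, dtype=float)

    local_pre = soup_pre.subset_near(apex, PROBE_DISTANCE + config.max_offset + 2)
    local_post = soup_post.subset_near(apex, PROBE_DISTANCE + config.max_offset + 2)

    def deviation_at(offset: float) -> Optional[float]:
        origin = apex + offset * axis + PROBE_DISTANCE * normal
        t_pre = local_pre.hits(origin, -normal)
        if len(t_pre) == 0:
            return None
        surface_point = origin + t_pre[0] * (-normal)
        start = surface_point + (RAY_MAX_DEVIATION + 0.5) * normal
        t_post = local_post.hits(start, -normal)
        if len(t_post) == 0:
            return None
        dev = (RAY_MAX_DEVIATION + 0.5) - t_post
        dev = dev[np.abs(dev) <= RAY_MAX_DEVIATION]
        if len(dev) == 0:
            return None
        return float(dev[np.argmin(np.abs(dev))])

    apex_dev = deviation_at(0.0)
    samples = [(float(k), deviation_at(float(k))) for k in config.offsets()]

    if apex_dev is None:
        raise MeasurementFailure("apex deviation ray misses the post-op surface")
    if all(d is not None for _, d in samples):
        gain = float(np.mean([d for _, d in samples]))
        return samples, gain, "full_profile"
    return samples, float(apex_dev), "apex_only"


# ---------------------------------------------------------------------------
# case orchestration
# ---------------------------------------------------------------------------


def assess_case(
    pre: Mesh,
    post: Mesh,
    annotations: Sequence[ToothAnnotation],
    registration: RegistrationResult,
    config: MeasurementConfig = MeasurementConfig(),
    raters: Sequence[str] = ("rater1",),
    n_replicates: int = 1,
    landmark_sd: float = 0.0,
    seed: int = 0,
) -> list:
    """Run all per-tooth metrics; one record per tooth x rater x replicate.

    The post-op mesh and its landmarks are mapped into the pre-op frame with
    ``registration.transform`` first.  Replication re-runs the measurement
    with landmark polylines perturbed by iid Gaussian jitter of
    ``landmark_sd`` mm (emulating repeated manual landmark selection by
    independent raters); ``landmark_sd = 0`` makes replicates identical.
    Per-tooth failures are recorded (``measurement_mode='failed'``), not
    raised.
    """
    T = registration.transform
    post_reg = apply_transform(post, T)
    soup_pre = TriangleSoup(pre)
    soup_post = TriangleSoup(post_reg)

    records: list[ToothMeasurementRecord] = []
    for ann in annotations:
        margin_post_common = apply_transform(ann.margin_post, T)
        for ri, rater in enumerate(raters):
            for rep in range(n_replicates):
                rng = np.random.default_rng(
                    [seed, zlib.crc32(ann.tooth_id.encode()), ri, rep]
                )
                jitter = (
                    (lambda poly: poly + rng.normal(0.0, landmark_sd, poly.shape))
                    if landmark_sd > 0
                    else (lambda poly: poly)
                )
                margin_pre = jitter(ann.margin_pre)
                margin_post = jitter(margin_post_common)
                cej = None if ann.cej is None else jitter(ann.cej)

                apex_pre = deepest_recession_point(margin_pre, ann.coronal_axis)
                apex_post = deepest_recession_point(margin_post, ann.coronal_axis)

                cej_ok = cej is not None
                depth_pre = depth_post = mrc = None
                complete = None
                if cej_ok:
                    depth_pre = recession_depth(apex_pre, cej, ann.coronal_axis)
                    depth_post = recession_depth(apex_post, cej, ann.coronal_axis)
                    complete = depth_post <= 0.0
                    if depth_pre > 0:
                        mrc = 100.0 * (depth_pre - depth_post) / depth_pre

                reduction = recession_reduction(
                    apex_pre, apex_post, ann.coronal_axis, mode=config.reduction
                )

                try:
                    samples, gain, mode = thickness_profile(
                        soup_pre,
                        soup_post,
                        apex_pre,
                        ann.coronal_axis,
                        ann.buccal_normal,
                        config,
                    )
                except MeasurementFailure:
                    samples, gain, mode = [], None, "failed"

                records.append(
                    ToothMeasurementRecord(
                        tooth_id=ann.tooth_id,
                        recession_depth_pre=depth_pre,
                        recession_depth_post=depth_post,
                        recession_reduction=reduction,
                        mrc_percent=mrc,
                        complete_coverage=complete,
                        thickness_gain=gain,
                        thickness_samples=samples,
                        measurement_mode=mode,
                        rater_id=rater,
                        replicate_index=rep,
                        cej_available=cej_ok,
                        jaw=ann.jaw,
                        tooth_type=ann.tooth_type,
                        recession_type=ann.recession_type,
                        artifact_flag=ann.artifact_flag,
                    )
                )
    return records


def records_to_frame(records: Sequence[ToothMeasurementRecord]):
    """Flatten measurement records into a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    rows = []
    for r in records:
        rows.append(
            {
                "tooth_id": r.tooth_id,
                "jaw": r.jaw,
                "tooth_type": r.tooth_type,
                "recession_type": r.recession_type,
                "rater_id": r.rater_id,
                "replicate_index": r.replicate_index,
                "recession_depth_pre": r.recession_depth_pre,
                "recession_depth_post": r.recession_depth_post,
                "recession_reduction": r.recession_reduction,
                "mrc_percent": r.mrc_percent,
                "complete_coverage": r.complete_coverage,
                "thickness_gain": r.thickness_gain,
                "measurement_mode": r.measurement_mode,
                "cej_available": r.cej_available,
                "artifact_flag": r.artifact_flag,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# heat-map export
# ---------------------------------------------------------------------------


def deviation_heatmap(pre: Mesh, post_registered: Mesh) -> np.ndarray:
    """Per-vertex signed deviation of the post-op surface from the pre-op
    one (positive = outward along the pre-op vertex normal), the quantity a
    surface-comparison heat map visualises."""
    normals = pre.normals if pre.normals is not None else pre.vertex_normals()
    tree = cKDTree(post_registered.vertices)
    _, idx = tree.query(pre.vertices)
    diff = post_registered.vertices[idx] - pre.vertices
    return np.einsum("ij,ij->i", diff, normals)


def export_heatmap_ply(pre: Mesh, scalars: np.ndarray, path) -> None:
    """Write an ASCII PLY with a per-vertex ``quality`` scalar attribute."""
    scalars = np.asarray(scalars, dtype=float)
    if scalars.shape != (pre.n_vertices,):
        raise ValueError("need one scalar per vertex")
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {pre.n_vertices}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write("property float quality\n")
        fh.write(f"element face {pre.n_faces}\n")
        fh.write("property list uchar int vertex_indices\nend_header\n")
        for v, s in zip(pre.vertices, scalars):
            fh.write(f"{v[0]:.6f} {v[1]:.6f} {v[2]:.6f} {s:.6f}\n")
        for f in pre.faces:
            fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
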