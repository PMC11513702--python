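"""Synthetic paired pre-/post-operative dental-arch casts with known truth.

The generator emulates a digitized full-arch cast: teeth modelled as smooth
crown bulges on a cylindrical gingival wall placed along a circular arc, with
a scalloped gingival-margin curve and a marked CEJ curve per tooth.  Each
tooth carries a drawn recession depth (pre-op margin displaced apically from
the CEJ), a coverage fraction (post-op margin displaced back coronally; may
exceed 1, so margins beyond the CEJ occur), and a buccal thickness gain
(outward inflation of the gingiva over a band apical of the post-op margin,
smoothly tapered).  The post-op mesh is additionally rigid-perturbed and
vertex-noise corrupted, and a configurable fraction of teeth receives a
crater-like impression artifact in the papilla region.

The surface is a "flush" model: the margin is a marked curve, not a step in
the mesh, so the only pre-to-post mesh difference is the inflation field --
which keeps every ground-truth quantity closed-form.  Defaults are calibrated
to the clinical scale this package targets: pre-op depth 1.34 +/- 0.92 mm,
coverage such that mean reduction ~ 0.87 mm and complete coverage ~ 26% of
teeth, thickness gain 0.33 +/- 0.30 mm, artifacts on ~10% of teeth.

Occlusal is +z for the mandible and -z for the maxilla; the buccal direction
is radially outward from the arch axis.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import truncnorm

from .mesh_io import Mesh, ToothAnnotation

# -- fixed anatomy of the synthetic profile (mm) ----------------------------
WALL_BOTTOM = -6.0        # below: mucosa flares outward
MUCOSA_FLARE = 0.8
Z_MIN = -9.0
CROWN_RISE = 0.8          # crown bulge starts this far coronal of the CEJ
CROWN_RISE_WIDTH = 1.2
CROWN_BULGE = 2.0         # radial crown prominence
SCALLOP = 0.8             # margin rise toward the papillae
MARGIN_HALF_SPAN = 0.8    # margin/CEJ polylines span this fraction of half-width
N_POLYLINE = 15           # odd, so the mid-axis point is sampled exactly
TAPER_RAMP = 1.2          # inflation ramp below the post-op margin
TAPER_BAND = 6.0          # inflation band extent apical of the margin
TAPER_FADE = 1.5          # apical fade-out width of the band
ARTIFACT_RADIUS = 1.6     # crater radius (1-2 mm scale)
ARTIFACT_APICAL = 2.5     # crater centre: this far apical of the recession apex
ARTIFACT_LATERAL = 1.0    # ... and this far off the mid-tooth plane
MAX_DEPTH = 4.0           # recession depths clipped here (keeps margins on the wall)

#: offsets (mm) of the thickness sampling grid along the coronal axis
THICKNESS_OFFSETS = (-3.0, -2.0, -1.0, 0.0, 1.0, 2.0, 3.0)

TOOTH_TYPE_WEIGHTS = {"incisor": 21, "canine": 16, "premolar": 26, "molar": 19}
RT1_FRACTION = 39.0 / 82.0


class ParameterError(ValueError):
    """Invalid generator parameters."""


def smoothstep(x):
    """C1 ramp: 0 for x <= 0, 1 for x >= 1, 3x^2 - 2x^3 between."""
    t = np.clip(x, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


# ---------------------------------------------------------------------------
# parameters and ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArchParams:
    """Generator parameters; distributions are (mean, sd) in mm.

    ``recession_depth_distribution`` is truncated at 0 (and clipped at
    ``MAX_DEPTH``); ``coverage_fraction_distribution`` is clipped to
    [0, 1.2] so complete coverage (margin to or beyond the CEJ) occurs
    stochastically; thickness gains may be negative (shrinkage).
    """

    n_teeth: int = 8
    jaw: str = "mandible"
    arch_radius: float = 25.0
    tooth_spacing: float = 7.0
    crown_height: float = 5.5
    recession_depth_distribution: tuple = (1.34, 0.92)
    coverage_fraction_distribution: tuple = (0.65, 0.48)
    thickness_gain_distribution: tuple = (0.33, 0.30)
    artifact_probability: float = 0.10
    mesh_edge_length: float = 0.25
    noise_sd: float = 0.01
    max_rotation_deg: float = 10.0
    max_translation_mm: float = 5.0
    seed: int = 0

    def validate(self) -> "ArchParams":
        if self.n_teeth < 1:
            raise ParameterError("n_teeth must be >= 1")
        if self.jaw not in ("maxilla", "mandible"):
            raise ParameterError("jaw must be 'maxilla' or 'mandible'")
        for name in ("arch_radius", "tooth_spacing", "crown_height", "mesh_edge_length"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        if not 0.0 <= self.artifact_probability <= 1.0:
            raise ParameterError("artifact_probability must be in [0, 1]")
        if self.noise_sd < 0 or self.max_rotation_deg < 0 or self.max_translation_mm < 0:
            raise ParameterError("noise/perturbation magnitudes must be >= 0")
        return self


@dataclass
class ToothTruth:
    tooth_id: str
    true_recession_depth_pre: float
    true_recession_depth_post: float
    true_reduction: float
    drawn_thickness_gain: float
    #: expectation of the deviation field at the 7-point sampling grid
    true_thickness_gain: float
    #: expectation of the deviation at the apex sample (fallback mode)
    true_thickness_gain_apex: float
    complete_coverage: bool
    artifact: bool


@dataclass
class SyntheticGroundTruth:
    """Known per-tooth parameters plus the applied global perturbation."""

    teeth: list
    applied_transform: np.ndarray
    noise_sd: float
    seed: int

    def array(self, attr: str) -> np.ndarray:
        return np.array([getattr(t, attr) for t in self.teeth])

    def by_id(self, tooth_id: str) -> ToothTruth:
        for t in self.teeth:
            if t.tooth_id == tooth_id:
                return t
        raise KeyError(tooth_id)


def _tooth_rng(seed: int, tooth_id: str) -> np.random.Generator:
    # per-tooth stream from a stable hash of (seed, tooth_id): reproducible
    # independently of tooth ordering
    return np.random.default_rng([seed, 0x7EE7, zlib.crc32(tooth_id.encode())])


def _truncated_normal(rng, mean, sd, lower, upper):
    if sd == 0:
        return float(np.clip(mean, lower, upper))
    a, b = (lower - mean) / sd, (upper - mean) / sd
    return float(truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng))


# ---------------------------------------------------------------------------
# surface model
# ---------------------------------------------------------------------------


def _tooth_window(u):
    """Lateral bump profile: 1 on the mid-tooth plateau (|u| <= 0.5), smooth
    to 0 at the papillae (|u| >= 1); u is arc distance / half-width."""
    return smoothstep((1.0 - np.abs(u)) / 0.5)


def _margin_curve(u, cej_z, depth):
    """Scalloped margin height: deepest at mid-tooth, rising to the papillae."""
    return cej_z - depth + SCALLOP * np.minimum(u * u, 1.0)


def _taper(z, margin_z):
    """Inflation taper: 0 at/above the margin curve, plateau below a short
    ramp, fading out at the apical end of the band."""
    s1 = smoothstep((margin_z - z) / TAPER_RAMP)
    s2 = smoothstep((z - (margin_z - TAPER_BAND)) / TAPER_FADE)
    return s1 * s2


def _radius_field(theta, z, teeth, params: ArchParams):
    """Pre-op surface radius r(theta, z) on broadcastable grids."""
    R = params.arch_radius
    r = np.full(np.broadcast_shapes(np.shape(theta), np.shape(z)), R, dtype=float)
    r = r + MUCOSA_FLARE * smoothstep((WALL_BOTTOM - z) / 3.0)
    half_w = 0.45 * params.tooth_spacing
    for t in teeth:
        u = (theta - t["theta"]) * R / half_w
        rise = smoothstep((z - (t["cej_z"] + CROWN_RISE)) / CROWN_RISE_WIDTH)
        fall = 1.0 - smoothstep((z - (t["z_top"] - 1.5)) / 1.5)
        r = r + t["crown_amp"] * _tooth_window(u) * rise * fall
    return r


def _inflation_field(theta, z, teeth, params: ArchParams):
    """Post-op minus pre-op radius: per-tooth buccal thickness inflation."""
    R = params.arch_radius
    out = np.zeros(np.broadcast_shapes(np.shape(theta), np.shape(z)), dtype=float)
    half_w = 0.45 * params.tooth_spacing
    for t in teeth:
        u = (theta - t["theta"]) * R / half_w
        margin_z = _margin_curve(u, t["cej_z"], t["depth_post"])
        out = out + t["gain"] * _tooth_window(u) * _taper(z, margin_z)
    return out


def _grid_mesh(theta_grid, z_grid, radius) -> Mesh:
    """Triangulate an r(theta, z) height field; outward winding."""
    nt, nz = len(theta_grid), len(z_grid)
    tt = theta_grid[:, None]
    x = radius * np.cos(tt)
    y = radius * np.sin(tt)
    zz = np.broadcast_to(z_grid[None, :], (nt, nz))
    vertices = np.stack([x.ravel(), y.ravel(), zz.ravel()], axis=1)
    i = np.arange(nt - 1)[:, None]
    j = np.arange(nz - 1)[None, :]
    a = (i * nz + j).ravel()
    b = ((i + 1) * nz + j).ravel()
    c = (i * nz + j + 1).ravel()
    d = ((i + 1) * nz + j + 1).ravel()
    faces = np.concatenate(
        [np.stack([a, b, c], axis=1), np.stack([b, d, c], axis=1)]
    )
    return Mesh(vertices, faces)


def _surface_point(theta, z, teeth, params, inflate: bool) -> np.ndarray:
    r = float(_radius_field(np.float64(theta), np.float64(z), teeth, params))
    if inflate:
        r += float(_inflation_field(np.float64(theta), np.float64(z), teeth, params))
    return np.array([r * np.cos(theta), r * np.sin(theta), z])


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _draw_teeth(params: ArchParams):
    d_mean, d_sd = params.recession_depth_distribution
    c_mean, c_sd = params.coverage_fraction_distribution
    g_mean, g_sd = params.thickness_gain_distribution
    types = list(TOOTH_TYPE_WEIGHTS)
    weights = np.array(list(TOOTH_TYPE_WEIGHTS.values()), dtype=float)
    weights /= weights.sum()

    teeth = []
    for i in range(params.n_teeth):
        tid = f"T{i + 1:02d}"
        rng = _tooth_rng(params.seed, tid)
        depth_pre = _truncated_normal(rng, d_mean, d_sd, 0.0, MAX_DEPTH)
        if c_sd == 0:
            coverage = float(np.clip(c_mean, 0.0, 1.2))
        else:
            coverage = float(np.clip(rng.normal(c_mean, c_sd), 0.0, 1.2))
        gain = float(rng.normal(g_mean, g_sd)) if g_sd > 0 else float(g_mean)
        teeth.append(
            {
                "tooth_id": tid,
                "theta": (i - (params.n_teeth - 1) / 2.0)
                * params.tooth_spacing
                / params.arch_radius,
                "cej_z": float(rng.uniform(-0.2, 0.2)),
                "depth_pre": depth_pre,
                "depth_post": depth_pre * (1.0 - coverage),
                "gain": gain,
                "crown_amp": CROWN_BULGE + float(rng.uniform(-0.3, 0.5)),
                "z_top": params.crown_height + float(rng.uniform(-0.5, 0.5)),
                "artifact": bool(rng.random() < params.artifact_probability),
                "tooth_type": types[int(rng.choice(len(types), p=weights))],
                "recession_type": "RT1" if rng.random() < RT1_FRACTION else "RT2",
                "artifact_seed": int(rng.integers(0, 2**31 - 1)),
            }
        )
    return teeth


def _random_rigid(rng, max_rotation_deg, max_translation_mm) -> np.ndarray:
    from scipy.spatial.transform import Rotation

    T = np.eye(4)
    if max_rotation_deg > 0:
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        angle = np.radians(rng.uniform(0.0, max_rotation_deg))
        T[:3, :3] = Rotation.from_rotvec(angle * axis).as_matrix()
    if max_translation_mm > 0:
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        T[:3, 3] = direction * rng.uniform(0.0, max_translation_mm)
    return T


def inject_artifact(mesh: Mesh, annotation: ToothAnnotation, seed: int) -> Mesh:
    """Carve an impression-artifact crater next to a tooth.

    Removes faces within ``ARTIFACT_RADIUS`` of a point in the
    interdental-papilla region apical of the tooth's recession apex, leaving
    the band around the apex itself intact -- so the thickness measurement
    later reports invalid samples at the apical grid offsets and falls back
    to the single-point (apex-only) mode.  Deterministic in ``seed``.
    """
    rng = np.random.default_rng([seed, 0xA27])
    margin = annotation.margin_pre
    apex = margin[int(np.argmin(margin @ annotation.coronal_axis))]
    lateral = np.cross(annotation.coronal_axis, annotation.buccal_normal)
    lateral /= np.linalg.norm(lateral)
    side = 1.0 if rng.random() < 0.5 else -1.0
    center = (
        apex
        - ARTIFACT_APICAL * annotation.coronal_axis
        + side * ARTIFACT_LATERAL * lateral
    )
    centroids = mesh.vertices[mesh.faces].mean(axis=1)
    keep = np.linalg.norm(centroids - center, axis=1) > ARTIFACT_RADIUS
    out = mesh.copy()
    out.faces = mesh.faces[keep]
    return out


def generate_arch_pair(params: ArchParams):
    """Generate a (pre, post, annotations, truth) quadruple.

    ``pre`` is in the reference frame; ``post`` is rigid-perturbed (the
    transform is recorded in ``truth.applied_transform``, mapping pre-frame
    points into the post frame) and vertex-noise corrupted.  Annotations
    carry exact landmark polylines in each mesh's own frame.  Fully
    reproducible from ``params.seed``.
    """
    params.validate()
    teeth = _draw_teeth(params)
    R = params.arch_radius

    span = (params.n_teeth + 1) * params.tooth_spacing / R
    n_theta = max(int(np.ceil(span * R / params.mesh_edge_length)) + 1, 8)
    z_max = params.crown_height + 1.0
    n_z = max(int(np.ceil((z_max - Z_MIN) / params.mesh_edge_length)) + 1, 8)
    theta_grid = np.linspace(-span / 2.0, span / 2.0, n_theta)
    z_grid = np.linspace(Z_MIN, z_max, n_z)

    r_pre = _radius_field(theta_grid[:, None], z_grid[None, :], teeth, params)
    r_post = r_pre + _inflation_field(theta_grid[:, None], z_grid[None, :], teeth, params)

    pre = _grid_mesh(theta_grid, z_grid, r_pre)
    post = _grid_mesh(theta_grid, z_grid, r_post)

    # landmark polylines on the smooth surface (exact, independent of meshing)
    half_w = 0.45 * params.tooth_spacing
    u_samples = np.linspace(-MARGIN_HALF_SPAN, MARGIN_HALF_SPAN, N_POLYLINE)
    annotations = []
    flip = -1.0 if params.jaw == "maxilla" else 1.0
    for t in teeth:
        thetas = t["theta"] + u_samples * half_w / R
        margin_pre = np.array(
            [
                _surface_point(th, _margin_curve(u, t["cej_z"], t["depth_pre"]), teeth, params, False)
                for th, u in zip(thetas, u_samples)
            ]
        )
        margin_post = np.array(
            [
                _surface_point(th, _margin_curve(u, t["cej_z"], t["depth_post"]), teeth, params, True)
                for th, u in zip(thetas, u_samples)
            ]
        )
        cej = np.array(
            [_surface_point(th, t["cej_z"], teeth, params, False) for th in thetas]
        )
        annotations.append(
            ToothAnnotation(
                tooth_id=t["tooth_id"],
                jaw=params.jaw,
                tooth_type=t["tooth_type"],
                recession_type=t["recession_type"],
                coronal_axis=np.array([0.0, 0.0, flip]),
                buccal_normal=np.array([np.cos(t["theta"]), np.sin(t["theta"]), 0.0]),
                margin_pre=margin_pre,
                margin_post=margin_post,
                cej=cej,
                artifact_flag=t["artifact"],
            )
        )

    if flip < 0:  # maxilla: occlusal points down
        for mesh in (pre, post):
            mesh.vertices[:, 2] *= -1.0
            mesh.faces = mesh.faces[:, ::-1]
        for ann in annotations:
            for poly in (ann.margin_pre, ann.margin_post, ann.cej):
                poly[:, 2] *= -1.0

    pre = pre.validated()
    post = post.validated()

    for t, ann in zip(teeth, annotations):
        if t["artifact"]:
            post = inject_artifact(post, ann, t["artifact_seed"])

    rng_global = np.random.default_rng([params.seed, 0xA5C])
    T = _random_rigid(rng_global, params.max_rotation_deg, params.max_translation_mm)
    Rm, tv = T[:3, :3], T[:3, 3]
    post.vertices = post.vertices @ Rm.T + tv
    if params.noise_sd > 0:
        post.vertices = post.vertices + rng_global.normal(
            0.0, params.noise_sd, size=post.vertices.shape
        )
    post.normals = post.vertex_normals()
    for ann in annotations:
        ann.margin_post = ann.margin_post @ Rm.T + tv
        ann.validate()

    truth_teeth = []
    for t in teeth:
        z1 = t["cej_z"] - t["depth_pre"]
        margin_post_apex = t["cej_z"] - t["depth_post"]
        taper_grid = _taper(z1 + np.array(THICKNESS_OFFSETS), margin_post_apex)
        truth_teeth.append(
            ToothTruth(
                tooth_id=t["tooth_id"],
                true_recession_depth_pre=t["depth_pre"],
                true_recession_depth_post=t["depth_post"],
                true_reduction=t["depth_pre"] - t["depth_post"],
                drawn_thickness_gain=t["gain"],
                true_thickness_gain=float(t["gain"] * taper_grid.mean()),
                true_thickness_gain_apex=float(t["gain"] * _taper(z1, margin_post_apex)),
                complete_coverage=bool(t["depth_post"] <= 0.0),
                artifact=t["artifact"],
            )
        )

    truth = SyntheticGroundTruth(
        teeth=truth_teeth,
        applied_transform=T,
        noise_sd=params.noise_sd,
        seed=params.seed,
    )
    return pre, post, annotations, truth


# ---------------------------------------------------------------------------
# study-scale layout
# ---------------------------------------------------------------------------


def study_design(seed: int = 0):
    """Per-patient arch parameters for a full study-scale run.

    19 patients totalling 82 recession teeth (six arches of 5 teeth, thirteen
    of 4), 38 maxillary / 44 mandibular sites -- the clustered layout the
    statistical layer expects.  Returns a list of (patient_id, ArchParams).
    """
    counts = [5] * 6 + [4] * 13
    # two 5-tooth and seven 4-tooth arches in the maxilla: 38 teeth there
    jaws = ["maxilla"] * 2 + ["mandible"] * 4 + ["maxilla"] * 7 + ["mandible"] * 6
    design = []
    for i, (n, jaw) in enumerate(zip(counts, jaws)):
        design.append(
            (
                f"P{i + 1:02d}",
                ArchParams(n_teeth=n, jaw=jaw, seed=int((seed * 1000 + i) % (2**31 - 1))),
            )
        )
    return design


def save_truth(truth: SyntheticGroundTruth, path) -> None:
    """Serialise ground truth as YAML (structured text)."""
    import yaml

    doc = {
        "seed": int(truth.seed),
        "noise_sd": float(truth.noise_sd),
        "applied_transform": [[float(x) for x in row] for row in truth.applied_transform],
        "teeth": [
            {
                "tooth_id": t.tooth_id,
                "true_recession_depth_pre": float(t.true_recession_depth_pre),
                "true_recession_depth_post": float(t.true_recession_depth_post),
                "true_reduction": float(t.true_reduction),
                "drawn_thickness_gain": float(t.drawn_thickness_gain),
                "true_thickness_gain": float(t.true_thickness_gain),
                "true_thickness_gain_apex": float(t.true_thickness_gain_apex),
                "complete_coverage": bool(t.complete_coverage),
                "artifact": bool(t.artifact),
            }
            for t in truth.teeth
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_truth(path) -> SyntheticGroundTruth:
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh)
    teeth = [ToothTruth(**rec) for rec in doc["teeth"]]
    return SyntheticGroundTruth(
        teeth=teeth,
        applied_transform=np.array(doc["applied_transform"], dtype=float),
        noise_sd=float(doc["noise_sd"]),
        seed=int(doc["seed"]),
    )
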