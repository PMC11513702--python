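"""Triangle-mesh and per-tooth annotation I/O.

All geometry is in millimetres in a right-handed frame.  A dental cast at this
scale has a bounding-box diagonal of roughly 40-120 mm.  Orientation of real
scans is never inferred from the mesh itself: the per-tooth annotation vectors
(``coronal_axis``, ``buccal_normal``) define the measurement directions.

STL parsing/serialisation is delegated to :mod:`trimesh`; this module adds the
validation layer (finite coordinates, in-range indices, degenerate-face
removal, duplicate-vertex merging) that every downstream stage relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh
import yaml

#: vertices closer than this (mm) are merged -- below scanner resolution,
#: removes STL's per-facet vertex duplication
MERGE_TOL = 1e-6

#: annotation landmark points must lie within the mesh bounding box expanded
#: by this much (mm)
BBOX_SLACK = 1.0

JAWS = ("maxilla", "mandible")
TOOTH_TYPES = ("incisor", "canine", "premolar", "molar")
RECESSION_TYPES = ("RT1", "RT2")


class MeshFormatError(ValueError):
    """File could not be parsed as a triangle mesh."""


class MeshValidationError(ValueError):
    """Geometry violates the mesh invariants (NaNs, bad indices, empty)."""


class AnnotationSchemaError(ValueError):
    """Annotation record is missing or violates a required field."""


# ---------------------------------------------------------------------------
# Mesh container
# ---------------------------------------------------------------------------


@dataclass
class Mesh:
    """Triangle surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices
    normals : optional (n, 3) per-vertex unit normals
    """

    vertices: np.ndarray
    faces: np.ndarray
    normals: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.normals is not None:
            self.normals = np.asarray(self.normals, dtype=np.float64).reshape(-1, 3)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def bounds(self) -> np.ndarray:
        """(2, 3) array of (min, max) vertex coordinates."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    def copy(self) -> "Mesh":
        return Mesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.normals is None else self.normals.copy(),
        )

    # -- validation --------------------------------------------------------

    def validated(self, merge_tol: float = MERGE_TOL) -> "Mesh":
        """Return a cleaned copy enforcing the mesh invariants.

        Non-finite coordinates or out-of-range face indices raise
        :class:`MeshValidationError`.  Vertices closer than ``merge_tol`` are
        merged, then faces with repeated indices or (near-)zero area are
        dropped, and per-vertex normals are recomputed from the winding.
        """
        v, f = self.vertices, self.faces
        if v.size == 0 or f.size == 0:
            raise MeshValidationError("empty geometry")
        if not np.isfinite(v).all():
            raise MeshValidationError("non-finite vertex coordinates")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshValidationError("face index out of range")

        # merge duplicates on a merge_tol grid (deterministic, order-stable)
        key = np.round(v / merge_tol).astype(np.int64)
        _, first_idx, inverse = np.unique(
            key, axis=0, return_index=True, return_inverse=True
        )
        order = np.argsort(first_idx, kind="stable")
        rank = np.empty_like(order)
        rank[order] = np.arange(len(order))
        v_merged = v[first_idx[order]]
        f_merged = rank[inverse][f]

        # drop degenerate faces
        ok = (
            (f_merged[:, 0] != f_merged[:, 1])
            & (f_merged[:, 1] != f_merged[:, 2])
            & (f_merged[:, 0] != f_merged[:, 2])
        )
        f_merged = f_merged[ok]
        tri = v_merged[f_merged]
        area2 = np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        f_merged = f_merged[area2 > 2e-12]
        if len(f_merged) == 0:
            raise MeshValidationError("no non-degenerate faces")

        out = Mesh(v_merged, f_merged)
        out.normals = out.vertex_normals()
        return out

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted per-vertex unit normals from face winding."""
        tri = self.vertices[self.faces]
        fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])  # 2*area weighted
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.faces[:, k], fn)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0] = 1.0
        return vn / norm

    # -- trimesh bridge ----------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh) -> "Mesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces))


# ---------------------------------------------------------------------------
# STL I/O
# ---------------------------------------------------------------------------


def read_stl(path) -> Mesh:
    """Read a binary or ASCII STL file into a validated :class:`Mesh`."""
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        tm = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # trimesh raises a zoo of exception types
        raise MeshFormatError(f"unreadable STL file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise MeshValidationError(f"{path}: empty geometry")
    return Mesh.from_trimesh(tm).validated()


def write_stl(mesh: Mesh, path, dialect: str = "binary") -> None:
    """Write ``mesh`` as STL (``binary``: 84 + 50*n_faces bytes, or ``ascii``)."""
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"dialect must be 'binary' or 'ascii', got {dialect!r}")
    tm = mesh.to_trimesh()
    file_type = "stl" if dialect == "binary" else "stl_ascii"
    data = trimesh.exchange.export.export_mesh(tm, None, file_type=file_type)
    mode = "wb" if isinstance(data, bytes) else "w"
    try:
        with open(path, mode) as fh:
            fh.write(data)
    except OSError as exc:
        raise IOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Tooth annotations
# ---------------------------------------------------------------------------


@dataclass
class ToothAnnotation:
    """Per-tooth landmarks and metadata.

    ``coronal_axis`` points coronally (toward the crown; apical is its
    negation) and ``buccal_normal`` points out of the buccal surface; both are
    unit vectors, roughly orthogonal.  ``margin_pre`` lives in the
    pre-operative frame, ``margin_post`` in the post-operative frame *before*
    registration.  ``cej`` is optional: when absent the CEJ-dependent metrics
    (recession depth, mRC, cRC) are flagged unavailable for this tooth.
    """

    tooth_id: str
    jaw: str
    tooth_type: str
    recession_type: str
    coronal_axis: np.ndarray
    buccal_normal: np.ndarray
    margin_pre: np.ndarray
    margin_post: np.ndarray
    cej: Optional[np.ndarray] = None
    artifact_flag: bool = False

    def __post_init__(self) -> None:
        self.coronal_axis = np.asarray(self.coronal_axis, dtype=np.float64).reshape(3)
        self.buccal_normal = np.asarray(self.buccal_normal, dtype=np.float64).reshape(3)
        self.margin_pre = np.asarray(self.margin_pre, dtype=np.float64).reshape(-1, 3)
        self.margin_post = np.asarray(self.margin_post, dtype=np.float64).reshape(-1, 3)
        if self.cej is not None:
            self.cej = np.asarray(self.cej, dtype=np.float64).reshape(-1, 3)
        self.artifact_flag = bool(self.artifact_flag)

    def validate(self, mesh_bounds: Optional[np.ndarray] = None) -> "ToothAnnotation":
        """Enforce the annotation invariants in place and return self.

        Vectors are re-normalised; an axis pair with |dot| >= 0.9 (not roughly
        orthogonal), an empty polyline, an unknown categorical value, or -- if
        ``mesh_bounds`` is given -- a landmark outside the box expanded by
        ``BBOX_SLACK`` raises :class:`AnnotationSchemaError`.
        """
        tid = self.tooth_id
        if not tid:
            raise AnnotationSchemaError("tooth_id must be non-empty")
        if self.jaw not in JAWS:
            raise AnnotationSchemaError(f"{tid}: jaw must be one of {JAWS}")
        if self.tooth_type not in TOOTH_TYPES:
            raise AnnotationSchemaError(f"{tid}: tooth_type must be one of {TOOTH_TYPES}")
        if self.recession_type not in RECESSION_TYPES:
            raise AnnotationSchemaError(
                f"{tid}: recession_type must be one of {RECESSION_TYPES}"
            )
        for name in ("coronal_axis", "buccal_normal"):
            vec = getattr(self, name)
            norm = np.linalg.norm(vec)
            if not np.isfinite(norm) or norm < 1e-12:
                raise AnnotationSchemaError(f"{tid}: {name} has zero/invalid norm")
            setattr(self, name, vec / norm)
        if abs(float(self.coronal_axis @ self.buccal_normal)) >= 0.9:
            raise AnnotationSchemaError(
                f"{tid}: coronal_axis and buccal_normal are not roughly orthogonal"
            )
        for name in ("margin_pre", "margin_post"):
            poly = getattr(self, name)
            if len(poly) < 2:
                raise AnnotationSchemaError(f"{tid}: {name} needs >= 2 points")
            if not np.isfinite(poly).all():
                raise AnnotationSchemaError(f"{tid}: {name} has non-finite points")
        if self.cej is not None:
            if len(self.cej) == 0 or not np.isfinite(self.cej).all():
                raise AnnotationSchemaError(f"{tid}: cej polyline invalid")
        if mesh_bounds is not None:
            lo = mesh_bounds[0] - BBOX_SLACK
            hi = mesh_bounds[1] + BBOX_SLACK
            polys = [self.margin_pre] + ([] if self.cej is None else [self.cej])
            for poly in polys:
                if (poly < lo).any() or (poly > hi).any():
                    raise AnnotationSchemaError(
                        f"{tid}: landmark outside mesh bounding box (+{BBOX_SLACK} mm)"
                    )
        return self


_REQUIRED_KEYS = (
    "tooth_id",
    "jaw",
    "tooth_type",
    "recession_type",
    "coronal_axis",
    "buccal_normal",
    "margin_pre",
    "margin_post",
)


def _annotation_from_dict(rec: dict) -> ToothAnnotation:
    tid = rec.get("tooth_id", "<missing tooth_id>")
    for key in _REQUIRED_KEYS:
        if key not in rec:
            raise AnnotationSchemaError(f"tooth {tid!r}: missing required field {key!r}")
    return ToothAnnotation(
        tooth_id=str(rec["tooth_id"]),
        jaw=rec["jaw"],
        tooth_type=rec["tooth_type"],
        recession_type=rec["recession_type"],
        coronal_axis=rec["coronal_axis"],
        buccal_normal=rec["buccal_normal"],
        margin_pre=rec["margin_pre"],
        margin_post=rec["margin_post"],
        cej=rec.get("cej"),
        artifact_flag=rec.get("artifact_flag", False),
    ).validate()


def read_annotations(path) -> list[ToothAnnotation]:
    """Read the YAML annotation file (``teeth:`` list of records).

    Schema (one record per tooth): tooth_id, jaw, tooth_type, recession_type,
    coronal_axis, buccal_normal, margin_pre, margin_post, cej (optional),
    artifact_flag (optional, default false).
    """
    path = Path(path)
    if not path.exists():
        raise AnnotationSchemaError(f"no such annotation file: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "teeth" not in doc:
        raise AnnotationSchemaError(f"{path}: expected top-level 'teeth' list")
    annotations = [_annotation_from_dict(rec) for rec in doc["teeth"]]
    ids = [a.tooth_id for a in annotations]
    if len(set(ids)) != len(ids):
        raise AnnotationSchemaError("duplicate tooth_id in annotation file")
    return annotations


def write_annotations(annotations: Sequence[ToothAnnotation], path) -> None:
    """Serialise annotations to the YAML schema read by :func:`read_annotations`."""
    doc = {"teeth": []}
    for a in annotations:
        rec = {
            "tooth_id": a.tooth_id,
            "jaw": a.jaw,
            "tooth_type": a.tooth_type,
            "recession_type": a.recession_type,
            "coronal_axis": [float(x) for x in a.coronal_axis],
            "buccal_normal": [float(x) for x in a.buccal_normal],
            "margin_pre": [[float(x) for x in p] for p in a.margin_pre],
            "margin_post": [[float(x) for x in p] for p in a.margin_post],
            "artifact_flag": bool(a.artifact_flag),
        }
        if a.cej is not None:
            rec["cej"] = [[float(x) for x in p] for p in a.cej]
        doc["teeth"].append(rec)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
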