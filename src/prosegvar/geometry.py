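"""Mesh / annotation data model, file I/O and geometric primitives.

All coordinates are millimetres in an abstract right-handed patient frame;
files carry no unit metadata by convention.  Meshes are triangle surfaces;
annotations are sparse expert point sets with three labelled anatomical
landmarks (apex, base, posterior).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

log = logging.getLogger(__name__)

LANDMARK_LABELS = ("apex", "base", "posterior")
ANNOTATION_COLUMNS = [
    "patient_id", "expert_id", "method", "session",
    "label", "x_mm", "y_mm", "z_mm", "plane",
]

_DEGENERATE_AREA_MM2 = 1e-12


class GeometryError(ValueError):
    """Invalid geometric input (degenerate, empty, mismatched)."""


class MeshFormatError(GeometryError):
    """Mesh file failed to parse or violates hard invariants."""


class AnnotationError(GeometryError):
    """Annotation file or object violates the annotation contract."""


# ---------------------------------------------------------------------------
# TriangleMesh
# ---------------------------------------------------------------------------

@dataclass
class TriangleMesh:
    """Closed triangulated surface in mm.

    ``topology_id`` tags meshes that share vertex correspondence (same face
    array, vertex i ↔ vertex i); shape-model sampling and the mesh consensus
    rely on it.
    """

    vertices: np.ndarray            # (V, 3) float64
    faces: np.ndarray               # (F, 3) int
    topology_id: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be (V, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshFormatError("faces must be (F, 3)")
        if len(self.vertices) <= 3:
            raise MeshFormatError("mesh needs more than 3 vertices")
        if len(self.faces) and (self.faces.min() < 0
                                or self.faces.max() >= len(self.vertices)):
            raise MeshFormatError("face indices out of range")
        if not np.isfinite(self.vertices).all():
            raise MeshFormatError("non-finite vertex coordinates")
        self._drop_degenerate_faces()

    def _drop_degenerate_faces(self) -> None:
        tri = self.vertices[self.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        bad = areas <= _DEGENERATE_AREA_MM2
        if bad.any():
            log.info("dropping %d degenerate face(s)", int(bad.sum()))
            self.faces = self.faces[~bad]
        if len(self.faces) == 0:
            raise MeshFormatError("mesh has no non-degenerate faces")

    # -- conversions --------------------------------------------------------

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(),
                               process=False)

    @classmethod
    def from_trimesh(cls, m: trimesh.Trimesh,
                     topology_id: str | None = None) -> "TriangleMesh":
        return cls(np.asarray(m.vertices, dtype=np.float64),
                   np.asarray(m.faces, dtype=np.int64),
                   topology_id=topology_id)

    # -- queries -------------------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)

    def volume_mm3(self) -> float:
        tm = self.to_trimesh()
        if not tm.is_watertight:
            raise GeometryError("volume requires a watertight mesh")
        return float(abs(tm.volume))

    def triangles(self) -> np.ndarray:
        """(F, 3, 3) corner coordinates."""
        return self.vertices[self.faces]

    def face_areas(self) -> np.ndarray:
        tri = self.triangles()
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric area share per vertex (1/3 of incident face areas)."""
        areas = self.face_areas()
        out = np.zeros(self.n_vertices)
        np.add.at(out, self.faces.ravel(), np.repeat(areas / 3.0, 3))
        return out

    def same_topology(self, other: "TriangleMesh") -> bool:
        return (self.faces.shape == other.faces.shape
                and np.array_equal(self.faces, other.faces))

    def with_vertices(self, vertices: np.ndarray) -> "TriangleMesh":
        return TriangleMesh(vertices, self.faces.copy(),
                            topology_id=self.topology_id)

    def copy(self) -> "TriangleMesh":
        return TriangleMesh(self.vertices.copy(), self.faces.copy(),
                            topology_id=self.topology_id)


# ---------------------------------------------------------------------------
# Mesh I/O — PLY ASCII is canonical; STL/OBJ supported through trimesh
# ---------------------------------------------------------------------------

_FORMATS = {".ply": "ply", ".stl": "stl", ".obj": "obj"}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in _FORMATS.values():
            raise MeshFormatError(f"unsupported mesh format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix not in _FORMATS:
        raise MeshFormatError(f"cannot infer mesh format from {path.name!r}")
    return _FORMATS[suffix]


def read_mesh(path: str | Path, fmt: str | None = None) -> TriangleMesh:
    """Load a PLY/STL/OBJ surface; degenerate faces are dropped with a log
    line.  Non-manifold input is allowed (only Dice needs watertightness)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if not path.exists():
        raise MeshFormatError(f"no such file: {path}")
    try:
        m = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - normalize loader errors
        raise MeshFormatError(f"failed to parse {path}: {exc}") from exc
    if not isinstance(m, trimesh.Trimesh) or len(m.vertices) == 0:
        raise MeshFormatError(f"{path} did not contain a triangle mesh")
    if fmt == "stl":
        m.merge_vertices()   # STL stores a triangle soup; restore sharing
    mesh = TriangleMesh.from_trimesh(m)
    if not mesh.to_trimesh().is_watertight:
        log.warning("%s is not watertight; Dice will reject it", path.name)
    return mesh


def write_mesh(mesh: TriangleMesh, path: str | Path,
               fmt: str | None = None) -> Path:
    """Write a mesh; PLY is ASCII with double precision (lossless round-trip)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "ply":
        _write_ply_ascii(mesh, path)
    else:
        mesh.to_trimesh().export(str(path), file_type=fmt)
    return path


def _write_ply_ascii(mesh: TriangleMesh, path: Path) -> None:
    lines = [
        "ply", "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x", "property double y", "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PointAnnotation
# ---------------------------------------------------------------------------

@dataclass
class PointAnnotation:
    """One expert's sparse point set for one prostate and session.

    ``session`` 0 is the first pass, 1 the repeat ("bis") used for
    intra-observer analysis.  ``points`` excludes the three landmarks.
    """

    patient_id: str
    expert_id: str
    method: str                       # "manual" | "semi_auto"
    session: int
    points: np.ndarray                # (N, 3) float64, may be empty
    landmarks: dict[str, np.ndarray]  # apex/base/posterior -> (3,)
    plane_tags: list[str | None] | None = None

    def __post_init__(self) -> None:
        if self.method not in ("manual", "semi_auto"):
            raise AnnotationError(f"unknown method {self.method!r}")
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        missing = [k for k in LANDMARK_LABELS if k not in self.landmarks]
        if missing:
            raise AnnotationError(f"missing landmark(s): {missing}")
        self.landmarks = {k: np.asarray(self.landmarks[k], dtype=np.float64)
                          for k in LANDMARK_LABELS}
        coords = [self.points] + [v[None, :] for v in self.landmarks.values()]
        if not np.isfinite(np.vstack(coords)).all():
            raise AnnotationError("non-finite coordinates in annotation")
        if self.plane_tags is not None and len(self.plane_tags) != len(self.points):
            raise AnnotationError("plane_tags length != point count")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def landmark_array(self) -> np.ndarray:
        """(3, 3) apex/base/posterior rows, in that fixed order."""
        return np.stack([self.landmarks[k] for k in LANDMARK_LABELS])

    def all_points(self) -> np.ndarray:
        """Landmarks followed by contour points."""
        return np.vstack([self.landmark_array(), self.points]) \
            if self.n_points else self.landmark_array()

    def transformed(self, transform: "SimilarityTransform") -> "PointAnnotation":
        return PointAnnotation(
            self.patient_id, self.expert_id, self.method, self.session,
            transform.apply(self.points) if self.n_points else self.points,
            {k: transform.apply(v[None, :])[0] for k, v in self.landmarks.items()},
            plane_tags=list(self.plane_tags) if self.plane_tags else None,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label in LANDMARK_LABELS:
            x, y, z = self.landmarks[label]
            rows.append((self.patient_id, self.expert_id, self.method,
                         self.session, label, x, y, z, ""))
        tags = self.plane_tags or [None] * self.n_points
        for p, tag in zip(self.points, tags):
            rows.append((self.patient_id, self.expert_id, self.method,
                         self.session, "point", p[0], p[1], p[2], tag or ""))
        return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


_PROVENANCES_WITH_MESH = {"manual_SSM", "manual_soft_SSM",
                          "semi_auto_soft_SSM", "consensus"}


@dataclass
class SegmentationRecord:
    """One counted segmentation: the annotation plus, where the method
    produces one, the reconstructed mesh."""
    annotation: PointAnnotation
    mesh: TriangleMesh | None
    provenance: str

    def __post_init__(self) -> None:
        if self.provenance == "manual_points":
            if self.mesh is not None:
                raise AnnotationError("manual_points record carries no mesh")
        elif self.provenance in _PROVENANCES_WITH_MESH:
            if self.mesh is None:
                raise AnnotationError(
                    f"{self.provenance} record requires a mesh")
        else:
            raise AnnotationError(f"unknown provenance {self.provenance!r}")


def write_annotation(ann: PointAnnotation, path: str | Path) -> Path:
    """Serialize to CSV (canonical) or a JSON mirror, by file suffix."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        payload = {
            "patient_id": ann.patient_id, "expert_id": ann.expert_id,
            "method": ann.method, "session": ann.session,
            "landmarks": {k: list(map(float, v))
                          for k, v in ann.landmarks.items()},
            "points": ann.points.tolist(),
            "plane_tags": ann.plane_tags,
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        ann.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_annotation(path: str | Path) -> PointAnnotation:
    path = Path(path)
    if not path.exists():
        raise AnnotationError(f"no such file: {path}")
    if path.suffix.lower() == ".json":
        return _annotation_from_json(path)
    try:
        df = pd.read_csv(path, dtype={"patient_id": str, "expert_id": str},
                         keep_default_na=False,
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc
    missing_cols = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing_cols:
        raise AnnotationError(f"{path}: missing columns {sorted(missing_cols)}")
    return annotation_from_frame(df)


def annotation_from_frame(df: pd.DataFrame) -> PointAnnotation:
    if df.empty:
        raise AnnotationError("empty annotation table")
    landmarks = {}
    for label in LANDMARK_LABELS:
        rows = df[df["label"] == label]
        if len(rows) == 0:
            raise AnnotationError(f"missing {label!r} landmark row")
        if len(rows) > 1:
            raise AnnotationError(f"duplicate {label!r} landmark rows")
        landmarks[label] = rows[["x_mm", "y_mm", "z_mm"]].to_numpy()[0]
    pts = df[df["label"] == "point"]
    tags = [t if t else None for t in pts["plane"].astype(str)] \
        if len(pts) else None
    first = df.iloc[0]
    return PointAnnotation(
        str(first["patient_id"]), str(first["expert_id"]),
        str(first["method"]), int(first["session"]),
        pts[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float),
        landmarks, plane_tags=tags,
    )


def _annotation_from_json(path: Path) -> PointAnnotation:
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationError(f"failed to parse {path}: {exc}") from exc
    known = {"patient_id", "expert_id", "method", "session",
             "landmarks", "points", "plane_tags"}
    extra = set(payload) - known
    if extra:
        log.info("%s: ignoring unknown keys %s", path.name, sorted(extra))
    try:
        return PointAnnotation(
            str(payload["patient_id"]), str(payload["expert_id"]),
            str(payload["method"]), int(payload["session"]),
            np.asarray(payload.get("points", []), dtype=float).reshape(-1, 3),
            {k: np.asarray(v, dtype=float)
             for k, v in payload.get("landmarks", {}).items()},
            plane_tags=payload.get("plane_tags"),
        )
    except KeyError as exc:
        raise AnnotationError(f"{path}: missing field {exc}") from exc


# ---------------------------------------------------------------------------
# Closest point on mesh — exact, vectorized over points x faces
# ---------------------------------------------------------------------------

def _closest_on_triangles(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Closest point on each candidate triangle for each query point.

    points: (N, 3); tri: (N, K, 3, 3) per-point candidates or (F, 3, 3)
    shared across points.  Returns (N, K, 3) / (N, F, 3).  Standard
    barycentric-region case analysis, fully vectorized.
    """
    if tri.ndim == 3:                               # shared face list
        tri = np.broadcast_to(tri[None], (len(points),) + tri.shape)
    a = tri[:, :, 0]                                # (N, K, 3)
    ab = tri[:, :, 1] - tri[:, :, 0]
    ac = tri[:, :, 2] - tri[:, :, 0]
    p = points[:, None, :]                          # (N, 1, 3)

    ap = p - a
    d1 = np.sum(ab * ap, axis=-1)
    d2 = np.sum(ac * ap, axis=-1)

    bp = p - (a + ab)
    d3 = np.sum(ab * bp, axis=-1)
    d4 = np.sum(ac * bp, axis=-1)

    cp = p - (a + ac)
    d5 = np.sum(ab * cp, axis=-1)
    d6 = np.sum(ac * cp, axis=-1)

    vc = d1 * d4 - d3 * d2
    vb = d5 * d2 - d1 * d6
    va = d3 * d6 - d5 * d4

    with np.errstate(divide="ignore", invalid="ignore"):
        v_ab = d1 / (d1 - d3)
        w_ac = d2 / (d2 - d6)
        w_bc = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        denom = 1.0 / (va + vb + vc)
        v_in = vb * denom
        w_in = vc * denom

    out = a + v_in[..., None] * ab + w_in[..., None] * ac     # interior default

    m_bc = (va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0)
    out = np.where(m_bc[..., None],
                   a + ab + w_bc[..., None] * (ac - ab), out)
    m_ac = (vb <= 0) & (d2 >= 0) & (d6 <= 0)
    out = np.where(m_ac[..., None], a + w_ac[..., None] * ac, out)
    m_ab = (vc <= 0) & (d1 >= 0) & (d3 <= 0)
    out = np.where(m_ab[..., None], a + v_ab[..., None] * ab, out)
    m_c = (d6 >= 0) & (d5 <= d6)
    out = np.where(m_c[..., None], a + ac, out)
    m_b = (d3 >= 0) & (d4 <= d3)
    out = np.where(m_b[..., None], a + ab, out)
    m_a = (d1 <= 0) & (d2 <= 0)
    out = np.where(m_a[..., None], a, out)
    return out


@dataclass
class SurfaceQuery:
    """Result of a closest-point query: one row per query point."""
    points: np.ndarray        # (N, 3) closest point on the surface
    distances: np.ndarray     # (N,) unsigned distance, mm
    face_indices: np.ndarray  # (N,) winning face (lowest index on ties)
    barycentric: np.ndarray   # (N, 3) coords within the winning face


def _pick_best(d2: np.ndarray, face_ids: np.ndarray) -> np.ndarray:
    """Row-wise argmin with ties broken toward the lowest face index."""
    best = d2.min(axis=1, keepdims=True)
    tied = d2 <= best + 1e-24
    masked = np.where(tied, face_ids, np.iinfo(np.int64).max)
    winner = masked.min(axis=1)
    # column of the winning face within this row
    return np.argmax(masked == winner[:, None], axis=1)


def _face_tree(mesh: TriangleMesh):
    """Cached KD-tree over face centroids + the max centroid-to-corner
    radius (used to certify that pruned faces cannot win)."""
    cached = getattr(mesh, "_face_tree_cache", None)
    if cached is not None:
        return cached
    from scipy.spatial import cKDTree
    tri = mesh.triangles()
    centroids = tri.mean(axis=1)
    radius = float(np.linalg.norm(tri - centroids[:, None, :],
                                  axis=2).max())
    cache = (cKDTree(centroids), radius)
    mesh._face_tree_cache = cache
    return cache


def closest_point_on_mesh(points: np.ndarray, mesh: TriangleMesh,
                          chunk: int = 256, k_candidates: int = 48
                          ) -> SurfaceQuery:
    """Exact point-to-surface minimum over all faces.

    A KD-tree over face centroids prunes the candidate set; the pruning is
    certified (a pruned face whose centroid lies further than the current
    best distance plus the max face radius cannot contain a closer point),
    with a full exhaustive scan as the fallback, so results are identical
    in value to brute force.  Ties go to the lowest face index.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if pts.size == 0:
        raise GeometryError("empty point set")
    if mesh.n_faces == 0:
        raise GeometryError("empty mesh")
    tri = mesh.triangles()
    n = len(pts)
    best_pts = np.empty((n, 3))
    best_d = np.empty(n)
    best_f = np.empty(n, dtype=np.int64)
    use_tree = mesh.n_faces > k_candidates + 16
    if use_tree:
        tree, face_radius = _face_tree(mesh)
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        p = pts[sl]
        if use_tree:
            dcent, cand_ids = tree.query(p, k=k_candidates)
            cand = _closest_on_triangles(p, tri[cand_ids])   # (m, K, 3)
            d2 = np.sum((cand - p[:, None, :]) ** 2, axis=-1)
            col = _pick_best(d2, cand_ids)
            rows = np.arange(len(p))
            d_best = np.sqrt(d2[rows, col])
            # certify: every pruned face has centroid dist >= kth centroid
            # dist, hence triangle dist >= that - face_radius
            uncertain = d_best > dcent[:, -1] - face_radius
            best_pts[sl] = cand[rows, col]
            best_d[sl] = d_best
            best_f[sl] = cand_ids[rows, col]
            if uncertain.any():
                idx_unc = np.flatnonzero(uncertain) + start
                for j in idx_unc:
                    cand_j = _closest_on_triangles(pts[j:j + 1], tri)
                    d2_j = np.sum((cand_j - pts[j][None, None, :]) ** 2,
                                  axis=-1)
                    cj = _pick_best(d2_j, np.arange(mesh.n_faces)[None, :])
                    best_pts[j] = cand_j[0, cj[0]]
                    best_d[j] = np.sqrt(d2_j[0, cj[0]])
                    best_f[j] = cj[0]
        else:
            cand = _closest_on_triangles(p, tri)             # (m, F, 3)
            d2 = np.sum((cand - p[:, None, :]) ** 2, axis=-1)
            col = _pick_best(d2, np.arange(mesh.n_faces)[None, :])
            rows = np.arange(len(p))
            best_pts[sl] = cand[rows, col]
            best_d[sl] = np.sqrt(d2[rows, col])
            best_f[sl] = col
    bary = _barycentric(best_pts, tri[best_f])
    return SurfaceQuery(best_pts, best_d, best_f, bary)


def _barycentric(points: np.ndarray, tri: np.ndarray) -> np.ndarray:
    """Barycentric coordinates of points known to lie on their triangles."""
    v0 = tri[:, 1] - tri[:, 0]
    v1 = tri[:, 2] - tri[:, 0]
    v2 = points - tri[:, 0]
    d00 = np.sum(v0 * v0, axis=1)
    d01 = np.sum(v0 * v1, axis=1)
    d11 = np.sum(v1 * v1, axis=1)
    d20 = np.sum(v2 * v0, axis=1)
    d21 = np.sum(v2 * v1, axis=1)
    denom = d00 * d11 - d01 * d01
    v = (d11 * d20 - d01 * d21) / denom
    w = (d00 * d21 - d01 * d20) / denom
    u = 1.0 - v - w
    bary = np.clip(np.stack([u, v, w], axis=1), 0.0, 1.0)
    return bary / bary.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Procrustes / similarity alignment
# ---------------------------------------------------------------------------

@dataclass
class SimilarityTransform:
    """x -> scale * rotation @ x + translation (no reflection)."""
    rotation: np.ndarray = field(
        default_factory=lambda: np.eye(3))     # (3, 3), det = +1
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scale: float = 1.0

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return self.scale * pts @ self.rotation.T + self.translation

    def inverse(self) -> "SimilarityTransform":
        r_inv = self.rotation.T
        return SimilarityTransform(
            rotation=r_inv,
            translation=-r_inv @ self.translation / self.scale,
            scale=1.0 / self.scale,
        )

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """self ∘ other (apply ``other`` first)."""
        return SimilarityTransform(
            rotation=self.rotation @ other.rotation,
            translation=self.scale * self.rotation @ other.translation
            + self.translation,
            scale=self.scale * other.scale,
        )


def procrustes_align(source: np.ndarray, target: np.ndarray,
                     allow_scale: bool = False) -> SimilarityTransform:
    """Least-squares rigid (optionally similarity) alignment source -> target.

    Kabsch with the reflection guard; requires >= 3 corresponded,
    non-collinear points.
    """
    src = np.atleast_2d(np.asarray(source, dtype=np.float64))
    tgt = np.atleast_2d(np.asarray(target, dtype=np.float64))
    if src.shape != tgt.shape:
        raise GeometryError("source/target must have equal shapes")
    if len(src) < 3:
        raise GeometryError("need at least 3 corresponded points")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    a, b = src - mu_s, tgt - mu_t
    if np.linalg.matrix_rank(a, tol=1e-9 * max(1.0, np.abs(a).max())) < 2:
        raise GeometryError("source points are collinear or coincident")
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    corr = np.array([1.0, 1.0, d])
    rot = vt.T @ np.diag(corr) @ u.T
    scale = float((s * corr).sum() / (a ** 2).sum()) if allow_scale else 1.0
    trans = mu_t - scale * rot @ mu_s
    return SimilarityTransform(rotation=rot, translation=trans, scale=scale)
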