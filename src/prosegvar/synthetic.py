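"""Synthetic multi-expert segmentation cohort.

Emulates the observational design of a multi-operator prostate TRUS
segmentation study: prostate-like closed surfaces (~30-60 mm extents),
several experts who annotate them manually (many points on axial slices
plus one medial sagittal and coronal slice, fewer near apex/base) or
semi-automatically (three landmarks, then iterative point-driven refinement
of a shape-prior mesh), with repeat ("bis") sessions, per-point Gaussian
placement noise and a smooth systematic per-expert bias field.  The ground
truth deliberately contains out-of-subspace surface detail so a
strict-subspace reconstruction cannot be exact while the deformable one
can — the mechanism behind the strict-vs-soft variability gap.

Everything is deterministic under (config, seed); the manifest records both
plus content hashes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.special import sph_harm_y

from .geometry import (
    GeometryError,
    PointAnnotation,
    SegmentationRecord,
    TriangleMesh,
    closest_point_on_mesh,
    read_annotation,
    read_mesh,
    write_annotation,
    write_mesh,
)
from .shape_model import (
    ShapeCoefficients,
    StatisticalShapeModel,
    StrictFitResult,
    build_ssm,
)
from .soft_ssm import SoftFitConfig, SoftSSMFitter


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-design and noise parameters of the simulated cohort.

    Defaults mirror the emulated study: 100 patients, 4 experts, a shared
    manual subset of 12, 5 bis patients, manual point counts spanning the
    observed per-expert medians (90-496), semi-automatic counts 39-77,
    ~1 mm placement noise, 2 mm axial slice spacing, and markedly sparser
    annotation near the apex/base poles.
    """
    n_patients: int = 100
    n_experts: int = 4
    seed: int = 0
    manual_points_range: tuple[int, int] = (90, 496)
    semi_auto_points_range: tuple[int, int] = (39, 77)
    point_noise_sd_mm: float = 1.0
    expert_bias_sd_mm: float = 1.0
    pole_sparsity: float = 0.6
    slice_spacing_mm: float = 2.0
    shared_subset_size: int = 12
    bis_subset_size: int = 5
    max_manual_per_expert: int = 25
    out_of_subspace_mm: float = 1.0
    ssm_n_train: int = 50
    ssm_subdivisions: int = 3

    def __post_init__(self) -> None:
        for rng_ in (self.manual_points_range, self.semi_auto_points_range):
            if not (0 < rng_[0] <= rng_[1]):
                raise GeometryError("point-count ranges must be ordered > 0")
        if not 0 <= self.pole_sparsity < 1:
            raise GeometryError("pole_sparsity must be in [0, 1)")
        if self.shared_subset_size > self.n_patients:
            raise GeometryError("shared subset larger than cohort")
        if self.bis_subset_size > self.shared_subset_size:
            raise GeometryError("bis subset must lie within the shared subset")
        if self.n_experts < 1 or self.n_patients < 1:
            raise GeometryError("need at least one expert and one patient")


# ---------------------------------------------------------------------------
# Band-limited radial fields on the sphere
# ---------------------------------------------------------------------------

def _real_sph_harm(deg: int, order: int, dirs: np.ndarray) -> np.ndarray:
    """Real spherical harmonic evaluated at unit directions."""
    theta = np.arccos(np.clip(dirs[:, 2], -1.0, 1.0))
    phi = np.arctan2(dirs[:, 1], dirs[:, 0])
    y = sph_harm_y(deg, abs(order), theta, phi)
    if order > 0:
        return np.sqrt(2.0) * (-1.0) ** order * y.real
    if order < 0:
        return np.sqrt(2.0) * (-1.0) ** order * y.imag
    return y.real


@dataclass
class RadialField:
    """Σ c_lm Y_lm over a small set of (degree, order) terms, rescaled to a
    target amplitude (max |field| on the evaluation directions)."""
    terms: list[tuple[int, int, float]]
    amplitude: float
    norm: str = "max"   # "max" or "rms"

    def __call__(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        f = np.zeros(len(dirs))
        for deg, order, coeff in self.terms:
            f += coeff * _real_sph_harm(deg, order, dirs)
        scale = np.abs(f).max() if self.norm == "max" \
            else np.sqrt(np.mean(f ** 2))
        if scale < 1e-12:
            return np.zeros(len(dirs))
        return f * (self.amplitude / scale)


def random_radial_field(rng: np.random.Generator, degrees,
                        amplitude: float, n_terms: int | None = None,
                        norm: str = "max") -> RadialField:
    pool = [(deg, order) for deg in degrees for order in range(-deg, deg + 1)]
    if n_terms is not None and n_terms < len(pool):
        idx = rng.choice(len(pool), size=n_terms, replace=False)
        pool = [pool[i] for i in sorted(idx)]
    coeffs = rng.normal(size=len(pool))
    return RadialField([(d, o, c) for (d, o), c in zip(pool, coeffs)],
                       amplitude, norm=norm)


# ---------------------------------------------------------------------------
# Toy shape model and ground-truth patients
# ---------------------------------------------------------------------------

def build_toy_ssm(seed: int, n_train: int = 50, subdivisions: int = 3,
                  variance_retained: float = 0.95,
                  perturb_amplitude_mm: float = 3.0
                  ) -> StatisticalShapeModel:
    """SSM trained on triaxial ellipsoids (semi-axes U(15, 30) mm) with
    band-limited (degree <= 4) radial perturbations on a shared icosphere
    topology; apex/base/posterior landmark vertices recorded on the mean."""
    if n_train < 10:
        raise GeometryError("need at least 10 training shapes")
    rng = np.random.default_rng(seed)
    sphere = trimesh.creation.icosphere(subdivisions=subdivisions, radius=1.0)
    dirs = np.asarray(sphere.vertices, dtype=float)
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    faces = np.asarray(sphere.faces, dtype=np.int64)
    meshes = []
    for _ in range(n_train):
        axes = rng.uniform(15.0, 30.0, size=3)
        base = dirs * axes
        if perturb_amplitude_mm > 0:
            amp = rng.uniform(0.5, perturb_amplitude_mm)
            fld = random_radial_field(rng, degrees=range(1, 5),
                                      amplitude=amp, n_terms=8)
            base = base + dirs * fld(dirs)[:, None]
        meshes.append(TriangleMesh(base, faces.copy(), topology_id="ssm"))
    ssm = build_ssm(meshes, variance_retained=variance_retained)
    mv = ssm.mean_mesh.vertices
    ssm.landmark_indices = {
        "apex": int(np.argmax(mv[:, 2])),
        "base": int(np.argmin(mv[:, 2])),
        "posterior": int(np.argmin(mv[:, 1])),
    }
    return ssm


def simulate_patient(ssm: StatisticalShapeModel, seed: int,
                     out_of_subspace_mm: float = 1.0,
                     pose_rotation_deg: float = 10.0,
                     pose_translation_mm: float = 5.0) -> TriangleMesh:
    """Ground-truth surface: a model sample (b ~ N(0, λ), clamped at ±3√λ)
    plus a high-frequency (degree 5-7) radial detail field the model cannot
    represent, under a small random rigid pose."""
    rng = np.random.default_rng(seed)
    sd = ssm.mode_sd()
    b = np.clip(rng.normal(size=ssm.n_modes) * sd, -3 * sd, 3 * sd)
    verts = ssm.shape_vertices(b)
    centroid = verts.mean(axis=0)
    if out_of_subspace_mm > 0:
        u = verts - centroid
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        fld = random_radial_field(rng, degrees=range(5, 8),
                                  amplitude=out_of_subspace_mm, n_terms=10,
                                  norm="rms")
        verts = verts + u * fld(u)[:, None]
    angle = np.deg2rad(rng.uniform(0, pose_rotation_deg))
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = trimesh.transformations.rotation_matrix(angle, axis)[:3, :3]
    shift = rng.uniform(-pose_translation_mm, pose_translation_mm, size=3)
    verts = (verts - centroid) @ rot.T + centroid + shift
    return TriangleMesh(verts, ssm.mean_mesh.faces.copy(), topology_id="ssm")


# ---------------------------------------------------------------------------
# Expert behaviour
# ---------------------------------------------------------------------------

@dataclass
class ExpertProfile:
    """A simulated rater: a smooth systematic radial bias field (where the
    expert consistently sees the boundary relative to truth) applied on top
    of iid placement noise."""
    expert_id: str
    bias_field: RadialField

    def bias(self, dirs: np.ndarray) -> np.ndarray:
        return self.bias_field(dirs)


def make_expert(rng: np.random.Generator, expert_id: str,
                bias_sd_mm: float) -> ExpertProfile:
    # Regional-scale bands (degrees 3-5): raters disagree systematically on
    # specific zones of the gland, not on near-global tilts; such fields
    # also lie outside the span of the global shape prior, so rater bias
    # contributes to inter-observer distances for every meshing method
    # rather than being absorbed by the model subspace.
    fld = random_radial_field(rng, degrees=range(3, 6), amplitude=bias_sd_mm,
                              n_terms=3, norm="rms")
    return ExpertProfile(expert_id, fld)


def _place_landmarks(truth: TriangleMesh, expert: ExpertProfile,
                     noise_sd: float, rng: np.random.Generator
                     ) -> dict[str, np.ndarray]:
    v = truth.vertices
    centroid = v.mean(axis=0)
    ideal = {
        "apex": v[np.argmax(v[:, 2])],
        "base": v[np.argmin(v[:, 2])],
        "posterior": v[np.argmin(v[:, 1])],
    }
    out = {}
    for label, p in ideal.items():
        u = p - centroid
        u /= np.linalg.norm(u)
        offset = expert.bias(u[None, :])[0] + rng.normal(0.0, noise_sd)
        out[label] = p + u * offset
    return out


def _plane_contour(truth_tm: trimesh.Trimesh, normal, origin) -> np.ndarray:
    """(S, 2, 3) intersection segments of the surface with a plane."""
    seg = trimesh.intersections.mesh_plane(truth_tm, normal, origin)
    return seg if len(seg) else np.empty((0, 2, 3))


def _sample_on_segments(segments: np.ndarray, n: int,
                        rng: np.random.Generator) -> np.ndarray:
    lengths = np.linalg.norm(segments[:, 1] - segments[:, 0], axis=1)
    total = lengths.sum()
    if total <= 0 or n == 0:
        return np.empty((0, 3))
    cum = np.cumsum(lengths)
    u = rng.uniform(0, total, size=n)
    idx = np.searchsorted(cum, u)
    frac = (u - (cum[idx] - lengths[idx])) / lengths[idx]
    return segments[idx, 0] + frac[:, None] * (segments[idx, 1]
                                               - segments[idx, 0])


def simulate_manual_annotation(truth: TriangleMesh, expert: ExpertProfile,
                               cfg: CohortConfig, seed: int,
                               patient_id: str = "p",
                               session: int = 0) -> PointAnnotation:
    """Plane-constrained noisy manual annotation.

    Points live on axial slices at ``slice_spacing_mm`` plus one medial
    sagittal and one medial coronal slice (10% of the budget each); per-slice
    allocation is proportional to contour length, down-weighted by
    ``pole_sparsity`` inside the apex/base z-caps; each point is displaced
    within its plane by iid noise and the expert's radial bias field.
    """
    rng = np.random.default_rng(seed)
    tm = truth.to_trimesh()
    centroid = truth.vertices.mean(axis=0)
    zmin, zmax = truth.vertices[:, 2].min(), truth.vertices[:, 2].max()
    extent = zmax - zmin
    cap_lo = zmin + 0.2 * extent      # base cap below, apex cap above
    cap_hi = zmax - 0.2 * extent

    n_total = int(rng.integers(cfg.manual_points_range[0],
                               cfg.manual_points_range[1] + 1))
    n_sag = max(1, int(round(0.10 * n_total)))
    n_cor = max(1, int(round(0.10 * n_total)))
    n_axial = n_total - n_sag - n_cor

    planes: list[tuple[str, np.ndarray, np.ndarray]] = [
        ("sagittal", np.array([1.0, 0, 0]), centroid),
        ("coronal", np.array([0, 1.0, 0]), centroid),
    ]
    margin = 0.03 * extent
    z_levels = np.arange(zmin + margin, zmax - margin + 1e-9,
                         cfg.slice_spacing_mm)
    axial_contours = []
    for z in z_levels:
        seg = _plane_contour(tm, np.array([0, 0, 1.0]),
                             np.array([centroid[0], centroid[1], z]))
        if len(seg):
            axial_contours.append((z, seg))
    if not axial_contours:
        raise GeometryError("no axial contour intersections found")

    weights = []
    for z, seg in axial_contours:
        length = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1).sum()
        w = length * ((1.0 - cfg.pole_sparsity)
                      if (z < cap_lo or z > cap_hi) else 1.0)
        weights.append(w)
    weights = np.asarray(weights)
    weights /= weights.sum()
    alloc = rng.multinomial(n_axial, weights)

    pts, tags = [], []
    for (z, seg), n in zip(axial_contours, alloc):
        pts.append(_sample_on_segments(seg, int(n), rng))
        tags.extend(["axial"] * int(n))
    for (label, normal, origin), n in zip(planes, (n_sag, n_cor)):
        seg = _plane_contour(tm, normal, origin)
        # the medial slices cross the poles: thin them there too
        got = _sample_on_segments(seg, 4 * n, rng)
        in_cap = (got[:, 2] < cap_lo) | (got[:, 2] > cap_hi)
        keep = ~in_cap | (rng.uniform(size=len(got)) > cfg.pole_sparsity)
        got = got[keep][:n]
        pts.append(got)
        tags.extend([label] * len(got))
    points = np.vstack([p for p in pts if len(p)])

    # Placement error acts along the local surface normal: boundary
    # ambiguity and slice thickness displace the perceived capsule
    # outward/inward, so the error leaves the viewing plane slightly.
    query = closest_point_on_mesh(points, truth)
    tm_normals = np.asarray(tm.face_normals, dtype=float)
    normals = tm_normals[query.face_indices]
    u_full = points - centroid
    u_full /= np.linalg.norm(u_full, axis=1, keepdims=True)
    # orient normals outward (away from the centroid)
    flip = np.sign(np.sum(normals * u_full, axis=1))
    flip[flip == 0] = 1.0
    normals *= flip[:, None]
    offsets = expert.bias(u_full) + rng.normal(0.0, cfg.point_noise_sd_mm,
                                               size=len(points))
    points = points + normals * offsets[:, None]

    landmarks = _place_landmarks(truth, expert, cfg.point_noise_sd_mm, rng)
    return PointAnnotation(patient_id, expert.expert_id, "manual", session,
                           points, landmarks, plane_tags=tags)


def simulate_semiauto_session(truth: TriangleMesh,
                              ssm: StatisticalShapeModel,
                              expert: ExpertProfile, cfg: CohortConfig,
                              seed: int, patient_id: str = "p",
                              session: int = 0,
                              soft_cfg: SoftFitConfig | None = None,
                              batch_size: int = 6,
                              n_candidates: int = 300
                              ) -> SegmentationRecord:
    """Interactive semi-automatic session: landmarks initialize a shape-prior
    mesh, then correction points are placed where the expert perceives the
    largest residual error, in batches, each followed by a deformable-model
    update."""
    rng = np.random.default_rng(seed)
    soft_cfg = soft_cfg or SoftFitConfig(max_iter=4)
    landmarks = _place_landmarks(truth, expert, cfg.point_noise_sd_mm, rng)
    ann0 = PointAnnotation(patient_id, expert.expert_id, "semi_auto", session,
                           np.empty((0, 3)), landmarks)
    # shape-prior initialization: the mean shape posed on the landmarks
    # (three points cannot determine mode loadings)
    from .geometry import procrustes_align
    pose = procrustes_align(ssm.landmark_positions(), ann0.landmark_array())
    prior = TriangleMesh(pose.apply(ssm.mean_mesh.vertices),
                         ssm.mean_mesh.faces.copy(),
                         topology_id=ssm.mean_mesh.topology_id)
    strict0 = StrictFitResult(
        ShapeCoefficients(np.zeros(ssm.n_modes), pose), prior, [], True)
    fitter = SoftSSMFitter(ssm, ann0, soft_cfg, strict=strict0)
    fitter.refine()

    # the boundary as this expert perceives it: surface samples + bias + noise
    tm = truth.to_trimesh()
    cand, _ = trimesh.sample.sample_surface(tm, n_candidates,
                                            seed=int(rng.integers(2 ** 31)))
    cand = np.asarray(cand, dtype=float)
    # experts under-annotate the apex/base caps in this mode too
    z = truth.vertices[:, 2]
    extent = z.max() - z.min()
    in_cap = (cand[:, 2] < z.min() + 0.2 * extent) | \
        (cand[:, 2] > z.max() - 0.2 * extent)
    cand = cand[~in_cap | (rng.uniform(size=len(cand))
                           > cfg.pole_sparsity)]
    centroid = truth.vertices.mean(axis=0)
    u = cand - centroid
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    cand = cand + u * (expert.bias(u)
                       + rng.normal(0, cfg.point_noise_sd_mm,
                                    len(cand)))[:, None]

    n_points = int(rng.integers(cfg.semi_auto_points_range[0],
                                cfg.semi_auto_points_range[1] + 1))
    n_corr = max(0, n_points - 3)
    available = np.ones(len(cand), dtype=bool)
    placed = 0
    refit_done = False
    while placed < n_corr and available.any():
        d = closest_point_on_mesh(cand[available], fitter.mesh).distances
        take = min(batch_size, n_corr - placed)
        worst = np.argsort(d)[::-1][:take]
        idx_avail = np.flatnonzero(available)[worst]
        if not refit_done and placed + take >= batch_size:
            # enough points to determine the mode loadings: re-run the full
            # two-stage fit (subspace solve + deformation) on everything
            # accumulated, as the shape-constrained model keeps the prior
            # in play throughout the interaction
            acc = np.vstack([fitter.points[3:], cand[idx_avail]])
            ann_acc = PointAnnotation(patient_id, expert.expert_id,
                                      "semi_auto", session, acc, landmarks)
            fitter = SoftSSMFitter(ssm, ann_acc, soft_cfg)
            fitter.refine()
            refit_done = True
        else:
            fitter.add_points(cand[idx_avail])
        available[idx_avail] = False
        placed += take
    mesh = fitter.mesh
    ann = PointAnnotation(patient_id, expert.expert_id, "semi_auto", session,
                          fitter.points[3:], landmarks)
    return SegmentationRecord(ann, mesh, "semi_auto_soft_SSM")


# ---------------------------------------------------------------------------
# Cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SessionSpec:
    patient_id: str
    expert_id: str
    method: str
    session: int


def plan_cohort(cfg: CohortConfig) -> list[SessionSpec]:
    """Deterministic allocation implementing the study design: a shared
    manual subset segmented by all experts, per-expert exclusive manual
    patients (capped), bis repeats on a sub-subset, and semi-automatic
    sessions covering every patient by >= 2 experts."""
    patients = [f"p{i:03d}" for i in range(cfg.n_patients)]
    experts = [chr(ord("A") + i) for i in range(cfg.n_experts)]
    shared = patients[:cfg.shared_subset_size]
    bis = patients[:cfg.bis_subset_size]
    exclusive: dict[str, list[str]] = {e: [] for e in experts}
    capacity = max(0, cfg.max_manual_per_expert - len(shared))
    for k, p in enumerate(patients[cfg.shared_subset_size:]):
        e = experts[k % len(experts)]
        if len(exclusive[e]) < capacity:
            exclusive[e].append(p)
    plan: list[SessionSpec] = []
    for e in experts:
        for p in shared + exclusive[e]:
            plan.append(SessionSpec(p, e, "manual", 0))
        for p in bis:
            plan.append(SessionSpec(p, e, "manual", 1))
    # semi-auto: all experts on the shared subset; two experts per other
    # patient (rotating pairs) so every patient has a pairwise comparison
    for e in experts:
        for p in shared:
            plan.append(SessionSpec(p, e, "semi_auto", 0))
    for k, p in enumerate(patients[cfg.shared_subset_size:]):
        if len(experts) >= 2:
            e1 = experts[k % len(experts)]
            e2 = experts[(k + 1) % len(experts)]
            plan.append(SessionSpec(p, e1, "semi_auto", 0))
            plan.append(SessionSpec(p, e2, "semi_auto", 0))
        else:
            plan.append(SessionSpec(p, experts[0], "semi_auto", 0))
    # semi-auto bis: two experts (or all if fewer) repeat the bis subset
    for e in experts[1:3] if len(experts) >= 3 else experts[:1]:
        for p in bis:
            plan.append(SessionSpec(p, e, "semi_auto", 1))
    return plan


@dataclass
class CohortData:
    config: CohortConfig
    ssm: StatisticalShapeModel
    truths: dict[str, TriangleMesh]
    experts: list[ExpertProfile]
    records: list[SegmentationRecord]
    manifest: dict = field(default_factory=dict)


def generate_cohort(cfg: CohortConfig,
                    soft_cfg: SoftFitConfig | None = None,
                    progress: bool = False) -> CohortData:
    """Simulate the full design: ground truths, expert profiles, manual and
    semi-automatic sessions, and a content-hashed manifest."""
    master = np.random.default_rng(cfg.seed)
    ssm_seed = int(master.integers(2 ** 31))
    ssm = build_toy_ssm(ssm_seed, n_train=cfg.ssm_n_train,
                        subdivisions=cfg.ssm_subdivisions)
    plan = plan_cohort(cfg)
    patients = sorted({s.patient_id for s in plan})
    expert_ids = sorted({s.expert_id for s in plan})
    truths = {
        p: simulate_patient(ssm, int(master.integers(2 ** 31)),
                            out_of_subspace_mm=cfg.out_of_subspace_mm)
        for p in patients
    }
    experts = [make_expert(master, e, cfg.expert_bias_sd_mm)
               for e in expert_ids]
    by_id = {e.expert_id: e for e in experts}
    records: list[SegmentationRecord] = []
    for i, spec in enumerate(plan):
        seed = int(master.integers(2 ** 31))
        if progress:
            print(f"[{i + 1}/{len(plan)}] {spec.method} {spec.patient_id} "
                  f"expert {spec.expert_id} session {spec.session}")
        if spec.method == "manual":
            ann = simulate_manual_annotation(
                truths[spec.patient_id], by_id[spec.expert_id], cfg, seed,
                patient_id=spec.patient_id, session=spec.session)
            records.append(SegmentationRecord(ann, None, "manual_points"))
        else:
            records.append(simulate_semiauto_session(
                truths[spec.patient_id], ssm, by_id[spec.expert_id], cfg,
                seed, patient_id=spec.patient_id, session=spec.session,
                soft_cfg=soft_cfg))
    cohort = CohortData(cfg, ssm, truths, experts, records)
    cohort.manifest = build_manifest(cohort)
    return cohort


def _hash_array(a: np.ndarray) -> str:
    return hashlib.sha256(
        np.ascontiguousarray(np.round(a, 6)).tobytes()).hexdigest()[:16]


def build_manifest(cohort: CohortData) -> dict:
    sessions = []
    for rec in cohort.records:
        a = rec.annotation
        entry = {
            "patient_id": a.patient_id, "expert_id": a.expert_id,
            "method": a.method, "session": a.session,
            "n_points": int(a.n_points) + 3,
            "points_hash": _hash_array(a.all_points()),
        }
        if rec.mesh is not None:
            entry["mesh_hash"] = _hash_array(rec.mesh.vertices)
        sessions.append(entry)
    body = {
        "config": asdict(cohort.config),
        "n_records": len(cohort.records),
        "truth_hashes": {p: _hash_array(m.vertices)
                         for p, m in sorted(cohort.truths.items())},
        "sessions": sessions,
    }
    canonical = json.dumps(body, sort_keys=True)
    body["manifest_hash"] = hashlib.sha256(canonical.encode()).hexdigest()
    return body


def save_cohort(cohort: CohortData, out_dir: str | Path) -> Path:
    """Persist annotations (CSV), semi-automatic and truth meshes (PLY) and
    the manifest (JSON)."""
    out = Path(out_dir)
    (out / "annotations").mkdir(parents=True, exist_ok=True)
    (out / "meshes").mkdir(exist_ok=True)
    (out / "truths").mkdir(exist_ok=True)
    cohort.ssm.save(out / "ssm")
    for p, m in cohort.truths.items():
        write_mesh(m, out / "truths" / f"{p}.ply")
    for rec in cohort.records:
        a = rec.annotation
        stem = f"{a.patient_id}_{a.expert_id}_{a.method}_s{a.session}"
        write_annotation(a, out / "annotations" / f"{stem}.csv")
        if rec.mesh is not None:
            write_mesh(rec.mesh, out / "meshes" / f"{stem}.ply")
    (out / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1))
    return out


def load_cohort(cohort_dir: str | Path) -> CohortData:
    """Load a persisted cohort directory (expert bias profiles are not
    persisted and are not needed to analyse an existing cohort)."""
    root = Path(cohort_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    raw_cfg = dict(manifest["config"])
    for key in ("manual_points_range", "semi_auto_points_range"):
        raw_cfg[key] = tuple(raw_cfg[key])
    cfg = CohortConfig(**raw_cfg)
    ssm = StatisticalShapeModel.load(root / "ssm")
    truths = {p.stem: read_mesh(p)
              for p in sorted((root / "truths").glob("*.ply"))}
    for m in truths.values():
        m.topology_id = "ssm"
    records = []
    for ann_path in sorted((root / "annotations").glob("*.csv")):
        ann = read_annotation(ann_path)
        mesh_path = root / "meshes" / (ann_path.stem + ".ply")
        if mesh_path.exists():
            mesh = read_mesh(mesh_path)
            mesh.topology_id = "ssm"
            records.append(SegmentationRecord(ann, mesh,
                                              "semi_auto_soft_SSM"))
        else:
            records.append(SegmentationRecord(ann, None, "manual_points"))
    cohort = CohortData(cfg, ssm, truths, [], records)
    cohort.manifest = manifest
    return cohort
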