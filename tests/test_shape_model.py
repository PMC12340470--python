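import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from prosegvar.geometry import GeometryError, PointAnnotation
from prosegvar.metrics import asd_mesh_to_mesh
from prosegvar.shape_model import (
    ShapeCoefficients,
    StatisticalShapeModel,
    build_ssm,
    fit_ssm_to_points,
    generalized_procrustes,
    sample_ssm,
    subspace_residual,
)
from prosegvar.synthetic import build_toy_ssm

from .conftest import icosphere, surface_points


def _training_meshes(n, seed, subdivisions=2):
    rng = np.random.default_rng(seed)
    base = icosphere(1.0, subdivisions)
    dirs = base.vertices / np.linalg.norm(base.vertices, axis=1,
                                          keepdims=True)
    return [base.with_vertices(dirs * rng.uniform(15, 30, 3))
            for _ in range(n)]


class TestBuildSSM:
    def test_identical_training_set_has_no_modes(self):
        mesh = icosphere(20.0, 2)
        ssm = build_ssm([mesh.copy() for _ in range(5)])
        assert ssm.n_modes == 0
        np.testing.assert_allclose(ssm.mean_mesh.vertices, mesh.vertices,
                                   atol=1e-9)

    def test_two_distinct_meshes_give_one_mode(self):
        meshes = _training_meshes(2, seed=0)
        ssm = build_ssm(meshes, variance_retained=1.0)
        assert ssm.n_modes == 1

    def test_pca_completeness_on_training_shapes(self):
        """With all modes retained, every (aligned) training shape is
        reconstructed exactly."""
        meshes = _training_meshes(20, seed=1)
        ssm = build_ssm(meshes, variance_retained=1.0, align=False)
        shapes = np.stack([m.vertices for m in meshes])
        shapes -= shapes.mean(axis=1, keepdims=True)
        mean = shapes.mean(axis=0)
        np.testing.assert_allclose(ssm.mean_mesh.vertices, mean, atol=1e-9)
        for v in shapes:
            b = ssm.project(v)
            np.testing.assert_allclose(ssm.shape_vertices(b), v, atol=1e-6)

    def test_variance_retention_threshold(self):
        meshes = _training_meshes(30, seed=2)
        ssm = build_ssm(meshes, variance_retained=0.95)
        full = build_ssm(meshes, variance_retained=1.0)
        total = full.eigenvalues.sum()
        assert ssm.eigenvalues.sum() / total >= 0.95
        if ssm.n_modes > 1:  # minimality: one fewer mode falls short
            assert ssm.eigenvalues[:-1].sum() / total < 0.95

    def test_modes_are_orthonormal(self, toy_ssm):
        gram = toy_ssm.modes.T @ toy_ssm.modes
        np.testing.assert_allclose(gram, np.eye(toy_ssm.n_modes), atol=1e-8)

    def test_topology_mismatch_rejected(self):
        a = icosphere(20.0, 2)
        b = icosphere(20.0, 1)
        with pytest.raises(GeometryError):
            build_ssm([a, b])

    def test_roundtrip_serialization(self, toy_ssm, tmp_path):
        toy_ssm.save(tmp_path / "ssm")
        back = StatisticalShapeModel.load(tmp_path / "ssm")
        np.testing.assert_allclose(back.mean_mesh.vertices,
                                   toy_ssm.mean_mesh.vertices)
        np.testing.assert_allclose(back.modes, toy_ssm.modes)
        np.testing.assert_allclose(back.eigenvalues, toy_ssm.eigenvalues)
        assert back.landmark_indices == toy_ssm.landmark_indices


class TestSampleSSM:
    def test_zero_coefficients_give_mean(self, toy_ssm):
        mesh = sample_ssm(toy_ssm, ShapeCoefficients(
            np.zeros(toy_ssm.n_modes)))
        np.testing.assert_allclose(mesh.vertices,
                                   toy_ssm.mean_mesh.vertices)

    def test_projection_recovers_coefficients(self, toy_ssm):
        b = np.zeros(toy_ssm.n_modes)
        b[0] = np.sqrt(toy_ssm.eigenvalues[0])
        mesh = sample_ssm(toy_ssm, ShapeCoefficients(b))
        np.testing.assert_allclose(toy_ssm.project(mesh.vertices), b,
                                   atol=1e-9)

    def test_wrong_length_rejected(self, toy_ssm):
        with pytest.raises(GeometryError):
            sample_ssm(toy_ssm, ShapeCoefficients(
                np.zeros(toy_ssm.n_modes + 1)))

    def test_sample_covariance_converges_to_model(self, toy_ssm):
        """Vertex covariance of model draws matches modes diag(λ) modesᵀ,
        checked in mode space at n = 2000."""
        rng = np.random.default_rng(7)
        sd = toy_ssm.mode_sd()
        draws = rng.normal(size=(2000, toy_ssm.n_modes)) * sd
        recovered = np.stack([
            toy_ssm.project(sample_ssm(toy_ssm,
                                       ShapeCoefficients(b)).vertices)
            for b in draws])
        emp = np.cov(recovered.T)
        np.testing.assert_allclose(np.diag(emp), toy_ssm.eigenvalues,
                                   rtol=0.15)
        off = emp - np.diag(np.diag(emp))
        assert np.abs(off).max() < 0.1 * toy_ssm.eigenvalues[0]


def _annotation_from_shape(ssm, mesh, n_points, seed,
                           transform=None) -> PointAnnotation:
    pts = surface_points(mesh, n_points, seed)
    lmk = {k: mesh.vertices[ssm.landmark_indices[k]].copy()
           for k in ("apex", "base", "posterior")}
    if transform is not None:
        pts = transform.apply(pts)
        lmk = {k: transform.apply(v[None])[0] for k, v in lmk.items()}
    return PointAnnotation("p", "A", "manual", 0, pts, lmk)


class TestStrictFit:
    def test_recovers_model_coefficients(self, toy_ssm):
        """200 noiseless samples of a model shape pin the loadings."""
        rng = np.random.default_rng(3)
        b_true = rng.normal(size=toy_ssm.n_modes) * toy_ssm.mode_sd() * 0.8
        truth = sample_ssm(toy_ssm, ShapeCoefficients(b_true))
        ann = _annotation_from_shape(toy_ssm, truth, 200, seed=4)
        res = fit_ssm_to_points(toy_ssm, ann)
        err = np.abs(res.coefficients.b - b_true) / toy_ssm.mode_sd()
        assert err.max() < 0.02
        assert asd_mesh_to_mesh(res.mesh, truth) < 0.1

    def test_mean_shape_points_give_zero_coefficients(self, toy_ssm):
        ann = _annotation_from_shape(toy_ssm, toy_ssm.mean_mesh, 150, seed=5)
        res = fit_ssm_to_points(toy_ssm, ann)
        assert np.abs(res.coefficients.b).max() < \
            0.02 * toy_ssm.mode_sd().max()

    def test_fitted_mesh_lies_in_subspace(self, toy_ssm):
        rng = np.random.default_rng(6)
        b_true = rng.normal(size=toy_ssm.n_modes) * toy_ssm.mode_sd()
        truth = sample_ssm(toy_ssm, ShapeCoefficients(b_true))
        ann = _annotation_from_shape(toy_ssm, truth, 60, seed=7)
        res = fit_ssm_to_points(toy_ssm, ann)
        assert subspace_residual(toy_ssm, res.mesh,
                                 res.coefficients.pose) < 1e-6

    def test_objective_trace_nonincreasing(self, toy_ssm):
        truth = sample_ssm(toy_ssm, ShapeCoefficients(
            0.5 * toy_ssm.mode_sd()))
        ann = _annotation_from_shape(toy_ssm, truth, 80, seed=8)
        res = fit_ssm_to_points(toy_ssm, ann)
        assert all(np.diff(res.objective_trace) <= 1e-9)

    def test_rigid_invariance_of_fit_quality(self, toy_ssm):
        from prosegvar.geometry import SimilarityTransform
        rng = np.random.default_rng(9)
        b_true = rng.normal(size=toy_ssm.n_modes) * toy_ssm.mode_sd() * 0.5
        truth = sample_ssm(toy_ssm, ShapeCoefficients(b_true))
        move = SimilarityTransform(
            rotation=Rotation.from_euler("zx", [40, 15],
                                         degrees=True).as_matrix(),
            translation=np.array([10.0, -5.0, 3.0]))
        ann0 = _annotation_from_shape(toy_ssm, truth, 120, seed=10)
        ann1 = _annotation_from_shape(toy_ssm, truth, 120, seed=10,
                                      transform=move)
        res0 = fit_ssm_to_points(toy_ssm, ann0)
        res1 = fit_ssm_to_points(toy_ssm, ann1)
        moved_truth = truth.with_vertices(move.apply(truth.vertices))
        asd0 = asd_mesh_to_mesh(res0.mesh, truth)
        asd1 = asd_mesh_to_mesh(res1.mesh, moved_truth)
        assert asd1 == pytest.approx(asd0, abs=1e-6)

    def test_model_without_landmarks_rejected(self, toy_ssm):
        bare = StatisticalShapeModel(
            toy_ssm.mean_mesh, toy_ssm.modes, toy_ssm.eigenvalues,
            toy_ssm.n_train, landmark_indices=None)
        ann = _annotation_from_shape(toy_ssm, toy_ssm.mean_mesh, 30, seed=11)
        with pytest.raises(GeometryError):
            fit_ssm_to_points(bare, ann)

    def test_sparse_points_strict_vs_soft_direction(self, toy_ssm):
        """~30 points from an out-of-subspace shape: the strict fit cannot
        track the detail the deformable fit can."""
        from prosegvar.metrics import asd_points_to_mesh
        from prosegvar.soft_ssm import SoftFitConfig, fit_soft_ssm
        from prosegvar.synthetic import simulate_patient
        truth = simulate_patient(toy_ssm, seed=12, out_of_subspace_mm=1.5,
                                 pose_rotation_deg=0, pose_translation_mm=0)
        ann = _annotation_from_shape(toy_ssm, truth, 30, seed=13)
        strict = fit_ssm_to_points(toy_ssm, ann)
        soft = fit_soft_ssm(toy_ssm, ann, SoftFitConfig())
        pts = ann.all_points()
        assert asd_points_to_mesh(pts, soft) < \
            asd_points_to_mesh(pts, strict.mesh)


class TestGPA:
    def test_alignment_restores_rotated_copies(self):
        rng = np.random.default_rng(14)
        base = icosphere(20.0, 1).vertices
        shapes = []
        for _ in range(5):
            rot = Rotation.random(random_state=rng.integers(2 ** 16))
            shapes.append(base @ rot.as_matrix().T + rng.normal(scale=5,
                                                                size=3))
        aligned = generalized_procrustes(np.stack(shapes))
        spread = aligned.std(axis=0).max()
        assert spread < 1e-6
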