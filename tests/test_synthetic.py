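import numpy as np
import pytest

from prosegvar.geometry import GeometryError, closest_point_on_mesh
from prosegvar.metrics import asd_points_to_mesh
from prosegvar.shape_model import ShapeCoefficients, fit_ssm_to_points, sample_ssm
from prosegvar.synthetic import (
    CohortConfig,
    build_toy_ssm,
    generate_cohort,
    load_cohort,
    make_expert,
    plan_cohort,
    save_cohort,
    simulate_manual_annotation,
    simulate_patient,
)

from .conftest import surface_points


class _ZeroBiasExpert:
    expert_id = "Z"

    def bias(self, dirs):
        return np.zeros(len(np.atleast_2d(dirs)))


def tiny_config(seed=0, **overrides) -> CohortConfig:
    base = dict(n_patients=2, n_experts=2, seed=seed,
                shared_subset_size=2, bis_subset_size=1,
                manual_points_range=(40, 60),
                semi_auto_points_range=(10, 14),
                ssm_n_train=15, ssm_subdivisions=2)
    base.update(overrides)
    return CohortConfig(**base)


class TestToySSM:
    def test_same_seed_is_bit_identical(self):
        a = build_toy_ssm(seed=5, n_train=12, subdivisions=1)
        b = build_toy_ssm(seed=5, n_train=12, subdivisions=1)
        assert np.array_equal(a.mean_mesh.vertices, b.mean_mesh.vertices)
        assert np.array_equal(a.modes, b.modes)
        assert np.array_equal(a.eigenvalues, b.eigenvalues)

    def test_sampled_volumes_are_prostate_plausible(self, toy_ssm):
        """Monte-Carlo over 200 clamped draws: volumes concentrate in the
        15-90 mL range typical of biopsy cohorts."""
        rng = np.random.default_rng(6)
        sd = toy_ssm.mode_sd()
        vols = []
        for _ in range(200):
            b = np.clip(rng.normal(size=toy_ssm.n_modes) * sd,
                        -3 * sd, 3 * sd)
            vols.append(sample_ssm(toy_ssm,
                                   ShapeCoefficients(b)).volume_mm3() / 1e3)
        vols = np.asarray(vols)
        assert ((vols >= 15) & (vols <= 90)).mean() >= 0.95
        assert vols.min() > 8 and vols.max() < 110

    def test_unperturbed_ellipsoids_have_low_rank(self):
        ssm = build_toy_ssm(seed=7, n_train=20, subdivisions=1,
                            perturb_amplitude_mm=0.0, variance_retained=1.0)
        assert ssm.n_modes <= 6

    def test_landmarks_recorded_on_mean(self, toy_ssm):
        v = toy_ssm.mean_mesh.vertices
        assert toy_ssm.landmark_indices["apex"] == np.argmax(v[:, 2])
        assert toy_ssm.landmark_indices["base"] == np.argmin(v[:, 2])


class TestSimulatePatient:
    def test_in_subspace_truth_fits_exactly(self, toy_ssm):
        from prosegvar.geometry import PointAnnotation
        truth = simulate_patient(toy_ssm, seed=8, out_of_subspace_mm=0.0,
                                 pose_rotation_deg=0, pose_translation_mm=0)
        pts = surface_points(truth, 250, seed=9)
        lmk = {k: truth.vertices[toy_ssm.landmark_indices[k]]
               for k in ("apex", "base", "posterior")}
        res = fit_ssm_to_points(
            toy_ssm, PointAnnotation("p", "A", "manual", 0, pts, lmk))
        assert asd_points_to_mesh(pts, res.mesh) < 0.05

    def test_out_of_subspace_truth_resists_strict_fit(self, toy_ssm):
        from prosegvar.geometry import PointAnnotation
        truth = simulate_patient(toy_ssm, seed=8, out_of_subspace_mm=1.0,
                                 pose_rotation_deg=0, pose_translation_mm=0)
        pts = surface_points(truth, 250, seed=9)
        lmk = {k: truth.vertices[toy_ssm.landmark_indices[k]]
               for k in ("apex", "base", "posterior")}
        res = fit_ssm_to_points(
            toy_ssm, PointAnnotation("p", "A", "manual", 0, pts, lmk))
        assert asd_points_to_mesh(pts, res.mesh) >= 0.3

    def test_distinct_seeds_give_distinct_truths(self, toy_ssm):
        a = simulate_patient(toy_ssm, seed=1)
        b = simulate_patient(toy_ssm, seed=2)
        assert not np.allclose(a.vertices, b.vertices)


@pytest.fixture(scope="module")
def truth(toy_ssm):
    return simulate_patient(toy_ssm, seed=10, out_of_subspace_mm=0.0,
                            pose_rotation_deg=0, pose_translation_mm=0)


class TestManualAnnotation:
    def test_noiseless_points_lie_on_surface(self, truth):
        cfg = tiny_config(point_noise_sd_mm=0.0, pole_sparsity=0.0)
        ann = simulate_manual_annotation(truth, _ZeroBiasExpert(), cfg,
                                         seed=11)
        assert asd_points_to_mesh(ann.points, truth) < 1e-9

    def test_point_count_within_configured_range(self, truth):
        cfg = tiny_config(manual_points_range=(80, 120))
        ann = simulate_manual_annotation(truth, _ZeroBiasExpert(), cfg,
                                         seed=12)
        # pole thinning of the medial slices may drop a few points
        assert 60 <= ann.n_points <= 120

    def test_unit_noise_mean_distance_matches_half_normal(self, truth):
        """E|N(0,1)| = 0.798 mm along the boundary normal; the in-plane
        displacement direction is slightly oblique to the true normal, so
        the realized mean sits a little below that."""
        cfg = tiny_config(point_noise_sd_mm=1.0, pole_sparsity=0.0,
                          manual_points_range=(300, 400))
        means = []
        for seed in (13, 14):
            ann = simulate_manual_annotation(truth, _ZeroBiasExpert(), cfg,
                                             seed=seed)
            means.append(closest_point_on_mesh(ann.points,
                                               truth).distances.mean())
        assert 0.6 < np.mean(means) < 0.87

    def test_pole_sparsity_thins_the_caps(self, truth):
        """Counting check: with sparsity 0.7 the apex cap's share of points
        falls far below its share of area."""
        def apex_ratio(sparsity, seed):
            cfg = tiny_config(point_noise_sd_mm=0.0, pole_sparsity=sparsity,
                              manual_points_range=(400, 500))
            ann = simulate_manual_annotation(truth, _ZeroBiasExpert(), cfg,
                                             seed=seed)
            z = truth.vertices[:, 2]
            cap_hi = z.max() - 0.2 * (z.max() - z.min())
            pt_share = (ann.points[:, 2] > cap_hi).mean()
            areas = truth.vertex_areas()
            area_share = areas[z > cap_hi].sum() / areas.sum()
            return pt_share / area_share

        sparse = apex_ratio(0.7, seed=15)
        dense = apex_ratio(0.0, seed=15)
        assert sparse < 0.6
        assert sparse < 0.55 * dense

    def test_points_are_plane_tagged_and_quantized(self, truth):
        cfg = tiny_config(point_noise_sd_mm=0.0, pole_sparsity=0.0,
                          slice_spacing_mm=3.0)
        ann = simulate_manual_annotation(truth, _ZeroBiasExpert(), cfg,
                                         seed=16)
        tags = np.asarray(ann.plane_tags)
        assert set(tags) <= {"axial", "sagittal", "coronal"}
        axial_z = np.unique(np.round(ann.points[tags == "axial", 2], 6))
        # every axial point sits on the 3 mm slice grid (some slices may
        # receive no points, so test grid membership, not adjacency)
        offsets = (axial_z - axial_z[0]) % 3.0
        offsets = np.minimum(offsets, 3.0 - offsets)
        np.testing.assert_allclose(offsets, 0.0, atol=1e-6)


class TestCohortPlan:
    def test_paper_scale_design_arithmetic(self):
        """4 experts / 100 patients / shared 12 / bis 5: session counts
        follow the allocation arithmetic exactly."""
        cfg = CohortConfig(n_patients=100, n_experts=4,
                           shared_subset_size=12, bis_subset_size=5)
        plan = plan_cohort(cfg)
        manual0 = [s for s in plan if s.method == "manual" and s.session == 0]
        manual1 = [s for s in plan if s.method == "manual" and s.session == 1]
        semi0 = [s for s in plan if s.method == "semi_auto"
                 and s.session == 0]
        semi1 = [s for s in plan if s.method == "semi_auto"
                 and s.session == 1]
        # each expert: 12 shared + 13 exclusive (25-patient cap)
        assert len(manual0) == 4 * 25
        assert len(manual1) == 4 * 5
        # semi-auto: all 4 on the shared 12, two experts on the other 88
        assert len(semi0) == 4 * 12 + 2 * 88
        assert len(semi1) == 2 * 5
        per_expert = {e: sum(1 for s in manual0 if s.expert_id == e)
                      for e in "ABCD"}
        assert all(v <= cfg.max_manual_per_expert
                   for v in per_expert.values())

    def test_single_expert_has_no_pairs(self):
        cfg = CohortConfig(n_patients=3, n_experts=1, shared_subset_size=2,
                           bis_subset_size=1)
        plan = plan_cohort(cfg)
        experts = {s.expert_id for s in plan}
        assert experts == {"A"}

    def test_invalid_configs_rejected(self):
        with pytest.raises(GeometryError):
            CohortConfig(n_patients=5, shared_subset_size=9)
        with pytest.raises(GeometryError):
            CohortConfig(pole_sparsity=1.0)
        with pytest.raises(GeometryError):
            CohortConfig(manual_points_range=(50, 10))


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(tiny_config(seed=3))


class TestCohortGeneration:
    def test_counts_match_plan(self, cohort):
        plan = plan_cohort(cohort.config)
        assert len(cohort.records) == len(plan)

    def test_same_seed_reproduces_manifest_hash(self, cohort):
        again = generate_cohort(tiny_config(seed=3))
        assert again.manifest["manifest_hash"] == \
            cohort.manifest["manifest_hash"]

    def test_different_seed_changes_manifest(self, cohort):
        other = generate_cohort(tiny_config(seed=4))
        assert other.manifest["manifest_hash"] != \
            cohort.manifest["manifest_hash"]

    def test_roundtrip_through_directory(self, cohort, tmp_path):
        save_cohort(cohort, tmp_path / "cohort")
        back = load_cohort(tmp_path / "cohort")
        assert len(back.records) == len(cohort.records)
        orig = {(r.annotation.patient_id, r.annotation.expert_id,
                 r.annotation.method, r.annotation.session): r
                for r in cohort.records}
        for rec in back.records:
            a = rec.annotation
            src = orig[(a.patient_id, a.expert_id, a.method, a.session)]
            np.testing.assert_allclose(a.points, src.annotation.points,
                                       atol=1e-12)
            if rec.mesh is not None:
                np.testing.assert_allclose(rec.mesh.vertices,
                                           src.mesh.vertices, atol=1e-12)

    def test_semiauto_counts_in_range(self, cohort):
        lo, hi = cohort.config.semi_auto_points_range
        for rec in cohort.records:
            if rec.annotation.method == "semi_auto":
                total = rec.annotation.n_points + 3
                assert lo <= total <= hi
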