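import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from prosegvar.geometry import (
    AnnotationError,
    GeometryError,
    MeshFormatError,
    PointAnnotation,
    SegmentationRecord,
    TriangleMesh,
    _closest_on_triangles,
    closest_point_on_mesh,
    procrustes_align,
    read_annotation,
    read_mesh,
    write_annotation,
    write_mesh,
)

from .conftest import extreme_landmarks, icosphere


# ---------------------------------------------------------------------------
# Mesh I/O
# ---------------------------------------------------------------------------

class TestMeshIO:
    def test_ply_ascii_roundtrip_is_bit_exact(self, sphere20, tmp_path):
        path = write_mesh(sphere20, tmp_path / "s.ply")
        back = read_mesh(path)
        assert np.array_equal(back.vertices, sphere20.vertices)
        assert np.array_equal(back.faces, sphere20.faces)

    @pytest.mark.parametrize("ext", ["stl", "obj"])
    def test_other_formats_preserve_counts(self, sphere20, tmp_path, ext):
        path = write_mesh(sphere20, tmp_path / f"s.{ext}")
        back = read_mesh(path)
        assert back.n_vertices == sphere20.n_vertices
        assert back.n_faces == sphere20.n_faces

    def test_degenerate_face_dropped_on_construction(self):
        verts = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1.0]])
        faces = np.array([[0, 1, 2], [0, 1, 3], [1, 2, 3], [0, 2, 3],
                          [0, 1, 1]])          # last face has zero area
        m = TriangleMesh(verts, faces)
        assert m.n_faces == 4

    def test_truncated_file_raises_format_error(self, sphere20, tmp_path):
        path = write_mesh(sphere20, tmp_path / "s.ply")
        data = path.read_text()
        path.write_text(data[: len(data) // 3])
        with pytest.raises(MeshFormatError):
            read_mesh(path)

    def test_unknown_suffix_rejected(self, tmp_path):
        with pytest.raises(MeshFormatError):
            read_mesh(tmp_path / "m.xyz")


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def _annotation(n=10, seed=0):
    rng = np.random.default_rng(seed)
    pts = rng.normal(scale=20, size=(n, 3))
    return PointAnnotation(
        "p001", "A", "manual", 0, pts,
        {"apex": [0, 0, 25.0], "base": [0, 0, -25.0],
         "posterior": [0, -22.0, 0]},
        plane_tags=["axial"] * n)


class TestAnnotationIO:
    @pytest.mark.parametrize("suffix", [".csv", ".json"])
    def test_roundtrip_lossless(self, tmp_path, suffix):
        ann = _annotation()
        back = read_annotation(write_annotation(ann, tmp_path / f"a{suffix}"))
        assert back.patient_id == ann.patient_id
        assert back.expert_id == ann.expert_id
        assert back.method == ann.method and back.session == ann.session
        np.testing.assert_allclose(back.points, ann.points, rtol=0, atol=0)
        for k in ann.landmarks:
            np.testing.assert_allclose(back.landmarks[k], ann.landmarks[k])
        assert back.plane_tags == ann.plane_tags

    def test_missing_apex_row_raises(self, tmp_path):
        ann = _annotation()
        path = write_annotation(ann, tmp_path / "a.csv")
        lines = [ln for ln in path.read_text().splitlines()
                 if ",apex," not in ln]
        path.write_text("\n".join(lines))
        with pytest.raises(AnnotationError, match="apex"):
            read_annotation(path)

    def test_json_unknown_keys_ignored(self, tmp_path):
        import json
        ann = _annotation(n=3)
        path = write_annotation(ann, tmp_path / "a.json")
        payload = json.loads(path.read_text())
        payload["vendor_field"] = {"irrelevant": True}
        path.write_text(json.dumps(payload))
        back = read_annotation(path)
        np.testing.assert_allclose(back.points, ann.points)

    def test_missing_landmark_at_construction(self):
        with pytest.raises(AnnotationError, match="posterior"):
            PointAnnotation("p", "A", "manual", 0, np.zeros((4, 3)),
                            {"apex": [0, 0, 1], "base": [0, 0, -1]})

    def test_record_provenance_consistency(self, sphere20):
        ann = _annotation()
        with pytest.raises(AnnotationError):
            SegmentationRecord(ann, sphere20, "manual_points")
        with pytest.raises(AnnotationError):
            SegmentationRecord(ann, None, "semi_auto_soft_SSM")
        SegmentationRecord(ann, None, "manual_points")
        SegmentationRecord(ann, sphere20, "manual_SSM")


# ---------------------------------------------------------------------------
# Closest point on mesh
# ---------------------------------------------------------------------------

class TestClosestPoint:
    def test_mesh_vertex_has_zero_distance(self, sphere20):
        q = closest_point_on_mesh(sphere20.vertices[:25], sphere20)
        assert q.distances.max() < 1e-12

    def test_sphere_distance_is_analytic(self, sphere25):
        # at 2r from the center of an r-sphere the distance is ~r
        p = np.array([[50.0, 0, 0], [0, 50.0, 0], [0, 0, 50.0]])
        q = closest_point_on_mesh(p, sphere25)
        np.testing.assert_allclose(q.distances, 25.0, atol=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_scan(self, seed):
        """Tree-pruned query must equal the exhaustive all-triangle scan."""
        rng = np.random.default_rng(seed)
        mesh = icosphere(rng.uniform(10, 25), subdivisions=2)
        mesh = mesh.with_vertices(mesh.vertices * rng.uniform(0.6, 1.5, 3))
        pts = rng.normal(scale=25, size=(100, 3))
        q = closest_point_on_mesh(pts, mesh)
        cand = _closest_on_triangles(pts, mesh.triangles())
        d_brute = np.sqrt(((cand - pts[:, None, :]) ** 2).sum(-1).min(1))
        np.testing.assert_allclose(q.distances, d_brute, rtol=0, atol=1e-12)

    def test_barycentric_reconstructs_closest_point(self, sphere20):
        rng = np.random.default_rng(3)
        pts = rng.normal(scale=30, size=(40, 3))
        q = closest_point_on_mesh(pts, sphere20)
        tri = sphere20.triangles()[q.face_indices]
        recon = np.einsum("nk,nkd->nd", q.barycentric, tri)
        np.testing.assert_allclose(recon, q.points, atol=1e-9)

    def test_empty_inputs_rejected(self, sphere20):
        with pytest.raises(GeometryError):
            closest_point_on_mesh(np.empty((0, 3)), sphere20)


# ---------------------------------------------------------------------------
# Procrustes
# ---------------------------------------------------------------------------

class TestProcrustes:
    def test_identity_when_target_equals_source(self):
        pts = np.random.default_rng(0).normal(size=(8, 3))
        t = procrustes_align(pts, pts)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-12)
        np.testing.assert_allclose(t.translation, 0, atol=1e-12)

    @pytest.mark.parametrize("allow_scale", [False, True])
    def test_apply_then_recover(self, allow_scale):
        rng = np.random.default_rng(1)
        src = rng.normal(scale=10, size=(12, 3))
        rot = Rotation.from_euler("zyx", [30, 10, -20],
                                  degrees=True).as_matrix()
        scale = 1.3 if allow_scale else 1.0
        tgt = scale * src @ rot.T + np.array([4.0, -2.0, 7.0])
        t = procrustes_align(src, tgt, allow_scale=allow_scale)
        np.testing.assert_allclose(t.apply(src), tgt, atol=1e-9)
        np.testing.assert_allclose(t.rotation, rot, atol=1e-9)

    def test_two_points_rejected(self):
        with pytest.raises(GeometryError):
            procrustes_align(np.zeros((2, 3)), np.ones((2, 3)))

    def test_collinear_rejected(self):
        src = np.outer(np.arange(5.0), [1.0, 2.0, 3.0])
        with pytest.raises(GeometryError):
            procrustes_align(src, src + 1.0)

    def test_least_squares_optimality_spot_check(self):
        """The fitted transform beats 1000 random similarity transforms."""
        rng = np.random.default_rng(2)
        src = rng.normal(scale=10, size=(15, 3))
        tgt = src @ Rotation.random(random_state=3).as_matrix().T \
            + [1, 2, 3] + rng.normal(scale=0.5, size=(15, 3))
        t = procrustes_align(src, tgt)
        best = np.sum((t.apply(src) - tgt) ** 2)
        rots = Rotation.random(1000, random_state=4).as_matrix()
        for rot in rots:
            trans = tgt.mean(0) - (src @ rot.T).mean(0)
            resid = np.sum((src @ rot.T + trans - tgt) ** 2)
            assert best <= resid + 1e-9

    def test_inverse_and_compose(self):
        rng = np.random.default_rng(5)
        src = rng.normal(size=(6, 3))
        tgt = rng.normal(size=(6, 3))
        t = procrustes_align(src, tgt, allow_scale=True)
        roundtrip = t.inverse().compose(t)
        np.testing.assert_allclose(roundtrip.apply(src), src, atol=1e-9)
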