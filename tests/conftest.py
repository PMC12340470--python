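import numpy as np
import pytest
import trimesh

from prosegvar.geometry import TriangleMesh
from prosegvar.synthetic import build_toy_ssm


def icosphere(radius: float, subdivisions: int = 3,
              center=(0.0, 0.0, 0.0)) -> TriangleMesh:
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriangleMesh(np.asarray(m.vertices) + np.asarray(center),
                        np.asarray(m.faces))


@pytest.fixture(scope="session")
def sphere20() -> TriangleMesh:
    return icosphere(20.0)


@pytest.fixture(scope="session")
def sphere25() -> TriangleMesh:
    return icosphere(25.0)


@pytest.fixture(scope="session")
def toy_ssm():
    """Small shape model shared across tests (coarse topology for speed)."""
    return build_toy_ssm(seed=11, n_train=30, subdivisions=2)


@pytest.fixture(scope="session")
def toy_ssm_fine():
    """Default-resolution shape model for fit-accuracy tests."""
    return build_toy_ssm(seed=11, n_train=40, subdivisions=3)


def surface_points(mesh: TriangleMesh, n: int, seed: int) -> np.ndarray:
    pts, _ = trimesh.sample.sample_surface(mesh.to_trimesh(), n, seed=seed)
    return np.asarray(pts, dtype=float)


def extreme_landmarks(mesh: TriangleMesh) -> dict:
    v = mesh.vertices
    return {"apex": v[np.argmax(v[:, 2])].copy(),
            "base": v[np.argmin(v[:, 2])].copy(),
            "posterior": v[np.argmin(v[:, 1])].copy()}
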