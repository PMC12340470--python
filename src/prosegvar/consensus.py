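"""STAPLE-like EM consensus over corresponded meshes.

Unlike voxel-probability STAPLE, the consensus lives on mesh vertices: the
E-step scores each input mesh by its ASD to the current consensus, the
M-step re-averages vertices with reliability weights derived from those
distances (inverse-square with a floor by default), iterated to a fixed
point.  Distant outlier meshes are down-weighted, so the consensus is
robust to individual segmentation errors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .geometry import GeometryError, TriangleMesh
from .metrics import asd_mesh_to_mesh

log = logging.getLogger(__name__)

WEIGHT_KERNELS = ("inverse_square", "gaussian")


@dataclass
class ConsensusResult:
    consensus: TriangleMesh
    weights: np.ndarray          # per input, sums to 1
    distances: np.ndarray        # per input, ASD to the final consensus (mm)
    n_iter: int
    converged: bool
    displacement_trace: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise GeometryError("consensus weights must sum to 1")


def _weights(distances: np.ndarray, kernel: str, eps_mm: float) -> np.ndarray:
    if kernel == "inverse_square":
        raw = 1.0 / (distances ** 2 + eps_mm ** 2)
    elif kernel == "gaussian":
        sigma = max(float(np.median(distances)), eps_mm)
        raw = np.exp(-0.5 * (distances / sigma) ** 2)
    else:
        raise GeometryError(f"unknown weight kernel {kernel!r}")
    return raw / raw.sum()


def staple_mesh_consensus(meshes: list[TriangleMesh],
                          tol_mm: float = 1e-4, max_iter: int = 100,
                          eps_mm: float = 0.1,
                          kernel: str = "inverse_square") -> ConsensusResult:
    """EM consensus of >= 2 meshes on shared topology.

    ``eps_mm`` floors the inverse-square weights so a mesh that happens to
    coincide with the consensus cannot absorb all the weight.
    """
    if len(meshes) == 0:
        raise GeometryError("no meshes given")
    ref = meshes[0]
    for m in meshes[1:]:
        if not ref.same_topology(m):
            raise GeometryError("consensus requires shared mesh topology")
    if len(meshes) == 1:
        log.warning("single input mesh: consensus is the input itself")
        return ConsensusResult(ref.copy(), np.ones(1),
                               np.zeros(1), 0, True)

    stack = np.stack([m.vertices for m in meshes])        # (n, V, 3)
    consensus_v = stack.mean(axis=0)
    weights = np.full(len(meshes), 1.0 / len(meshes))
    trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        cons_mesh = ref.with_vertices(consensus_v)
        dists = np.array([asd_mesh_to_mesh(m, cons_mesh) for m in meshes])
        weights = _weights(dists, kernel, eps_mm)
        new_v = np.tensordot(weights, stack, axes=1)
        disp = float(np.linalg.norm(new_v - consensus_v, axis=1).max())
        trace.append(disp)
        consensus_v = new_v
        if disp < tol_mm:
            converged = True
            break
    cons_mesh = ref.with_vertices(consensus_v)
    dists = np.array([asd_mesh_to_mesh(m, cons_mesh) for m in meshes])
    return ConsensusResult(cons_mesh, weights, dists, n_iter, converged,
                           trace)
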