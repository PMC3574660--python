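"""Triangular spring mesh over the pixel grid and Jacobi spring relaxation.

Every grid point carries a mesh vertex; every mesh edge is a linear spring
with Batina stiffness ``k_ij = 1/|x_j - x_i|`` (inverse edge length), which
penalises vertex collision and with it the fold/cross/tear events that break
topology.  Relaxation replaces each vertex displacement by the stiffness-
weighted average of its neighbours' displacements,

    u_i^{n+1} = (1/Σ_j k_ij) Σ_j k_ij u_j^n ,

a Jacobi sweep of the spring-equilibrium system Σ_j k_ij (u_j - u_i) = 0.

In 2-D each unit cell is split into two triangles along the
(i,j)→(i+1,j+1) diagonal, so interior vertices have degree 6.  In 3-D the
edge set is the 6-connected axis graph plus the three fixed-orientation face
diagonals per cell, preserving the inverse-edge-length stiffness semantics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ShapeMismatchError
from .grids import DisplacementField

__all__ = [
    "SpringMesh",
    "EquilibriumResidual",
    "build_mesh",
    "spring_stiffness",
    "spring_relax",
    "equilibrium_residual",
    "regularization_energy",
]

#: Shortest admissible edge length (grid units); shorter edges are clamped.
MIN_EDGE_LENGTH = 1e-6

_DIAG_OFFSETS = {
    2: [(1, 0), (0, 1), (1, 1)],
    3: [(1, 0, 0), (0, 1, 0), (0, 0, 1), (1, 1, 0), (1, 0, 1), (0, 1, 1)],
}


@dataclass
class SpringMesh:
    """Vertex positions, undirected edges and per-edge spring stiffness.

    ``positions`` has shape (n_vertices, d); ``edges`` is an (n_edges, 2)
    integer array of vertex index pairs; ``stiffness`` one positive float
    per edge.  ``grid_shape`` records the originating grid when the mesh was
    built over an image, and is None for free-form meshes.
    """

    positions: np.ndarray
    edges: np.ndarray
    stiffness: np.ndarray
    grid_shape: tuple = None

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.edges = np.asarray(self.edges, dtype=np.intp)
        self.stiffness = np.asarray(self.stiffness, dtype=np.float64)
        if self.positions.ndim != 2:
            raise ValueError("positions must be (n_vertices, d)")
        if self.edges.ndim != 2 or self.edges.shape[1] != 2:
            raise ValueError("edges must be (n_edges, 2)")
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        if self.stiffness.shape != (len(self.edges),):
            raise ValueError("one stiffness per edge required")
        if not (np.all(self.stiffness > 0) and np.all(np.isfinite(self.stiffness))):
            raise ValueError("stiffness must be positive and finite")

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    @property
    def ndim(self) -> int:
        return self.positions.shape[1]


@dataclass(frozen=True)
class EquilibriumResidual:
    """Net spring-force magnitude per vertex and its maximum."""

    per_vertex: np.ndarray
    max_norm: float


def spring_stiffness(
    positions: np.ndarray, edges: np.ndarray, eps: float = MIN_EDGE_LENGTH
) -> np.ndarray:
    """Batina stiffness ``k_ij = 1/|x_j - x_i|``, clamped at edge length eps."""
    positions = np.asarray(positions, dtype=np.float64)
    edges = np.asarray(edges, dtype=np.intp)
    delta = positions[edges[:, 1]] - positions[edges[:, 0]]
    length = np.sqrt(np.sum(delta**2, axis=-1))
    if np.any(length < eps):
        warnings.warn(
            "spring_stiffness: coincident adjacent vertices; edge length "
            f"clamped at {eps:g}",
            stacklevel=2,
        )
    return 1.0 / np.maximum(length, eps)


def _grid_edges(shape) -> np.ndarray:
    ndim = len(shape)
    idx = np.arange(int(np.prod(shape)), dtype=np.intp).reshape(shape)
    pairs = []
    for off in _DIAG_OFFSETS[ndim]:
        src = idx[tuple(slice(0, s - o) for s, o in zip(shape, off))]
        dst = idx[tuple(slice(o, s) for s, o in zip(shape, off))]
        pairs.append(np.stack([src.ravel(), dst.ravel()], axis=1))
    return np.concatenate(pairs, axis=0)


def build_mesh(shape) -> SpringMesh:
    """Triangular mesh with one vertex per grid point of ``shape``.

    2-D: the sides of every unit cell plus one fixed-direction diagonal per
    cell (two triangles per cell).  Stiffness initialised from the
    undeformed positions: 1.0 on axis edges, 1/√2 on diagonals.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) not in _DIAG_OFFSETS:
        raise ValueError("build_mesh supports 2-D and 3-D grids")
    if any(s < 2 for s in shape):
        raise ValueError(f"every grid dimension must be >= 2, got {shape}")
    positions = (
        np.indices(shape, dtype=np.float64).reshape(len(shape), -1).T.copy()
    )
    edges = _grid_edges(shape)
    stiffness = spring_stiffness(positions, edges)
    return SpringMesh(positions, edges, stiffness, grid_shape=shape)


def _as_flat_vectors(fld, mesh: SpringMesh) -> np.ndarray:
    if isinstance(fld, DisplacementField):
        if mesh.grid_shape is not None and fld.shape != mesh.grid_shape:
            raise ShapeMismatchError(
                f"field grid {fld.shape} != mesh grid {mesh.grid_shape}"
            )
        u = fld.vectors.reshape(-1, fld.ndim)
    else:
        u = np.asarray(fld, dtype=np.float64)
    if u.shape != (mesh.n_vertices, mesh.ndim):
        raise ShapeMismatchError(
            f"displacement array {u.shape} does not match mesh "
            f"({mesh.n_vertices} vertices, d={mesh.ndim})"
        )
    return u


def spring_relax(
    fld,
    mesh: SpringMesh,
    n_iter: int = 3,
    fixed: np.ndarray = None,
    update_stiffness: bool = True,
) -> "DisplacementField | np.ndarray":
    """Run ``n_iter`` Jacobi sweeps of the spring-equilibrium update.

    Each sweep simultaneously replaces every non-fixed vertex displacement
    by the stiffness-weighted average of its neighbours' previous
    displacements.  With ``update_stiffness`` (default) the Batina stiffness
    is recomputed before each sweep from the moved positions
    ``x^0 + u^n``; the frozen mode keeps the mesh's stored stiffness, which
    makes the iteration the exact Jacobi method for the linear equilibrium
    system (used by the direct-solve oracle).

    ``fixed`` is an optional boolean mask (grid- or vertex-shaped): marked
    vertices keep their input displacement.  Returns the same container type
    as the input field.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    u = _as_flat_vectors(fld, mesh).copy()
    fixed_flat = None
    if fixed is not None:
        fixed_flat = np.asarray(fixed, dtype=bool).ravel()
        if fixed_flat.shape != (mesh.n_vertices,):
            raise ShapeMismatchError("fixed mask does not match mesh vertex count")
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    n = mesh.n_vertices
    for _ in range(n_iter):
        if update_stiffness:
            k = spring_stiffness(mesh.positions + u, mesh.edges)
        else:
            k = mesh.stiffness
        wsum = np.bincount(i, weights=k, minlength=n) + np.bincount(
            j, weights=k, minlength=n
        )
        new = np.empty_like(u)
        for c in range(mesh.ndim):
            acc = np.bincount(i, weights=k * u[j, c], minlength=n)
            acc += np.bincount(j, weights=k * u[i, c], minlength=n)
            new[:, c] = acc / wsum
        if fixed_flat is not None:
            new[fixed_flat] = u[fixed_flat]
        u = new
    if isinstance(fld, DisplacementField):
        return DisplacementField(u.reshape(fld.vectors.shape))
    return u


def _net_forces(u: np.ndarray, mesh: SpringMesh) -> np.ndarray:
    i, j = mesh.edges[:, 0], mesh.edges[:, 1]
    k = mesh.stiffness
    n = mesh.n_vertices
    f = np.zeros_like(u)
    for c in range(mesh.ndim):
        pull = k * (u[j, c] - u[i, c])
        f[:, c] = np.bincount(i, weights=pull, minlength=n) - np.bincount(
            j, weights=pull, minlength=n
        )
    return f


def equilibrium_residual(fld, mesh: SpringMesh) -> EquilibriumResidual:
    """Magnitude of the net Hooke force ``F_i = Σ_j k_ij (u_j - u_i)`` per
    vertex, evaluated with the mesh's stored stiffness."""
    u = _as_flat_vectors(fld, mesh)
    f = _net_forces(u, mesh)
    per_vertex = np.sqrt(np.sum(f**2, axis=-1))
    return EquilibriumResidual(per_vertex, float(per_vertex.max(initial=0.0)))


def regularization_energy(fld, mesh: SpringMesh) -> float:
    """Spring regularization energy: Σ_vertices ||net spring force||."""
    return float(equilibrium_residual(fld, mesh).per_vertex.sum())
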