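import numpy as np
import pytest

from meshreg import (
    DisplacementField,
    SpringMesh,
    build_mesh,
    equilibrium_residual,
    regularization_energy,
    spring_relax,
    spring_stiffness,
)


def chain_mesh(n=5):
    """1-D chain of n vertices at unit spacing (free-form mesh)."""
    positions = np.arange(n, dtype=float).reshape(n, 1)
    edges = np.stack([np.arange(n - 1), np.arange(1, n)], axis=1)
    return SpringMesh(positions, edges, spring_stiffness(positions, edges))


class TestBuildMesh:
    @pytest.mark.parametrize(
        "shape,n_vertices,n_edges",
        [((2, 2), 4, 5), ((3, 3), 9, 16), ((4, 6), 24, 53)],
    )
    def test_counts_match_enumeration(self, shape, n_vertices, n_edges):
        # edges = axis edges + one diagonal per cell:
        # (m-1)n + m(n-1) + (m-1)(n-1)
        m, n = shape
        assert n_edges == (m - 1) * n + m * (n - 1) + (m - 1) * (n - 1)
        mesh = build_mesh(shape)
        assert mesh.n_vertices == n_vertices
        assert len(mesh.edges) == n_edges

    def test_interior_degree_is_six(self):
        mesh = build_mesh((5, 5))
        deg = np.bincount(mesh.edges.ravel(), minlength=25)
        interior = np.ravel_multi_index((2, 2), (5, 5))
        assert deg[interior] == 6

    def test_no_self_edges_and_unique(self):
        mesh = build_mesh((4, 4))
        assert np.all(mesh.edges[:, 0] != mesh.edges[:, 1])
        canon = {tuple(sorted(e)) for e in mesh.edges.tolist()}
        assert len(canon) == len(mesh.edges)

    def test_degenerate_shape_rejected(self):
        with pytest.raises(ValueError):
            build_mesh((1, 5))

    def test_3d_mesh_axis_plus_face_diagonals(self):
        mesh = build_mesh((3, 3, 3))
        m = 3
        axis = 3 * (m - 1) * m * m
        diag = 3 * (m - 1) * (m - 1) * m
        assert len(mesh.edges) == axis + diag
        assert mesh.n_vertices == 27


class TestStiffness:
    def test_undeformed_grid_values_exact(self):
        mesh = build_mesh((3, 3))
        lengths = np.sqrt(
            np.sum(
                (mesh.positions[mesh.edges[:, 1]] - mesh.positions[mesh.edges[:, 0]])
                ** 2,
                axis=1,
            )
        )
        axis = lengths < 1.2
        assert np.all(mesh.stiffness[axis] == 1.0)
        assert np.allclose(mesh.stiffness[~axis], 1.0 / np.sqrt(2.0), atol=1e-15)

    def test_inverse_length(self):
        pos = np.array([[0.0, 0.0], [2.0, 0.0]])
        k = spring_stiffness(pos, np.array([[0, 1]]))
        assert k[0] == 0.5

    def test_coincident_vertices_clamped_with_warning(self):
        pos = np.zeros((2, 2))
        with pytest.warns(UserWarning):
            k = spring_stiffness(pos, np.array([[0, 1]]))
        assert np.isfinite(k[0]) and k[0] > 0


class TestRelax:
    def test_constant_field_is_fixed_point(self):
        mesh = build_mesh((5, 5))
        u = np.full((5, 5, 2), 1.7)
        out = spring_relax(DisplacementField(u), mesh, n_iter=4)
        assert np.allclose(out.vectors, 1.7, atol=1e-13)

    def test_lone_displacement_averages_to_zero_neighbors(self):
        mesh = build_mesh((5, 5))
        u = np.zeros((5, 5, 2))
        u[2, 2] = (0.4, -0.2)
        fixed = np.ones((5, 5), bool)
        fixed[2, 2] = False
        out = spring_relax(DisplacementField(u), mesh, n_iter=1, fixed=fixed)
        assert np.allclose(out.vectors[2, 2], 0.0)

    def test_chain_converges_to_direct_solve(self):
        # ends fixed at u=0 and u=4; equilibrium is the tridiagonal system
        mesh = chain_mesh(5)
        u = np.zeros((5, 1))
        u[-1] = 4.0
        fixed = np.array([True, False, False, False, True])
        out = np.asarray(u)
        out = spring_relax(u, mesh, n_iter=500, fixed=fixed, update_stiffness=False)
        # direct dense solve of sum_j k_ij (u_j - u_i) = 0
        K = np.zeros((5, 5))
        for (a, b), k in zip(mesh.edges, mesh.stiffness):
            K[a, a] += k
            K[b, b] += k
            K[a, b] -= k
            K[b, a] -= k
        free = ~fixed
        rhs = -K[np.ix_(free, fixed)] @ u[fixed]
        direct = np.linalg.solve(K[np.ix_(free, free)], rhs)
        assert np.allclose(out[free], direct, atol=1e-8)
        res = equilibrium_residual(out, mesh)
        assert res.per_vertex[free].max() < 1e-8

    @pytest.mark.parametrize("seed", range(5))
    def test_discrete_maximum_principle(self, seed):
        rng = np.random.default_rng(seed)
        mesh = build_mesh((7, 7))
        u = rng.normal(size=(7, 7, 2))
        out = spring_relax(
            DisplacementField(u), mesh, n_iter=1, update_stiffness=False
        )
        for c in range(2):
            assert out.vectors[..., c].max() <= u[..., c].max() + 1e-12
            assert out.vectors[..., c].min() >= u[..., c].min() - 1e-12

    def test_energy_nonincreasing_over_frozen_sweeps(self):
        mesh = build_mesh((8, 8))
        fixed = np.zeros((8, 8), bool)
        fixed[0, :] = fixed[-1, :] = fixed[:, 0] = fixed[:, -1] = True
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = DisplacementField(rng.normal(size=(8, 8, 2)))
            e_prev = regularization_energy(f, mesh)
            for _ in range(4):
                f = spring_relax(f, mesh, 1, fixed=fixed, update_stiffness=False)
                e = regularization_energy(f, mesh)
                assert e <= e_prev + 1e-10
                e_prev = e


class TestResidualAndEnergy:
    def test_constant_field_zero_residual(self):
        mesh = build_mesh((4, 4))
        res = equilibrium_residual(np.full((16, 2), 0.9), mesh)
        assert res.max_norm < 1e-12
        assert regularization_energy(np.full((16, 2), 0.9), mesh) < 1e-10

    def test_single_perturbed_vertex_closed_form(self):
        mesh = build_mesh((5, 5))
        i = np.ravel_multi_index((2, 2), (5, 5))
        delta = 0.3
        u = np.zeros((25, 2))
        u[i, 0] = delta
        res = equilibrium_residual(u, mesh)
        on_i = (mesh.edges[:, 0] == i) | (mesh.edges[:, 1] == i)
        k_i = mesh.stiffness[on_i]
        assert res.per_vertex[i] == pytest.approx(delta * k_i.sum(), abs=1e-12)
        neighbors = np.setdiff1d(mesh.edges[on_i].ravel(), [i])
        for nb, k in zip(
            [e[0] if e[1] == i else e[1] for e in mesh.edges[on_i]], k_i
        ):
            assert res.per_vertex[nb] == pytest.approx(k * delta, abs=1e-12)
        # energy identity: sum of per-vertex magnitudes
        assert regularization_energy(u, mesh) == pytest.approx(
            res.per_vertex.sum(), abs=1e-12
        )

    def test_max_norm_is_max_of_per_vertex(self, rng):
        mesh = build_mesh((4, 5))
        u = rng.normal(size=(20, 2))
        res = equilibrium_residual(u, mesh)
        assert res.max_norm == res.per_vertex.max()
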