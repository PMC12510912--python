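"""FE kernel: spaces, assembly, solvers, point location and norms."""

import numpy as np
import pytest
import scipy.sparse.linalg as spla

from grom import fem


def _single_triangle():
    nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    cells = np.array([[0, 1, 2]])
    facets = fem.boundary_facets(cells)
    return fem.Mesh(nodes, cells, facets, np.full(len(facets), fem.PIAL))


class TestSpaces:
    @pytest.mark.parametrize("order,expected", [(1, 3), (2, 6)])
    def test_single_triangle_dof_count(self, order, expected):
        space = fem.build_space(_single_triangle(), order)
        assert space.D == expected

    def test_p2_dof_count_is_p1_plus_edges(self, coarse_mesh):
        s1 = fem.build_space(coarse_mesh, 1)
        s2 = fem.build_space(coarse_mesh, 2)
        assert s2.D == s1.D + len(coarse_mesh.edges())

    def test_unsupported_order_rejected(self, coarse_mesh):
        with pytest.raises(ValueError):
            fem.build_space(coarse_mesh, 3)


class TestAssembly:
    def test_pure_neumann_operator_annihilates_constants(self, coarse_mesh):
        space = fem.build_space(coarse_mesh, 1)
        sys = fem.assemble_operator(space, diffusion=[1.0])
        ones = np.ones(space.D)
        assert np.max(np.abs(sys.A @ ones)) < 1e-10 * abs(sys.A).max()

    def test_strong_robin_recovers_boundary_value(self):
        """Laplace with Robin k(u - g), k -> 1e6: solution -> g everywhere."""
        mesh = fem.rectangle_mesh(12, 12)
        space = fem.build_space(mesh, 1)
        g = 2.5
        sys = fem.assemble_operator(space, diffusion=[1.0],
                                    robin=[(0, fem.PIAL, 1e6, g)])
        x = fem.solve_full(sys)
        assert np.max(np.abs(x - g)) < 1e-6 * g

    def test_exchange_coupling_conserves_mass(self, coarse_mesh, rng):
        """Pairwise exchange has zero row sums across field blocks: the
        all-ones functional annihilates A x for any x (no boundary terms)."""
        space = fem.build_space(coarse_mesh, 1, n_fields=2)
        W = np.array([[0.0, 0.37], [0.37, 0.0]])
        sys = fem.assemble_operator(space, diffusion=[1.0, 2.0], exchange=W)
        for _ in range(3):
            x = rng.normal(size=space.total_dofs)
            total = np.ones(space.total_dofs) @ (sys.A @ x)
            assert abs(total) < 1e-9 * np.linalg.norm(x)

    def test_asymmetric_exchange_rejected(self, coarse_mesh):
        space = fem.build_space(coarse_mesh, 1, n_fields=2)
        with pytest.raises(ValueError, match="symmetric"):
            fem.assemble_operator(space, diffusion=[1.0, 1.0],
                                  exchange=np.array([[0, 1.0], [2.0, 0]]))

    def test_assembled_systems_are_symmetric_psd(self, coarse_mesh, rng):
        space = fem.build_space(coarse_mesh, 2, n_fields=2)
        sys = fem.assemble_operator(
            space, diffusion=[1e-4, 3e-4],
            exchange=np.array([[0, 0.03], [0.03, 0]]), reaction=[0.0, 1e-8],
            robin=[(0, fem.PIAL, 1e-5, 0.5), (1, fem.VENTRICLE, 3e-4, 0.2)])
        assert abs(sys.A - sys.A.T).max() < 1e-12 * abs(sys.A).max()
        for _ in range(5):
            x = rng.normal(size=space.total_dofs)
            assert x @ (sys.A @ x) >= -1e-12 * np.linalg.norm(x) ** 2


def _manufactured_problem(nx, order):
    """-div(grad u) = f on the unit square, u* = sin(pi x) sin(pi y),
    Robin closure -grad(u).n = k (u - g) with k = 1 and matching g."""
    mesh = fem.rectangle_mesh(nx, nx)
    space = fem.build_space(mesh, order)
    k = 1.0
    u = lambda p: np.sin(np.pi * p[:, 0]) * np.sin(np.pi * p[:, 1])
    f = lambda p: 2 * np.pi ** 2 * u(p)

    def du_dn(p):
        gx = np.pi * np.cos(np.pi * p[:, 0]) * np.sin(np.pi * p[:, 1])
        gy = np.pi * np.sin(np.pi * p[:, 0]) * np.cos(np.pi * p[:, 1])
        n = np.zeros_like(p)
        n[np.isclose(p[:, 0], 0.0)] = [-1, 0]
        n[np.isclose(p[:, 0], 1.0)] = [1, 0]
        n[np.isclose(p[:, 1], 0.0), :] = [0, -1]
        n[np.isclose(p[:, 1], 1.0), :] = [0, 1]
        return gx * n[:, 0] + gy * n[:, 1]

    g = lambda p: u(p) + du_dn(p) / k
    sys = fem.assemble_operator(space, diffusion=[1.0],
                                robin=[(0, fem.PIAL, k, g)],
                                volume_sources=[f])
    x = fem.solve_full(sys)
    field = fem.Field(space, x)
    exact = fem.Field(space, u(space.dof_coords))
    return fem.relative_l2(field, exact)


class TestSolve:
    @pytest.mark.parametrize("order,min_rate", [(1, 1.7), (2, 2.6)])
    def test_manufactured_solution_convergence(self, order, min_rate):
        """L2 error decays at the Lagrange rate O(h^{order+1})."""
        errs = [_manufactured_problem(nx, order) for nx in (8, 16, 32)]
        rates = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(rates > min_rate)

    def test_p2_reproduces_quadratic_exactly(self):
        """u* = x^2 + y^2 lies in the P2 space: error at roundoff."""
        mesh = fem.rectangle_mesh(6, 6)
        space = fem.build_space(mesh, 2)
        k = 1.0
        u = lambda p: p[:, 0] ** 2 + p[:, 1] ** 2

        def g(p):
            n = np.zeros_like(p)
            n[np.isclose(p[:, 0], 0.0)] = [-1, 0]
            n[np.isclose(p[:, 0], 1.0)] = [1, 0]
            n[np.isclose(p[:, 1], 0.0), :] = [0, -1]
            n[np.isclose(p[:, 1], 1.0), :] = [0, 1]
            return u(p) + (2 * p[:, 0] * n[:, 0] + 2 * p[:, 1] * n[:, 1]) / k

        sys = fem.assemble_operator(space, diffusion=[1.0],
                                    robin=[(0, fem.PIAL, k, g)],
                                    volume_sources=[-4.0])
        x = fem.solve_full(sys)
        assert np.max(np.abs(x - u(space.dof_coords))) < 1e-8

    def test_direct_and_cg_agree(self, coarse_mesh):
        space = fem.build_space(coarse_mesh, 1)
        sys = fem.assemble_operator(space, diffusion=[1.0],
                                    robin=[(0, fem.PIAL, 1.0, 1.0)])
        xd = fem.solve_full(sys, method="direct")
        xc = fem.solve_full(sys, method="cg")
        assert np.linalg.norm(xd - xc) < 1e-8 * np.linalg.norm(xd)

    def test_singular_system_raises(self, coarse_mesh):
        space = fem.build_space(coarse_mesh, 1)
        sys = fem.assemble_operator(space, diffusion=[1.0])
        sys.F[:] = 1.0  # incompatible RHS for the pure-Neumann operator
        with pytest.raises(RuntimeError):
            fem.solve_full(sys)


class TestInterpolation:
    def test_exact_at_dof_coordinates(self, coarse_mesh, rng):
        """Lagrange property: evaluation at a dof coordinate returns the
        dof coefficient."""
        space = fem.build_space(coarse_mesh, 2)
        field = fem.Field(space, rng.normal(size=space.D))
        take = rng.choice(space.D, 40, replace=False)
        vals, found = fem.locate_and_interpolate(field, space.dof_coords[take])
        assert found.all()
        assert np.allclose(vals[:, 0], field.coeffs[take], atol=1e-9)

    def test_outside_hull_flagged(self, coarse_mesh):
        space = fem.build_space(coarse_mesh, 1)
        field = fem.Field(space, np.ones(space.D))
        far = np.array([[500.0, 500.0], [0.0, 0.0]])  # second is in the hole
        vals, found = fem.locate_and_interpolate(field, far)
        assert not found[0]

    def test_spatial_hash_matches_bruteforce(self, coarse_mesh, rng):
        locator = fem.CellLocator(coarse_mesh)
        lo = coarse_mesh.nodes.min(axis=0)
        hi = coarse_mesh.nodes.max(axis=0)
        pts = rng.uniform(lo, hi, (100, 2))
        c_fast, b_fast = locator.locate(pts)
        c_slow, b_slow = locator.locate_bruteforce(pts)
        same = c_fast == c_slow
        # ambiguity only on shared cell edges: values must still agree
        for i in np.flatnonzero(~same):
            assert c_fast[i] >= 0 and c_slow[i] >= 0
            assert np.min(b_fast[i]) < 1e-8 or np.min(b_slow[i]) < 1e-8
        assert np.allclose(b_fast[same], b_slow[same], atol=1e-9)


class TestNorms:
    def test_constant_field_norm_closed_form(self, coarse_mesh):
        space = fem.build_space(coarse_mesh, 1)
        c = 3.2
        field = fem.Field(space, np.full(space.D, c))
        assert fem.l2_norm(field) == pytest.approx(
            c * np.sqrt(coarse_mesh.area()), rel=1e-10)

    def test_relative_error_of_identical_fields_is_zero(self, coarse_mesh,
                                                        rng):
        space = fem.build_space(coarse_mesh, 2, n_fields=2)
        f = fem.Field(space, rng.normal(size=space.total_dofs))
        assert fem.relative_l2(f, f) == 0.0

    def test_interpolant_norm_approaches_quadrature_oracle(self):
        """||sin(pi x)||_L2 on the unit square is 1/sqrt(2); the P1
        interpolant norm converges to it under refinement."""
        exact = 1.0 / np.sqrt(2.0)
        errs = []
        for nx in (8, 32):
            mesh = fem.rectangle_mesh(nx, nx)
            space = fem.build_space(mesh, 1)
            field = fem.Field(space, np.sin(np.pi * space.dof_coords[:, 0]))
            errs.append(abs(fem.l2_norm(field) - exact))
        assert errs[1] < errs[0]
        assert errs[1] < 1e-3  # O(h^2) interpolation bias at h = 1/32

    def test_zero_reference_rejected(self, coarse_mesh):
        space = fem.build_space(coarse_mesh, 1)
        f = fem.Field(space, np.ones(space.D))
        z = fem.Field(space, np.zeros(space.D))
        with pytest.raises(ZeroDivisionError):
            fem.relative_l2(f, z)


def test_boundary_integral_of_constant(coarse_mesh):
    space = fem.build_space(coarse_mesh, 2)
    field = fem.Field(space, np.full(space.D, 2.0))
    for marker in (fem.PIAL, fem.VENTRICLE):
        assert fem.boundary_integral(field, 0, marker) == pytest.approx(
            2.0 * coarse_mesh.boundary_length(marker), rel=1e-12)
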