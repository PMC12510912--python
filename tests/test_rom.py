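"""POD construction, Galerkin projection and reduced solves."""

import numpy as np
import pytest

from grom import fem, models, rom


@pytest.fixture(scope="module")
def small_problem(tiny_cohort):
    """A small two-compartment system plus synthetic snapshot vectors."""
    from grom.cohort import build_mesh

    mesh = build_mesh(tiny_cohort[0], 5.0)
    space = models.model_space(mesh, "A")
    system = models.assemble_model_a(space, models.ModelAParams())
    solution = fem.Field(space, fem.solve_full(system),
                         field_names=models.MODEL_A_FIELDS)
    rng = np.random.default_rng(7)
    # smooth-ish perturbed snapshots around the solution
    snaps = [fem.Field(space,
                       solution.coeffs * (1 + 0.05 * rng.standard_normal())
                       + 0.01 * rng.standard_normal(space.total_dofs),
                       field_names=models.MODEL_A_FIELDS)
             for _ in range(8)]
    return space, system, solution, snaps


class TestSnapshotMatrix:
    def test_single_snapshot_single_column(self, small_problem):
        space, _, solution, _ = small_problem
        mat = rom.build_snapshots([solution])
        assert mat.X.shape == (space.total_dofs, 1)
        assert np.array_equal(mat.X[:, 0], solution.coeffs)

    def test_row_count_is_fields_times_dofs(self, small_problem):
        space, _, _, snaps = small_problem
        mat = rom.build_snapshots(snaps)
        assert mat.X.shape[0] == 2 * space.D

    def test_column_permutation_leaves_spectrum_invariant(self, small_problem,
                                                          rng):
        _, _, _, snaps = small_problem
        mat = rom.build_snapshots(snaps)
        perm = rng.permutation(mat.M)
        mat_p = rom.build_snapshots([snaps[i] for i in perm])
        s0 = rom.pod(mat, 1).singular_values
        s1 = rom.pod(mat_p, 1).singular_values
        assert np.allclose(s0, s1, rtol=1e-10)
        assert np.array_equal(mat_p.X, mat.X[:, perm])


class TestPod:
    def test_repeated_column_is_rank_one(self):
        rng = np.random.default_rng(3)
        c = rng.normal(size=40)
        layout = _vector_layout(40)
        X = np.tile(c[:, None], (1, 5))
        mat = rom.SnapshotMatrix(X, tuple("abcde"), layout, "h")
        basis = rom.pod(mat, 1)
        s = basis.singular_values
        assert s[0] == pytest.approx(np.linalg.norm(c) * np.sqrt(5), rel=1e-10)
        assert np.max(np.abs(s[1:])) < 1e-10 * s[0]
        u1 = basis.U[:, 0]
        assert np.allclose(np.abs(u1), np.abs(c) / np.linalg.norm(c),
                           atol=1e-12)

    def test_eckart_young_squared_identity_all_d(self):
        """||X - U_d U_d^T X||_F^2 = sum_{i>d} sigma_i^2 for every d (the
        squared-Frobenius form of the optimality theorem)."""
        rng = np.random.default_rng(11)
        X = rng.normal(size=(50, 10))
        mat = rom.SnapshotMatrix(X, tuple(f"s{i}" for i in range(10)),
                                 _vector_layout(50), "h")
        for d in range(1, 11):
            lhs, rhs = rom.eckart_young_gap(mat, d)
            assert lhs == pytest.approx(rhs, rel=1e-8, abs=1e-10)

    def test_full_rank_reconstruction_is_exact(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 6))
        mat = rom.SnapshotMatrix(X, tuple(f"s{i}" for i in range(6)),
                                 _vector_layout(30), "h")
        lhs, _ = rom.eckart_young_gap(mat, 6)
        assert lhs < 1e-20 * np.sum(X ** 2)

    def test_basis_is_orthonormal(self, small_problem):
        _, _, _, snaps = small_problem
        mat = rom.build_snapshots(snaps)
        for d in (1, 4, 8):
            U = rom.pod(mat, d).U
            assert np.max(np.abs(U.T @ U - np.eye(d))) < 1e-10

    def test_sign_convention_is_deterministic(self, small_problem):
        _, _, _, snaps = small_problem
        mat = rom.build_snapshots(snaps)
        U1 = rom.pod(mat, 4).U
        U2 = rom.pod(mat, 4).U
        assert np.array_equal(U1, U2)
        idx = np.argmax(np.abs(U1), axis=0)
        assert np.all(U1[idx, np.arange(4)] > 0)


class TestProjection:
    def test_canonical_basis_projection_recovers_matrix(self, small_problem):
        space, system, _, _ = small_problem
        n = space.total_dofs
        eye_basis = rom.ReducedBasis(np.eye(n), np.ones(n), space)
        rs = rom.project(system, eye_basis)
        assert np.max(np.abs(rs.A_rb - system.A.toarray())) < 1e-12

    def test_projected_matrix_keeps_symmetry(self, small_problem):
        space, system, _, snaps = small_problem
        rs = rom.project(system, rom.pod(rom.build_snapshots(snaps), 5))
        assert np.max(np.abs(rs.A_rb - rs.A_rb.T)) < 1e-10 * np.max(
            np.abs(rs.A_rb))

    def test_quadratic_form_identity(self, small_problem, rng):
        """x^T A_rb x = (U x)^T A (U x) for random reduced vectors."""
        space, system, _, snaps = small_problem
        basis = rom.pod(rom.build_snapshots(snaps), 6)
        rs = rom.project(system, basis)
        for _ in range(5):
            x = rng.normal(size=6)
            lhs = x @ rs.A_rb @ x
            Ux = basis.U @ x
            assert lhs == pytest.approx(Ux @ (system.A @ Ux), rel=1e-10)


class TestReducedSolve:
    def test_residual_contract(self, small_problem):
        space, system, _, snaps = small_problem
        rs = rom.project(system, rom.pod(rom.build_snapshots(snaps), 5))
        u = rom.solve_reduced(rs)
        res = np.linalg.norm(rs.A_rb @ u - rs.F_rb) / np.linalg.norm(rs.F_rb)
        assert res < 1e-12

    def test_d1_is_scalar_division(self, small_problem):
        space, system, _, snaps = small_problem
        rs = rom.project(system, rom.pod(rom.build_snapshots(snaps), 1))
        u = rom.solve_reduced(rs)
        assert u[0] == pytest.approx(rs.F_rb[0] / rs.A_rb[0, 0], rel=1e-14)

    def test_agrees_with_iterative_dense_solve(self, small_problem):
        from scipy.sparse.linalg import cg

        space, system, _, snaps = small_problem
        rs = rom.project(system, rom.pod(rom.build_snapshots(snaps), 6))
        u_direct = rom.solve_reduced(rs)
        u_iter, info = cg(rs.A_rb, rs.F_rb, rtol=1e-14, atol=0.0)
        assert info == 0
        assert np.linalg.norm(u_direct - u_iter) < 1e-10 * np.linalg.norm(
            u_direct)


class TestLift:
    def test_unit_vector_lifts_to_basis_column(self, small_problem):
        _, _, _, snaps = small_problem
        basis = rom.pod(rom.build_snapshots(snaps), 4)
        e1 = np.zeros(4)
        e1[0] = 1.0
        f = rom.lift(basis, e1)
        assert np.array_equal(f.coeffs, basis.U[:, 0])

    def test_zero_lifts_to_zero(self, small_problem):
        _, _, _, snaps = small_problem
        basis = rom.pod(rom.build_snapshots(snaps), 3)
        assert np.all(rom.lift(basis, np.zeros(3)).coeffs == 0)

    def test_project_then_lift_preserves_span_members(self, small_problem):
        _, _, _, snaps = small_problem
        basis = rom.pod(rom.build_snapshots(snaps), 8)
        v = basis.U @ np.arange(1.0, 9.0)
        recon = basis.U @ (basis.U.T @ v)
        assert np.linalg.norm(recon - v) < 1e-10 * np.linalg.norm(v)


class TestGalerkinProperties:
    def test_snapshot_inclusion_yields_exact_reduced_solution(
            self, small_problem):
        """If the target's full solution is one of the snapshots and d = M,
        the symmetric-coercive Galerkin solution reproduces it."""
        space, system, solution, snaps = small_problem
        mat = rom.build_snapshots(snaps + [solution])
        _, diag = rom.reduce_and_solve(system, mat, mat.M, reference=solution)
        assert diag.error_combined < 1e-8

    def test_energy_error_monotone_in_d(self, small_problem):
        """Nested POD bases: the energy-norm Galerkin error is nonincreasing
        as the basis grows."""
        space, system, solution, snaps = small_problem
        mat = rom.build_snapshots(snaps)
        errs = []
        for d in (1, 2, 4, 6, 8):
            field, _ = rom.reduce_and_solve(system, mat, d)
            errs.append(rom.energy_norm_error(field, solution, system))
        assert all(b <= a * (1 + 1e-10) for a, b in zip(errs, errs[1:]))

    def test_span_nesting_projection_errors(self, small_problem):
        """Distance to span(all snapshots) <= distance to span(subset)."""
        space, system, solution, snaps = small_problem
        full = rom.build_snapshots(snaps)
        sub = rom.build_snapshots(snaps[:4])
        e_full = rom.projection_error(full.X, solution.coeffs)
        e_sub = rom.projection_error(sub.X, solution.coeffs)
        assert e_full <= e_sub + 1e-12


def _vector_layout(n_rows: int):
    """Minimal FESpace-like layout for raw-matrix POD tests."""

    class _Layout:
        total_dofs = n_rows
        n_fields = 1
        D = n_rows

        class mesh:  # noqa: N801 - structural stand-in
            @staticmethod
            def content_hash():
                return "raw"

    return _Layout()


def test_invalid_d_rejected(small_problem):
    _, _, _, snaps = small_problem
    mat = rom.build_snapshots(snaps)
    for bad in (0, mat.M + 1):
        with pytest.raises(ValueError):
            rom.pod(mat, bad)
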