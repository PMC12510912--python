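"""Proper orthogonal decomposition and Galerkin reduction.

Snapshots (full-order solutions mapped onto the target geometry) are stacked
column-wise into X in R^{D-tilde x M}, D-tilde = n_fields * D.  The POD basis
U consists of the first d left singular vectors of X — by the Eckart-Young
theorem the rank-d minimizer of ||X - U U^T X||_F, with squared reconstruction
error sum_{i>d} sigma_i^2.  The full-order operators are then projected,
A_rb = U^T A U and F_rb = U^T F, the small dense system solved directly, and
the solution lifted back as u = U u_rb.

The POD inner product is plain Euclidean on coefficient vectors (matching
the Frobenius-norm optimality statement); a mass-matrix-weighted variant is
available behind a flag.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import scipy.sparse as sp

from .fem import AssembledSystem, FESpace, Field


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class SnapshotMatrix:
    """Column-stacked snapshot coefficients on one target space."""

    X: np.ndarray                       # (D_tilde, M)
    source_ids: tuple[str, ...]
    layout: FESpace
    target_mesh_hash: str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[1] < 1:
            raise ValueError("X must be (D_tilde, M) with M >= 1")
        if self.X.shape[0] != self.layout.total_dofs:
            raise ValueError("row count must equal n_fields * D of the layout")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("snapshot matrix contains non-finite entries")
        if len(self.source_ids) != self.X.shape[1]:
            raise ValueError("one source id per column required")

    @property
    def M(self) -> int:
        return self.X.shape[1]

    def subset(self, ids) -> "SnapshotMatrix":
        ids = list(ids)
        pos = [self.source_ids.index(i) for i in ids]
        return SnapshotMatrix(self.X[:, pos], tuple(ids), self.layout,
                              self.target_mesh_hash)


@dataclass
class ReducedBasis:
    """POD basis U (D_tilde x d) with the full singular spectrum."""

    U: np.ndarray
    singular_values: np.ndarray
    layout: FESpace

    def __post_init__(self) -> None:
        self.U = np.asarray(self.U, dtype=float)
        self.singular_values = np.asarray(self.singular_values, dtype=float)
        if self.U.ndim != 2:
            raise ValueError("U must be 2D")
        if np.any(np.diff(self.singular_values) > 1e-12 * self.singular_values[0]):
            raise ValueError("singular values must be nonincreasing")
        G = self.U.T @ self.U
        if np.max(np.abs(G - np.eye(self.d))) > 1e-10:
            raise ValueError("basis columns are not orthonormal to 1e-10")

    @property
    def d(self) -> int:
        return self.U.shape[1]

    def truncate(self, d: int) -> "ReducedBasis":
        if not 1 <= d <= self.d:
            raise ValueError(f"need 1 <= d <= {self.d}")
        return ReducedBasis(self.U[:, :d], self.singular_values, self.layout)


@dataclass
class ReducedSystem:
    """Dense Galerkin-projected system A_rb u = F_rb."""

    A_rb: np.ndarray
    F_rb: np.ndarray
    basis: ReducedBasis
    projection_time: float = 0.0

    def __post_init__(self) -> None:
        d = self.basis.d
        if self.A_rb.shape != (d, d) or self.F_rb.shape != (d,):
            raise ValueError("reduced system dimensions inconsistent with basis")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_snapshots(fields: list[Field], source_ids=None) -> SnapshotMatrix:
    """Stack mapped solutions column-wise (input order preserved)."""
    if not fields:
        raise ValueError("need at least one snapshot")
    layout = fields[0].space
    for f in fields[1:]:
        if not f.space.compatible_with(layout):
            raise ValueError("all snapshots must share the same mesh and space")
    X = np.column_stack([f.coeffs for f in fields])
    if source_ids is None:
        source_ids = tuple(f"snap-{i:03d}" for i in range(len(fields)))
    return SnapshotMatrix(X, tuple(source_ids), layout,
                          layout.mesh.content_hash())


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|entry| component positive.

    Ties broken by the lowest row index (argmax on |column|).
    """
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs[None, :]


def pod(snapshots: SnapshotMatrix, d: int,
        mass_weighted: bool = False) -> ReducedBasis:
    """POD basis: first d left singular vectors of X, sign-fixed.

    With ``mass_weighted=True`` the SVD is taken of M^{1/2}-scaled rows
    (lumped per-field mass), i.e. optimality in the L2 function norm rather
    than the Euclidean coefficient norm; off by default.
    """
    X = snapshots.X
    if not 1 <= d <= min(X.shape):
        raise ValueError(f"need 1 <= d <= min(D_tilde, M) = {min(X.shape)}")
    if mass_weighted:
        from .fem import mass_matrix

        m = np.asarray(mass_matrix(snapshots.layout).sum(axis=1)).ravel()
        w = np.sqrt(np.tile(m, snapshots.layout.n_fields))
        Uw, s, _ = np.linalg.svd(X * w[:, None], full_matrices=False)
        U = _fix_signs(Uw / w[:, None])
        # re-orthonormalize in the Euclidean sense for downstream projection
        U, _ = np.linalg.qr(U[:, :d])
        U = _fix_signs(U)
        return ReducedBasis(U, s, snapshots.layout)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return ReducedBasis(_fix_signs(U[:, :d]), s, snapshots.layout)


def eckart_young_gap(snapshots: SnapshotMatrix, d: int) -> tuple[float, float]:
    """(||X - U_d U_d^T X||_F^2, sum_{i>d} sigma_i^2) — equal by Eckart-Young."""
    basis = pod(snapshots, d)
    X = snapshots.X
    resid = X - basis.U @ (basis.U.T @ X)
    return float(np.sum(resid ** 2)), float(np.sum(basis.singular_values[d:] ** 2))


def project(system: AssembledSystem, basis: ReducedBasis) -> ReducedSystem:
    """Galerkin projection A_rb = U^T A U, F_rb = U^T F (timed)."""
    if system.A.shape[0] != basis.U.shape[0]:
        raise ValueError("system and basis dimensions do not match")
    t0 = time.perf_counter()
    AU = system.A @ basis.U
    A_rb = basis.U.T @ AU
    F_rb = basis.U.T @ system.F
    dt = time.perf_counter() - t0
    return ReducedSystem(A_rb=A_rb, F_rb=F_rb, basis=basis, projection_time=dt)


def solve_reduced(rs: ReducedSystem) -> np.ndarray:
    """Direct dense solve of the reduced system; residual < 1e-12 relative."""
    try:
        u = np.linalg.solve(rs.A_rb, rs.F_rb)
    except np.linalg.LinAlgError as err:
        cond = np.linalg.cond(rs.A_rb)
        raise RuntimeError(f"reduced system singular (cond ~ {cond:.2e})") from err
    nF = np.linalg.norm(rs.F_rb)
    res = np.linalg.norm(rs.A_rb @ u - rs.F_rb) / (nF if nF > 0 else 1.0)
    if res > 1e-12:
        cond = np.linalg.cond(rs.A_rb)
        raise RuntimeError(
            f"reduced solve residual {res:.2e} > 1e-12 (cond ~ {cond:.2e})")
    return u


def lift(basis: ReducedBasis, u_rb: np.ndarray,
         field_names=()) -> Field:
    """Inverse projection u = U u_rb wrapped as a Field on the target space."""
    u_rb = np.asarray(u_rb, dtype=float).ravel()
    if u_rb.size != basis.d:
        raise ValueError(f"expected {basis.d} reduced coefficients")
    return Field(basis.layout, basis.U @ u_rb, field_names=tuple(field_names))


@dataclass
class GromDiagnostics:
    """Per-run record of the online phase."""

    errors_per_field: np.ndarray
    error_combined: float
    singular_values: np.ndarray
    d: int
    M: int
    timings: dict = dataclass_field(default_factory=dict)


def reduce_and_solve(system: AssembledSystem, snapshots: SnapshotMatrix, d: int,
                     reference: Field | None = None, M_mass=None,
                     field_names=()) -> tuple[Field, GromDiagnostics]:
    """Online phase: POD(d) -> project -> dense solve -> lift (+ error vs truth).

    ``reference``, when given, must be the stored full-order solution on the
    target; per-field and combined relative L2 errors are then reported.
    """
    from .fem import relative_l2

    t0 = time.perf_counter()
    basis = pod(snapshots, d)
    t_pod = time.perf_counter() - t0
    rs = project(system, basis)
    t0 = time.perf_counter()
    u_rb = solve_reduced(rs)
    t_solve = time.perf_counter() - t0
    field = lift(basis, u_rb, field_names=field_names)
    errs = np.full(snapshots.layout.n_fields, np.nan)
    comb = float("nan")
    if reference is not None:
        errs = relative_l2(field, reference, per_field=True, M=M_mass)
        comb = relative_l2(field, reference, M=M_mass)
    diag = GromDiagnostics(
        errors_per_field=np.asarray(errs),
        error_combined=comb,
        singular_values=basis.singular_values,
        d=d, M=snapshots.M,
        timings={"pod": t_pod, "projection": rs.projection_time,
                 "reduced_solve": t_solve},
    )
    return field, diag


def energy_norm_error(field: Field, reference: Field,
                      system: AssembledSystem) -> float:
    """sqrt(e^T A e) with e = u - ref; the norm in which Galerkin is optimal."""
    e = field.coeffs - reference.coeffs
    val = float(e @ (system.A @ e))
    return float(np.sqrt(max(val, 0.0)))


def projection_error(basis_or_X, vector: np.ndarray) -> float:
    """Euclidean distance of a vector to span(columns) (orthogonal projection).

    Accepts a ReducedBasis (orthonormal) or a raw matrix (orthonormalized
    internally) — used for span-nesting checks between snapshot subsets.
    """
    if isinstance(basis_or_X, ReducedBasis):
        Q = basis_or_X.U
    else:
        Q, _ = np.linalg.qr(np.asarray(basis_or_X, dtype=float))
    r = vector - Q @ (Q.T @ vector)
    return float(np.linalg.norm(r))
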