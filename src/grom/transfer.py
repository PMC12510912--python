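"""Transport of snapshot solutions between geometries.

The pipeline stores each full-order solution on its own subject mesh; to use
it as a snapshot on a target geometry the subject mesh is morphed by the
inter-subject deformation (the Lagrange nodal values ride along with the
nodes), and the morphed solution is then read off at the target mesh's dof
coordinates: FE interpolation where a target dof falls inside a morphed
cell, and Gaussian-weighted nearest-neighbour extrapolation in the thin
boundary band where the (generally inexact) deformation leaves target dofs
uncovered.

The modified-operator residual verifies the change-of-variables identity:
a solution of the original problem, pulled back, satisfies the variational
problem assembled with gradients composed with J^{-T} and measures scaled by
|det J|.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from . import imaging
from .fem import (
    CellLocator,
    FESpace,
    Field,
    Mesh,
    build_space,
    relative_l2,
    shape_values,
    solve_full,
)
from .models import assemble_model

PointMap = Callable[[np.ndarray], np.ndarray]


# ---------------------------------------------------------------------------
# Mesh morphing
# ---------------------------------------------------------------------------

def _as_point_map(deformation) -> PointMap:
    if isinstance(deformation, imaging.DeformationField):
        return lambda pts: imaging.apply_deformation(deformation, pts)
    if callable(deformation):
        return deformation
    raise TypeError("deformation must be a DeformationField or a point-map callable")


def deform_mesh(mesh: Mesh, deformation) -> tuple[Mesh, int]:
    """Morph mesh nodes through a deformation; connectivity/markers preserved.

    ``deformation`` is a :class:`~grom.imaging.DeformationField` or a
    callable mapping (n, 2) world points to (n, 2) points.  Returns the
    morphed mesh and the number of inverted (orientation-flipped) cells —
    nonzero counts mirror imperfect registration and are tolerated
    downstream (reported, never silently dropped).
    """
    phi = _as_point_map(deformation)
    new_nodes = phi(mesh.nodes)
    deformed = mesh.with_nodes(new_nodes)
    n_inverted = int(np.sum(deformed.signed_areas() <= 0))
    return deformed, n_inverted


# ---------------------------------------------------------------------------
# Field transfer
# ---------------------------------------------------------------------------

@dataclass
class TransferReport:
    """Bookkeeping for one snapshot transfer (per scalar field layout)."""

    n_interpolated: int
    n_extrapolated: int
    max_extrapolation_distance: float
    n_inverted_cells: int = 0
    boundary_drift: float = float("nan")

    @property
    def n_target_dofs(self) -> int:
        return self.n_interpolated + self.n_extrapolated


def transfer_field(src_field: Field, target_space: FESpace,
                   k_neighbors: int = 8, sigma_factor: float = 1.0,
                   n_inverted_cells: int = 0) -> tuple[Field, TransferReport]:
    """Read a (morphed) source field off at the target space's dofs.

    Target dof coordinates inside a source cell get exact FE interpolation;
    uncovered dofs get a normalized Gaussian average of the ``k_neighbors``
    nearest source dof values, weights exp(-d^2 / (2 sigma^2)) with
    sigma = ``sigma_factor`` x local source mesh size at the nearest source
    dof.  Both branches reproduce constants exactly, and extrapolated values
    are convex combinations of source dof values.
    """
    space = src_field.space
    if space.order != target_space.order or space.n_fields != target_space.n_fields:
        raise ValueError("source and target spaces must share order and field count")
    pts = target_space.dof_coords
    locator = CellLocator(space.mesh)
    cells, bary = locator.locate(pts)
    inside = cells >= 0
    D_src, D_tgt = space.D, target_space.D
    n = space.n_fields
    out = np.zeros(n * D_tgt)

    idx_in = np.flatnonzero(inside)
    if idx_in.size:
        N = shape_values(space.order, bary[idx_in])
        dofs = space.cell_dofs[cells[idx_in]]
        for f in range(n):
            cf = src_field.coeffs[f * D_src:(f + 1) * D_src]
            out[idx_in + f * D_tgt] = np.einsum("mc,mc->m", N, cf[dofs])

    idx_out = np.flatnonzero(~inside)
    max_dist = 0.0
    if idx_out.size:
        tree = cKDTree(space.dof_coords)
        k = min(k_neighbors, space.D)
        dist, nn = tree.query(pts[idx_out], k=k)
        dist = np.atleast_2d(dist.reshape(len(idx_out), k))
        nn = np.atleast_2d(nn.reshape(len(idx_out), k))
        h_local = _dof_local_size(space)[nn[:, 0]]
        sigma = sigma_factor * h_local
        if np.any(dist[:, 0] > 10.0 * sigma):
            worst = float(np.max(dist[:, 0] / sigma))
            raise RuntimeError(
                "extrapolation failure: nearest source dof lies "
                f"{worst:.1f} sigma away (>10); geometries are grossly mismatched"
            )
        w = np.exp(-(dist ** 2) / (2.0 * sigma[:, None] ** 2))
        w /= w.sum(axis=1, keepdims=True)
        for f in range(n):
            cf = src_field.coeffs[f * D_src:(f + 1) * D_src]
            out[idx_out + f * D_tgt] = np.sum(w * cf[nn], axis=1)
        max_dist = float(dist[:, 0].max())

    report = TransferReport(
        n_interpolated=int(idx_in.size),
        n_extrapolated=int(idx_out.size),
        max_extrapolation_distance=max_dist,
        n_inverted_cells=n_inverted_cells,
    )
    return Field(target_space, out, field_names=src_field.field_names), report


def _dof_local_size(space: FESpace) -> np.ndarray:
    """Local mesh size per scalar dof (mean incident edge length)."""
    node_h = space.mesh.node_h()
    if space.order == 1:
        return node_h
    edges = space.mesh.edges()
    return np.concatenate([node_h, 0.5 * (node_h[edges[:, 0]] + node_h[edges[:, 1]])])


def map_snapshot(src_field: Field, deformation, target_space: FESpace,
                 k_neighbors: int = 8, sigma_factor: float = 1.0
                 ) -> tuple[Field, TransferReport]:
    """Morph the source mesh and transfer the solution in one step.

    This is the u_i -> u-tilde_i -> u-hat_i chain: the source field's mesh is
    deformed onto the target geometry (nodal values riding along), then
    extended onto the target space.
    """
    deformed, n_inv = deform_mesh(src_field.space.mesh, deformation)
    deformed_space = build_space(deformed, src_field.space.order,
                                 src_field.space.n_fields)
    riding = Field(deformed_space, src_field.coeffs.copy(),
                   field_names=src_field.field_names)
    return transfer_field(riding, target_space, k_neighbors=k_neighbors,
                          sigma_factor=sigma_factor, n_inverted_cells=n_inv)


# ---------------------------------------------------------------------------
# Modified-operator (pulled-back) residual
# ---------------------------------------------------------------------------

def numerical_point_map_jacobian(phi: PointMap, points: np.ndarray,
                                 eps: float = 1e-4) -> np.ndarray:
    """Central finite-difference Jacobian of a point map, (n, 2, 2)."""
    points = np.atleast_2d(points)
    J = np.empty((len(points), 2, 2))
    for a in range(2):
        d = np.zeros(2)
        d[a] = eps
        J[:, :, a] = (phi(points + d) - phi(points - d)) / (2 * eps)
    return J


def _as_jacobian(deformation) -> Callable[[np.ndarray], np.ndarray]:
    if isinstance(deformation, imaging.DeformationField):
        return lambda pts: imaging.jacobian(deformation, pts)[0]
    if callable(deformation):
        return lambda pts: numerical_point_map_jacobian(deformation, pts)
    raise TypeError("deformation must be a DeformationField or a point-map callable")


def modified_form_residual(src_field: Field, deformation, which: str,
                           params=None) -> float:
    """Relative residual of the source solution in the pulled-back forms.

    Assembles the model's bilinear/linear forms on the *source* mesh with
    per-quadrature-point deformation Jacobians (gradients composed with
    J^{-T}, volume measures scaled by |det J|, boundary measures by the
    tangential stretch |J tau|) and returns ||A-hat u - F-hat|| / ||F-hat||.
    For the identity map this is exactly the full-order solve residual; for
    an affine map it matches direct assembly on the mapped mesh to roundoff.
    """
    jac = _as_jacobian(deformation)
    space = src_field.space
    system = assemble_model(space, which, params, deformation_jacobian=jac)
    nF = np.linalg.norm(system.F)
    if nF == 0:
        raise ZeroDivisionError("pulled-back linear form is zero")
    return float(np.linalg.norm(system.A @ src_field.coeffs - system.F) / nF)


# ---------------------------------------------------------------------------
# Mapping error and diagnostics
# ---------------------------------------------------------------------------

def mapping_error(mapped: Field, reference: Field, M=None) -> np.ndarray:
    """Per-field relative L2 errors of a mapped snapshot vs the target truth."""
    return relative_l2(mapped, reference, per_field=True, M=M)


def boundary_condition_drift(field: Field, marker: int,
                             expected_value: float) -> float:
    """Sup over boundary dofs of |field - expected| (diagnostic only).

    Transfer does not preserve boundary conditions exactly; this quantifies
    the drift at the dofs of the marked boundary, per field maximum.
    """
    space = field.space
    sel = space.mesh.facet_markers == marker
    dofs = np.unique(space.facet_dofs[sel].ravel())
    worst = 0.0
    for f in range(space.n_fields):
        worst = max(worst, float(np.max(np.abs(
            field.component(f)[dofs] - expected_value))))
    return worst
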