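"""Finite-element primitives on simplicial (triangle) meshes.

Provides the small FE kernel shared by the forward PDE models and the
snapshot-transfer machinery: continuous Lagrange spaces of order 1 and 2,
vectorized sparse assembly of diffusion / reaction / exchange / Robin forms,
point location with interpolation, and mass-matrix (true function-space)
L2 norms.

Conventions
-----------
* Coordinates are in millimetres throughout.
* Boundary facets carry integer markers: ``PIAL = 1`` (outer / subarachnoid
  surface) and ``VENTRICLE = 2`` (inner surface).
* Multi-field systems use a field-major block layout: the global degree of
  freedom of (field ``f``, scalar dof ``i``) is ``f * D + i`` where ``D`` is
  the per-field dof count.  This makes snapshot stacking of an ``n``-field
  solution into a vector of length ``n * D`` well defined and reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field as dataclass_field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

PIAL = 1
VENTRICLE = 2
MARKER_NAMES = {PIAL: "pial", VENTRICLE: "ventricle"}


# ---------------------------------------------------------------------------
# Mesh
# ---------------------------------------------------------------------------

@dataclass
class Mesh:
    """Conforming triangle mesh with marked boundary facets.

    Parameters
    ----------
    nodes : (N, 2) float array, mm
    cells : (T, 3) int array; reoriented counter-clockwise on construction
    facets : (F, 2) int array of boundary facet node pairs
    facet_markers : (F,) int array with values in ``{PIAL, VENTRICLE}``
    """

    nodes: np.ndarray
    cells: np.ndarray
    facets: np.ndarray
    facet_markers: np.ndarray

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        self.facets = np.ascontiguousarray(self.facets, dtype=np.int64)
        self.facet_markers = np.ascontiguousarray(self.facet_markers, dtype=np.int64)
        if self.nodes.ndim != 2 or self.nodes.shape[1] != 2:
            raise ValueError("nodes must be (N, 2)")
        if not np.all(np.isfinite(self.nodes)):
            raise ValueError("mesh nodes contain non-finite coordinates")
        # enforce CCW orientation so signed areas are positive
        a = self.signed_areas()
        flip = a < 0
        if np.any(flip):
            self.cells[flip] = self.cells[flip][:, [0, 2, 1]]
        if np.any(self.signed_areas() <= 0):
            raise ValueError("mesh contains degenerate (zero-area) cells")
        unknown = set(np.unique(self.facet_markers)) - set(MARKER_NAMES)
        if unknown:
            raise ValueError(f"unknown facet markers {sorted(unknown)}")

    # -- geometry -----------------------------------------------------------

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.cells]
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        return 0.5 * (d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0])

    def cell_areas(self) -> np.ndarray:
        return np.abs(self.signed_areas())

    def area(self) -> float:
        return float(self.cell_areas().sum())

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cells.shape[0]

    def edges(self) -> np.ndarray:
        """Unique mesh edges as sorted (lo, hi) node pairs, lexicographic order."""
        e = np.vstack([
            self.cells[:, [0, 1]],
            self.cells[:, [1, 2]],
            self.cells[:, [2, 0]],
        ])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    @property
    def h(self) -> float:
        """Characteristic size: median edge length [mm]."""
        e = self.edges()
        lengths = np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)
        return float(np.median(lengths))

    def node_h(self) -> np.ndarray:
        """Mean incident-edge length per node (local mesh size) [mm]."""
        e = self.edges()
        lengths = np.linalg.norm(self.nodes[e[:, 0]] - self.nodes[e[:, 1]], axis=1)
        acc = np.zeros(self.n_nodes)
        cnt = np.zeros(self.n_nodes)
        np.add.at(acc, e[:, 0], lengths)
        np.add.at(acc, e[:, 1], lengths)
        np.add.at(cnt, e[:, 0], 1.0)
        np.add.at(cnt, e[:, 1], 1.0)
        return acc / np.maximum(cnt, 1.0)

    def facet_lengths(self) -> np.ndarray:
        return np.linalg.norm(
            self.nodes[self.facets[:, 1]] - self.nodes[self.facets[:, 0]], axis=1
        )

    def boundary_length(self, marker: int) -> float:
        sel = self.facet_markers == marker
        return float(self.facet_lengths()[sel].sum())

    def content_hash(self) -> str:
        m = hashlib.sha1()
        m.update(np.round(self.nodes, 9).tobytes())
        m.update(self.cells.tobytes())
        m.update(self.facets.tobytes())
        m.update(self.facet_markers.tobytes())
        return m.hexdigest()[:16]

    def with_nodes(self, nodes: np.ndarray) -> "Mesh":
        """Same connectivity and markers on new node coordinates.

        Does NOT reorient cells (a deformation may legitimately invert some);
        used by mesh morphing, which reports inverted cells instead.
        """
        out = object.__new__(Mesh)
        out.nodes = np.ascontiguousarray(nodes, dtype=float)
        out.cells = self.cells.copy()
        out.facets = self.facets.copy()
        out.facet_markers = self.facet_markers.copy()
        return out


def boundary_facets(cells: np.ndarray) -> np.ndarray:
    """Facets (edges) belonging to exactly one cell, as node pairs."""
    e = np.vstack([cells[:, [0, 1]], cells[:, [1, 2]], cells[:, [2, 0]]])
    key = np.sort(e, axis=1)
    uniq, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    return uniq[counts == 1]


def rectangle_mesh(nx: int, ny: int, lx: float = 1.0, ly: float = 1.0,
                   marker: int = PIAL) -> Mesh:
    """Structured triangle mesh of [0, lx] x [0, ly]; whole boundary one marker.

    Test utility for manufactured-solution studies.
    """
    x = np.linspace(0.0, lx, nx + 1)
    y = np.linspace(0.0, ly, ny + 1)
    X, Y = np.meshgrid(x, y, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel()])

    def nid(i, j):
        return i * (ny + 1) + j

    cells = []
    for i in range(nx):
        for j in range(ny):
            v00, v10 = nid(i, j), nid(i + 1, j)
            v01, v11 = nid(i, j + 1), nid(i + 1, j + 1)
            cells.append([v00, v10, v11])
            cells.append([v00, v11, v01])
    cells = np.array(cells, dtype=np.int64)
    facets = boundary_facets(cells)
    markers = np.full(len(facets), marker, dtype=np.int64)
    return Mesh(nodes, cells, facets, markers)


# ---------------------------------------------------------------------------
# Reference elements and quadrature
# ---------------------------------------------------------------------------

# P2 local dof order: 3 vertices then midpoints of local edges (0,1), (1,2), (2,0).
_LOCAL_EDGES = np.array([[0, 1], [1, 2], [2, 0]])


def _tri_quadrature(degree: int) -> tuple[np.ndarray, np.ndarray]:
    """Symmetric Gauss rules on the reference triangle (barycentric points, weights).

    Weights sum to 1 (multiply by cell area).
    """
    if degree <= 2:
        # 3-point edge-midpoint rule, exact to degree 2
        pts = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
        w = np.full(3, 1.0 / 3.0)
    else:
        # 6-point Dunavant rule, exact to degree 4
        a1, w1 = 0.445948490915965, 0.223381589678011
        a2, w2 = 0.091576213509771, 0.109951743655322
        pts = np.array([
            [1 - 2 * a1, a1, a1], [a1, 1 - 2 * a1, a1], [a1, a1, 1 - 2 * a1],
            [1 - 2 * a2, a2, a2], [a2, 1 - 2 * a2, a2], [a2, a2, 1 - 2 * a2],
        ])
        w = np.array([w1, w1, w1, w2, w2, w2])
    return pts, w


def _gauss_1d(npts: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre on [0, 1]; weights sum to 1."""
    x, w = np.polynomial.legendre.leggauss(npts)
    return 0.5 * (x + 1.0), 0.5 * w


def shape_values(order: int, lam: np.ndarray) -> np.ndarray:
    """Lagrange shape functions at barycentric points lam (..., 3) -> (..., ndof)."""
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    if order == 1:
        return np.stack([l1, l2, l3], axis=-1)
    if order == 2:
        return np.stack([
            l1 * (2 * l1 - 1), l2 * (2 * l2 - 1), l3 * (2 * l3 - 1),
            4 * l1 * l2, 4 * l2 * l3, 4 * l3 * l1,
        ], axis=-1)
    raise ValueError(f"unsupported order {order}")


def shape_gradients_bary(order: int, lam: np.ndarray) -> np.ndarray:
    """d(shape)/d(lambda) at barycentric points lam (..., 3) -> (..., ndof, 3)."""
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    z = np.zeros_like(l1)
    if order == 1:
        one = np.ones_like(l1)
        rows = [
            [one, z, z],
            [z, one, z],
            [z, z, one],
        ]
    elif order == 2:
        rows = [
            [4 * l1 - 1, z, z],
            [z, 4 * l2 - 1, z],
            [z, z, 4 * l3 - 1],
            [4 * l2, 4 * l1, z],
            [z, 4 * l3, 4 * l2],
            [4 * l3, z, 4 * l1],
        ]
    else:
        raise ValueError(f"unsupported order {order}")
    return np.stack([np.stack(r, axis=-1) for r in rows], axis=-2)


def _segment_shape(order: int, t: np.ndarray) -> np.ndarray:
    """Trace of the Lagrange basis on a boundary facet, parameter t in [0, 1].

    Column order: the two endpoint dofs, then (P2) the midpoint dof.
    """
    if order == 1:
        return np.stack([1 - t, t], axis=-1)
    if order == 2:
        return np.stack([(1 - t) * (1 - 2 * t), t * (2 * t - 1), 4 * t * (1 - t)], axis=-1)
    raise ValueError(f"unsupported order {order}")


# ---------------------------------------------------------------------------
# Function space
# ---------------------------------------------------------------------------

@dataclass
class FESpace:
    """Continuous Lagrange space of order 1 or 2 with ``n_fields`` components.

    ``D`` scalar dofs per field; total system size ``n_fields * D``.
    Dof enumeration is deterministic: vertex dofs in node order, then (P2)
    edge-midpoint dofs in lexicographic (lo, hi) edge order.
    """

    mesh: Mesh
    order: int
    n_fields: int = 1
    dof_coords: np.ndarray = dataclass_field(init=False)
    cell_dofs: np.ndarray = dataclass_field(init=False)
    facet_dofs: np.ndarray = dataclass_field(init=False)

    def __post_init__(self) -> None:
        if self.order not in (1, 2):
            raise ValueError("only Lagrange orders 1 and 2 are supported")
        if self.n_fields < 1:
            raise ValueError("n_fields must be >= 1")
        mesh = self.mesh
        if self.order == 1:
            self.dof_coords = mesh.nodes.copy()
            self.cell_dofs = mesh.cells.copy()
            self.facet_dofs = mesh.facets.copy()
        else:
            edges = mesh.edges()                     # lexicographically sorted
            n_edge = len(edges)
            key = edges[:, 0] * mesh.n_nodes + edges[:, 1]
            midpoints = 0.5 * (mesh.nodes[edges[:, 0]] + mesh.nodes[edges[:, 1]])
            self.dof_coords = np.vstack([mesh.nodes, midpoints])
            # cell -> edge dof lookup
            cd = np.empty((mesh.n_cells, 6), dtype=np.int64)
            cd[:, :3] = mesh.cells
            for k, (a, b) in enumerate(_LOCAL_EDGES):
                pair = np.sort(mesh.cells[:, [a, b]], axis=1)
                ek = np.searchsorted(key, pair[:, 0] * mesh.n_nodes + pair[:, 1])
                cd[:, 3 + k] = mesh.n_nodes + ek
            self.cell_dofs = cd
            pair = np.sort(mesh.facets, axis=1)
            ef = np.searchsorted(key, pair[:, 0] * mesh.n_nodes + pair[:, 1])
            self.facet_dofs = np.column_stack([mesh.facets, mesh.n_nodes + ef])
            del n_edge

    @property
    def D(self) -> int:
        """Scalar dofs per field."""
        return self.dof_coords.shape[0]

    @property
    def total_dofs(self) -> int:
        return self.n_fields * self.D

    @property
    def ndof_cell(self) -> int:
        return 3 if self.order == 1 else 6

    def compatible_with(self, other: "FESpace") -> bool:
        return (
            self.order == other.order
            and self.n_fields == other.n_fields
            and self.D == other.D
            and self.mesh.content_hash() == other.mesh.content_hash()
        )


def build_space(mesh: Mesh, order: int, n_fields: int = 1) -> FESpace:
    return FESpace(mesh, order, n_fields)


@dataclass
class Field:
    """FE function: coefficient vector of length ``n_fields * D`` on a space."""

    space: FESpace
    coeffs: np.ndarray
    field_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.coeffs = np.asarray(self.coeffs, dtype=float).ravel()
        if self.coeffs.size != self.space.total_dofs:
            raise ValueError(
                f"coefficient length {self.coeffs.size} != {self.space.total_dofs}"
            )
        if not np.all(np.isfinite(self.coeffs)):
            raise ValueError("field coefficients contain non-finite values")
        if not self.field_names:
            self.field_names = tuple(f"u{i}" for i in range(self.space.n_fields))
        if len(self.field_names) != self.space.n_fields:
            raise ValueError("field_names length must equal n_fields")

    def component(self, f: int) -> np.ndarray:
        D = self.space.D
        return self.coeffs[f * D:(f + 1) * D]

    def by_name(self, name: str) -> np.ndarray:
        return self.component(self.field_names.index(name))


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass
class AssembledSystem:
    """Sparse symmetric system A x = F in field-major block layout."""

    A: sp.csr_matrix
    F: np.ndarray
    n_fields: int
    D: int
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.A.shape != (self.n_fields * self.D, self.n_fields * self.D):
            raise ValueError("system dimensions inconsistent")
        if self.symmetric:
            diff = abs(self.A - self.A.T)
            scale = max(abs(self.A).max(), 1e-300)
            if diff.max() > 1e-10 * scale:
                raise ValueError("assembled matrix is not symmetric to 1e-10 relative")


JacobianCallable = Callable[[np.ndarray], np.ndarray]


def _cell_geometry(mesh: Mesh) -> tuple[np.ndarray, np.ndarray]:
    """Barycentric gradients (T, 3, 2) and unsigned areas (T,)."""
    p = mesh.nodes[mesh.cells]                     # (T, 3, 2)
    d1 = p[:, 1] - p[:, 0]
    d2 = p[:, 2] - p[:, 0]
    det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]   # 2 * signed area
    # gradients of (l2, l3) from inverse Jacobian; l1 = 1 - l2 - l3
    inv = np.empty((len(det), 2, 2))
    inv[:, 0, 0] = d2[:, 1] / det
    inv[:, 0, 1] = -d2[:, 0] / det
    inv[:, 1, 0] = -d1[:, 1] / det
    inv[:, 1, 1] = d1[:, 0] / det
    grad = np.empty((len(det), 3, 2))
    grad[:, 1] = inv[:, 0]
    grad[:, 2] = inv[:, 1]
    grad[:, 0] = -inv[:, 0] - inv[:, 1]
    return grad, 0.5 * np.abs(det)


def _scalar_or_call(v, points: np.ndarray) -> np.ndarray:
    if callable(v):
        return np.asarray(v(points), dtype=float)
    return np.full(points.shape[0], float(v))


def assemble_operator(
    space: FESpace,
    diffusion: Sequence[float],
    exchange: np.ndarray | None = None,
    reaction: Sequence[float] | None = None,
    robin: Sequence[tuple[int, int, float, float | Callable]] = (),
    neumann: Sequence[tuple[int, int, float | Callable]] = (),
    volume_sources: Sequence[float | Callable] | None = None,
    deformation_jacobian: JacobianCallable | None = None,
) -> AssembledSystem:
    """Assemble the coupled diffusion / exchange / Robin system.

    The bilinear form, per field ``f`` with test functions ``v_f``::

        sum_f  D_f (grad u_f, grad v_f)  +  r_f (u_f, v_f)
      + sum_{f<g}  w_fg (u_f - u_g, v_f - v_g)
      + sum_(f,m)  k_fm <u_f, v_f>_Gamma_m

    and linear form ``sum k_fm <g_fm, v_f> + sum <q_fm, v_f> + (s_f, v_f)``.
    ``exchange`` is the symmetric nonnegative matrix ``w_fg`` (zero diagonal);
    its pairwise form guarantees zero row sums across field blocks
    (inter-compartment exchange conserves mass).

    ``deformation_jacobian``, if given, maps physical points (m, 2) to
    deformation Jacobians (m, 2, 2); the form is then assembled in
    pulled-back (modified-operator) fashion: gradients are composed with
    ``J^{-T}`` and measures scaled by ``|det J|`` (boundary measures by the
    tangential stretch ``|J tau|``).
    """
    n = space.n_fields
    D = space.D
    mesh = space.mesh
    diffusion = np.asarray(diffusion, dtype=float)
    if diffusion.shape != (n,):
        raise ValueError("diffusion must give one coefficient per field")
    if np.any(diffusion <= 0):
        raise ValueError("diffusion coefficients must be positive")
    if exchange is None:
        exchange = np.zeros((n, n))
    exchange = np.asarray(exchange, dtype=float)
    if exchange.shape != (n, n):
        raise ValueError("exchange matrix must be n_fields x n_fields")
    if not np.allclose(exchange, exchange.T):
        raise ValueError("exchange matrix must be symmetric")
    if np.any(np.diag(exchange) != 0):
        raise ValueError("exchange matrix must have zero diagonal")
    if np.any(exchange < 0):
        raise ValueError("exchange coefficients must be nonnegative")
    reaction = np.zeros(n) if reaction is None else np.asarray(reaction, dtype=float)

    order = space.order
    ndc = space.ndof_cell
    lam, wq = _tri_quadrature(2 * order)
    nq = len(wq)
    grad_l, areas = _cell_geometry(mesh)            # (T,3,2), (T,)
    T = mesh.n_cells
    Nq = shape_values(order, lam)                   # (nq, ndc)
    dN = shape_gradients_bary(order, lam)           # (nq, ndc, 3)
    # physical gradients per (cell, qpoint): (T, nq, ndc, 2)
    G = np.einsum("qcb,tbd->tqcd", dN, grad_l)
    p0 = mesh.nodes[mesh.cells]                     # (T, 3, 2)
    Xq = np.einsum("qb,tbd->tqd", lam, p0)          # quad points (T, nq, 2)

    if deformation_jacobian is not None:
        J = deformation_jacobian(Xq.reshape(-1, 2)).reshape(T, nq, 2, 2)
        detJ = J[..., 0, 0] * J[..., 1, 1] - J[..., 0, 1] * J[..., 1, 0]
        if np.any(detJ <= 0):
            bad = np.argwhere(detJ <= 0)[0]
            loc = Xq[bad[0], bad[1]]
            raise ValueError(
                f"deformation Jacobian determinant <= 0 at quadrature point {loc}"
            )
        Jinv = np.empty_like(J)
        Jinv[..., 0, 0] = J[..., 1, 1] / detJ
        Jinv[..., 0, 1] = -J[..., 0, 1] / detJ
        Jinv[..., 1, 0] = -J[..., 1, 0] / detJ
        Jinv[..., 1, 1] = J[..., 0, 0] / detJ
        # hat-grad = J^{-T} grad
        G = np.einsum("tqed,tqce->tqcd", Jinv, G)
        meas = detJ                                  # (T, nq)
    else:
        meas = np.ones((T, nq))

    wmeas = wq[None, :] * meas * areas[:, None]      # (T, nq)
    K_loc = np.einsum("tq,tqcd,tqed->tce", wmeas, G, G)          # stiffness
    M_loc = np.einsum("tq,qc,qe->tce", wmeas, Nq, Nq)            # mass

    rows_c = np.repeat(space.cell_dofs, ndc, axis=1).ravel()
    cols_c = np.tile(space.cell_dofs, (1, ndc)).ravel()

    tot = n * D
    blocks_r, blocks_c, blocks_v = [], [], []

    def add_cells(f: int, g: int, loc: np.ndarray, scale: float) -> None:
        blocks_r.append(rows_c + f * D)
        blocks_c.append(cols_c + g * D)
        blocks_v.append(scale * loc.ravel())

    # coupling through exchange: diag  += (sum_g w_fg + r_f) M ; offdiag -w_fg M
    wsum = exchange.sum(axis=1)
    for f in range(n):
        add_cells(f, f, K_loc, diffusion[f])
        c_diag = wsum[f] + reaction[f]
        if c_diag != 0.0:
            add_cells(f, f, M_loc, c_diag)
        for g in range(n):
            if g != f and exchange[f, g] != 0.0:
                add_cells(f, g, M_loc, -exchange[f, g])

    F = np.zeros(tot)

    # volume sources
    if volume_sources is not None:
        flat_X = Xq.reshape(-1, 2)
        for f, s in enumerate(volume_sources):
            if s is None:
                continue
            sval = _scalar_or_call(s, flat_X).reshape(T, nq)
            contrib = np.einsum("tq,tq,qc->tc", wmeas, sval, Nq)
            np.add.at(F, space.cell_dofs.ravel() + f * D, contrib.ravel())

    # boundary terms
    if robin or neumann:
        tq, tw = _gauss_1d(3)
        Sq = _segment_shape(order, tq)               # (3, nfdof)
        nfd = Sq.shape[1]
        p1 = mesh.nodes[mesh.facets[:, 0]]
        p2 = mesh.nodes[mesh.facets[:, 1]]
        tang = p2 - p1                               # (F, 2)
        Xf = p1[:, None, :] + tq[None, :, None] * tang[:, None, :]   # (F, 3, 2)
        if deformation_jacobian is not None:
            Jb = deformation_jacobian(Xf.reshape(-1, 2)).reshape(len(p1), len(tq), 2, 2)
            stretched = np.einsum("fqde,fe->fqd", Jb, tang)
            dl = np.linalg.norm(stretched, axis=-1)  # (F, 3)
        else:
            dl = np.linalg.norm(tang, axis=1)[:, None] * np.ones((1, len(tq)))
        wdl = tw[None, :] * dl                       # (F, 3)

        def facet_sel(marker: int) -> np.ndarray:
            sel = np.flatnonzero(mesh.facet_markers == marker)
            if sel.size == 0:
                raise ValueError(f"mesh has no facets with marker {marker}")
            return sel

        for f, marker, k, g in robin:
            sel = facet_sel(marker)
            fd = space.facet_dofs[sel]
            loc = np.einsum("fq,qc,qe->fce", wdl[sel], Sq, Sq) * float(k)
            blocks_r.append(np.repeat(fd, nfd, axis=1).ravel() + f * D)
            blocks_c.append(np.tile(fd, (1, nfd)).ravel() + f * D)
            blocks_v.append(loc.ravel())
            gval = _scalar_or_call(g, Xf[sel].reshape(-1, 2)).reshape(len(sel), len(tq))
            rhs = float(k) * np.einsum("fq,fq,qc->fc", wdl[sel], gval, Sq)
            np.add.at(F, fd.ravel() + f * D, rhs.ravel())

        for f, marker, q in neumann:
            sel = facet_sel(marker)
            fd = space.facet_dofs[sel]
            qval = _scalar_or_call(q, Xf[sel].reshape(-1, 2)).reshape(len(sel), len(tq))
            rhs = np.einsum("fq,fq,qc->fc", wdl[sel], qval, Sq)
            np.add.at(F, fd.ravel() + f * D, rhs.ravel())

    A = sp.coo_matrix(
        (np.concatenate(blocks_v), (np.concatenate(blocks_r), np.concatenate(blocks_c))),
        shape=(tot, tot),
    ).tocsr()
    A.sum_duplicates()
    return AssembledSystem(A=A, F=F, n_fields=n, D=D)


def mass_matrix(space: FESpace) -> sp.csr_matrix:
    """Consistent per-field (scalar) mass matrix, D x D."""
    order = space.order
    lam, wq = _tri_quadrature(2 * order)
    _, areas = _cell_geometry(space.mesh)
    Nq = shape_values(order, lam)
    M_loc = np.einsum("q,qc,qe->ce", wq, Nq, Nq)
    loc = areas[:, None, None] * M_loc[None, :, :]
    ndc = space.ndof_cell
    rows = np.repeat(space.cell_dofs, ndc, axis=1).ravel()
    cols = np.tile(space.cell_dofs, (1, ndc)).ravel()
    M = sp.coo_matrix((loc.ravel(), (rows, cols)), shape=(space.D, space.D)).tocsr()
    M.sum_duplicates()
    return M


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def solve_full(system: AssembledSystem, method: str = "direct",
               rtol: float = 1e-12) -> np.ndarray:
    """Solve A x = F; verifies the relative residual is < 1e-10."""
    A, F = system.A, system.F
    if method == "direct":
        x = spla.spsolve(A.tocsc(), F)
    elif method == "cg":
        ilu = spla.spilu(A.tocsc(), drop_tol=1e-5, fill_factor=20)
        Mop = spla.LinearOperator(A.shape, ilu.solve)
        x, info = spla.cg(A, F, rtol=rtol, atol=0.0, maxiter=20000, M=Mop)
        if info != 0:
            raise RuntimeError(f"CG did not converge (info={info})")
    else:
        raise ValueError(f"unknown method {method!r}")
    nF = np.linalg.norm(F)
    res = np.linalg.norm(A @ x - F) / (nF if nF > 0 else 1.0)
    if not np.isfinite(res) or res > 1e-10:
        raise RuntimeError(f"solver residual {res:.2e} exceeds 1e-10 (singular system?)")
    return x


# ---------------------------------------------------------------------------
# Point location and interpolation
# ---------------------------------------------------------------------------

class CellLocator:
    """Uniform-grid spatial hash over cell bounding boxes.

    The bin size is at least the largest cell bounding-box extent, so any
    cell overlaps at most 2x2 bins and the cell containing a query point is
    always registered in the point's own bin.
    """

    def __init__(self, mesh: Mesh):
        self.mesh = mesh
        p = mesh.nodes[mesh.cells]                   # (T, 3, 2)
        lo = p.min(axis=1)
        hi = p.max(axis=1)
        ext = (hi - lo).max(axis=0)
        self.origin = mesh.nodes.min(axis=0) - 1e-9
        self.bin = float(max(ext.max(), 1e-12)) * (1 + 1e-9)
        span = mesh.nodes.max(axis=0) - self.origin
        self.nb = np.maximum((span / self.bin).astype(int) + 1, 1)
        ij_lo = np.clip(((lo - self.origin) / self.bin).astype(int), 0, self.nb - 1)
        ij_hi = np.clip(((hi - self.origin) / self.bin).astype(int), 0, self.nb - 1)
        pairs_bin, pairs_cell = [], []
        cell_idx = np.arange(mesh.n_cells)
        for dx in (0, 1):
            for dy in (0, 1):
                bi = np.minimum(ij_lo[:, 0] + dx, ij_hi[:, 0])
                bj = np.minimum(ij_lo[:, 1] + dy, ij_hi[:, 1])
                pairs_bin.append(bi * self.nb[1] + bj)
                pairs_cell.append(cell_idx)
        b = np.concatenate(pairs_bin)
        c = np.concatenate(pairs_cell)
        uniq = b * np.int64(mesh.n_cells) + c
        keep = np.unique(uniq)
        b, c = keep // mesh.n_cells, keep % mesh.n_cells
        order = np.argsort(b, kind="stable")
        self.sorted_bins = b[order]
        self.sorted_cells = c[order]
        # precompute barycentric transform per cell
        p0 = p[:, 0]
        d1 = p[:, 1] - p0
        d2 = p[:, 2] - p0
        det = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
        det = np.where(det == 0, 1e-300, det)
        self._p0 = p0
        self._inv = np.empty((mesh.n_cells, 2, 2))
        self._inv[:, 0, 0] = d2[:, 1] / det
        self._inv[:, 0, 1] = -d2[:, 0] / det
        self._inv[:, 1, 0] = -d1[:, 1] / det
        self._inv[:, 1, 1] = d1[:, 0] / det

    def locate(self, points: np.ndarray, tol: float = 1e-9
               ) -> tuple[np.ndarray, np.ndarray]:
        """Containing cell per point (-1 if none) and barycentric coords (n, 3).

        Inverted cells are handled by the signed barycentric test (the
        transform is orientation-agnostic), mirroring imperfect-registration
        tolerance in mesh morphing.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        npts = len(points)
        ij = ((points - self.origin) / self.bin).astype(int)
        inside_grid = np.all((ij >= 0) & (ij < self.nb), axis=1)
        bins = np.where(inside_grid, ij[:, 0] * self.nb[1] + ij[:, 1], -1)
        lo = np.searchsorted(self.sorted_bins, bins, side="left")
        hi = np.searchsorted(self.sorted_bins, bins, side="right")
        counts = np.where(inside_grid, hi - lo, 0)
        found = np.full(npts, -1, dtype=np.int64)
        bary = np.zeros((npts, 3))
        if counts.sum() == 0:
            return found, bary
        pt_idx = np.repeat(np.arange(npts), counts)
        offs = np.concatenate([np.arange(c) for c in counts]) if npts else np.array([], int)
        cand = self.sorted_cells[np.repeat(lo, counts) + offs]
        rel = points[pt_idx] - self._p0[cand]
        l23 = np.einsum("nij,nj->ni", self._inv[cand], rel)
        l1 = 1.0 - l23.sum(axis=1)
        lam = np.column_stack([l1, l23])
        ok = np.all(lam >= -tol, axis=1)
        # first matching candidate wins (reverse order so earliest overwrites)
        sel = np.flatnonzero(ok)[::-1]
        found[pt_idx[sel]] = cand[sel]
        bary[pt_idx[sel]] = lam[sel]
        return found, bary

    def locate_bruteforce(self, points: np.ndarray, tol: float = 1e-9
                          ) -> tuple[np.ndarray, np.ndarray]:
        """All-cells scan oracle (quadratic cost; for verification only)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        found = np.full(len(points), -1, dtype=np.int64)
        bary = np.zeros((len(points), 3))
        for i, pt in enumerate(points):
            rel = pt[None, :] - self._p0
            l23 = np.einsum("nij,nj->ni", self._inv, rel)
            l1 = 1.0 - l23.sum(axis=1)
            lam = np.column_stack([l1, l23])
            ok = np.flatnonzero(np.all(lam >= -tol, axis=1))
            if ok.size:
                found[i] = ok[0]
                bary[i] = lam[ok[0]]
        return found, bary


def locate_and_interpolate(field: Field, points: np.ndarray,
                           locator: CellLocator | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate a (multi-field) FE function at arbitrary points.

    Returns ``(values, found)`` where values is (n_points, n_fields); rows of
    points outside every cell are zero-filled with ``found = False`` (the
    caller decides how to extrapolate).
    """
    space = field.space
    if locator is None:
        locator = CellLocator(space.mesh)
    points = np.atleast_2d(np.asarray(points, dtype=float))
    cells, bary = locator.locate(points)
    found = cells >= 0
    values = np.zeros((len(points), space.n_fields))
    if np.any(found):
        idx = np.flatnonzero(found)
        N = shape_values(space.order, bary[idx])            # (m, ndc)
        dofs = space.cell_dofs[cells[idx]]                  # (m, ndc)
        D = space.D
        for f in range(space.n_fields):
            cf = field.coeffs[f * D:(f + 1) * D]
            values[idx, f] = np.einsum("mc,mc->m", N, cf[dofs])
    return values, found


def boundary_integral(field: Field, f: int, marker: int) -> float:
    """Integral of component ``f`` over the marked boundary (3-pt Gauss)."""
    space = field.space
    mesh = space.mesh
    sel = np.flatnonzero(mesh.facet_markers == marker)
    tq, tw = _gauss_1d(3)
    Sq = _segment_shape(space.order, tq)
    lengths = mesh.facet_lengths()[sel]
    vals = field.component(f)[space.facet_dofs[sel]]       # (F, nfdof)
    per_facet = (vals @ Sq.T) @ tw                          # (F,)
    return float(np.sum(per_facet * lengths))


# ---------------------------------------------------------------------------
# Norms
# ---------------------------------------------------------------------------

def l2_norm(field: Field, fields: Sequence[int] | None = None,
            M: sp.csr_matrix | None = None) -> float:
    """True L2 norm sqrt(u^T M u), summed in quadrature over selected fields."""
    if M is None:
        M = mass_matrix(field.space)
    sel = range(field.space.n_fields) if fields is None else fields
    total = 0.0
    for f in sel:
        c = field.component(f)
        total += float(c @ (M @ c))
    return float(np.sqrt(total))


def relative_l2(field: Field, reference: Field,
                fields: Sequence[int] | None = None,
                per_field: bool = False,
                M: sp.csr_matrix | None = None):
    """Relative L2 error ||u - ref|| / ||ref|| (combined or per field)."""
    if not field.space.compatible_with(reference.space):
        raise ValueError("field and reference must share mesh and space")
    if M is None:
        M = mass_matrix(field.space)
    sel = list(range(field.space.n_fields)) if fields is None else list(fields)
    if per_field:
        out = []
        for f in sel:
            d = field.component(f) - reference.component(f)
            r = reference.component(f)
            nr = np.sqrt(float(r @ (M @ r)))
            if nr == 0.0:
                raise ZeroDivisionError(f"reference field {f} has zero L2 norm")
            out.append(float(np.sqrt(float(d @ (M @ d)))) / nr)
        return np.array(out)
    num = sq_den = 0.0
    for f in sel:
        d = field.component(f) - reference.component(f)
        r = reference.component(f)
        num += float(d @ (M @ d))
        sq_den += float(r @ (M @ r))
    if sq_den == 0.0:
        raise ZeroDivisionError("reference has zero L2 norm")
    return float(np.sqrt(num / sq_den))
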