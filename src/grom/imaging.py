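"""Images, dense displacement fields, and deformable registration.

An :class:`ImageGrid` is a 2D intensity volume with a voxel-to-world affine
(mm).  A :class:`DeformationField` stores a dense displacement field u(x) in
world millimetres on such a grid; the deformation is x -> x + u(x)
(identity-plus-displacement convention).  Both round-trip through NIfTI
(2D data stored as single-slice volumes) so externally computed warps, e.g.
from ANTs-style pipelines, can be plugged in.

The in-repo registration is a diffusion-regularized, multi-resolution
demons scheme (SSD metric, Gaussian-smoothed updates) — a deliberately
simple, fully deterministic stand-in for heavier registration frameworks;
it treats registration as a pluggable vehicle for the geometry-mapping
pipeline rather than a contribution of its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import scipy.ndimage as ndi

try:
    import nibabel as nib
except ImportError:  # pragma: no cover - nibabel is a hard dependency
    nib = None


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass
class ImageGrid:
    """2D intensity image with voxel-to-world affine.

    ``affine`` is 3x3 homogeneous: world = A[:2, :2] @ (i, j) + A[:2, 2],
    where (i, j) index ``data``.  Synthetic images use axis-aligned affines
    with isotropic positive voxel size.
    """

    data: np.ndarray
    affine: np.ndarray
    description: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("only 2D images are supported")
        if self.affine.shape != (3, 3):
            raise ValueError("affine must be 3x3 homogeneous")
        if abs(np.linalg.det(self.affine[:2, :2])) < 1e-15:
            raise ValueError("affine is singular")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("image data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:2, :2], axis=0)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        inv = np.linalg.inv(self.affine[:2, :2])
        return (points - self.affine[:2, 2]) @ inv.T

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(idx)
        return idx @ self.affine[:2, :2].T + self.affine[:2, 2]

    def sample(self, points: np.ndarray, order: int = 1) -> np.ndarray:
        """Interpolate intensities at world points (edge-clamped)."""
        ij = self.world_to_index(points)
        return ndi.map_coordinates(self.data, ij.T, order=order, mode="nearest")


def centered_affine(shape: tuple[int, int], voxel_size: float) -> np.ndarray:
    """Axis-aligned affine placing the grid centre at the world origin."""
    A = np.eye(3)
    A[0, 0] = A[1, 1] = voxel_size
    A[:2, 2] = -0.5 * (np.asarray(shape) - 1) * voxel_size
    return A


@dataclass
class DeformationField:
    """Dense displacement field u(x) [mm, world axes] on an image lattice."""

    displacement: np.ndarray          # (nx, ny, 2)
    affine: np.ndarray
    interp_order: int = 1
    metric_history: np.ndarray | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.displacement = np.asarray(self.displacement, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.displacement.ndim != 3 or self.displacement.shape[2] != 2:
            raise ValueError("displacement must be (nx, ny, 2) for 2D grids")
        if self.interp_order not in (1, 3):
            raise ValueError("interp_order must be 1 (linear) or 3 (cubic)")
        if not np.all(np.isfinite(self.displacement)):
            raise ValueError("displacement contains non-finite values")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid(np.zeros(self.displacement.shape[:2]), self.affine)

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:2, :2], axis=0)

    def displacement_at(self, points: np.ndarray) -> np.ndarray:
        """Interpolated displacement [mm] at world points (edge-clamped)."""
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inv = np.linalg.inv(self.affine[:2, :2])
        ij = ((points - self.affine[:2, 2]) @ inv.T).T
        out = np.empty_like(points)
        for c in range(2):
            out[:, c] = ndi.map_coordinates(
                self.displacement[..., c], ij, order=self.interp_order, mode="nearest"
            )
        return out


def apply_deformation(field: DeformationField, points: np.ndarray) -> np.ndarray:
    """Map world points through x -> x + u(x).

    Points outside the lattice use nearest-edge-clamped displacement values.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if not np.all(np.isfinite(points)):
        raise ValueError("points must be finite")
    return points + field.displacement_at(points)


def jacobian(field: DeformationField, points: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """Deformation Jacobians J = I + grad u at world points.

    Gradients are central finite differences on the lattice (one-sided on the
    boundary ring), interpolated to the query points.  Returns ``(J, interior)``
    where ``J`` is (n, 2, 2) and ``interior`` flags points at least one voxel
    inside the lattice (outside that band the one-sided stencil applies).
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    A = field.affine[:2, :2]
    inv = np.linalg.inv(A)
    # du/dworld via chain rule: du/didx @ didx/dworld
    grads = np.empty(field.displacement.shape[:2] + (2, 2))
    for c in range(2):
        gi, gj = np.gradient(field.displacement[..., c])
        didx = np.stack([gi, gj], axis=-1)           # du_c/d(i,j)
        grads[..., c, :] = didx @ inv                # du_c/d(x,y)
    ij = ((points - field.affine[:2, 2]) @ inv.T).T
    J = np.empty((len(points), 2, 2))
    for a in range(2):
        for b in range(2):
            J[:, a, b] = ndi.map_coordinates(
                grads[..., a, b], ij, order=1, mode="nearest"
            )
    J += np.eye(2)
    shp = np.asarray(field.displacement.shape[:2])
    interior = np.all((ij.T >= 1.0) & (ij.T <= shp - 2), axis=1)
    return J, interior


def det_jacobian(field: DeformationField, points: np.ndarray) -> np.ndarray:
    J, _ = jacobian(field, points)
    return np.linalg.det(J)


# ---------------------------------------------------------------------------
# Demons registration
# ---------------------------------------------------------------------------

@dataclass
class RegistrationOptions:
    """Multi-resolution demons settings (all deterministic).

    ``sigma_update`` smooths each iteration's force field (fluid-like term),
    ``sigma_total`` smooths the accumulated field (diffusion regularization);
    both in voxels of the current level.  ``max_step`` caps the per-iteration
    displacement update in voxels.
    """

    levels: tuple[int, ...] = (4, 2, 1)
    iterations: tuple[int, ...] = (100, 100, 100)
    sigma_update: float = 1.0
    sigma_total: float = 1.5
    max_step: float = 0.5
    plateau_window: int = 10
    plateau_rtol: float = 0.01
    com_init: bool = True


def _downsample(img: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return img
    sm = ndi.gaussian_filter(img, sigma=0.5 * factor)
    return sm[::factor, ::factor]


def _demons_level(fixed: np.ndarray, moving: np.ndarray, u: np.ndarray,
                  opts: RegistrationOptions, iterations: int,
                  history: list[float]) -> np.ndarray:
    """Demons iterations at one level; u in index units of this level's grid."""
    nx, ny = fixed.shape
    gi, gj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    base = np.stack([gi, gj]).astype(float)
    eps = 1e-12
    best_u, best_m = u.copy(), np.inf
    for it in range(iterations):
        coords = base + np.moveaxis(u, -1, 0)
        mw = ndi.map_coordinates(moving, coords, order=1, mode="nearest")
        diff = fixed - mw
        metric = float(np.mean(diff ** 2))
        history.append(metric)
        if metric < best_m:
            best_m, best_u = metric, u.copy()
        if not np.isfinite(metric):
            raise FloatingPointError("registration metric became non-finite")
        gx, gy = np.gradient(mw)
        gnorm2 = gx ** 2 + gy ** 2
        denom = gnorm2 + diff ** 2
        scale = np.where(denom > eps, diff / np.maximum(denom, eps), 0.0)
        v = np.stack([scale * gx, scale * gy], axis=-1)
        v[..., 0] = ndi.gaussian_filter(v[..., 0], opts.sigma_update)
        v[..., 1] = ndi.gaussian_filter(v[..., 1], opts.sigma_update)
        vmax = float(np.max(np.abs(v)))
        if vmax > opts.max_step:
            v *= opts.max_step / vmax
        u = u + v
        u[..., 0] = ndi.gaussian_filter(u[..., 0], opts.sigma_total)
        u[..., 1] = ndi.gaussian_filter(u[..., 1], opts.sigma_total)
    return best_u


def register(moving: ImageGrid, fixed: ImageGrid,
             opts: RegistrationOptions | None = None) -> DeformationField:
    """Deformable registration; returns the point map moving-space -> fixed-space.

    The field is sampled on the ``moving`` grid: ``x + u(x)`` carries a point
    of the moving image (e.g. a mesh node in subject space) onto the
    corresponding anatomy in the fixed (target) image, the convention needed
    for morphing subject meshes onto a target geometry.  Internally the
    demons iteration resamples ``fixed`` toward ``moving``, which yields
    exactly this forward point map on the moving lattice.

    Fully deterministic given (images, opts).  The returned field carries the
    SSD metric history; ``converged`` is True once the metric has stopped
    decreasing (relative reduction below ``plateau_rtol`` over the final
    ``plateau_window`` iterations) and False when it was still decreasing at
    the iteration cap; the best-so-far field is returned in either case.
    """
    if opts is None:
        opts = RegistrationOptions()
    if moving.shape != fixed.shape or not np.allclose(moving.affine, fixed.affine):
        raise ValueError("moving and fixed must share grid shape and affine")
    vox = float(moving.voxel_size[0])
    if not np.allclose(moving.voxel_size, vox):
        raise ValueError("registration requires isotropic voxels")

    # role swap: demons 'fixed' = moving image so u lives on the moving grid
    F_img, M_img = moving.data, fixed.data
    history: list[float] = []
    u = None
    for factor, iters in zip(opts.levels, opts.iterations):
        Fl = _downsample(F_img, factor)
        Ml = _downsample(M_img, factor)
        if u is None:
            u = np.zeros(Fl.shape + (2,))
            if opts.com_init:
                cf = np.array(ndi.center_of_mass(np.maximum(Fl, 0) + 1e-12))
                cm = np.array(ndi.center_of_mass(np.maximum(Ml, 0) + 1e-12))
                u += (cm - cf)[None, None, :]
        else:
            zoom = np.array(Fl.shape) / np.array(u.shape[:2])
            u = np.stack(
                [ndi.zoom(u[..., c], zoom, order=1) * zoom[c] for c in range(2)],
                axis=-1,
            )
        u = _demons_level(Fl, Ml, u, opts, iters, history)
    assert u is not None

    w = opts.plateau_window
    converged = True
    if len(history) > w and history[-1 - w] > 0:
        converged = (history[-1 - w] - history[-1]) / history[-1 - w] < opts.plateau_rtol

    u_mm = u * vox * opts.levels[-1]
    return DeformationField(
        displacement=u_mm,
        affine=moving.affine.copy(),
        metric_history=np.asarray(history),
        converged=converged,
    )


def ssd(a: ImageGrid, b: ImageGrid) -> float:
    return float(np.mean((a.data - b.data) ** 2))


def warp_image(image: ImageGrid, field: DeformationField,
               target_grid: ImageGrid) -> ImageGrid:
    """Pull ``image`` back through the field onto ``target_grid``'s lattice.

    Each lattice point x of ``target_grid`` samples ``image`` at x + u(x),
    producing ``image`` composed with the deformation.  With the
    :func:`register` convention (field on the moving grid, pointing into the
    fixed image's space) this composes the fixed image with the map, giving
    an approximation of the moving image for visual/SSD diagnostics.
    """
    nx, ny = target_grid.shape
    gi, gj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = target_grid.index_to_world(np.column_stack([gi.ravel(), gj.ravel()]))
    mapped = apply_deformation(field, pts)
    vals = image.sample(mapped)
    return ImageGrid(vals.reshape(nx, ny), target_grid.affine.copy(),
                     description=f"warped:{image.description}")


# ---------------------------------------------------------------------------
# NIfTI interop
# ---------------------------------------------------------------------------

def _affine_2d_to_4d(affine: np.ndarray) -> np.ndarray:
    A = np.eye(4)
    A[:2, :2] = affine[:2, :2]
    A[:2, 3] = affine[:2, 2]
    return A


def _affine_4d_to_2d(A: np.ndarray) -> np.ndarray:
    out = np.eye(3)
    out[:2, :2] = A[:2, :2]
    out[:2, 2] = A[:2, 3]
    return out


def save_image(image: ImageGrid, path: str | Path) -> None:
    """Write as a single-slice NIfTI volume."""
    img = nib.Nifti1Image(image.data[..., None].astype(np.float64),
                          _affine_2d_to_4d(image.affine))
    img.header["descrip"] = image.description[:79].encode()
    nib.save(img, str(path))


def load_image(path: str | Path) -> ImageGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        if data.shape[2] != 1:
            raise ValueError("expected a single-slice (2D) volume")
        data = data[..., 0]
    desc = img.header["descrip"].tobytes().rstrip(b"\x00").decode(errors="replace")
    return ImageGrid(data, _affine_4d_to_2d(img.affine), description=desc)


def save_field(field: DeformationField, path: str | Path) -> None:
    """Write displacement as a vector-valued single-slice NIfTI (mm units)."""
    # (nx, ny, 1, ncomp): components along the 4th axis
    data = field.displacement[:, :, None, :].astype(np.float64)
    img = nib.Nifti1Image(data, _affine_2d_to_4d(field.affine))
    img.header["intent_code"] = 1007  # displacement vector
    nib.save(img, str(path))


def load_field(path: str | Path, interp_order: int = 1) -> DeformationField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[2] != 1:
        raise ValueError("expected (nx, ny, 1, ncomp) displacement volume")
    if data.shape[3] != 2:
        raise ValueError(
            f"displacement has {data.shape[3]} components, expected 2 for a 2D grid"
        )
    return DeformationField(data[:, :, 0, :], _affine_4d_to_2d(img.affine),
                            interp_order=interp_order)
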