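"""Synthetic cohort of brain-slice geometries.

Each synthetic "subject" is a 2D annular domain: a star-shaped outer (pial)
boundary with low-order Fourier folding, and an elliptic inner hole standing
in for the cerebral ventricles.  The cohort mimics the structure of a
clinical CSF-disorder dataset: a majority subgroup with normal-range
ventricles ("healthy-like") and a subgroup with markedly enlarged ventricles
("iNPH-like" — ventriculomegaly being the geometric hallmark of idiopathic
normal pressure hydrocephalus).

Because every geometry is analytic, the cohort comes with exact
inter-subject correspondence maps (:func:`analytic_map_points`): polar angle
about the ventricle centre and the normalized annular coordinate rho are
preserved, so registration and solution-transfer accuracy can be measured
against ground truth — something impossible with real MRI.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field, asdict
from pathlib import Path

import numpy as np

from .fem import Mesh, PIAL, VENTRICLE
from .imaging import ImageGrid, DeformationField, centered_affine

FOLD_MODES = tuple(range(3, 9))       # Fourier modes k = 3..8 on the pial boundary
MAX_FOLD_SUM = 0.3                    # sum |a_k| bound keeping the curve star-shaped


# ---------------------------------------------------------------------------
# Parameter types
# ---------------------------------------------------------------------------

@dataclass
class GeometryParams:
    """Analytic description of one subject's annular brain-slice geometry.

    Outer boundary (polar about the origin):
        R(theta) = R0 * (1 + sum_k a_k cos(k theta + psi_k)),  k = 3..8.
    Inner (ventricle) boundary: ellipse with semi-axes ``vent_axes`` centred
    at ``vent_center``.  All lengths in mm.
    """

    subject_id: str
    group: str                         # "healthy" | "inph"
    R0: float
    fold_amps: np.ndarray
    fold_phases: np.ndarray
    vent_center: np.ndarray
    vent_axes: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        self.fold_amps = np.asarray(self.fold_amps, dtype=float)
        self.fold_phases = np.asarray(self.fold_phases, dtype=float)
        self.vent_center = np.asarray(self.vent_center, dtype=float)
        self.vent_axes = np.asarray(self.vent_axes, dtype=float)
        if self.group not in ("healthy", "inph"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.R0 <= 0 or np.any(self.vent_axes <= 0):
            raise ValueError("R0 and ventricle semi-axes must be positive")
        if len(self.fold_amps) != len(FOLD_MODES):
            raise ValueError(f"expected {len(FOLD_MODES)} fold amplitudes")
        if np.sum(np.abs(self.fold_amps)) >= MAX_FOLD_SUM:
            raise ValueError(
                f"sum |a_k| = {np.sum(np.abs(self.fold_amps)):.3f} >= {MAX_FOLD_SUM}; "
                "outer boundary may lose star-shapedness"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k in ("fold_amps", "fold_phases", "vent_center", "vent_axes"):
            d[k] = np.asarray(d[k]).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeometryParams":
        return cls(**d)


@dataclass
class CohortSpec:
    """Cohort-level generation settings.

    Defaults mirror the reference study conditions at desk scale: a 2D
    analogue of 1 mm isotropic T1-like volumes, and ~1.5 mm meshes.  The
    image field of view (192 mm) covers the full sampling range of outer
    radii (up to ~81 mm) with at least a 5-voxel margin.
    """

    n_healthy: int
    n_inph: int
    master_seed: int = 1
    image_shape: tuple[int, int] = (192, 192)
    voxel_size: float = 1.0
    mesh_h: float = 1.5

    def __post_init__(self) -> None:
        if self.n_healthy < 0 or self.n_inph < 0 or self.n_healthy + self.n_inph < 2:
            raise ValueError("need n_healthy >= 0, n_inph >= 0 and at least 2 subjects")
        if self.voxel_size <= 0 or self.mesh_h <= 0:
            raise ValueError("voxel_size and mesh_h must be positive")

    @property
    def n_subjects(self) -> int:
        return self.n_healthy + self.n_inph

    def affine(self) -> np.ndarray:
        return centered_affine(tuple(self.image_shape), self.voxel_size)


# Sampling ranges (study conditions; see docs/methods.md)
_R0_RANGE = (55.0, 65.0)
_AMP_RANGE = (0.0, 0.04)
_VENT_HEALTHY = (6.0, 10.0)
_VENT_INPH = (14.0, 22.0)
_VENT_CENTER_RANGE = (-3.0, 3.0)
_MIN_CLEARANCE = 2.0                  # mm of parenchyma required at the thinnest point


# ---------------------------------------------------------------------------
# Boundary curves
# ---------------------------------------------------------------------------

def outer_radius(params: GeometryParams, theta: np.ndarray) -> np.ndarray:
    """Pial boundary radius about the origin, R(theta)."""
    theta = np.asarray(theta, dtype=float)
    r = np.ones_like(theta)
    for k, a, psi in zip(FOLD_MODES, params.fold_amps, params.fold_phases):
        r = r + a * np.cos(k * theta + psi)
    return params.R0 * r


def ventricle_radius(params: GeometryParams, theta: np.ndarray) -> np.ndarray:
    """Ventricle (ellipse) boundary radius about ``vent_center``."""
    theta = np.asarray(theta, dtype=float)
    A, B = params.vent_axes
    return A * B / np.sqrt((B * np.cos(theta)) ** 2 + (A * np.sin(theta)) ** 2)


def boundary_radius(params: GeometryParams, theta, which: str):
    """Polar radius of one boundary curve; ``which`` in {"outer", "ventricle"}.

    "outer" is measured about the origin, "ventricle" about ``vent_center``.
    """
    if which == "outer":
        return outer_radius(params, theta)
    if which == "ventricle":
        return ventricle_radius(params, theta)
    raise ValueError(f"which must be 'outer' or 'ventricle', got {which!r}")


def outer_radius_about_center(params: GeometryParams, theta: np.ndarray,
                              iters: int = 60) -> np.ndarray:
    """Distance from ``vent_center`` to the pial curve along direction theta.

    Solved per angle by bisection on s in [0, 1.4 R0 + |c|]; the outer curve
    is star-shaped about the origin and the ventricle centre is well inside
    it, so the ray crosses the curve exactly once.
    """
    theta = np.asarray(theta, dtype=float)
    c = params.vent_center
    e = np.stack([np.cos(theta), np.sin(theta)], axis=-1)

    def f(s):
        p = c + s[..., None] * e
        r = np.linalg.norm(p, axis=-1)
        ang = np.arctan2(p[..., 1], p[..., 0])
        return r - outer_radius(params, ang)

    lo = np.zeros_like(theta)
    hi = np.full_like(theta, 1.4 * params.R0 + np.linalg.norm(c))
    if np.any(f(lo) >= 0) or np.any(f(hi) <= 0):
        raise ValueError("outer boundary not star-shaped about the ventricle centre")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        neg = f(mid) < 0
        lo = np.where(neg, mid, lo)
        hi = np.where(neg, hi, mid)
    return 0.5 * (lo + hi)


def min_clearance(params: GeometryParams, n_angles: int = 2048) -> float:
    """Smallest parenchymal thickness over a dense angular scan [mm]."""
    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    return float(np.min(outer_radius_about_center(params, theta)
                        - ventricle_radius(params, theta)))


def analytic_area(params: GeometryParams, n_angles: int = 4096) -> float:
    """Area of the annular domain by polar quadrature about ``vent_center``."""
    theta = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    R = outer_radius_about_center(params, theta)
    rv = ventricle_radius(params, theta)
    return float(0.5 * np.sum(R ** 2 - rv ** 2) * (2 * np.pi / n_angles))


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

def _draw_subject(subject_id: str, group: str, seed: int) -> GeometryParams:
    rng = np.random.default_rng(seed)
    R0 = rng.uniform(*_R0_RANGE)
    amps = rng.uniform(*_AMP_RANGE, size=len(FOLD_MODES))
    phases = rng.uniform(0.0, 2 * np.pi, size=len(FOLD_MODES))
    center = rng.uniform(*_VENT_CENTER_RANGE, size=2)
    rng_axes = _VENT_INPH if group == "inph" else _VENT_HEALTHY
    axes = rng.uniform(*rng_axes, size=2)
    return GeometryParams(
        subject_id=subject_id, group=group, R0=R0,
        fold_amps=amps, fold_phases=phases,
        vent_center=center, vent_axes=axes, seed=seed,
    )


def sample_cohort(spec: CohortSpec) -> list[GeometryParams]:
    """Draw the cohort deterministically from ``spec.master_seed``.

    Subjects carry independent per-subject seeds.  A draw violating the
    annular-topology invariant is retried with an incremented seed (at most
    100 attempts) — rare for the default ranges.
    """
    master = np.random.default_rng(spec.master_seed)
    seeds = master.integers(0, 2 ** 31 - 1, size=spec.n_subjects)
    groups = ["healthy"] * spec.n_healthy + ["inph"] * spec.n_inph
    out = []
    for i, group in enumerate(groups):
        sid = f"sub-{i:03d}"
        seed = int(seeds[i])
        for attempt in range(100):
            params = _draw_subject(sid, group, seed + attempt * 1_000_003)
            if min_clearance(params) > _MIN_CLEARANCE:
                break
        else:
            raise RuntimeError(
                f"could not draw a valid geometry for {sid} ({group}) "
                f"after 100 attempts from seed {seed}"
            )
        out.append(params)
    return out


def save_manifest(cohort: list[GeometryParams], spec: CohortSpec,
                  path: str | Path, files: dict[str, dict] | None = None) -> None:
    """JSON cohort manifest: spec, subjects and (optionally) artifact paths."""
    doc = {
        "spec": {
            "n_healthy": spec.n_healthy, "n_inph": spec.n_inph,
            "master_seed": spec.master_seed,
            "image_shape": list(spec.image_shape),
            "voxel_size": spec.voxel_size, "mesh_h": spec.mesh_h,
        },
        "subjects": [p.to_dict() for p in cohort],
    }
    if files:
        doc["files"] = files
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def load_manifest(path: str | Path) -> tuple[list[GeometryParams], CohortSpec]:
    doc = json.loads(Path(path).read_text())
    s = doc["spec"]
    spec = CohortSpec(
        n_healthy=s["n_healthy"], n_inph=s["n_inph"], master_seed=s["master_seed"],
        image_shape=tuple(s["image_shape"]), voxel_size=s["voxel_size"],
        mesh_h=s["mesh_h"],
    )
    cohort = [GeometryParams.from_dict(d) for d in doc["subjects"]]
    return cohort, spec


# ---------------------------------------------------------------------------
# Meshing
# ---------------------------------------------------------------------------

def build_mesh(params: GeometryParams, h: float) -> Mesh:
    """Structured conforming triangulation of the annulus at target size h.

    Nodes are laid out on rings of constant normalized annular coordinate
    rho about the ventricle centre; the inner ring is marked VENTRICLE, the
    outer ring PIAL (every boundary facet carries exactly one marker).
    """
    if h <= 0:
        raise ValueError("mesh size h must be positive")
    probe = np.linspace(0.0, 2 * np.pi, 720, endpoint=False)
    R = outer_radius_about_center(params, probe)
    rv = ventricle_radius(params, probe)
    if np.any(R - rv <= 0):
        raise ValueError(
            f"degenerate annulus for subject {params.subject_id}: "
            f"min thickness {float(np.min(R - rv)):.2f} mm <= 0 "
            f"(params: {params.to_dict()})"
        )
    mid = 0.5 * (R + rv)
    circumference = float(np.sum(mid) * (2 * np.pi / len(probe)))
    thickness = float(np.mean(R - rv))
    n_theta = max(16, int(round(circumference / h)))
    n_rho = max(3, int(round(thickness / h)))

    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    Rt = outer_radius_about_center(params, theta)
    rvt = ventricle_radius(params, theta)
    rho = np.linspace(0.0, 1.0, n_rho + 1)
    r = rvt[None, :] + rho[:, None] * (Rt - rvt)[None, :]      # (n_rho+1, n_theta)
    e = np.stack([np.cos(theta), np.sin(theta)], axis=-1)       # (n_theta, 2)
    nodes = params.vent_center[None, None, :] + r[..., None] * e[None, :, :]
    nodes = nodes.reshape(-1, 2)

    def nid(i, j):
        return i * n_theta + (j % n_theta)

    i_idx = np.arange(n_rho)[:, None]
    j_idx = np.arange(n_theta)[None, :]
    v00 = nid(i_idx, j_idx)
    v01 = nid(i_idx, j_idx + 1)
    v10 = nid(i_idx + 1, j_idx)
    v11 = nid(i_idx + 1, j_idx + 1)
    tris = np.concatenate([
        np.stack([v00, v01, v11], axis=-1).reshape(-1, 3),
        np.stack([v00, v11, v10], axis=-1).reshape(-1, 3),
    ])
    j = np.arange(n_theta)
    inner = np.column_stack([nid(0, j), nid(0, j + 1)])
    outer = np.column_stack([nid(n_rho, j), nid(n_rho, j + 1)])
    facets = np.vstack([inner, outer])
    markers = np.concatenate([
        np.full(n_theta, VENTRICLE, dtype=np.int64),
        np.full(n_theta, PIAL, dtype=np.int64),
    ])
    return Mesh(nodes, tris, facets, markers)


# ---------------------------------------------------------------------------
# Rasterization
# ---------------------------------------------------------------------------

def annular_coordinates(params: GeometryParams, points: np.ndarray
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(theta, rho) about the ventricle centre for arbitrary world points.

    rho = (r - r_v(theta)) / (R(theta) - r_v(theta)) is 0 on the ventricle
    boundary and 1 on the pial boundary; unclamped (may be <0 or >1).
    """
    points = np.atleast_2d(points)
    d = points - params.vent_center
    r = np.linalg.norm(d, axis=-1)
    theta = np.arctan2(d[:, 1], d[:, 0])
    R = outer_radius_about_center(params, theta)
    rv = ventricle_radius(params, theta)
    rho = (r - rv) / (R - rv)
    return theta, rho


def rasterize(params: GeometryParams, spec: CohortSpec) -> ImageGrid:
    """T1-like intensity image of the geometry on the cohort image grid.

    Intensity is 0 in the background and ventricle, and 0.4 + 0.6 rho inside
    the parenchyma (a radial gradient giving intensity-based registration
    signal away from edges, as T1 images have internal contrast), with an
    anti-aliased one-voxel band at both boundaries.
    """
    nx, ny = spec.image_shape
    affine = spec.affine()
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()]) @ affine[:2, :2].T + affine[:2, 2]

    d = pts - params.vent_center
    r = np.linalg.norm(d, axis=1)
    theta = np.arctan2(d[:, 1], d[:, 0])
    R = outer_radius_about_center(params, theta)
    rv = ventricle_radius(params, theta)

    fov = 0.5 * min(nx, ny) * spec.voxel_size
    max_extent = float(np.max(np.linalg.norm(params.vent_center))
                       + params.R0 * (1 + np.sum(np.abs(params.fold_amps))))
    if max_extent + 5 * spec.voxel_size > fov:
        raise ValueError(
            f"geometry (extent {max_extent:.1f} mm) exceeds the field of view "
            f"({fov:.1f} mm) with the required 5-voxel margin"
        )

    rho = np.clip((r - rv) / (R - rv), 0.0, 1.0)
    v = spec.voxel_size
    alpha_in = np.clip((r - rv) / v + 0.5, 0.0, 1.0)
    alpha_out = np.clip((R - r) / v + 0.5, 0.0, 1.0)
    intensity = (0.4 + 0.6 * rho) * alpha_in * alpha_out
    return ImageGrid(intensity.reshape(nx, ny), affine,
                     description=f"synthetic:{params.subject_id}")


# ---------------------------------------------------------------------------
# Analytic inter-subject map
# ---------------------------------------------------------------------------

def analytic_map_points(src: GeometryParams, dst: GeometryParams,
                        points: np.ndarray) -> np.ndarray:
    """Exact geometric correspondence map, src space -> dst space.

    Preserves the polar angle about the ventricle centre and the normalized
    annular coordinate rho: a point at (theta, rho) in the source annulus is
    sent to (theta, rho) in the destination annulus (ventricle centres are
    translated onto each other).  The map extends continuously to the whole
    plane: radial scaling inside the ventricle (centre onto centre) and a
    constant radial offset beyond the pial curve, so src == dst gives the
    identity everywhere.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d = points - src.vent_center
    r = np.linalg.norm(d, axis=-1)
    theta = np.arctan2(d[:, 1], d[:, 0])
    Rs = outer_radius_about_center(src, theta)
    rvs = ventricle_radius(src, theta)
    Rd = outer_radius_about_center(dst, theta)
    rvd = ventricle_radius(dst, theta)
    rho = (r - rvs) / (Rs - rvs)
    r_new = np.where(
        rho < 0.0, r * rvd / rvs,                          # inside ventricle
        np.where(rho > 1.0, Rd + (r - Rs),                 # outside pial curve
                 rvd + rho * (Rd - rvd)))                  # annulus proper
    e = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    return dst.vent_center[None, :] + r_new[:, None] * e


def analytic_map(src: GeometryParams, dst: GeometryParams,
                 spec: CohortSpec) -> DeformationField:
    """Ground-truth deformation field sampled on the cohort image grid.

    The displacement implements :func:`analytic_map_points` at the voxel
    centres of the source image grid (identity-plus-displacement, world mm).
    """
    nx, ny = spec.image_shape
    affine = spec.affine()
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()]) @ affine[:2, :2].T + affine[:2, 2]
    mapped = analytic_map_points(src, dst, pts)
    disp = (mapped - pts).reshape(nx, ny, 2)
    return DeformationField(disp, affine)
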