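"""Cohort-level experiment drivers.

These functions chain the full pipeline on the synthetic cohort — generate
geometries, solve both forward models on every subject, map the solutions
onto a target subject's geometry, build POD bases and quantify mapping /
reduction errors — mirroring the leave-one-out, unseen-target evaluation
protocol: a target's own full-order solution is never part of its snapshot
set (except in dedicated inclusion-exactness checks).

The deformation backend is configurable: ``"analytic"`` uses the exact
closed-form inter-subject correspondence (isolating transfer and reduction
behaviour from registration error), ``"demons"`` uses the in-repo
intensity-based registration on the rasterized images (quantifying the
registration contribution).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd

from . import cohort as co
from . import imaging, rom, transfer
from .fem import Field, mass_matrix, relative_l2
from .models import (
    MODEL_A_FIELDS,
    MODEL_B_FIELDS,
    assemble_model,
    model_space,
    solve_model,
)


@dataclass
class Subject:
    params: co.GeometryParams
    mesh: "co.Mesh"

    @property
    def subject_id(self) -> str:
        return self.params.subject_id

    @property
    def group(self) -> str:
        return self.params.group


def build_cohort(spec: co.CohortSpec) -> list[Subject]:
    """Sample the cohort and mesh every subject at ``spec.mesh_h``."""
    return [Subject(p, co.build_mesh(p, spec.mesh_h))
            for p in co.sample_cohort(spec)]


def default_targets(subjects: list[Subject]) -> dict[str, int]:
    """Designated evaluation targets: the first subject of each group."""
    out: dict[str, int] = {}
    for i, s in enumerate(subjects):
        if s.group not in out:
            out[s.group] = i
    return out


def solve_cohort(subjects: list[Subject], which: str, params=None) -> list[Field]:
    """Full-order solve of one model on every subject geometry."""
    return [solve_model(s.mesh, which, params) for s in subjects]


def make_deformation(src: co.GeometryParams, dst: co.GeometryParams,
                     spec: co.CohortSpec, backend: str = "analytic",
                     reg_opts: imaging.RegistrationOptions | None = None):
    """Subject-to-target deformation under the chosen backend.

    ``"analytic"``: the exact closed-form point map (ground truth).
    ``"demons"``: intensity-based registration of the rasterized images;
    returns a dense displacement field on the source grid.
    """
    if backend == "analytic":
        return lambda pts: co.analytic_map_points(src, dst, pts)
    if backend == "demons":
        moving = co.rasterize(src, spec)
        fixed = co.rasterize(dst, spec)
        return imaging.register(moving, fixed, reg_opts)
    raise ValueError(f"unknown deformation backend {backend!r}")


def map_cohort_to_target(
    subjects: list[Subject],
    fields: list[Field],
    target_idx: int,
    spec: co.CohortSpec,
    backend: str = "analytic",
    k_neighbors: int = 8,
    sigma_factor: float = 1.0,
    reg_opts: imaging.RegistrationOptions | None = None,
) -> tuple[rom.SnapshotMatrix, list[transfer.TransferReport]]:
    """Map every non-target solution onto the target geometry (leave-one-out)."""
    target = subjects[target_idx]
    target_space = fields[target_idx].space
    mapped, reports, ids = [], [], []
    for i, (s, f) in enumerate(zip(subjects, fields)):
        if i == target_idx:
            continue
        deform = make_deformation(s.params, target.params, spec, backend, reg_opts)
        snap, rep = transfer.map_snapshot(f, deform, target_space,
                                          k_neighbors=k_neighbors,
                                          sigma_factor=sigma_factor)
        mapped.append(snap)
        reports.append(rep)
        ids.append(s.subject_id)
    return rom.build_snapshots(mapped, source_ids=ids), reports


def registration_accuracy(field: imaging.DeformationField,
                          src: co.GeometryParams, dst: co.GeometryParams,
                          spec: co.CohortSpec,
                          rho_band: tuple[float, float] = (0.1, 0.9)) -> dict:
    """Registration-vs-ground-truth diagnostics over the annulus interior.

    The synthetic intensity is a function of the annular coordinate rho
    alone, so image matching constrains motion only along grad(rho); the
    component sliding along intensity isocontours is a gauge freedom no
    intensity-driven registration can observe.  Accordingly this reports
    both the full-vector displacement error against the analytic map
    (``mean_error_mm`` — includes the unobservable gauge part, diagnostic
    only) and the intensity-observable error projected on the local
    grad(rho) direction (``mean_observable_error_mm`` — the accuracy gate).
    """
    nx, ny = spec.image_shape
    A = spec.affine()
    ii, jj = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.column_stack([ii.ravel(), jj.ravel()]) @ A[:2, :2].T + A[:2, 2]
    _, rho = co.annular_coordinates(src, pts)
    sel = (rho > rho_band[0]) & (rho < rho_band[1])
    p = pts[sel]
    u_true = co.analytic_map_points(src, dst, p) - p
    u_est = field.displacement_at(p)
    diff = u_est - u_true
    # grad(rho) direction by central differences
    eps = 0.5 * spec.voxel_size
    gx = (co.annular_coordinates(src, p + [eps, 0])[1]
          - co.annular_coordinates(src, p - [eps, 0])[1])
    gy = (co.annular_coordinates(src, p + [0, eps])[1]
          - co.annular_coordinates(src, p - [0, eps])[1])
    g = np.column_stack([gx, gy])
    ghat = g / np.linalg.norm(g, axis=1, keepdims=True)
    observable = np.abs(np.einsum("ij,ij->i", diff, ghat))
    dets = imaging.det_jacobian(field, p)
    return {
        "mean_error_mm": float(np.linalg.norm(diff, axis=1).mean()),
        "mean_observable_error_mm": float(observable.mean()),
        "det_j_positive_fraction": float(np.mean(dets > 0)),
        "voxel_size_mm": float(spec.voxel_size),
        "n_points": int(sel.sum()),
    }


def inverse_consistency(field_ab: imaging.DeformationField,
                        field_ba: imaging.DeformationField,
                        points: np.ndarray) -> float:
    """Mean ||phi_ba(phi_ab(x)) - x|| [mm] — reported, never asserted
    (greedy demons is not symmetric by construction)."""
    fwd = imaging.apply_deformation(field_ab, points)
    back = imaging.apply_deformation(field_ba, fwd)
    return float(np.linalg.norm(back - np.atleast_2d(points), axis=1).mean())


# ---------------------------------------------------------------------------
# Experiment: mapping error by subgroup
# ---------------------------------------------------------------------------

def mapping_error_table(subjects: list[Subject], fields: list[Field],
                        target_idx: int, snapshots: rom.SnapshotMatrix
                        ) -> pd.DataFrame:
    """Per-(source, field) relative L2 error of mapped vs target solution."""
    reference = fields[target_idx]
    M = mass_matrix(reference.space)
    groups = {s.subject_id: s.group for s in subjects}
    rows = []
    for col, sid in enumerate(snapshots.source_ids):
        mapped = Field(reference.space, snapshots.X[:, col],
                       field_names=reference.field_names)
        errs = relative_l2(mapped, reference, per_field=True, M=M)
        for fname, e in zip(reference.field_names, errs):
            rows.append({
                "source_id": sid, "group": groups[sid],
                "target_id": subjects[target_idx].subject_id,
                "field": fname, "rel_l2_error": float(e),
            })
    return pd.DataFrame(rows)


def subgroup_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Median and quartiles of the mapping error by source subgroup.

    Subsets follow the evaluation protocol: the full dataset, the
    healthy-like-only subset and the iNPH-like-only subset.
    """
    out = []
    subsets = {"full": table,
               "healthy": table[table.group == "healthy"],
               "inph": table[table.group == "inph"]}
    for name, sub in subsets.items():
        if len(sub) == 0:
            continue
        q = sub.rel_l2_error.quantile([0.25, 0.5, 0.75])
        out.append({"subset": name, "n": sub.source_id.nunique(),
                    "q25": q[0.25], "median": q[0.5], "q75": q[0.75]})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Experiment: SVD spectra and reduced error vs basis size
# ---------------------------------------------------------------------------

def snapshot_subsets(subjects: list[Subject],
                     snapshots: rom.SnapshotMatrix) -> dict[str, rom.SnapshotMatrix]:
    """full / healthy-only / inph-only column subsets of a snapshot matrix."""
    groups = {s.subject_id: s.group for s in subjects}
    out = {"full": snapshots}
    for g in ("healthy", "inph"):
        ids = [sid for sid in snapshots.source_ids if groups[sid] == g]
        if ids:
            out[g] = snapshots.subset(ids)
    return out


def svd_spectra(subsets: dict[str, rom.SnapshotMatrix]) -> pd.DataFrame:
    """Normalized singular values sigma_i / sigma_1 per snapshot subset."""
    rows = []
    for name, snap in subsets.items():
        s = np.linalg.svd(snap.X, compute_uv=False)
        for i, v in enumerate(s / s[0]):
            rows.append({"subset": name, "index": i + 1,
                         "sigma_normalized": float(v)})
    return pd.DataFrame(rows)


def reduced_error_vs_d(system, subsets: dict[str, rom.SnapshotMatrix],
                       reference: Field, d_list) -> pd.DataFrame:
    """Relative L2 error of the reduced solution for each subset and basis size."""
    M = mass_matrix(reference.space)
    rows = []
    for name, snap in subsets.items():
        for d in d_list:
            if d > min(snap.X.shape):
                continue
            _, diag = rom.reduce_and_solve(system, snap, d, reference=reference,
                                           M_mass=M,
                                           field_names=reference.field_names)
            for fname, e in zip(reference.field_names, diag.errors_per_field):
                rows.append({"subset": name, "d": d, "field": fname,
                             "rel_l2_error": float(e),
                             "combined_error": diag.error_combined})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment: timing breakdown
# ---------------------------------------------------------------------------

def timing_table(mesh, which: str, snapshots: rom.SnapshotMatrix,
                 d_list, params=None) -> pd.DataFrame:
    """Wall-clock accounting of the online phase per basis size.

    Reports full assembly and solve times, the projection overhead and the
    reduced solve time, plus the solve-time ratio.  Informational only —
    wall times are hardware-dependent and never asserted.
    """
    from .fem import solve_full

    space = model_space(mesh, which)
    t0 = time.perf_counter()
    system = assemble_model(space, which, params)
    t_assembly = time.perf_counter() - t0
    t0 = time.perf_counter()
    solve_full(system)
    t_full_solve = time.perf_counter() - t0
    rows = []
    for d in d_list:
        if d > min(snapshots.X.shape):
            continue
        basis = rom.pod(snapshots, d)
        rs = rom.project(system, basis)
        t0 = time.perf_counter()
        rom.solve_reduced(rs)
        t_red = time.perf_counter() - t0
        rows.append({
            "d": d,
            "full_assembly_s": t_assembly,
            "projection_overhead_s": rs.projection_time,
            "full_solve_s": t_full_solve,
            "reduced_solve_s": t_red,
            "solve_speedup": t_full_solve / max(t_red, 1e-12),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Headline study driver
# ---------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Everything the desk-scale evaluation produces."""

    spec: co.CohortSpec
    target_ids: dict[str, str]
    pooled_errors: pd.DataFrame            # per-field reduced errors at d_rom
    largest_basis_combined: dict[str, dict[str, float]]   # model -> group -> err
    mapping_tables: dict[tuple[str, str], pd.DataFrame]
    spectra: dict[tuple[str, str], pd.DataFrame]
    timing: dict[str, pd.DataFrame] = dataclass_field(default_factory=dict)

    def median_pooled_error(self) -> float:
        return float(self.pooled_errors.rel_l2_error.median())


def run_study(spec: co.CohortSpec, d_rom: int = 30,
              models: tuple[str, ...] = ("A", "B"),
              backend: str = "analytic",
              model_params: dict | None = None,
              with_mapping_tables: bool = False,
              with_timing: bool = False) -> StudyResult:
    """Leave-one-out GROM evaluation on the default synthetic cohort.

    For each model and each designated target (first healthy-like and first
    iNPH-like subject) the remaining solutions are mapped onto the target,
    a POD basis of size ``d_rom`` built, and the reduced solution compared
    with the stored full-order solution.  Also records the combined error at
    the largest basis (d = M - 1, no truncation).
    """
    model_params = model_params or {}
    subjects = build_cohort(spec)
    targets = default_targets(subjects)
    pooled_rows = []
    largest: dict[str, dict[str, float]] = {}
    mapping_tables: dict[tuple[str, str], pd.DataFrame] = {}
    spectra: dict[tuple[str, str], pd.DataFrame] = {}
    timing: dict[str, pd.DataFrame] = {}

    for which in models:
        params = model_params.get(which)
        fields = solve_cohort(subjects, which, params)
        largest[which] = {}
        for group, t_idx in targets.items():
            snaps, _ = map_cohort_to_target(subjects, fields, t_idx, spec,
                                            backend=backend)
            reference = fields[t_idx]
            system = assemble_model(reference.space, which, params)
            Mm = mass_matrix(reference.space)
            d_use = min(d_rom, snaps.M)
            _, diag = rom.reduce_and_solve(system, snaps, d_use,
                                           reference=reference, M_mass=Mm,
                                           field_names=reference.field_names)
            for fname, e in zip(reference.field_names, diag.errors_per_field):
                pooled_rows.append({
                    "model": which, "target_group": group,
                    "target_id": subjects[t_idx].subject_id,
                    "field": fname, "d": d_use,
                    "rel_l2_error": float(e),
                })
            _, diag_full = rom.reduce_and_solve(system, snaps, snaps.M,
                                                reference=reference, M_mass=Mm,
                                                field_names=reference.field_names)
            largest[which][group] = float(diag_full.error_combined)
            if with_mapping_tables:
                mapping_tables[(which, group)] = mapping_error_table(
                    subjects, fields, t_idx, snaps)
            spectra[(which, group)] = svd_spectra(
                snapshot_subsets(subjects, snaps))
        if with_timing:
            t_idx = targets[next(iter(targets))]
            snaps, _ = map_cohort_to_target(subjects, fields, t_idx, spec,
                                            backend=backend)
            timing[which] = timing_table(
                subjects[t_idx].mesh, which, snaps,
                d_list=[2, 5, 10, 20, min(30, snaps.M), snaps.M], params=params)

    return StudyResult(
        spec=spec,
        target_ids={g: subjects[i].subject_id for g, i in targets.items()},
        pooled_errors=pd.DataFrame(pooled_rows),
        largest_basis_combined=largest,
        mapping_tables=mapping_tables,
        spectra=spectra,
        timing=timing,
    )


def default_study_spec(master_seed: int = 1) -> co.CohortSpec:
    """The default seeded evaluation cohort: 28 healthy-like + 12 iNPH-like
    subjects, 1 mm images, ~1.5 mm meshes."""
    return co.CohortSpec(n_healthy=28, n_inph=12, master_seed=master_seed,
                         mesh_h=1.5)
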