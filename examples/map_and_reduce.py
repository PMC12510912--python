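"""Full geometry-reduced-order-modeling loop on a small cohort.

Solves the two-compartment tracer model on every subject, maps the
solutions onto a held-out target geometry through the exact inter-subject
correspondence, builds a POD basis from the mapped snapshots, and solves
the target problem in the reduced space — the offline/online split that
makes repeated forward solves on a new geometry cheap.
"""

import numpy as np

from grom import experiments as ex, models, rom
from grom.cohort import CohortSpec
from grom.fem import mass_matrix

spec = CohortSpec(n_healthy=7, n_inph=3, master_seed=17, mesh_h=2.5)
subjects = ex.build_cohort(spec)
fields = ex.solve_cohort(subjects, "A")
t_idx = ex.default_targets(subjects)["healthy"]
print(f"cohort of {len(subjects)}; target {subjects[t_idx].subject_id} "
      f"({subjects[t_idx].group}), {fields[t_idx].coeffs.size} dofs")

snaps, reports = ex.map_cohort_to_target(subjects, fields, t_idx, spec,
                                         backend="analytic")
n_ex = int(np.mean([r.n_extrapolated for r in reports]))
print(f"mapped {snaps.M} snapshots (leave-one-out); "
      f"~{n_ex} boundary dofs per field needed Gaussian extrapolation")

sigma = rom.pod(snaps, snaps.M).singular_values
print("normalized singular values:",
      " ".join(f"{s:.1e}" for s in (sigma / sigma[0])[:6]), "...")

ref = fields[t_idx]
system = models.assemble_model(ref.space, "A")
M = mass_matrix(ref.space)
print(f"\n{'d':>3} {'relative L2 error':>18}")
for d in (1, 2, 5, snaps.M):
    _, diag = rom.reduce_and_solve(system, snaps, d, reference=ref, M_mass=M)
    print(f"{d:3d} {100 * diag.error_combined:17.2f}%")
print("\nThe error drops steeply over the first few modes and then plateaus")
print("at the level set by how well mapped snapshots span the target")
print("solution — more subjects and finer meshes push the plateau down.")
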