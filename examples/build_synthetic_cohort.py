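"""Generate a small synthetic cohort and inspect its geometry.

Each subject is a 2D brain-slice analogue: a folded star-shaped pial
boundary around an elliptic ventricle.  The "inph" subgroup has enlarged
ventricles (the geometric hallmark of idiopathic normal pressure
hydrocephalus); everything is reproducible from the master seed.
"""

import numpy as np

from grom import cohort as co

spec = co.CohortSpec(n_healthy=4, n_inph=2, master_seed=42, mesh_h=2.0)
cohort = co.sample_cohort(spec)

print(f"{'subject':>9} {'group':>8} {'R0 [mm]':>8} {'vent axes [mm]':>15} "
      f"{'mesh nodes':>10} {'area [mm^2]':>12}")
for params in cohort:
    mesh = co.build_mesh(params, spec.mesh_h)
    ax = "x".join(f"{a:.1f}" for a in params.vent_axes)
    print(f"{params.subject_id:>9} {params.group:>8} {params.R0:8.1f} "
          f"{ax:>15} {mesh.n_nodes:10d} {mesh.area():12.0f}")

img = co.rasterize(cohort[0], spec)
print(f"\nimage: {img.shape} voxels at {spec.voxel_size} mm, "
      f"intensity range [{img.data.min():.2f}, {img.data.max():.2f}]")
print("Parenchyma intensity ramps 0.4 -> 1.0 from ventricle to pial surface;")
print("the iNPH-like rows show ventricle semi-axes roughly twice the")
print("healthy-like ones at comparable outer radius — the geometric contrast")
print("the downstream mapping experiments probe.")
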