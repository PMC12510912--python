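"""Register one synthetic subject to another and compare with ground truth.

The demons registration matches the T1-like intensity images; because the
synthetic intensity is a pure function of the annular depth coordinate, the
displacement component along the intensity gradient is the part any image
metric can determine — the along-isocontour component is a gauge the
analytic ground-truth map fixes arbitrarily.  The report below separates
the two.
"""

import numpy as np

from grom import cohort as co, imaging
from grom.experiments import registration_accuracy

spec = co.CohortSpec(n_healthy=2, n_inph=0, master_seed=3)
src, dst = co.sample_cohort(spec)

moving = co.rasterize(src, spec)
fixed = co.rasterize(dst, spec)
pre = imaging.ssd(moving, fixed)

field = imaging.register(moving, fixed)   # maps src-space points to dst-space
warped = imaging.warp_image(fixed, field, moving)
post = float(np.mean((warped.data - moving.data) ** 2))
acc = registration_accuracy(field, src, dst, spec)

print(f"SSD before / after registration : {pre:.5f} / {post:.5f} "
      f"({post / pre:.1%} of initial)")
print(f"observable displacement error   : {acc['mean_observable_error_mm']:.2f} mm "
      f"(along grad I; < 1 voxel expected)")
print(f"full-vector error vs analytic   : {acc['mean_error_mm']:.2f} mm "
      f"(includes the unobservable tangential gauge)")
print(f"det J > 0 on annulus voxels     : {acc['det_j_positive_fraction']:.0%}")
print(f"iterations: {len(field.metric_history)}, converged: {field.converged}")
print("\nA small observable error with det J > 0 everywhere means the field")
print("is usable for mesh morphing even though the full-vector figure is")
print("dominated by the isocontour-sliding gauge the images cannot see.")
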