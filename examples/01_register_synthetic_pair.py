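"""Recover a known synthetic warp with staged multi-resolution registration.

Builds a 2-d warped image pair with a known ground-truth B-spline field,
registers the moving image back to the fixed one through the
similarity -> affine -> B-spline staging, and reports the displacement-field
RMSE before and after.  An RMSE well below one voxel means the nonrigid stage
found the true deformation, not just a global alignment.
"""

import numpy as np

from voxelreg import (FixtureSpec, GainSchedule, RegistrationConfig,
                      displacement_field, make_warped_pair, register)

spec = FixtureSpec(shape=(64, 64), seed=3, max_displacement=3.0, noise_sd=2.0)
fixed, moving, truth = make_warped_pair(spec)

config = RegistrationConfig(
    resolutions=3, iterations=300, metric="msd", samples=2000,
    stages=("similarity", "affine", "bspline"), final_grid_spacing=8.0,
    stage_iterations={"similarity": 40, "affine": 40},
    gain=GainSchedule(a=3.0), tail_average=0.3, seed=1)
transform, logs, resampled = register(fixed, moving, config)

true_field = displacement_field(truth, fixed.geometry)
got_field = displacement_field(transform, fixed.geometry)
initial = np.sqrt((np.linalg.norm(true_field, axis=-1) ** 2).mean())
final = np.sqrt((np.linalg.norm(got_field - true_field, axis=-1) ** 2).mean())

print(f"initial field RMSE : {initial:.3f} mm (the planted misalignment)")
print(f"final field RMSE   : {final:.3f} mm (residual after registration)")
print(f"improvement        : {initial / final:.1f}x")
print(f"final metric value : {logs[-1].records[-1].value:.2f} "
      "(mean squared intensity difference over the last sample set)")
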