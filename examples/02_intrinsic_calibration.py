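"""Zhang-style intrinsic calibration on eight synthetic checkerboard views.

Four board tilts at each of two depth planes are projected through a known
camera; the calibration recovers the focal lengths, principal point and
distortion from the 2-D corners alone. The mean reprojection error tracks
the injected corner noise.
"""

import numpy as np

from depthreg import reprojection_error_px, zhang_calibrate
from depthreg.simulator import default_board, default_intrinsics, simulate_intrinsics_views

intr = default_intrinsics()
board = default_board()

for noise_px in (0.0, 0.2):
    obs, _ = simulate_intrinsics_views(intr, board, corner_noise_px=noise_px, seed=1)
    est, poses = zhang_calibrate(obs, board, width=intr.width, height=intr.height)
    errs = [reprojection_error_px(est, p, board, o)[0] for p, o in zip(poses, obs)]
    print(f"corner noise {noise_px:.1f} px:")
    print(f"  fx recovered {est.fx:8.3f} px (truth {intr.fx:.1f}, error {abs(est.fx-intr.fx):.2e})")
    print(f"  mean reprojection error {np.mean(errs):.4f} px")
# With zero noise the recovery is exact to numerical precision; with 0.2 px
# noise the reprojection error settles at the noise level (sub-pixel), the
# regime a well-run calibration should reach.
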