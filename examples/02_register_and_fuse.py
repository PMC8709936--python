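"""Register a gaze set and fuse it into a gaze-dependent image.

Runs the full pipeline on a simulated acquisition — low-pass filtered
phase correlation and Fourier-Mellin rotation per pair, global
least-squares consensus, NaN-padded canvas assembly, photometric
normalization, and max-pair-SD fusion — then scores the registration
against the simulator's ground truth.
"""

import numpy as np

from gazefuse import (
    AcquisitionParams,
    assemble_stack,
    fuse,
    invert,
    make_phantom,
    max_pairwise_sd,
    photometric_normalize,
    register,
    save_fused,
    simulate_gaze_set,
)

phantom = make_phantom(seed=1)
gaze_set, truth = simulate_gaze_set(phantom, params=AcquisitionParams(seed=11))

result = register(gaze_set)
print(f"registration success: {result.success}, "
      f"pair-graph residual {result.residual_px:.3f} px")

anchor_true = truth.transforms[result.anchor]
for k, est in enumerate(result.transforms):
    true = truth.transforms[k].relative_to(anchor_true)
    err = np.hypot(est.dx_px - true.dx_px, est.dy_px - true.dy_px)
    print(f"  image {k}: shift ({est.dx_px:+8.2f}, {est.dy_px:+8.2f}) px, "
          f"rot {est.theta_deg:+.2f} deg, error vs truth {err:.2f} px")

stack = photometric_normalize(assemble_stack(gaze_set, result))
fused = max_pairwise_sd(stack)
mean_img = fuse(stack, "mean")
print(f"\ncanvas {fused.values.shape}, coverage up to {fused.coverage.max()} images")
print("gaze-varying structures (drusen margins, SDD rings) are bright in the")
print("max-pair-SD image; static structures (atrophy, mosaic) cancel out.")

save_fused(fused, "fused_max_pair_sd")
save_fused(invert(fused), "fused_max_pair_sd_inverted", raw=False)
save_fused(mean_img, "fused_mean", raw=False)
print("wrote fused_max_pair_sd.tif (+ raw float and inverted renderings)")
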