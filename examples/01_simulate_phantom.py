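"""Generate a synthetic instrumented-spine CT pair with known ground truth.

Builds a one-level phantom, applies a known inter-scan motion and a planted
screw deviation, and prints what the generator knows — the oracle every
downstream example measures against.
"""

import numpy as np

from screwsight import phantom as ph

spec = ph.PhantomSpec(seed=42)
pre, mask, plans, gt = ph.generate_preop(spec)
print(f"preop volume {pre.shape}, spacing {pre.spacing} mm")
print(f"levels: {mask.level_ids}")

rng = np.random.default_rng(7)
motions = {lvl: ph.random_motion(rng, 10.0, 10.0) for lvl in spec.level_names()}
deviations = {
    (p.level, p.side): ph.random_deviation(rng, p.length, 3.0, 5.0)
    for p in plans
}
post, gt = ph.generate_postop(spec, gt, deviations, motions)

M = motions["T7"]
print(f"\ninter-scan motion at T7: {M.rotation_angle_deg():.2f} deg, "
      f"|t| = {np.linalg.norm(M.translation):.2f} mm")
for (lvl, side), (tip_off, tail_off) in gt.deviations.items():
    print(f"planted deviation {lvl}/{side}: tip offset (ML,AP,SI) = "
          f"{np.round(tip_off, 2)} mm, tail offset = {np.round(tail_off, 2)} mm")
print(f"\n{len(gt.beads_pre)} fiducial beads embedded; metal threshold "
      f"{spec.metal_threshold:.0f} HU")
# the offsets above are what a perfect measurement pipeline should report
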