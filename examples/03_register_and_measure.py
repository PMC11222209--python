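"""Full measurement chain on one phantom: detect, register, resolve errors.

Runs `analyze_case` (detection, SVD-initialised masked MI registration with
beads masked out, screw-frame error resolution) and compares what it reports
against the planted ground truth.
"""

import numpy as np

import screwsight as ss
from screwsight import phantom as ph
from screwsight.study import planted_record

spec = ph.PhantomSpec(seed=42)
pre, mask, plans, gt = ph.generate_preop(spec)
rng = np.random.default_rng(7)
motions = {lvl: ph.random_motion(rng, 10.0, 10.0) for lvl in spec.level_names()}
deviations = {(p.level, p.side): ph.random_deviation(rng, p.length, 3.0, 5.0)
              for p in plans}
post, gt = ph.generate_postop(spec, gt, deviations, motions)

result = ss.analyze_case(
    pre, mask, post, plans, spec.metal_threshold,
    beads_pre=gt.beads_pre, beads_post=gt.beads_post,
)

reg = result.registrations["T7"]
print(f"T7 registration: MI {reg.mi_init:.3f} -> {reg.mi_final:.3f} "
      f"({reg.n_iterations} iterations)")
print(f"fiducial bead MAE: {result.fiducial_report.mae_mm:.3f} mm "
      f"(sub-voxel: slice spacing is {spec.spacing[2]} mm)")

print("\nper-screw errors, measured vs planted (ML, AP, SI in mm):")
for rec in result.records:
    key = (rec.level, rec.side)
    pl = planted_record(gt, rec.level, rec.side,
                        result.frames[key], result.loci[key])
    print(f"  {rec.level}/{rec.side} tip measured "
          f"({rec.tip_ml:+.2f}, {rec.tip_ap:+.2f}, {rec.tip_si:+.2f})"
          f"  planted ({pl.tip_ml:+.2f}, {pl.tip_ap:+.2f}, {pl.tip_si:+.2f})"
          f"  angle {rec.angle_deg:.2f} vs {pl.angle_deg:.2f} deg")
# agreement to a few tenths of a millimetre shows the chain recovers the
# planted deviations despite the 10 deg / 10 mm inter-scan motion
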