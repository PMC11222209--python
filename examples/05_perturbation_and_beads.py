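"""Registration self-validation: perturbation restarts and fiducial beads.

Re-runs the MI refinement from ten randomly perturbed initialisations
(2 degrees / 2 mm) and scores the embedded beads, the two checks that
establish how much of the measured screw error could come from registration
itself.
"""

import numpy as np

import screwsight as ss
from screwsight import phantom as ph
from screwsight.registration import perturbation_analysis

spec = ph.PhantomSpec(seed=42)
pre, mask, plans, gt = ph.generate_preop(spec)
rng = np.random.default_rng(7)
motions = {lvl: ph.random_motion(rng, 10.0, 10.0) for lvl in spec.level_names()}
post, gt = ph.generate_postop(spec, gt, motions=motions)

result = ss.analyze_case(
    pre, mask, post, plans, spec.metal_threshold,
    beads_pre=gt.beads_pre, beads_post=gt.beads_post,
)

rep = perturbation_analysis(
    result.problems["T7"], result.registrations["T7"],
    n=10, rot_deg=2.0, trans_mm=2.0, seed=0,
)
print(f"perturbation restarts (n={rep.n_perturbations}, "
      f"{rep.rot_magnitude_deg} deg / {rep.trans_magnitude_mm} mm):")
print(f"  translation discrepancy {rep.mean_translation_mm:.3f} "
      f"+/- {rep.sd_translation_mm:.3f} mm")
print(f"  rotation discrepancy    {rep.mean_rotation_deg:.3f} "
      f"+/- {rep.sd_rotation_deg:.3f} deg")

fid = result.fiducial_report
print(f"\nfiducial beads (n={fid.n_usable}): "
      f"MAE {fid.mae_mm:.3f} +/- {fid.sd_mm:.3f} mm")
print("per-bead errors:", np.round(fid.per_bead_mm, 3), "mm")
# discrepancies of a few hundredths of a unit mean the optimiser lands on
# the same optimum from anywhere in the perturbation ball; bead errors well
# below the 0.625 mm slice spacing mean registration is sub-voxel
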