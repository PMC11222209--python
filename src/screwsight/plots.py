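"""Target-plot visualisation of coronal screw errors.

One marker per screw at its (ML, SI) error in the chosen analysis plane,
the signed mean error as a star, an axis-aligned 2 SD ellipse, and reference
rings at fixed radii around the planned position (the origin). Because ML is
medial-positive on both sides, right-sided screws are already mirrored and
both sides pool in one plot. The plotted mean and ellipse are taken directly
from :func:`screwsight.metrics.summarize` — nothing is recomputed here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from matplotlib.patches import Circle, Ellipse

from .metrics import summarize

__all__ = ["TargetPlotSpec", "render_target_plot"]

log = logging.getLogger(__name__)

_PLANE_COLUMNS = {
    "tail": ("tail_ml", "tail_si"),
    "mid-pedicle": ("mid_ml", "mid_si"),
    "tip": ("tip_ml", "tip_si"),
}


@dataclass(frozen=True)
class TargetPlotSpec:
    """What to draw: the analysis plane and the target-ring radii (mm)."""

    plane: str = "mid-pedicle"
    ring_radii: tuple = (2.0, 4.0)
    show_mean: bool = True
    show_ellipse: bool = True
    covariance_ellipse: bool = False  # per-axis 2 SD by default

    def __post_init__(self):
        if self.plane not in _PLANE_COLUMNS:
            raise ValueError(f"plane must be one of {sorted(_PLANE_COLUMNS)}")
        radii = tuple(float(r) for r in self.ring_radii)
        if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValueError("ring radii must be positive and ascending")
        object.__setattr__(self, "ring_radii", radii)


def render_target_plot(records: list, spec: TargetPlotSpec, out) -> Path:
    """Write the target plot (and a data table next to it) to ``out``.

    Returns the image path. A single record yields a scatter without an
    ellipse (SD undefined), with a logged warning.
    """
    if not records:
        raise ValueError("need at least one record")
    col_ml, col_si = _PLANE_COLUMNS[spec.plane]
    ml = np.array([getattr(r, col_ml) for r in records])
    si = np.array([getattr(r, col_si) for r in records])
    stats = summarize(records, group="all")["all"]
    sme_ml, sme_si = stats.sme[col_ml], stats.sme[col_si]
    prec_ml, prec_si = stats.precision[col_ml], stats.precision[col_si]

    fig, ax = plt.subplots(figsize=(5, 5))
    for r in spec.ring_radii:
        ax.add_patch(Circle((0, 0), r, fill=False, color="0.6", lw=1))
    if spec.show_ellipse:
        if len(records) < 2:
            log.warning("only one record: skipping the 2 SD ellipse")
        elif spec.covariance_ellipse:
            cov = np.cov(np.vstack([ml, si]))
            evals, evecs = np.linalg.eigh(cov)
            angle = np.degrees(np.arctan2(evecs[1, 1], evecs[0, 1]))
            ax.add_patch(
                Ellipse(
                    (sme_ml, sme_si),
                    4 * np.sqrt(evals[1]), 4 * np.sqrt(evals[0]),
                    angle=angle, alpha=0.25, color="tab:purple",
                )
            )
        else:
            ax.add_patch(
                Ellipse(
                    (sme_ml, sme_si), 2 * prec_ml, 2 * prec_si,
                    alpha=0.25, color="tab:purple",
                )
            )
    ax.plot(ml, si, "o", color="tab:blue", ms=4, alpha=0.8)
    if spec.show_mean:
        ax.plot([sme_ml], [sme_si], "*", color="tab:purple", ms=14)
    lim = max(spec.ring_radii[-1] * 1.2, np.abs(np.r_[ml, si]).max() * 1.2 + 0.5)
    ax.set_xlim(-lim, lim)
    ax.set_ylim(-lim, lim)
    ax.set_aspect("equal")
    ax.set_xlabel("ML error (mm, medial +)")
    ax.set_ylabel("SI error (mm, superior +)")
    ax.set_title(f"{spec.plane} plane (n={len(records)})")
    out = Path(out)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)

    table = pd.DataFrame(
        {
            "ml_mm": ml,
            "si_mm": si,
        }
    )
    table.attrs["plane"] = spec.plane
    summary = pd.DataFrame(
        {
            "stat": ["sme_ml", "sme_si", "precision_2sd_ml", "precision_2sd_si",
                     "mae_ml", "mae_si"],
            "value": [sme_ml, sme_si, prec_ml, prec_si,
                      stats.mae[col_ml], stats.mae[col_si]],
        }
    )
    table.to_csv(out.with_suffix(".points.csv"), index=False)
    summary.to_csv(out.with_suffix(".stats.csv"), index=False)
    return out
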