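"""Bead-based validation of registration accuracy.

Small high-density fiducial beads embedded in bone measure registration
error independently of the registration itself: after aligning the scans
(with the beads masked out of the similarity), the residual distance between
each mapped preoperative bead and its postoperative position is a direct
fiducial registration error. Beads may be detected automatically here, or
supplied from manual identification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import CTVolume, RigidTransform

__all__ = [
    "FiducialSet",
    "FiducialErrorReport",
    "NoFiducialsError",
    "detect_beads",
    "fiducial_registration_error",
]


class NoFiducialsError(ValueError):
    """No usable bead pairs."""


@dataclass
class FiducialSet:
    """Paired bead positions in preop and postop space (world mm)."""

    pre: np.ndarray
    post: np.ndarray
    usable: np.ndarray | None = None

    def __post_init__(self):
        self.pre = np.asarray(self.pre, dtype=float).reshape(-1, 3)
        self.post = np.asarray(self.post, dtype=float).reshape(-1, 3)
        if len(self.pre) != len(self.post):
            raise ValueError("pre and post bead lists must have equal length")
        if self.usable is None:
            self.usable = np.ones(len(self.pre), dtype=bool)
        else:
            self.usable = np.asarray(self.usable, dtype=bool).reshape(len(self.pre))


@dataclass
class FiducialErrorReport:
    per_bead_mm: np.ndarray
    mae_mm: float
    sd_mm: float
    n_usable: int


def detect_beads(
    volume: CTVolume,
    threshold: float,
    expected_diameter: float = 1.0,
    exclusion: list | None = None,
    volume_tolerance: float = 0.5,
    min_separation_mm: float = 2.0,
) -> np.ndarray:
    """Locate spherical fiducial beads as small bright components.

    Supra-threshold 26-connected components whose voxel volume is within
    ``volume_tolerance`` (fractional) of the expected sphere are kept;
    components overlapping or within ``min_separation_mm`` of any
    ``exclusion`` component (screws) are dropped, since metal overlap makes
    the bead position unreliable. Each bead is reduced to an
    intensity-weighted centroid over its 2-voxel-dilated neighbourhood,
    which recovers sub-voxel symmetry lost to thresholding.
    """
    binary = volume.data > threshold
    labeled, n = ndimage.label(binary, structure=np.ones((3, 3, 3), dtype=bool))
    if n == 0:
        return np.zeros((0, 3))
    sphere_vol = np.pi / 6.0 * expected_diameter**3
    voxel_vol = float(np.prod(volume.spacing))
    lo = (1.0 - volume_tolerance) * sphere_vol
    hi = (1.0 + volume_tolerance) * sphere_vol
    excl_pts = None
    if exclusion:
        excl_pts = np.vstack([c.points for c in exclusion if c.n_voxels])

    centroids = []
    for lab in range(1, n + 1):
        comp = labeled == lab
        vol_mm3 = comp.sum() * voxel_vol
        if not (lo <= vol_mm3 <= hi):
            continue
        region = ndimage.binary_dilation(comp, iterations=2)
        idx = np.argwhere(region)
        world = idx @ volume.affine[:3, :3].T + volume.affine[:3, 3]
        vals = volume.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
        shell = region & ~comp
        bg = float(np.median(volume.data[shell])) if shell.any() else float(vals.min())
        w = np.clip(vals - bg, 0.0, None)
        if w.sum() <= 0:
            continue
        c = (world * w[:, None]).sum(axis=0) / w.sum()
        if excl_pts is not None:
            if np.linalg.norm(excl_pts - c, axis=1).min() < (
                expected_diameter / 2.0 + min_separation_mm
            ):
                continue
        centroids.append(c)
    return np.asarray(centroids).reshape(-1, 3)


def fiducial_registration_error(
    beads: FiducialSet, T: RigidTransform
) -> FiducialErrorReport:
    """Per-bead ``|T(pre) - post|`` plus MAE and sample SD over usable beads."""
    use = beads.usable
    if not use.any():
        raise NoFiducialsError("no usable bead pairs")
    mapped = T.apply(beads.pre[use])
    errs = np.linalg.norm(mapped - beads.post[use], axis=1)
    sd = float(errs.std(ddof=1)) if len(errs) >= 2 else float("nan")
    return FiducialErrorReport(
        per_bead_mm=errs, mae_mm=float(errs.mean()), sd_mm=sd, n_usable=int(use.sum())
    )
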