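"""Screw-aligned anatomical reference frames.

Placement errors are reported in a frame anchored to each planned
trajectory: the AP axis runs along the planned shaft (anterior positive),
the SI axis is the part of the inferior-endplate normal perpendicular to the
shaft (superior positive), and the ML axis completes the frame with its sign
chosen so that medial is positive for either side — right-sided screws are
thereby mirrored across the sagittal plane and pool directly with left-sided
ones. The mid-pedicle point is the sample along the planned trajectory that
comes closest to (or maximally breaches) the medial pedicle wall.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import LabelMask
from .detection import ScrewPlan

__all__ = [
    "EndplatePlane",
    "ScrewFrame",
    "MidPedicleLocus",
    "InsufficientSurfaceError",
    "DegenerateFrameError",
    "NoIntersectionError",
    "fit_endplate_plane",
    "build_screw_frame",
    "locate_mid_pedicle",
]


class InsufficientSurfaceError(ValueError):
    """Too few candidate endplate surface voxels."""


class DegenerateFrameError(ValueError):
    """Endplate normal nearly parallel to the planned shaft."""


class NoIntersectionError(ValueError):
    """A trajectory misses the pedicle, or an axis misses the analysis plane."""


@dataclass(frozen=True)
class EndplatePlane:
    """A plane through the inferior vertebral endplate, normal pointing
    superiorly."""

    point: np.ndarray
    normal: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))
        n = np.asarray(self.normal, dtype=float).reshape(3)
        nn = np.linalg.norm(n)
        if abs(nn - 1.0) > 1e-9:
            n = n / nn
        object.__setattr__(self, "normal", n)


@dataclass(frozen=True)
class ScrewFrame:
    """Orthonormal (e_ML, e_AP, e_SI) axes anchored at the planned tail.

    Sign conventions: ML medial(+)/lateral(-), AP anterior(+)/posterior(-)
    along the planned shaft, SI superior(+)/inferior(-). Because ML points
    medially on both sides, the frame is right-handed for one side and
    left-handed (mirrored) for the other: e_ML x e_AP = +e_SI on the side
    where medial coincides with the right-handed cross product, -e_SI on the
    contralateral side.
    """

    origin: np.ndarray
    e_ml: np.ndarray
    e_ap: np.ndarray
    e_si: np.ndarray
    side: str

    def __post_init__(self):
        for name in ("origin", "e_ml", "e_ap", "e_si"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float).reshape(3)
            )

    @property
    def matrix(self) -> np.ndarray:
        """Columns e_ML, e_AP, e_SI."""
        return np.column_stack([self.e_ml, self.e_ap, self.e_si])

    def resolve(self, vector) -> np.ndarray:
        """World vector -> (ML, AP, SI) components."""
        return self.matrix.T @ np.asarray(vector, dtype=float)


@dataclass(frozen=True)
class MidPedicleLocus:
    """The planned-trajectory point of closest approach to the medial wall.

    ``arc_param`` is the distance (mm) from the tail along the planned axis;
    ``wall_distance`` is the signed distance to the medial pedicle wall,
    negative when the point has breached toward the canal.
    """

    point: np.ndarray
    arc_param: float
    wall_distance: float

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float).reshape(3))


def _surface_voxels(binary: np.ndarray):
    """Exterior surface voxels of a binary mask and their outward directions.

    The outward direction is the (negated, normalised) gradient of a lightly
    smoothed indicator, evaluated at the surface voxels.
    """
    eroded = ndimage.binary_erosion(binary)
    surface = binary & ~eroded
    smoothed = ndimage.gaussian_filter(binary.astype(float), 1.0)
    grads = np.gradient(smoothed)
    idx = np.argwhere(surface)
    g = np.stack([gr[idx[:, 0], idx[:, 1], idx[:, 2]] for gr in grads], axis=1)
    norms = np.linalg.norm(g, axis=1)
    ok = norms > 1e-9
    out = np.zeros_like(g)
    out[ok] = -g[ok] / norms[ok, None]
    return idx[ok], out[ok]


def fit_endplate_plane(
    mask: LabelMask,
    level: str,
    body_axis_hint=(0.0, 0.0, 1.0),
    min_voxels: int = 20,
) -> EndplatePlane:
    """Least-squares plane through the inferior endplate surface.

    Candidate voxels are exterior surface voxels of the level's label whose
    outward direction is within 45 degrees of inferior and that lie in the
    inferior 30% of the label's extent along ``body_axis_hint``. The endplate
    is the largest planar patch among the candidates, found by a seeded
    RANSAC search (0.4 mm inlier band) and polished by least squares on the
    inliers; smaller inferior-facing surfaces of the posterior elements
    therefore cannot bias it. Deterministic; the returned normal points
    superiorly.
    """
    hint = np.asarray(body_axis_hint, dtype=float)
    hint = hint / np.linalg.norm(hint)
    label = mask.label_for_level(level)
    binary = mask.labels == label
    idx, outward = _surface_voxels(binary)
    if len(idx) == 0:
        raise InsufficientSurfaceError(f"label for {level} has no surface")
    world = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    # outward direction is in voxel-gradient space; convert to world
    world_dir = outward @ np.linalg.inv(mask.affine[:3, :3])
    nrm = np.linalg.norm(world_dir, axis=1)
    ok = nrm > 1e-9
    world, world_dir = world[ok], world_dir[ok] / nrm[ok, None]
    proj = world @ hint
    lo, hi = proj.min(), proj.max()
    inferior = -hint
    cand = (world_dir @ inferior > np.cos(np.radians(45.0))) & (
        proj <= lo + 0.30 * (hi - lo)
    )
    cand_pts = world[cand]
    cand_proj = proj[cand]
    if len(cand_pts) < min_voxels:
        raise InsufficientSurfaceError(
            f"only {len(cand_pts)} candidate endplate voxels at {level}"
        )

    def _fit(pts):
        center = pts.mean(axis=0)
        _, _, Vt = np.linalg.svd(pts - center, full_matrices=False)
        normal = Vt[-1]
        if normal @ hint < 0:
            normal = -normal
        return center, normal

    # RANSAC: the endplate is the largest planar patch among the candidates
    ransac_rng = np.random.default_rng(0)
    band = 0.4
    best_inliers = None
    for _ in range(300):
        tri = cand_pts[ransac_rng.choice(len(cand_pts), size=3, replace=False)]
        n = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        nn = np.linalg.norm(n)
        if nn < 1e-6:
            continue
        n = n / nn
        if abs(n @ hint) < np.cos(np.radians(45.0)):
            continue  # not an endplate-like orientation
        inliers = np.abs((cand_pts - tri[0]) @ n) <= band
        if best_inliers is None or inliers.sum() > best_inliers.sum():
            best_inliers = inliers
    if best_inliers is None or best_inliers.sum() < min_voxels:
        raise InsufficientSurfaceError(f"no planar endplate patch found at {level}")
    center, normal = _fit(cand_pts[best_inliers])
    for _ in range(2):
        keep = np.abs((cand_pts - center) @ normal) <= band
        if keep.sum() < min_voxels:
            break
        center, normal = _fit(cand_pts[keep])
    return EndplatePlane(point=center, normal=normal)


def build_screw_frame(plan: ScrewPlan, endplate: EndplatePlane) -> ScrewFrame:
    """Construct the ML/AP/SI frame for one planned screw.

    AP runs along the planned shaft; SI is the endplate normal
    Gram-Schmidt-orthogonalised against AP; ML completes the frame with the
    medial-positive sign for the plan's side (the sagittal midplane is x=0 in
    the RAS world frame, right side at +x).
    """
    e_ap = plan.axis
    n = endplate.normal
    if abs(n @ e_ap) > np.cos(np.radians(5.0)):
        raise DegenerateFrameError("endplate normal nearly parallel to planned shaft")
    e_si = n - (n @ e_ap) * e_ap
    e_si = e_si / np.linalg.norm(e_si)
    e_ml = np.cross(e_si, e_ap)
    medial = np.array([-1.0, 0.0, 0.0]) if plan.side == "R" else np.array([1.0, 0.0, 0.0])
    if e_ml @ medial < 0:
        e_ml = -e_ml
    return ScrewFrame(origin=plan.tail, e_ml=e_ml, e_ap=e_ap, e_si=e_si, side=plan.side)


def _medial_wall_points(
    mask: LabelMask, level: str, plan: ScrewPlan, capture_radius_mm: float = 10.0
):
    """Boundary voxels of the level's label that face the canal (medially)
    and lie near the planned trajectory."""
    label = mask.label_for_level(level)
    binary = mask.labels == label
    idx, outward = _surface_voxels(binary)
    world = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
    world_dir = outward @ np.linalg.inv(mask.affine[:3, :3])
    nrm = np.linalg.norm(world_dir, axis=1)
    ok = nrm > 1e-9
    world, world_dir = world[ok], world_dir[ok] / nrm[ok, None]
    medial = np.array([-1.0, 0.0, 0.0]) if plan.side == "R" else np.array([1.0, 0.0, 0.0])
    # 30 degree cone: keeps the canal-facing wall band, rejects corner voxels
    # of end/posterior faces whose blended normals lean medially
    facing = world_dir @ medial > np.cos(np.radians(30.0))
    d = _distance_to_segment(world, plan.tail, plan.tip)
    near = d <= capture_radius_mm
    return world[facing & near]


def _distance_to_segment(pts, a, b):
    ab = b - a
    t = np.clip((pts - a) @ ab / (ab @ ab), 0.0, 1.0)
    return np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)


def locate_mid_pedicle(
    plan: ScrewPlan,
    mask: LabelMask,
    level: str | None = None,
    step_mm: float = 0.1,
    tie_tol_mm: float = 1e-6,
) -> MidPedicleLocus:
    """Find the planned-trajectory point closest to the medial pedicle wall.

    The wall is represented by label-boundary voxels facing the canal near
    the trajectory. The trajectory is sampled every ``step_mm`` across the
    wall's extent along the axis; each sample's distance to the nearest wall voxel is signed negative
    when the sample lies outside the label (breached toward the canal). Ties
    within ``tie_tol_mm`` break toward the smaller arc length.
    """
    if level is None:
        level = plan.level
    wall = _medial_wall_points(mask, level, plan)
    if len(wall) == 0:
        raise NoIntersectionError(f"no medial wall voxels near the {level} trajectory")
    label = mask.label_for_level(level)
    # only trajectory samples within the wall's extent along the axis are in
    # the pedicle; outside it, "outside the label" does not mean breach
    s_wall = (wall - plan.tail) @ plan.axis
    s_lo = max(0.0, float(s_wall.min()))
    s_hi = min(plan.length, float(s_wall.max()))
    if s_hi <= s_lo:
        raise NoIntersectionError("planned trajectory outside the pedicle extent")
    s = np.arange(s_lo, s_hi + step_mm / 2.0, step_mm)
    samples = plan.tail + np.outer(s, plan.axis)
    inv = np.linalg.inv(mask.affine)
    vox = np.rint(samples @ inv[:3, :3].T + inv[:3, 3]).astype(int)
    shape = np.array(mask.labels.shape)
    inb = np.all((vox >= 0) & (vox < shape), axis=1)
    inside = np.zeros(len(s), dtype=bool)
    inside[inb] = mask.labels[vox[inb, 0], vox[inb, 1], vox[inb, 2]] == label
    if not inside.any():
        raise NoIntersectionError("planned trajectory entirely outside the label")
    # nearest wall voxel per sample (chunked to bound memory)
    d = np.empty(len(s))
    chunk = 4096
    for i in range(0, len(s), chunk):
        diff = samples[i:i + chunk, None, :] - wall[None, :, :]
        d[i:i + chunk] = np.sqrt((diff ** 2).sum(axis=2)).min(axis=1)
    signed = np.where(inside, d, -d)
    best = signed.min()
    i_best = int(np.flatnonzero(signed <= best + tie_tol_mm)[0])
    return MidPedicleLocus(
        point=samples[i_best], arc_param=float(s[i_best]), wall_distance=float(signed[i_best])
    )
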