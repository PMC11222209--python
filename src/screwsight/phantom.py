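"""Synthetic instrumented-spine CT phantoms with full ground truth.

The generator emulates the imaging conditions of a helical CT protocol for
spine instrumentation: anisotropic voxels (default 0.5 x 0.5 mm in-plane,
0.625 mm slice spacing), air / soft-tissue / trabecular / cortical / metal
intensity plateaus, 4.5 mm screws of known length inserted with controlled
deviation from plan, 1 mm high-intensity fiducial beads, per-level rigid
inter-scan motion, Gaussian blur (partial volume) and Gaussian noise.

Each vertebra is a simple analytic solid: an elliptic-cylinder body with a
flat inferior endplate, two pedicles flanking the spinal canal with a slight
medial angulation, and a posterior-element block. Bilateral screw plans run
along the pedicle axes from the posterior bone surface into the body. The
postoperative scan is re-rendered from the same analytic scene with each
vertebra moved by its own rigid motion and metal inserted along the deviated
trajectories, so every downstream stage can be checked against exact ground
truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields, replace

import numpy as np
from scipy import ndimage

from .core import CTVolume, LabelMask, RigidTransform
from .detection import ScrewPlan

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PhantomSpecError",
    "GenerationError",
    "generate_preop",
    "generate_postop",
    "random_motion",
    "rigid_deviation",
    "random_deviation",
    "SPINE_LEVELS",
]

SPINE_LEVELS = [f"T{i}" for i in range(1, 13)] + [f"L{i}" for i in range(1, 6)]


class PhantomSpecError(ValueError):
    """Inconsistent phantom specification."""


class GenerationError(RuntimeError):
    """Requested scene does not fit in the simulated field of view."""


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the synthetic scene. All lengths in mm, intensities HU."""

    n_levels: int = 1
    first_level: str = "T7"
    spacing: tuple = (0.5, 0.5, 0.625)

    # vertebra geometry
    body_halfwidth: float = 16.0      # body semi-axis, medial-lateral
    body_halfdepth: float = 12.0      # body semi-axis, antero-posterior
    body_height: float = 22.0
    body_center_y: float = 8.0
    canal_radius: float = 6.0
    pedicle_radius: float = 4.0
    posterior_halfwidth: float = 12.0
    posterior_halfheight: float = 8.0
    posterior_depth: float = 10.0
    cortical_thickness: float = 1.2
    level_pitch: float = 30.0
    body_tilt_deg: float = 0.0        # tilt of each vertebra about the ML axis

    # implants
    screw_radius: float = 2.25        # 4.5 mm screws
    screw_length: float = 35.0
    tulip_radius: float = 4.0
    tulip_length: float = 7.0
    n_beads_per_level: int = 4
    bead_diameter: float = 1.0

    # intensity model
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_trabecular: float = 250.0
    hu_cortical: float = 1200.0
    hu_metal: float = 3000.0
    # anatomy-locked trabecular texture (SD in HU, ~2.5-6 mm correlation):
    # moves rigidly with each vertebra, like real trabecular structure
    trabecular_texture_hu: float = 60.0

    # degradation
    blur_sigma_mm: float = 0.25
    noise_sigma_hu: float = 20.0

    motion_margin: float = 12.0       # field-of-view slack for inter-scan motion
    antialias_metal: bool = True
    seed: int = 0

    def __post_init__(self):
        order = [self.hu_air, self.hu_soft, self.hu_trabecular,
                 self.hu_cortical, self.hu_metal]
        if not all(a < b for a, b in zip(order, order[1:])):
            raise PhantomSpecError(
                "intensities must satisfy metal > cortical > trabecular > soft > air"
            )
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("body_tilt_deg", "noise_sigma_hu", "blur_sigma_mm",
                          "hu_air", "hu_soft", "hu_trabecular", "hu_cortical",
                          "hu_metal", "trabecular_texture_hu",
                          "n_beads_per_level", "seed",
                          "antialias_metal", "first_level", "spacing"):
                continue
            if isinstance(v, (int, float)) and v <= 0:
                raise PhantomSpecError(f"geometric parameter {f.name} must be positive")
        if self.screw_radius >= self.pedicle_radius:
            raise PhantomSpecError("screw radius must be smaller than pedicle radius")
        if self.first_level not in SPINE_LEVELS:
            raise PhantomSpecError(f"unknown level {self.first_level!r}")
        if SPINE_LEVELS.index(self.first_level) + self.n_levels > len(SPINE_LEVELS):
            raise PhantomSpecError("too many levels for the naming table")

    @property
    def metal_threshold(self) -> float:
        """Midpoint between the cortical and metal plateaus."""
        return 0.5 * (self.hu_cortical + self.hu_metal)

    def level_names(self) -> list:
        i0 = SPINE_LEVELS.index(self.first_level)
        return SPINE_LEVELS[i0:i0 + self.n_levels]


@dataclass
class TrueScrew:
    """Ground-truth screw geometry in preop (deviated) and postop space."""

    tip_pre: np.ndarray
    tail_pre: np.ndarray
    tip_post: np.ndarray
    tail_post: np.ndarray


@dataclass
class GroundTruth:
    """Everything the generator knows: the oracle for every pipeline stage."""

    plans: list
    frames: dict          # (level, side) -> 3x3 with columns e_ML, e_AP, e_SI
    endplates: dict       # level -> (point, normal) of the inferior endplate
    beads_pre: np.ndarray
    bead_levels: list
    motions: dict = field(default_factory=dict)       # level -> RigidTransform
    beads_post: np.ndarray | None = None
    true_screws: dict = field(default_factory=dict)   # (level, side) -> TrueScrew
    deviations: dict = field(default_factory=dict)    # (level, side) -> (tip_off, tail_off)

    def plan_for(self, level: str, side: str) -> ScrewPlan:
        for p in self.plans:
            if p.level == level and p.side == side:
                return p
        raise KeyError((level, side))

    def frame_error(self, level: str, side: str) -> dict:
        """Planted tip/tail error components resolved in the screw frame."""
        plan = self.plan_for(level, side)
        F = self.frames[(level, side)]
        ts = self.true_screws[(level, side)]
        return {
            "tip": F.T @ (ts.tip_pre - plan.tip),
            "tail": F.T @ (ts.tail_pre - plan.tail),
        }


# ---------------------------------------------------------------------------
# scene geometry


class _Vertebra:
    """Analytic solids for one level, in its own local frame.

    Local coordinates: origin at the level centre, +x left/right, +y anterior,
    +z superior; the inferior endplate is the plane z = -body_height/2.
    """

    def __init__(self, spec: PhantomSpec, center: np.ndarray):
        self.spec = spec
        self.center = np.asarray(center, dtype=float)
        tilt = np.radians(spec.body_tilt_deg)
        c, s = np.cos(tilt), np.sin(tilt)
        # tilt about the ML (x) axis
        self.R = np.array([[1, 0, 0], [0, c, -s], [0, s, c]], dtype=float)

        y_canal = spec.body_center_y - spec.body_halfdepth - spec.canal_radius
        self.y_canal = y_canal
        y_post1 = y_canal - spec.canal_radius            # anterior face of block
        y_post0 = y_post1 - spec.posterior_depth         # posterior face (entry)
        self.y_post0 = y_post0
        x_ped = spec.canal_radius + spec.pedicle_radius
        self.pedicles = {}
        for side, sx in (("L", -1.0), ("R", 1.0)):
            a = np.array([sx * x_ped, y_post0 + 2.0, 0.0])
            b = np.array([sx * (x_ped - 2.25), spec.body_center_y - spec.body_halfdepth + 2.0, 0.0])
            self.pedicles[side] = (a, b)

    def to_world(self, p_local: np.ndarray) -> np.ndarray:
        return np.asarray(p_local, dtype=float) @ self.R.T + self.center

    def to_local(self, p_world: np.ndarray) -> np.ndarray:
        return (np.asarray(p_world, dtype=float) - self.center) @ self.R

    def bone_mask(self, world_pts: np.ndarray, shape) -> np.ndarray:
        sp = self.spec
        q = self.to_local(world_pts)
        x, y, z = q[:, 0], q[:, 1], q[:, 2]
        body = (
            ((x / sp.body_halfwidth) ** 2
             + ((y - sp.body_center_y) / sp.body_halfdepth) ** 2) <= 1.0
        ) & (np.abs(z) <= sp.body_height / 2.0)
        y_post1 = self.y_canal - sp.canal_radius
        block = (
            (np.abs(x) <= sp.posterior_halfwidth)
            & (y >= self.y_post0) & (y <= y_post1)
            & (np.abs(z) <= sp.posterior_halfheight)
        )
        mask = body | block
        for a, b in self.pedicles.values():
            mask |= _segment_distance(q, a, b) <= sp.pedicle_radius
        return mask.reshape(shape)

    def screw_plan(self, side: str) -> ScrewPlan:
        sp = self.spec
        a, b = self.pedicles[side]
        axis = (b - a) / np.linalg.norm(b - a)
        # entry point: intersection of the pedicle axis with the posterior face
        tail_local = a + axis * ((self.y_post0 - a[1]) / axis[1])
        tip_local = tail_local + axis * sp.screw_length
        return ScrewPlan(
            level="?", side=side,
            tip=self.to_world(tip_local), tail=self.to_world(tail_local),
            radius=sp.screw_radius, length=sp.screw_length,
        )

    def endplate(self):
        """Inferior endplate (point, superior normal) in world coordinates."""
        sp = self.spec
        point = self.to_world(np.array([0.0, sp.body_center_y, -sp.body_height / 2.0]))
        normal = self.R @ np.array([0.0, 0.0, 1.0])
        return point, normal

    def bead_positions(self, rng: np.random.Generator) -> np.ndarray:
        sp = self.spec
        base = np.array(
            [
                [-7.0, sp.body_center_y - 4.0, -5.0],
                [7.0, sp.body_center_y - 4.0, 5.0],
                [-6.0, sp.body_center_y + 4.0, 5.0],
                [6.0, sp.body_center_y + 4.0, -5.0],
            ]
        )
        n = sp.n_beads_per_level
        reps = int(np.ceil(n / 4.0)) if n else 0
        pts = np.tile(base, (max(reps, 1), 1))[:n]
        if n:
            pts = pts + rng.uniform(-1.5, 1.5, size=pts.shape)
        return np.array([self.to_world(p) for p in pts]).reshape(-1, 3)


def _segment_distance(pts: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    L2 = float(ab @ ab)
    t = np.clip((pts - a) @ ab / L2, 0.0, 1.0)
    return np.linalg.norm(pts - (a + t[:, None] * ab), axis=1)


# ---------------------------------------------------------------------------
# rendering


def _grid_geometry(spec: PhantomSpec):
    m = spec.motion_margin + 4.0
    x_half = spec.body_halfwidth + m
    tail_y = (
        spec.body_center_y - spec.body_halfdepth - 2.0 * spec.canal_radius
        - spec.posterior_depth
    )
    y_min = tail_y - spec.tulip_length - spec.tulip_radius - m
    y_max = spec.body_center_y + spec.body_halfdepth + m
    z_min = -spec.body_height / 2.0 - m
    z_max = (spec.n_levels - 1) * spec.level_pitch + spec.body_height / 2.0 + m
    origin = np.array([-x_half, y_min, z_min])
    extent = np.array([2 * x_half, y_max - y_min, z_max - z_min])
    shape = tuple(int(np.ceil(e / s)) + 1 for e, s in zip(extent, spec.spacing))
    affine = np.eye(4)
    affine[:3, :3] = np.diag(spec.spacing)
    affine[:3, 3] = origin
    return shape, affine


def _world_points(shape, affine) -> np.ndarray:
    idx = np.indices(shape).reshape(3, -1).T.astype(np.float32)
    return idx @ affine[:3, :3].T.astype(np.float32) + affine[:3, 3].astype(np.float32)


def _paint_metal(img, world_pts, dist_mm, spec: PhantomSpec):
    """Blend metal into the image with linear partial-volume coverage."""
    if spec.antialias_metal:
        w = float(np.prod(spec.spacing)) ** (1.0 / 3.0)
        cov = np.clip(0.5 - dist_mm / w, 0.0, 1.0)
    else:
        cov = (dist_mm < 0.0).astype(np.float32)
    flat = img.reshape(-1)
    nz = cov > 0
    flat[nz] = flat[nz] * (1.0 - cov[nz]) + spec.hu_metal * cov[nz]


def _render(
    spec: PhantomSpec,
    vertebrae: list,
    motions: dict | None,
    screws: list,
    beads: np.ndarray | None,
    rng: np.random.Generator,
    make_labels: bool = False,
):
    """Rasterise the scene. ``screws`` is a list of (tail, tip) world pairs
    already in the output (post-motion) space; ``motions`` maps level name to
    the rigid motion of that vertebra (None means identity for all)."""
    shape, affine = _grid_geometry(spec)
    pts = _world_points(shape, affine)
    img = np.full(shape, spec.hu_air, dtype=np.float32)

    # soft-tissue torso: everything except a 3 mm air rim
    lo = affine[:3, 3] + 3.0
    hi = affine[:3, 3] + np.array(shape) * np.asarray(spec.spacing) - 3.0
    torso = np.all((pts >= lo) & (pts <= hi), axis=1).reshape(shape)
    img[torso] = spec.hu_soft

    labels = np.zeros(shape, dtype=np.int16) if make_labels else None
    names = spec.level_names()
    interior_margin = 2  # voxels; bone must stay off the volume boundary
    for k, vert in enumerate(vertebrae):
        level = names[k]
        if motions is not None and level in motions:
            sample_pts = motions[level].inverse().apply(pts)
        else:
            sample_pts = pts
        bone = vert.bone_mask(sample_pts, shape)
        if _touches_boundary(bone, interior_margin):
            raise GenerationError(f"vertebra {level} leaves the field of view")
        # cortical shell: bone within cortical_thickness of the outside
        dist_in = ndimage.distance_transform_edt(bone, sampling=spec.spacing)
        cortical = dist_in[bone] <= spec.cortical_thickness
        trab_val = np.full(int((~cortical).sum()), spec.hu_trabecular)
        if spec.trabecular_texture_hu > 0:
            flat_bone = bone.reshape(-1)
            trab_local = vert.to_local(
                sample_pts[flat_bone.nonzero()[0][~cortical]]
            )
            trab_val = trab_val + _texture_field(
                trab_local, (spec.seed, k), spec.trabecular_texture_hu
            )
        vals = np.empty(int(bone.sum()), dtype=np.float32)
        vals[cortical] = spec.hu_cortical
        vals[~cortical] = trab_val
        img[bone] = vals
        if make_labels:
            labels[bone] = k + 1

    for tail, tip in screws:
        axis = (tip - tail) / np.linalg.norm(tip - tail)
        d = _segment_distance(pts, tail, tip) - spec.screw_radius
        _paint_metal(img, pts, d, spec)
        # tulip: flat-faced cylinder sitting on the entry point — it does not
        # protrude anterior of the tail into the bone
        rel = pts - tail
        s = rel @ axis
        radial = np.linalg.norm(rel - s[:, None] * axis, axis=1)
        d = np.maximum.reduce(
            [radial - spec.tulip_radius, s, -(s + spec.tulip_length)]
        )
        _paint_metal(img, pts, d, spec)
    if beads is not None and len(beads):
        for b in np.asarray(beads).reshape(-1, 3):
            d = np.linalg.norm(pts - b, axis=1) - spec.bead_diameter / 2.0
            _paint_metal(img, pts, d, spec)

    if spec.blur_sigma_mm > 0:
        sig = [spec.blur_sigma_mm / s for s in spec.spacing]
        img = ndimage.gaussian_filter(img, sig)
    if spec.noise_sigma_hu > 0:
        img = img + rng.normal(0.0, spec.noise_sigma_hu, size=img.shape).astype(
            np.float32
        )
    return CTVolume(img.astype(np.float32), affine), labels


def _texture_field(local_pts: np.ndarray, seed_key, amplitude: float) -> np.ndarray:
    """Smooth pseudo-random field evaluated at vertebra-local coordinates.

    A fixed sum of random cosines (wavelengths 2.5-6 mm), seeded by the
    phantom seed and level index, so the pattern is identical in the pre-
    and postoperative renders and moves rigidly with the vertebra.
    """
    rng = np.random.default_rng(np.random.SeedSequence([*seed_key, 97]))
    n_waves = 24
    dirs = rng.normal(size=(n_waves, 3))
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    wavelen = rng.uniform(2.5, 6.0, size=n_waves)
    kvec = (2 * np.pi / wavelen)[:, None] * dirs
    phases = rng.uniform(0, 2 * np.pi, size=n_waves)
    out = np.zeros(len(local_pts))
    for k, phi in zip(kvec, phases):
        out += np.cos(local_pts @ k + phi)
    return (amplitude * np.sqrt(2.0 / n_waves) * out).astype(np.float32)


def _touches_boundary(mask: np.ndarray, margin: int) -> bool:
    interior = np.zeros_like(mask)
    sl = tuple(slice(margin, s - margin) for s in mask.shape)
    interior[sl] = True
    return bool(np.any(mask & ~interior))


def _build_vertebrae(spec: PhantomSpec) -> list:
    return [
        _Vertebra(spec, np.array([0.0, 0.0, k * spec.level_pitch]))
        for k in range(spec.n_levels)
    ]


def _screw_frame(plan: ScrewPlan, normal: np.ndarray) -> np.ndarray:
    """Columns e_ML, e_AP, e_SI; e_ML points medially for the plan's side."""
    e_ap = plan.axis
    e_si = normal - (normal @ e_ap) * e_ap
    e_si = e_si / np.linalg.norm(e_si)
    e_ml = np.cross(e_si, e_ap)
    medial = np.array([-1.0, 0.0, 0.0]) if plan.side == "R" else np.array([1.0, 0.0, 0.0])
    if e_ml @ medial < 0:
        e_ml = -e_ml
    return np.column_stack([e_ml, e_ap, e_si])


# ---------------------------------------------------------------------------
# public generators


def generate_preop(spec: PhantomSpec):
    """Render the preoperative scan.

    Returns ``(volume, mask, plans, ground_truth)`` with the ground truth
    partially filled (plans, frames, endplates, bead positions); the postop
    generator completes it. Deterministic given ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    vertebrae = _build_vertebrae(spec)
    names = spec.level_names()

    plans, frames, endplates = [], {}, {}
    beads, bead_levels = [], []
    for k, vert in enumerate(vertebrae):
        level = names[k]
        point, normal = vert.endplate()
        endplates[level] = (point, normal)
        for side in ("L", "R"):
            plan = replace(vert.screw_plan(side), level=level)
            plans.append(plan)
            frames[(level, side)] = _screw_frame(plan, normal)
        pb = vert.bead_positions(rng)
        beads.extend(pb)
        bead_levels.extend([level] * len(pb))
    beads = np.asarray(beads, dtype=float).reshape(-1, 3)

    volume, labels = _render(
        spec, vertebrae, None, screws=[],
        beads=beads if len(beads) else None, rng=rng, make_labels=True,
    )
    mask = LabelMask(labels, volume.affine.copy(),
                     {k + 1: names[k] for k in range(spec.n_levels)})
    gt = GroundTruth(
        plans=plans, frames=frames, endplates=endplates,
        beads_pre=beads, bead_levels=bead_levels,
    )
    return volume, mask, plans, gt


def generate_postop(
    spec: PhantomSpec,
    gt: GroundTruth,
    screw_deviations: dict | None = None,
    motions: dict | None = None,
):
    """Render the postoperative scan and complete the ground truth.

    ``screw_deviations`` maps ``(level, side)`` to a pair of screw-frame
    offset vectors ``(tip_offset, tail_offset)`` in (ML, AP, SI) mm applied to
    the planned landmarks; ``motions`` maps level name to its rigid inter-scan
    motion (identity when absent). The deviated trajectory is rendered exactly
    as declared, then moved by the level motion.
    """
    screw_deviations = screw_deviations or {}
    motions = motions or {}
    names = spec.level_names()
    vertebrae = _build_vertebrae(spec)
    full_motions = {
        lvl: motions.get(lvl, RigidTransform.identity()) for lvl in names
    }

    true_screws, deviations = {}, {}
    screw_segments = []
    for plan in gt.plans:
        key = (plan.level, plan.side)
        F = gt.frames[key]
        tip_off, tail_off = screw_deviations.get(key, (np.zeros(3), np.zeros(3)))
        tip_pre = plan.tip + F @ np.asarray(tip_off, dtype=float)
        tail_pre = plan.tail + F @ np.asarray(tail_off, dtype=float)
        M = full_motions[plan.level]
        ts = TrueScrew(tip_pre, tail_pre, M.apply(tip_pre), M.apply(tail_pre))
        true_screws[key] = ts
        deviations[key] = (np.asarray(tip_off, float), np.asarray(tail_off, float))
        screw_segments.append((ts.tail_post, ts.tip_post))

    beads_post = np.array(
        [full_motions[lvl].apply(b) for b, lvl in zip(gt.beads_pre, gt.bead_levels)]
    ).reshape(-1, 3)

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    volume, _ = _render(
        spec, vertebrae, full_motions, screws=screw_segments,
        beads=beads_post if len(beads_post) else None, rng=rng,
    )
    gt_full = GroundTruth(
        plans=gt.plans, frames=gt.frames, endplates=gt.endplates,
        beads_pre=gt.beads_pre, bead_levels=gt.bead_levels,
        motions=full_motions, beads_post=beads_post,
        true_screws=true_screws, deviations=deviations,
    )
    return volume, gt_full


# ---------------------------------------------------------------------------
# randomised conditions


def random_motion(
    rng: np.random.Generator, max_rot_deg: float = 10.0, max_trans_mm: float = 10.0,
    center=None,
) -> RigidTransform:
    """Uniform random rigid motion: angle U[0, max] about a uniform axis,
    translation of magnitude U[0, max] in a uniform direction."""
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rot_deg))
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    trans = direction * rng.uniform(0.0, max_trans_mm)
    return RigidTransform.from_rotvec(axis * angle, trans, center=center)


def rigid_deviation(
    translation_frame, tilt_deg: float, tilt_azimuth_deg: float, length: float
):
    """Length-preserving planted deviation, in screw-frame components.

    The screw is translated by ``translation_frame`` (ML, AP, SI mm) and its
    axis tilted ``tilt_deg`` about a direction in the ML-SI plane at
    ``tilt_azimuth_deg`` through the tail. Returns ``(tip_offset,
    tail_offset)`` suitable for :func:`generate_postop`.
    """
    t = np.asarray(translation_frame, dtype=float)
    az = np.radians(tilt_azimuth_deg)
    # tilt axis perpendicular to the shaft (AP) direction, in frame coords
    axis = np.array([np.cos(az), 0.0, np.sin(az)])
    th = np.radians(tilt_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    R = np.eye(3) + np.sin(th) * K + (1 - np.cos(th)) * (K @ K)
    shaft = np.array([0.0, length, 0.0])  # tail->tip in frame coordinates
    tail_off = t
    tip_off = t + (R @ shaft - shaft)
    return tip_off, tail_off


def random_deviation(
    rng: np.random.Generator, length: float,
    max_trans_mm: float = 3.0, max_tilt_deg: float = 5.0,
):
    """Random length-preserving deviation within the stated bounds."""
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    t = direction * rng.uniform(0.0, max_trans_mm)
    return rigid_deviation(
        t, rng.uniform(0.0, max_tilt_deg), rng.uniform(0.0, 360.0), length
    )


# ---------------------------------------------------------------------------
# serialisation (CLI `simulate` writes these)


def ground_truth_to_dict(gt: GroundTruth) -> dict:
    def arr(a):
        return np.asarray(a, dtype=float).tolist()

    return {
        "plans": [
            {
                "level": p.level, "side": p.side, "tip_xyz_mm": arr(p.tip),
                "tail_xyz_mm": arr(p.tail), "radius_mm": p.radius,
                "length_mm": p.length,
            }
            for p in gt.plans
        ],
        "frames": {
            f"{lvl}:{side}": arr(F) for (lvl, side), F in gt.frames.items()
        },
        "endplates": {
            lvl: {"point": arr(p), "normal": arr(n)}
            for lvl, (p, n) in gt.endplates.items()
        },
        "beads_pre": arr(gt.beads_pre),
        "bead_levels": list(gt.bead_levels),
        "beads_post": None if gt.beads_post is None else arr(gt.beads_post),
        "motions": {lvl: T.to_dict() for lvl, T in gt.motions.items()},
        "true_screws": {
            f"{lvl}:{side}": {
                "tip_pre": arr(ts.tip_pre), "tail_pre": arr(ts.tail_pre),
                "tip_post": arr(ts.tip_post), "tail_post": arr(ts.tail_post),
            }
            for (lvl, side), ts in gt.true_screws.items()
        },
    }


def save_ground_truth(gt: GroundTruth, path) -> None:
    with open(path, "w") as fh:
        json.dump(ground_truth_to_dict(gt), fh, indent=1)
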