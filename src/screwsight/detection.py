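"""Postoperative screw localisation.

Screws are the brightest objects in the postoperative scan, so candidate
voxels are found by intensity thresholding and connected-component analysis.
Each component seeds a parametric shaft model — a capsule of the planned
radius and length — which is then refined by maximising the contrast between
the mean (clipped) intensity inside the capsule and in a surrounding shell.
Because the screws are poly-axial, the tulip head can angulate relative to
the shaft; the model therefore fits the shaft only, and the tail is the
shaft's posterior end (the bone entry point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, optimize

from .core import CTVolume, RigidTransform

__all__ = [
    "ScrewPlan",
    "DetectedScrew",
    "MetalComponent",
    "MatchResult",
    "DegenerateGeometryError",
    "ConvergenceError",
    "detect_metal_components",
    "init_screw_from_component",
    "fit_screw_model",
    "match_screws_to_plans",
]


class DegenerateGeometryError(ValueError):
    """Component geometry does not determine a screw axis."""


class ConvergenceError(RuntimeError):
    """Model fit hit its iteration cap; carries the best iterate."""

    def __init__(self, msg: str, best: "DetectedScrew"):
        super().__init__(msg)
        self.best = best


@dataclass(frozen=True)
class ScrewPlan:
    """A planned trajectory: tip and tail in preoperative world mm.

    The tail is the posterior entry point at the bone surface; the tip is the
    anterior end of the shaft. ``length`` must match ``|tip - tail|`` to
    within 0.5 mm.
    """

    level: str
    side: str  # "L" or "R"
    tip: np.ndarray
    tail: np.ndarray
    radius: float
    length: float

    def __post_init__(self):
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float).reshape(3))
        object.__setattr__(self, "tail", np.asarray(self.tail, dtype=float).reshape(3))
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        d = float(np.linalg.norm(self.tip - self.tail))
        if abs(d - self.length) > 0.5:
            raise ValueError(
                f"plan length {self.length:.2f} inconsistent with |tip-tail| {d:.2f}"
            )

    @property
    def axis(self) -> np.ndarray:
        v = self.tip - self.tail
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class DetectedScrew:
    """A fitted screw shaft in postoperative world mm."""

    tip: np.ndarray
    tail: np.ndarray
    fit_score: float
    level: str | None = None
    side: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "tip", np.asarray(self.tip, dtype=float).reshape(3))
        object.__setattr__(self, "tail", np.asarray(self.tail, dtype=float).reshape(3))
        if not np.isfinite(self.fit_score):
            raise ValueError("fit_score must be finite")

    @property
    def axis(self) -> np.ndarray:
        v = self.tip - self.tail
        return v / np.linalg.norm(v)


@dataclass
class MetalComponent:
    """One 26-connected supra-threshold component of the postop volume."""

    indices: np.ndarray      # (n, 3) voxel indices
    points: np.ndarray       # (n, 3) world mm
    intensities: np.ndarray  # (n,)

    @property
    def n_voxels(self) -> int:
        return len(self.indices)

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)


def detect_metal_components(
    postop: CTVolume,
    metal_threshold: float,
    min_volume_mm3: float | None = None,
    nominal_radius: float = 2.25,
    nominal_length: float = 30.0,
) -> list[MetalComponent]:
    """Find metal components above ``metal_threshold``, largest first.

    Components smaller than ``min_volume_mm3`` (default: half the volume of a
    nominal screw shaft) are discarded — this removes fiducial beads and
    streak speckle while keeping every screw. A volume with no
    supra-threshold voxels yields an empty list.
    """
    if not np.isfinite(metal_threshold):
        raise ValueError("metal_threshold must be finite")
    if min_volume_mm3 is None:
        min_volume_mm3 = 0.5 * np.pi * nominal_radius**2 * nominal_length
    voxel_vol = float(np.prod(postop.spacing))
    min_voxels = max(1, int(np.ceil(min_volume_mm3 / voxel_vol)))

    binary = postop.data > metal_threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, n = ndimage.label(binary, structure=structure)
    if n == 0:
        return []
    sizes = ndimage.sum_labels(np.ones_like(labeled), labeled, index=np.arange(1, n + 1))
    keep = [i + 1 for i in np.argsort(sizes)[::-1] if sizes[i] >= min_voxels]
    components = []
    for lab in keep:
        idx = np.argwhere(labeled == lab)
        pts = idx @ postop.affine[:3, :3].T + postop.affine[:3, 3]
        vals = postop.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        components.append(MetalComponent(idx, pts, np.asarray(vals, dtype=float)))
    return components


def init_screw_from_component(
    component: MetalComponent, radius: float, length: float
) -> DetectedScrew:
    """Seed a screw model from a metal component by principal-axis analysis.

    The axis is the leading eigenvector of the component's world-coordinate
    covariance, oriented so the tip is the end farther from the volume's
    posterior (-y) face. The shaft of nominal ``length`` is anchored at the
    component's anterior extreme (the rounded tip cap reaches ``radius``
    beyond the tip point), which keeps the poly-axial tulip's extra bulk at
    the posterior end from dragging the initial pose off the shaft.
    """
    if component.n_voxels == 0:
        raise DegenerateGeometryError("empty component")
    pts = component.points
    centroid = component.centroid
    cov = np.cov((pts - centroid).T)
    evals, evecs = np.linalg.eigh(cov)
    # eigh returns ascending order; leading axis last
    if evals[2] < 4.0 * evals[1]:
        raise DegenerateGeometryError(
            "component is not elongated enough to define a screw axis"
        )
    axis = evecs[:, 2]
    if axis[1] < 0:  # orient anteriorly: tip away from the posterior face
        axis = -axis
    s = (pts - centroid) @ axis
    tip = centroid + axis * (float(s.max()) - radius)
    tail = tip - axis * length
    return DetectedScrew(tip=tip, tail=tail, fit_score=0.0)


def _capsule_objective(
    points: np.ndarray,
    clipped: np.ndarray,
    tip: np.ndarray,
    axis: np.ndarray,
    radius: float,
    length: float,
    edge_mm: float = 0.5,
) -> float:
    """Mean clipped intensity inside the shaft capsule minus the shell mean.

    Capsule and shell memberships ramp linearly over ``edge_mm`` (about one
    voxel) instead of switching at the surface: with hard memberships the
    objective is a staircase in the pose (voxels jump sets discretely) and
    the optimiser stalls on spurious flats up to ~0.5 mm from the true
    shaft. The shell spans radial distance (r, 2r] over the shaft's axial
    extent only, so the tulip head (posterior of the tail) stays out of the
    contrast term at the optimum while still penalising posterior drift the
    moment it would slide under the shaft.
    """
    tail = tip - axis * length
    rel = points - tail
    s = rel @ axis
    s_clamped = np.clip(s, 0.0, length)
    closest = tail + s_clamped[:, None] * axis
    d = np.linalg.norm(points - closest, axis=1)
    w_in = np.clip(0.5 + (radius - d) / edge_mm, 0.0, 1.0)
    w_shell = (
        np.clip(0.5 + (d - radius) / edge_mm, 0.0, 1.0)
        * np.clip(0.5 + (2.0 * radius - d) / edge_mm, 0.0, 1.0)
        * np.clip(0.5 + s / edge_mm, 0.0, 1.0)
        * np.clip(0.5 + (length - s) / edge_mm, 0.0, 1.0)
    )
    sw_in, sw_shell = w_in.sum(), w_shell.sum()
    if sw_in <= 0 or sw_shell <= 0:
        return -np.inf
    return float((clipped @ w_in) / sw_in - (clipped @ w_shell) / sw_shell)


def fit_screw_model(
    postop: CTVolume,
    init: DetectedScrew,
    radius: float,
    length: float,
    clip_level: float | None = None,
    max_iter: int = 400,
) -> DetectedScrew:
    """Refine a screw pose by maximising capsule-vs-shell intensity contrast.

    Five degrees of freedom: the tip position (3) and the axis direction (2);
    the shaft length is fixed to the plan, which disambiguates the tip from
    the tulip. Intensities are clipped at ``clip_level`` (default: the 99th
    percentile of the init capsule neighbourhood) so streak artefact does not
    dominate the means. Derivative-free local optimisation (Powell) from the
    initial pose.
    """
    axis0 = init.axis
    # orthonormal complement of the initial axis, for the 2-DOF direction update
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis0 @ ref) > 0.9:
        ref = np.array([0.0, 0.0, 1.0])
    u = np.cross(axis0, ref)
    u /= np.linalg.norm(u)
    v = np.cross(axis0, u)

    # region of interest: voxels near the initial shaft (bounding box, then a
    # cylindrical crop so the objective only ever touches relevant voxels)
    margin = 3.0 * radius + 3.0
    lo_w = np.minimum(init.tip, init.tail) - margin
    hi_w = np.maximum(init.tip, init.tail) + margin
    corners = np.array(
        [
            [x, y, z]
            for x in (lo_w[0], hi_w[0])
            for y in (lo_w[1], hi_w[1])
            for z in (lo_w[2], hi_w[2])
        ]
    )
    vox = postop.to_voxel(corners)
    lo = np.maximum(np.floor(vox.min(axis=0)).astype(int), 0)
    hi = np.minimum(np.ceil(vox.max(axis=0)).astype(int) + 1, postop.shape)
    if np.any(hi <= lo):
        raise ValueError("initial screw pose lies outside the volume")
    grid = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]].reshape(3, -1).T
    points = grid @ postop.affine[:3, :3].T + postop.affine[:3, 3]
    rel = points - init.tail
    s0 = rel @ init.axis
    radial = np.linalg.norm(rel - np.outer(s0, init.axis), axis=1)
    near = (radial <= margin) & (s0 >= -margin) & (s0 <= length + margin)
    grid, points = grid[near], points[near]
    vals = postop.data[grid[:, 0], grid[:, 1], grid[:, 2]].astype(float)
    if clip_level is None:
        clip_level = float(np.percentile(vals, 99))
    clipped = np.minimum(vals, clip_level)

    def unpack(p):
        tip = p[:3]
        a = axis0 + p[3] * u + p[4] * v
        return tip, a / np.linalg.norm(a)

    def neg_obj(p):
        tip, axis = unpack(p)
        return -_capsule_objective(points, clipped, tip, axis, radius, length)

    x0 = np.concatenate([init.tip, [0.0, 0.0]])
    res = optimize.minimize(
        neg_obj,
        x0,
        method="Powell",
        options={"xtol": 1e-4, "ftol": 1e-8, "maxiter": max_iter},
    )
    tip, axis = unpack(res.x)
    best = DetectedScrew(
        tip=tip,
        tail=tip - axis * length,
        fit_score=-float(res.fun),
        level=init.level,
        side=init.side,
    )
    if not res.success and res.status not in (0, 1):
        raise ConvergenceError(f"screw fit did not converge: {res.message}", best)
    return best


@dataclass
class MatchResult:
    pairs: list  # list[(ScrewPlan, DetectedScrew)]
    unmatched_plans: list = field(default_factory=list)
    unmatched_detections: list = field(default_factory=list)
    ambiguous: bool = False


def match_screws_to_plans(
    detected: list[DetectedScrew],
    plans: list[ScrewPlan],
    coarse_T: RigidTransform | dict | None = None,
    ambiguity_tol_mm: float = 1.0,
) -> MatchResult:
    """One-to-one plan/detection assignment by tip proximity.

    Plans are first mapped through ``coarse_T`` (a single transform, or a
    per-level dict of transforms; identity when omitted). The assignment
    minimises summed tip-to-tip distance (Hungarian algorithm); surplus
    plans or detections are reported, never dropped silently. If a different
    complete assignment comes within ``ambiguity_tol_mm`` of the optimal
    total cost the result is flagged ambiguous.
    """
    if not plans or not detected:
        return MatchResult([], list(plans), list(detected))

    def map_tip(plan: ScrewPlan) -> np.ndarray:
        if coarse_T is None:
            return plan.tip
        T = coarse_T[plan.level] if isinstance(coarse_T, dict) else coarse_T
        return T.apply(plan.tip)

    cost = np.array(
        [[np.linalg.norm(map_tip(p) - d.tip) for d in detected] for p in plans]
    )
    rows, cols = optimize.linear_sum_assignment(cost)
    total = cost[rows, cols].sum()
    pairs = [(plans[r], detected[c]) for r, c in zip(rows, cols)]
    unmatched_plans = [p for i, p in enumerate(plans) if i not in set(rows)]
    unmatched_det = [d for j, d in enumerate(detected) if j not in set(cols)]

    ambiguous = False
    assign = dict(zip(rows, cols))
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            r1, r2 = rows[i], rows[j]
            swapped = (
                total
                - cost[r1, assign[r1]] - cost[r2, assign[r2]]
                + cost[r1, assign[r2]] + cost[r2, assign[r1]]
            )
            if swapped - total < ambiguity_tol_mm:
                ambiguous = True
    return MatchResult(pairs, unmatched_plans, unmatched_det, ambiguous)
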