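"""Per-screw placement errors and the accuracy/precision roll-up.

Errors are resolved in the screw-aligned (ML, AP, SI) frame, carried through
the per-level registration so they are expressed relative to the planned
trajectory regardless of inter-scan motion. Group statistics follow the
standard accuracy/precision decomposition for surgical navigation: SME
(signed mean error, systematic bias), MAE (mean absolute error, accuracy)
and 2 SD of the signed errors (precision). Euclidean composites (tip/tail 3D
and mid-pedicle 2D) carry MAE only — their signed mean is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import RigidTransform
from .detection import DetectedScrew, ScrewPlan
from .frames import MidPedicleLocus, NoIntersectionError, ScrewFrame

__all__ = [
    "AccuracyRecord",
    "SummaryStats",
    "screw_errors",
    "angular_deviation",
    "summarize",
    "regional_comparison",
    "records_to_frame",
    "region_of_level",
    "COMPONENT_COLUMNS",
    "EUCLIDEAN_COLUMNS",
]

COMPONENT_COLUMNS = [
    "tail_ml", "tail_ap", "tail_si",
    "mid_ml", "mid_si",
    "tip_ml", "tip_ap", "tip_si",
    "angle_deg",
]
EUCLIDEAN_COLUMNS = ["tail_3d", "mid_2d", "tip_3d"]


def region_of_level(level: str) -> str:
    """Upper thoracic (T2-T6), lower thoracic (T7-T12) or lumbar (L1+)."""
    kind, num = level[0].upper(), int(level[1:])
    if kind == "T":
        return "upper thoracic" if num <= 6 else "lower thoracic"
    if kind == "L":
        return "lumbar"
    raise ValueError(f"unrecognised level {level!r}")


@dataclass(frozen=True)
class AccuracyRecord:
    """Frame-resolved errors of one screw (mm / degrees, medial-positive)."""

    level: str
    side: str
    tail_ml: float
    tail_ap: float
    tail_si: float
    tip_ml: float
    tip_ap: float
    tip_si: float
    mid_ml: float
    mid_si: float
    angle_deg: float
    region: str = ""

    def __post_init__(self):
        if not self.region:
            object.__setattr__(self, "region", region_of_level(self.level))
        if not (0.0 <= self.angle_deg <= 180.0):
            raise ValueError("angle_deg must lie in [0, 180]")

    @property
    def tail_3d(self) -> float:
        return float(np.sqrt(self.tail_ml**2 + self.tail_ap**2 + self.tail_si**2))

    @property
    def tip_3d(self) -> float:
        return float(np.sqrt(self.tip_ml**2 + self.tip_ap**2 + self.tip_si**2))

    @property
    def mid_2d(self) -> float:
        return float(np.sqrt(self.mid_ml**2 + self.mid_si**2))


def angular_deviation(a, b) -> float:
    """Angle (degrees) between two unit vectors; symmetric in its arguments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na < 1e-12 or nb < 1e-12:
        raise ValueError("zero-length direction vector")
    return float(np.degrees(np.arccos(np.clip((a @ b) / (na * nb), -1.0, 1.0))))


def screw_errors(
    plan: ScrewPlan,
    detected: DetectedScrew,
    T: RigidTransform,
    frame: ScrewFrame,
    locus: MidPedicleLocus,
) -> AccuracyRecord:
    """Resolve one screw's tip/tail/mid-pedicle errors in its planned frame.

    The planned landmarks, the mid-pedicle locus and the frame axes are all
    mapped through the per-level registration ``T`` into postoperative space;
    tip and tail errors are the detected-minus-planned offsets resolved on
    the mapped axes, and the mid-pedicle error is the in-plane (ML, SI)
    offset where the detected axis pierces the plane through the mapped locus
    normal to the mapped AP axis.
    """
    R = T.rotation
    e_ml, e_ap, e_si = R @ frame.e_ml, R @ frame.e_ap, R @ frame.e_si
    tip_err = detected.tip - T.apply(plan.tip)
    tail_err = detected.tail - T.apply(plan.tail)

    locus_m = T.apply(locus.point)
    denom = detected.axis @ e_ap
    if abs(denom) < 1e-6:
        raise NoIntersectionError("detected axis parallel to the mid-pedicle plane")
    t = ((locus_m - detected.tail) @ e_ap) / denom
    pierce = detected.tail + t * detected.axis
    mid_err = pierce - locus_m

    return AccuracyRecord(
        level=plan.level,
        side=plan.side,
        tail_ml=float(tail_err @ e_ml),
        tail_ap=float(tail_err @ e_ap),
        tail_si=float(tail_err @ e_si),
        tip_ml=float(tip_err @ e_ml),
        tip_ap=float(tip_err @ e_ap),
        tip_si=float(tip_err @ e_si),
        mid_ml=float(mid_err @ e_ml),
        mid_si=float(mid_err @ e_si),
        angle_deg=angular_deviation(R @ plan.axis, detected.axis),
    )


def records_to_frame(records: list) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "level": r.level, "side": r.side, "region": r.region,
                **{c: getattr(r, c) for c in COMPONENT_COLUMNS},
                **{c: getattr(r, c) for c in EUCLIDEAN_COLUMNS},
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SummaryStats:
    """SME / MAE / 2 SD per metric column for one group of screws."""

    n: int
    sme: dict = field(default_factory=dict)
    mae: dict = field(default_factory=dict)
    precision: dict = field(default_factory=dict)  # 2 * sample SD of signed errors

    def to_frame(self) -> pd.DataFrame:
        cols = COMPONENT_COLUMNS + EUCLIDEAN_COLUMNS
        ordered = [
            "tail_ml", "tail_ap", "tail_si", "tail_3d",
            "mid_ml", "mid_si", "mid_2d",
            "tip_ml", "tip_ap", "tip_si", "tip_3d",
            "angle_deg",
        ]
        assert set(ordered) == set(cols)
        return pd.DataFrame(
            {
                c: {
                    "Systematic Error (SME)": self.sme.get(c, np.nan),
                    "Precision (2 SDs)": self.precision.get(c, np.nan),
                    "Accuracy (MAE)": self.mae.get(c, np.nan),
                }
                for c in ordered
            }
        )


def summarize(records: list, group: str = "all") -> dict:
    """Roll per-screw records up into SME/MAE/2SD per group.

    ``group`` is ``"all"`` (one pooled group) or ``"region"``. SME and
    precision use the signed per-axis errors (sample SD, n-1 denominator);
    the Euclidean 3D/2D composites report MAE only. Groups with n < 2 report
    precision as NaN (undefined), never 0.
    """
    if group not in ("all", "region"):
        raise ValueError("group must be 'all' or 'region'")
    buckets: dict = {}
    for r in records:
        key = "all" if group == "all" else r.region
        buckets.setdefault(key, []).append(r)
    out = {}
    for key, recs in buckets.items():
        stats_ = SummaryStats(n=len(recs))
        for c in COMPONENT_COLUMNS:
            vals = np.array([getattr(r, c) for r in recs], dtype=float)
            stats_.sme[c] = float(vals.mean())
            stats_.mae[c] = float(np.abs(vals).mean())
            stats_.precision[c] = (
                float(2.0 * vals.std(ddof=1)) if len(vals) >= 2 else np.nan
            )
        for c in EUCLIDEAN_COLUMNS:
            vals = np.array([getattr(r, c) for r in recs], dtype=float)
            stats_.mae[c] = float(vals.mean())
        out[key] = stats_
    return out


def regional_comparison(records: list, metric: str) -> dict:
    """One-way ANOVA across regions plus Bonferroni-corrected pairwise tests.

    Computed on absolute errors of ``metric`` (e.g. ``"mid_ml"``). Regions
    with fewer than 2 screws are dropped with a warning entry.
    """
    groups: dict = {}
    for r in records:
        groups.setdefault(r.region, []).append(abs(getattr(r, metric)))
    warnings_ = [
        f"region {k!r} has n={len(v)} < 2 and was excluded"
        for k, v in groups.items()
        if len(v) < 2
    ]
    usable = {k: np.asarray(v, float) for k, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need at least two regions with n >= 2")
    names = sorted(usable)
    F, p = stats.f_oneway(*[usable[k] for k in names])
    pairs = []
    n_pairs = len(names) * (len(names) - 1) // 2
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            _, praw = stats.ttest_ind(usable[names[i]], usable[names[j]])
            pairs.append(
                {
                    "groups": (names[i], names[j]),
                    "p_raw": float(praw),
                    "p_bonferroni": float(min(1.0, praw * n_pairs)),
                }
            )
    return {
        "metric": metric,
        "anova_F": float(F),
        "anova_p": float(p),
        "group_means": {k: float(v.mean()) for k, v in usable.items()},
        "group_n": {k: int(len(v)) for k, v in usable.items()},
        "pairwise": pairs,
        "warnings": warnings_,
    }


def bonferroni(p_values, n_tests: int | None = None) -> list:
    """Bonferroni adjustment: multiply by the number of tests, cap at 1."""
    p = list(p_values)
    m = n_tests if n_tests is not None else len(p)
    return [min(1.0, v * m) for v in p]
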