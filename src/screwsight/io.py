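"""Reading and writing plans, detections, transforms and bead tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import RigidTransform
from .detection import DetectedScrew, ScrewPlan

__all__ = [
    "read_plans",
    "write_plans",
    "read_beads_csv",
    "write_beads_csv",
    "write_detections",
    "read_detections",
    "write_transforms",
    "read_transforms",
]

_PLAN_COLUMNS = [
    "level", "side",
    "tip_x_mm", "tip_y_mm", "tip_z_mm",
    "tail_x_mm", "tail_y_mm", "tail_z_mm",
    "radius_mm", "length_mm",
]


def write_plans(plans: list, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = [
            {
                "level": p.level, "side": p.side,
                "tip_xyz_mm": [float(v) for v in p.tip],
                "tail_xyz_mm": [float(v) for v in p.tail],
                "radius_mm": float(p.radius), "length_mm": float(p.length),
            }
            for p in plans
        ]
        path.write_text(json.dumps(payload, indent=1))
        return
    rows = [
        [p.level, p.side, *p.tip, *p.tail, p.radius, p.length] for p in plans
    ]
    pd.DataFrame(rows, columns=_PLAN_COLUMNS).to_csv(path, index=False)


def read_plans(path) -> list:
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return [
            ScrewPlan(
                level=d["level"], side=d["side"],
                tip=np.asarray(d["tip_xyz_mm"], float),
                tail=np.asarray(d["tail_xyz_mm"], float),
                radius=float(d["radius_mm"]), length=float(d["length_mm"]),
            )
            for d in payload
        ]
    df = pd.read_csv(path)
    plans = []
    for _, row in df.iterrows():
        plans.append(
            ScrewPlan(
                level=str(row["level"]), side=str(row["side"]),
                tip=row[["tip_x_mm", "tip_y_mm", "tip_z_mm"]].to_numpy(float),
                tail=row[["tail_x_mm", "tail_y_mm", "tail_z_mm"]].to_numpy(float),
                radius=float(row["radius_mm"]), length=float(row["length_mm"]),
            )
        )
    return plans


def write_detections(detections: list, path) -> None:
    payload = [
        {
            "level": d.level, "side": d.side,
            "tip_xyz_mm": [float(v) for v in d.tip],
            "tail_xyz_mm": [float(v) for v in d.tail],
            "fit_score": float(d.fit_score),
        }
        for d in detections
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def read_detections(path) -> list:
    payload = json.loads(Path(path).read_text())
    return [
        DetectedScrew(
            tip=np.asarray(d["tip_xyz_mm"], float),
            tail=np.asarray(d["tail_xyz_mm"], float),
            fit_score=float(d["fit_score"]),
            level=d.get("level"), side=d.get("side"),
        )
        for d in payload
    ]


def write_transforms(transforms: dict, path) -> None:
    """Per-level rigid transforms as unit quaternion (x, y, z, w) +
    translation, mapping preoperative world mm to postoperative world mm."""
    payload = {
        "convention": "T(p) = R p + t, preop world mm -> postop world mm; "
        "quaternion is (x, y, z, w)",
        "levels": {lvl: T.to_dict() for lvl, T in transforms.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_transforms(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {
        lvl: RigidTransform.from_dict(d) for lvl, d in payload["levels"].items()
    }


def write_beads_csv(pre: np.ndarray, post: np.ndarray, path, usable=None) -> None:
    pre = np.asarray(pre, float).reshape(-1, 3)
    post = np.asarray(post, float).reshape(-1, 3)
    if usable is None:
        usable = np.ones(len(pre), dtype=bool)
    df = pd.DataFrame(
        {
            "pre_x_mm": pre[:, 0], "pre_y_mm": pre[:, 1], "pre_z_mm": pre[:, 2],
            "post_x_mm": post[:, 0], "post_y_mm": post[:, 1], "post_z_mm": post[:, 2],
            "usable": np.asarray(usable, bool),
        }
    )
    df.to_csv(path, index=False)


def read_beads_csv(path):
    df = pd.read_csv(path)
    pre = df[["pre_x_mm", "pre_y_mm", "pre_z_mm"]].to_numpy(float)
    post = df[["post_x_mm", "post_y_mm", "post_z_mm"]].to_numpy(float)
    usable = (
        df["usable"].to_numpy(bool) if "usable" in df else np.ones(len(pre), bool)
    )
    return pre, post, usable
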