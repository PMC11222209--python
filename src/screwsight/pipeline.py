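"""End-to-end orchestration: detect -> match -> register -> frames -> errors.

`analyze_case` is the library entry point operating on in-memory objects;
`run_pipeline` wraps it for the command line, reading a config file,
loading the inputs it names, and writing tables, transforms and plots to an
artifact directory with per-stage logging. Both are deterministic given
their inputs and configuration.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .core import CTVolume, LabelMask, mask_centroid
from .detection import (
    detect_metal_components,
    fit_screw_model,
    init_screw_from_component,
    match_screws_to_plans,
)
from .fiducials import FiducialErrorReport
from .frames import build_screw_frame, fit_endplate_plane, locate_mid_pedicle
from .io import read_beads_csv, read_plans, write_detections, write_transforms
from .metrics import (
    records_to_frame,
    regional_comparison,
    screw_errors,
    summarize,
)
from .plots import TargetPlotSpec, render_target_plot
from .registration import (
    RefinementProblem,
    RegistrationConfig,
    perturbation_analysis,
    register_level,
)

__all__ = ["CaseResult", "analyze_case", "run_pipeline", "validate_beads"]

log = logging.getLogger("screwsight.pipeline")


@dataclass
class CaseResult:
    detections: list = field(default_factory=list)
    matches: object = None
    registrations: dict = field(default_factory=dict)      # level -> RegistrationResult
    problems: dict = field(default_factory=dict)           # level -> RefinementProblem
    records: list = field(default_factory=list)
    loci: dict = field(default_factory=dict)               # (level, side) -> MidPedicleLocus
    frames: dict = field(default_factory=dict)             # (level, side) -> ScrewFrame
    summary: dict = field(default_factory=dict)
    regional_summary: dict = field(default_factory=dict)
    perturbations: dict = field(default_factory=dict)      # level -> PerturbationReport
    fiducial_report: FiducialErrorReport | None = None


def analyze_case(
    preop: CTVolume,
    mask: LabelMask,
    postop: CTVolume,
    plans: list,
    metal_threshold: float,
    reg_config: RegistrationConfig = RegistrationConfig(),
    beads_pre: np.ndarray | None = None,
    beads_post: np.ndarray | None = None,
    perturbation: dict | None = None,
) -> CaseResult:
    """Run the full measurement chain on one pre/post scan pair.

    ``beads_pre``/``beads_post`` (optional, world mm) are masked out of the
    registration similarity and afterwards scored as fiducial registration
    errors. ``perturbation`` (optional) is a dict of keyword arguments for
    :func:`perturbation_analysis` (n, rot_deg, trans_mm, seed) run per level.
    """
    result = CaseResult()
    t0 = time.perf_counter()

    nominal_r = float(np.median([p.radius for p in plans]))
    nominal_l = float(np.median([p.length for p in plans]))
    components = detect_metal_components(
        postop, metal_threshold, nominal_radius=nominal_r, nominal_length=nominal_l
    )
    log.info("detected %d metal components", len(components))
    inits = [init_screw_from_component(c, nominal_r, nominal_l) for c in components]
    matches = match_screws_to_plans(inits, plans)
    result.matches = matches
    for p in matches.unmatched_plans:
        log.warning("plan %s/%s has no matching detection", p.level, p.side)

    fitted_pairs = []
    for plan, init in matches.pairs:
        init = replace(init, level=plan.level, side=plan.side)
        det = fit_screw_model(postop, init, plan.radius, plan.length)
        fitted_pairs.append((plan, det))
        result.detections.append(det)
    log.info(
        "fitted %d screws in %.1f s", len(fitted_pairs), time.perf_counter() - t0
    )

    levels = sorted(
        {p.level for p, _ in fitted_pairs}, key=lambda s: list(mask.level_ids.values()).index(s)
    )
    for level in levels:
        t1 = time.perf_counter()
        problem = RefinementProblem(
            preop, mask, level, postop, metal_threshold, reg_config,
            exclude_spheres_fixed=beads_pre,
            exclude_spheres_moving=beads_post,
        )
        reg = register_level(
            preop, mask, level, postop, fitted_pairs, metal_threshold,
            reg_config, problem=problem,
        )
        result.problems[level] = problem
        result.registrations[level] = reg
        log.info(
            "registered %s: MI %.4f -> %.4f (%.1f s)",
            level, reg.mi_init, reg.mi_final, time.perf_counter() - t1,
        )

    for plan, det in fitted_pairs:
        endplate = fit_endplate_plane(mask, plan.level)
        frame = build_screw_frame(plan, endplate)
        locus = locate_mid_pedicle(plan, mask, plan.level)
        T = result.registrations[plan.level].T
        rec = screw_errors(plan, det, T, frame, locus)
        result.records.append(rec)
        result.frames[(plan.level, plan.side)] = frame
        result.loci[(plan.level, plan.side)] = locus

    result.summary = summarize(result.records, group="all")
    result.regional_summary = summarize(result.records, group="region")

    if perturbation:
        for level in levels:
            result.perturbations[level] = perturbation_analysis(
                result.problems[level], result.registrations[level], **perturbation
            )

    if beads_pre is not None and beads_post is not None and len(beads_pre):
        result.fiducial_report = validate_beads(
            beads_pre, beads_post, result.registrations, mask
        )
    return result


def validate_beads(
    beads_pre, beads_post, registrations: dict, mask: LabelMask
) -> FiducialErrorReport:
    """Score beads against the per-level transforms.

    Each bead pair is assigned to the level whose mask centroid is nearest
    its preoperative position, then scored as ``|T_level(pre) - post|``.
    """
    beads_pre = np.asarray(beads_pre, float).reshape(-1, 3)
    beads_post = np.asarray(beads_post, float).reshape(-1, 3)
    centroids = {
        lvl: mask_centroid(mask, mask.label_for_level(lvl)) for lvl in registrations
    }
    names = list(centroids)
    cents = np.array([centroids[n] for n in names])
    mapped = np.empty_like(beads_pre)
    for i, b in enumerate(beads_pre):
        lvl = names[int(np.argmin(np.linalg.norm(cents - b, axis=1)))]
        mapped[i] = registrations[lvl].T.apply(b)
    errs = np.linalg.norm(mapped - beads_post, axis=1)
    sd = float(errs.std(ddof=1)) if len(errs) >= 2 else float("nan")
    return FiducialErrorReport(
        per_bead_mm=errs, mae_mm=float(errs.mean()), sd_mm=sd, n_usable=len(errs)
    )


# ---------------------------------------------------------------------------
# config-file driver


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config, out_dir=None) -> Path:
    """Execute the full pipeline from a YAML/dict config; returns the
    artifact directory.

    Config sections: ``inputs`` (preop, mask, postop, plans, optional
    level_ids, beads), ``detection`` (metal_threshold), ``registration``
    (RegistrationConfig fields, optional ``perturbation`` block),
    ``report`` (ring_radii). Reruns with the same config reproduce
    identical outputs.
    """
    cfg = _load_config(config)
    inputs = cfg.get("inputs", {})
    required = ("preop", "mask", "postop", "plans")
    missing = [k for k in required if k not in inputs]
    if missing:
        raise ValueError(f"config missing inputs: {', '.join(missing)}")
    for key in required:
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    out_dir = Path(out_dir or cfg.get("output", "screwsight_out"))
    out_dir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out_dir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("screwsight")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        preop = CTVolume.load(inputs["preop"])
        level_ids = inputs.get("level_ids")
        mask = LabelMask.load(inputs["mask"], level_ids=level_ids)
        postop = CTVolume.load(inputs["postop"])
        plans = read_plans(inputs["plans"])
        det_cfg = cfg.get("detection", {})
        metal_threshold = float(det_cfg.get("metal_threshold", 2500.0))
        reg_cfg_d = dict(cfg.get("registration", {}))
        perturb = reg_cfg_d.pop("perturbation", None)
        reg_config = RegistrationConfig(
            **{k: v for k, v in reg_cfg_d.items() if k in RegistrationConfig.__dataclass_fields__}
        )
        beads_pre = beads_post = None
        if "beads" in inputs:
            beads_pre, beads_post, usable = read_beads_csv(inputs["beads"])
            beads_pre, beads_post = beads_pre[usable], beads_post[usable]

        result = analyze_case(
            preop, mask, postop, plans, metal_threshold,
            reg_config=reg_config, beads_pre=beads_pre, beads_post=beads_post,
            perturbation=perturb,
        )

        df = records_to_frame(result.records)
        df.to_csv(out_dir / "screw_records.csv", index=False)
        result.summary["all"].to_frame().to_csv(out_dir / "summary_all.csv")
        for region, s in result.regional_summary.items():
            safe = region.replace(" ", "_")
            s.to_frame().to_csv(out_dir / f"summary_{safe}.csv")
        write_transforms(
            {lvl: r.T for lvl, r in result.registrations.items()},
            out_dir / "transforms.json",
        )
        write_detections(result.detections, out_dir / "detections.json")

        if len({r.region for r in result.records}) >= 2:
            anova = regional_comparison(result.records, "mid_ml")
            (out_dir / "anova_mid_ml.json").write_text(json.dumps(anova, indent=1))

        rings = tuple(cfg.get("report", {}).get("ring_radii", (2.0, 4.0)))
        for plane in ("tail", "mid-pedicle", "tip"):
            render_target_plot(
                result.records,
                TargetPlotSpec(plane=plane, ring_radii=rings),
                out_dir / f"target_{plane.replace('-', '_')}.png",
            )
        if result.perturbations:
            payload = {
                lvl: {
                    "n": rep.n_perturbations,
                    "mean_translation_mm": rep.mean_translation_mm,
                    "sd_translation_mm": rep.sd_translation_mm,
                    "mean_rotation_deg": rep.mean_rotation_deg,
                    "sd_rotation_deg": rep.sd_rotation_deg,
                    "translation_mm": rep.translation_discrepancies_mm.tolist(),
                    "rotation_deg": rep.rotation_discrepancies_deg.tolist(),
                }
                for lvl, rep in result.perturbations.items()
            }
            (out_dir / "perturbation.json").write_text(json.dumps(payload, indent=1))
        if result.fiducial_report is not None:
            rep = result.fiducial_report
            (out_dir / "fiducial_errors.json").write_text(
                json.dumps(
                    {
                        "per_bead_mm": rep.per_bead_mm.tolist(),
                        "mae_mm": rep.mae_mm, "sd_mm": rep.sd_mm,
                        "n_usable": rep.n_usable,
                    },
                    indent=1,
                )
            )
    finally:
        root.removeHandler(handler)
        handler.close()
    return out_dir
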