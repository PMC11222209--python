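"""Shared phantom fixtures.

The expensive objects (rendered phantom pair, full pipeline result) are
session-scoped and reused across test modules; every fixture is fully
deterministic.
"""

import numpy as np
import pytest

import screwsight as ss
from screwsight import phantom as ph


@pytest.fixture(scope="session")
def spec():
    """One-level phantom at the study's default imaging conditions."""
    return ph.PhantomSpec(seed=11)


@pytest.fixture(scope="session")
def preop_case(spec):
    return ph.generate_preop(spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Noise-free phantom (blur still on) for geometry-sensitive checks."""
    return ph.PhantomSpec(seed=12, noise_sigma_hu=0.0)


@pytest.fixture(scope="session")
def clean_preop(clean_spec):
    return ph.generate_preop(clean_spec)


def _default_motions_and_deviations(spec, plans, seed):
    rng = np.random.default_rng(seed)
    motions = {
        lvl: ph.random_motion(rng, 10.0, 10.0) for lvl in spec.level_names()
    }
    deviations = {
        (p.level, p.side): ph.random_deviation(rng, p.length, 3.0, 5.0)
        for p in plans
    }
    return motions, deviations


@pytest.fixture(scope="session")
def postop_case(spec, preop_case):
    """Postop render with known motion and planted deviations."""
    _, _, plans, gt = preop_case
    motions, deviations = _default_motions_and_deviations(spec, plans, seed=21)
    post, gt_full = ph.generate_postop(spec, gt, deviations, motions)
    return post, gt_full, motions, deviations


@pytest.fixture(scope="session")
def analyzed(spec, preop_case, postop_case):
    """Full pipeline result on the standard phantom (beads validated)."""
    pre, mask, plans, _ = preop_case
    post, gt, _, _ = postop_case
    result = ss.analyze_case(
        pre, mask, post, plans, spec.metal_threshold,
        beads_pre=gt.beads_pre, beads_post=gt.beads_post,
    )
    return result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
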