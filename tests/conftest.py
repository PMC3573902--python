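"""Shared synthetic fixtures.

Expensive rendered scenes are session-scoped so the flow, leaf and
acceptance tests reuse the same stacks instead of re-rendering them.
"""

import logging
import warnings

import pytest

from dielgrow.leaf_growth import AOI
from dielgrow.synthetic_data import (
    LeafSceneConfig,
    RootSceneConfig,
    make_leaf_stack,
    make_root_stack,
    make_translating_stack,
)

logging.disable(logging.WARNING)


@pytest.fixture(autouse=True)
def _quiet_flow_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        yield


@pytest.fixture(scope="session")
def translating_stack_1px():
    """256×256×20 textured scene translating at exactly (1, 0) px/frame."""
    return make_translating_stack(shift_per_frame=(1.0, 0.0), n_frames=20, seed=11)


@pytest.fixture(scope="session")
def translating_stack_subpx():
    """Same scene translating at (0.3, 0) px/frame (sub-pixel regime)."""
    return make_translating_stack(shift_per_frame=(0.3, 0.0), n_frames=20, seed=11)


@pytest.fixture(scope="session")
def leaf_expansion():
    """Isotropic expansion at r = 0.015 h⁻¹, 90 s cadence, 4 h, with truth."""
    cfg = LeafSceneConfig(
        rgr_profile=0.015, duration_h=4.0, image_size=(160, 160), seed=5
    )
    stack, truth = make_leaf_stack(cfg)
    return cfg, stack, truth


@pytest.fixture(scope="session")
def leaf_expansion_aoi(leaf_expansion):
    _, _, truth = leaf_expansion
    return AOI(truth.aoi_polygons[0])


@pytest.fixture(scope="session")
def root_constant():
    """Root elongating at a constant 0.6 mm h⁻¹ (30 s cadence, 30 min)."""
    cfg = RootSceneConfig(duration_h=0.5, velocity_profile=0.6, seed=9)
    stack, truth = make_root_stack(cfg)
    return cfg, stack, truth


def rel_err(estimate, truth):
    return abs(estimate - truth) / abs(truth)


@pytest.fixture(scope="session")
def relerr():
    return rel_err
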