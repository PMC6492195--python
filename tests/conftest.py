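"""Shared fixtures: one default-seeded end-to-end run plus small helpers."""

import numpy as np
import pytest

from cardiomoco.config import PipelineConfig
from cardiomoco.phantom import PhantomConfig, make_phantom
from cardiomoco.pipeline import (
    ground_truth_resp_ops,
    pet_resp_ops,
    reconstruct_pet_variants,
    run_pipeline,
)
from cardiomoco.registration import DeformationField, MotionOperator

DEFAULT_SEED = 1


@pytest.fixture(scope="session")
def pipe():
    """Full pipeline on the default phantom (shared across tests)."""
    return run_pipeline(PipelineConfig(seed=DEFAULT_SEED))


@pytest.fixture(scope="session")
def pet_gt_variant(pipe):
    """PET reconstructions redone with ground-truth motion operators."""
    ph = pipe.phantom
    gt_resp = ground_truth_resp_ops(ph, pipe.bins)
    ops = pet_resp_ops(
        {"systole": gt_resp, "diastole": gt_resp},
        pipe.bins,
        pipe.translations,
        ph.config.spacing,
    )
    gt_card = MotionOperator(DeformationField(ph.cardiac_field(), ph.config.spacing))
    mc, respmc, nmc = reconstruct_pet_variants(
        pipe.config,
        ph,
        pipe.events.geom,
        pipe.events,
        pipe.gated,
        pipe.timeline,
        pipe.bins,
        pipe.translations,
        ops,
        gt_card,
    )
    return {"mc": mc, "respmc": respmc, "nmc": nmc}


@pytest.fixture(scope="session")
def default_phantom():
    return make_phantom(PhantomConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
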