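import dataclasses

import numpy as np
import pytest

import wavecargo as wc
from wavecargo.segmentation import WaveMaskPair


@pytest.fixture(scope="session")
def planar_transient():
    """Noiseless asymmetric-pulse planar scene, κ=0.5."""
    params = wc.default_params("planar", "transient", depletion_strength=0.5)
    stack, truth = wc.generate_planar_scene(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def planar_square():
    """Noiseless square-pulse planar scene, κ=0.5 (exact-oracle scene)."""
    params = wc.default_params(
        "planar", "transient", pulse_shape="square", depletion_strength=0.5
    )
    stack, truth = wc.generate_planar_scene(params)
    return params, stack, truth


@pytest.fixture(scope="session")
def planar_anchored():
    params = wc.default_params("planar", "anchored")
    stack, truth = wc.generate_planar_scene(params)
    return params, stack, truth


def true_mask_pair(truth: wc.GroundTruth) -> WaveMaskPair:
    """Masks built from generator ground truth rather than segmentation."""
    return WaveMaskPair(
        wave_mask=truth.true_mask,
        complement_mask=~truth.true_mask,
        threshold_method="ground_truth",
        threshold_values=np.full(truth.true_mask.shape[0], np.nan),
    )


def with_noise(params: wc.SceneParams, **overrides) -> wc.SceneParams:
    noise = wc.scenes.default_noise(params.width, params.height, params.mode)
    noise.update(overrides)
    return dataclasses.replace(params, **noise)
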