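"""Shared fixtures.

Training runs are expensive on one CPU, so trained networks are
session-scoped and shared between the unit, integration and acceptance
tests.  All randomness is seeded; every fixture is a pure function of
its seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from planistem.phantom import PhantomSpec, make_roi_scene, make_volume
from planistem.segnet import (TINY_CONFIG, TrainConfig, UNet,
                              dice_coefficient, predict, save_model, train)

#: the scaled-down training protocol: 64 training scenes, 30 epochs,
#: batch 4, with the standard shift/rotate/zoom augmentation
N_TRAIN, N_VAL, N_TEST = 64, 12, 16
SCENE_SEEDS = list(range(N_TRAIN + N_VAL + N_TEST))

#: volume geometry used for detection tests (isotropic 1 mm voxels);
#: half the native MSP grid in each direction, so the standardized
#: 176x256 MSP image has isotropic 0.5 mm pixels
TEST_VOLUME_SHAPE = (88, 128, 128)
TEST_MSP_SPACING = 0.5  # mm per MSP/ROI pixel for TEST_VOLUME_SHAPE

#: geometry for end-to-end pipeline runs: three quarters of the native
#: MSP grid, so MSP pixels are isotropic 0.75 mm and the extraction's
#: interpolation softness matches the PSF the training scenes emulate
PIPELINE_VOLUME_SHAPE = (132, 192, 192)
PIPELINE_MSP_SPACING = 0.75


def training_scenes():
    return [make_roi_scene(s) for s in SCENE_SEEDS]


def train_task_model(task: str, seed: int, scenes=None,
                     epochs: int = 30, n_train: int = N_TRAIN,
                     n_val: int = N_VAL, learning_rate: float = 1e-3):
    """Train a tiny U-Net on phantom scenes; returns (net, test_pairs)."""
    scenes = scenes if scenes is not None else training_scenes()
    pairs = [(s.image, s.masks[task]) for s in scenes]
    net = UNet(TINY_CONFIG, seed=seed)
    cfg = TrainConfig(epochs=epochs, seed=seed,
                      learning_rate=learning_rate)
    _, history = train(net, pairs[:n_train],
                       pairs[n_train:n_train + n_val], cfg)
    return net, pairs[n_train + n_val:], history


def heldout_dice(net, test_pairs) -> float:
    return float(np.mean([dice_coefficient(m, predict(net, im)[1])
                          for im, m in test_pairs]))


@pytest.fixture(scope="session")
def scenes_pool():
    return training_scenes()


@pytest.fixture(scope="session")
def pons_model(scenes_pool):
    """Pons-area network trained with the full scaled-down protocol."""
    net, test_pairs, history = train_task_model("pons_area", seed=0,
                                                scenes=scenes_pool)
    return {"net": net, "test_pairs": test_pairs, "history": history,
            "heldout_dice": heldout_dice(net, test_pairs)}


@pytest.fixture(scope="session")
def quad_models(scenes_pool, pons_model, tmp_path_factory):
    """One trained network per task, saved to disk for the pipeline.

    The pons-area model reuses the full-protocol network; the other three
    use a shorter schedule, which is sufficient for the high-contrast
    phantom tasks.
    """
    models = {"pons_area": pons_model["net"]}
    # the midbrain measurement ellipse is the smallest, lowest-contrast
    # structure and converges slowest; it gets a longer schedule
    for task, epochs in (("midbrain_area", 30), ("midbrain_ellipse", 45),
                         ("pons_ellipse", 30)):
        net, _, _ = train_task_model(task, seed=0, scenes=scenes_pool,
                                     epochs=epochs)
        models[task] = net
    weights_dir = tmp_path_factory.mktemp("weights")
    paths = {}
    for task, net in models.items():
        path = weights_dir / f"{task}.npz"
        save_model(net, path, meta={"task": task})
        paths[task] = str(path)
    return {"models": models, "paths": paths}


@pytest.fixture(scope="session")
def aligned_phantom():
    """A phantom with the plane exactly at the central sagittal position."""
    return make_volume(PhantomSpec(shape=TEST_VOLUME_SHAPE, seed=7))


@pytest.fixture(scope="session")
def tilted_phantom():
    return make_volume(PhantomSpec(shape=TEST_VOLUME_SHAPE, fissure_yaw=5.0,
                                   fissure_roll=-3.0, fissure_offset=4.0,
                                   seed=11))
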