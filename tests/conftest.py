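import numpy as np
import pytest

from cdtl import (BackboneSpec, CDTLConfig, SliceRule, TaskSpec, TrainConfig,
                  make_classification_task)

ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def brute_force_glcm(image, distance, angle, levels, symmetric):
    """Independent double-loop pair-enumeration oracle for the GLCM."""
    image = np.asarray(image)
    h, w = image.shape
    if angle == "mean4":
        mats = [brute_force_glcm(image, distance, a, levels, symmetric)
                for a in (0, 45, 90, 135)]
        return np.mean(mats, axis=0)
    dr, dc = ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    counts = np.zeros((levels, levels))
    for r in range(h):
        for c in range(w):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < h and 0 <= c2 < w:
                counts[image[r, c], image[r2, c2]] += 1
                if symmetric:
                    counts[image[r2, c2], image[r, c]] += 1
    return counts / counts.sum()


def entropy_oracle(p, base="e"):
    """Direct summation over all matrix cells."""
    total = 0.0
    for row in p:
        for v in row:
            if v > 0:
                total -= v * np.log(v)
    return total / np.log(2) if base == "2" else total


@pytest.fixture(scope="session")
def small_task():
    """A default two-class task with planted subclusters (40 subjects)."""
    return make_classification_task(TaskSpec(seed=0))


@pytest.fixture()
def texture_cfg():
    """Fast fully deterministic pipeline config for tests."""
    return CDTLConfig(
        backbone=BackboneSpec(name="deterministic_texture"),
        base_slice_rule=SliceRule("all", 20),
        target_slice_rule=SliceRule("all", 30),
        train=TrainConfig(epochs=3, seed=0),
        folds=4, n_boot=100, seed=0,
    )
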