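"""Shared fixtures: geometric helpers and a small trained network.

The trained-model fixture is session-scoped: training even a tiny
network dominates test runtime, and every consumer only needs *a*
model whose probability maps separate vesicles from background.
"""

from __future__ import annotations

import numpy as np
import pytest

from sevseg.frunet import FRUNet
from sevseg.preprocess import stretch_intensity
from sevseg.synthgen import SceneConfig, generate_scene


def make_disk(shape, center, radius):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2


def make_ellipse(shape, center, a, b, angle):
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = (dx * ca + dy * sa) / a
    v = (-dx * sa + dy * ca) / b
    return u * u + v * v <= 1


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_scene_stack():
    """Twelve 96x96 synthetic scenes as (patches, masks) float stacks."""
    patches, masks = [], []
    for i in range(12):
        scene = generate_scene(SceneConfig(
            image_size_px=96, n_vesicles=2, diameter_range_nm=(30.0, 70.0),
            cluster_fraction=0.0, n_artifacts=0, seed=300 + i))
        patches.append(stretch_intensity(scene.image))
        masks.append((scene.gt.labels > 0).astype(np.float32))
    return np.stack(patches), np.stack(masks)


@pytest.fixture(scope="session")
def trained_tiny_model(small_scene_stack):
    """A small FRU-Net trained until it separates vesicles from background."""
    X, y = small_scene_stack
    est = FRUNet(base_features=4, epochs=60, batch_size=4,
                 learning_rate=2e-3, validation_fraction=0.1,
                 random_state=7)
    est.fit(X, y)
    return est
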