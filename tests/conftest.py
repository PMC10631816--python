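"""Shared fixtures: small phantoms and a session-trained network.

Everything is generated programmatically; heavyweight objects (rendered
phantom volumes, the trained segmentation network) are session-scoped so
the suite renders/trains each of them once.
"""

import numpy as np
import pytest

from endooct import (
    PhantomGeometry,
    make_segmentation_dataset,
    make_tissue_scene,
    render_frame_sequence,
    train_network,
)


@pytest.fixture(scope="session")
def small_geometry():
    """Desk-scale geometry for fast phantom tests."""
    return PhantomGeometry(n_depth=64, n_fast=64, n_slow=8, n_repeats=4)


@pytest.fixture(scope="session")
def full_geometry():
    return PhantomGeometry()


@pytest.fixture(scope="session")
def vessel_phantom(full_geometry):
    """A rendered full-size phantom with 25% vessel fraction."""
    scene = make_tissue_scene(full_geometry, thickness_um=150.0,
                              vessel_fraction=0.25, seed=1)
    vol = render_frame_sequence(scene, decorrelation=1.0, noise_floor=0.05, seed=2)
    return scene, vol


@pytest.fixture(scope="session")
def segmentation_data():
    """260 synthetic (B-scan, mask) pairs at 64x64: 200 train / 50 val / 10 test."""
    images, masks, thicknesses = make_segmentation_dataset(260, seed=42)
    return images, masks, thicknesses


@pytest.fixture(scope="session")
def trained_model(segmentation_data):
    """Encoder-decoder trained on the 200-pair synthetic training split."""
    images, masks, _ = segmentation_data
    model, history = train_network(
        (images[:200], masks[:200]), (images[200:250], masks[200:250]),
        epochs=10, seed=0,
    )
    return model, history


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
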