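"""Shared phantom fixtures; everything is generated from seeds at test time."""

import numpy as np
import pytest

from rfmirsi.classifier import train
from rfmirsi.labels import assemble_training_set
from rfmirsi.phantom import PhantomSpec, make_bundle
from rfmirsi.preprocess import preprocess_cube


@pytest.fixture(scope="session")
def default_bundle():
    """A phantom at the default (study-condition) generator settings."""
    return make_bundle(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def holdout_bundle():
    """Second phantom at the same settings, disjoint seed: held-out data."""
    return make_bundle(PhantomSpec(seed=22))


@pytest.fixture(scope="session")
def separable_bundles():
    """Low-noise phantom pair: a cleanly separable classification task."""
    return (
        make_bundle(PhantomSpec(seed=31, noise_sd=0.02)),
        make_bundle(PhantomSpec(seed=32, noise_sd=0.02)),
    )


def truth_trained_model(bundle, seed_labels=1, seed_forest=2, n_trees=50):
    """Forest trained on truth-labeled preprocessed spectra of a bundle."""
    processed, tissue, _ = preprocess_cube(bundle.cube)
    ts = assemble_training_set(
        processed,
        bundle.tissue_mask_true & tissue,
        bundle.collagen_mask_true & tissue,
        seed=seed_labels,
    )
    return train(ts, n_trees=n_trees, seed=seed_forest), ts


@pytest.fixture(scope="session")
def default_model(default_bundle):
    """Forest trained on the default bundle with truth labels."""
    return truth_trained_model(default_bundle)


@pytest.fixture(scope="session")
def separable_model(separable_bundles):
    return truth_trained_model(separable_bundles[0])


def grating(angle_deg, shape=(64, 64), freq=0.15):
    """Sinusoidal grating whose ridges (fibers) run along ``angle_deg``.

    Angle is counterclockwise from the +x (column) axis with y upward.
    """
    r, c = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    x, y = c, -r
    a = np.deg2rad(angle_deg)
    nx, ny = -np.sin(a), np.cos(a)
    return 0.5 + 0.5 * np.cos(2 * np.pi * freq * (x * nx + y * ny))
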