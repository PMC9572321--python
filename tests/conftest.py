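import dataclasses

import numpy as np
import pandas as pd
import pytest

import ripegrade as rg
from ripegrade.pipeline import preprocess_dataset


@pytest.fixture(scope="session")
def profiles():
    return rg.default_profiles()


@pytest.fixture(scope="session")
def small_scene():
    """A reduced scene for fast per-test generation."""
    return rg.SceneConfig(image_size=(60, 80), fruit_axes=(13, 19), seed=7)


@pytest.fixture(scope="session")
def zero_noise_profile():
    return rg.ClassColorProfile(
        stage=rg.RipenessStage.RIPE, mean_rgb=(0.0, 1.0, 0.0),
        rgb_covariance=np.zeros((3, 3)))


@pytest.fixture(scope="session")
def zero_noise_scene():
    return rg.SceneConfig(image_size=(60, 80), fruit_axes=(13, 19),
                          shadow_strength=0.0, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def tiny_dataset(profiles, small_scene):
    """6 images/class at reduced size, segmented, with the feature table."""
    ds = rg.generate_dataset(profiles, per_class=6, scene=small_scene)
    masked = preprocess_dataset(ds, rg.PreprocessConfig())
    table = rg.extract_table(masked, ds.labels, ds.image_ids)
    return ds, masked, table


@pytest.fixture(scope="session")
def blob_table():
    """Well-separated 4-class Gaussian blobs as a small feature table."""
    rng = np.random.default_rng(42)
    centers = np.array([[0, 0], [6, 0], [0, 6], [6, 6]], dtype=float)
    rows, labels = [], []
    for c, cls in zip(centers, rg.CLASS_ORDER):
        rows.append(c + rng.normal(0, 0.5, size=(20, 2)))
        labels += [cls] * 20
    X = np.vstack(rows)
    table = pd.DataFrame(X, columns=["f0", "f1"])
    table["class"] = labels
    return table
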