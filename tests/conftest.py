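"""Shared fixtures: small deterministic images, ratings and beta simulations."""

import numpy as np
import pandas as pd
import pytest

from matdecode.grouping import form_groups, mean_ratings
from matdecode.synthetic import (BetaSimulation, default_config,
                                 generate_ratings, generate_textures,
                                 image_driving_statistics)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cfg():
    """Reduced-size study: 24 images, 4 raters, 3 participants, small volume."""
    return default_config(
        n_images=24, image_size=128, n_raters=4, n_participants=3,
        volume_shape=(16, 18, 16), roi_radius=3, signal_voxels=10,
        seed=99,
    )


@pytest.fixture(scope="session")
def small_images(small_cfg):
    return generate_textures(small_cfg)


@pytest.fixture(scope="session")
def small_ratings(small_cfg, small_images):
    return generate_ratings(small_images, small_cfg)


@pytest.fixture(scope="session")
def small_stats(small_cfg, small_images):
    stats = image_driving_statistics(small_images)
    return stats.set_axis(pd.Index(small_cfg.image_ids(), name="image_id"))


@pytest.fixture(scope="session")
def small_groups(small_cfg, small_ratings):
    means = mean_ratings(small_ratings, "roughness")
    return form_groups(means, 0.25, property="roughness")


@pytest.fixture(scope="session")
def small_sim(small_cfg, small_stats):
    return BetaSimulation(small_stats[["hf_energy", "contrast"]], small_cfg)
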