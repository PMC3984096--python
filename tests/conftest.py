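import numpy as np
import pytest

from somroi import (
    EffectRegion,
    PhantomConfig,
    SomConfig,
    build_feature_space,
    difference_image,
    generate_cohort,
    tissue_mask,
    train,
)
from somroi.som3d import PhaseSchedule
from somroi.voxelstats import StatImages


@pytest.fixture(scope="session")
def small_config():
    """16^3 grid, 5 subjects per class, one GM sphere of effect 0.3."""
    return PhantomConfig(
        grid_shape=(16, 16, 16),
        n_per_class=5,
        effect_regions=(EffectRegion(center=(8.0, 8.0, 8.0), radius=3.0, effect_size=0.3, tissue="GM"),),
        baseline_smoothness=3.0,
        noise_sd=0.02,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def noiseless_cohort(small_config):
    from dataclasses import replace

    return generate_cohort(replace(small_config, noise_sd=0.0))


@pytest.fixture(scope="session")
def small_feature_space(small_cohort):
    gm, _ = small_cohort
    stats = StatImages.from_stack(gm)
    c1, c2 = stats.class_order
    D = difference_image(stats.means[c1], stats.means[c2])
    mask = tissue_mask(gm, p_min=0.05)
    return build_feature_space(D, mask)


@pytest.fixture(scope="session")
def fast_som_config():
    """Small map + short schedule for unit tests."""
    return SomConfig(
        lattice_shape=(4, 4, 2),
        phase1=PhaseSchedule(alpha0=0.1, sigma0=None, epochs=3, sigma_floor=1.0),
        phase2=PhaseSchedule(alpha0=0.01, sigma0=None, epochs=5, sigma_floor=0.5),
        subsample=512,
        seed=7,
    )


@pytest.fixture(scope="session")
def trained_som(small_feature_space, fast_som_config):
    return train(small_feature_space, fast_som_config)
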