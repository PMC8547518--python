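import numpy as np
import pytest

import morphattn as m
from morphattn.io import sampleset_from_cohort_subject

#: cheap training settings for desk-scale cohorts; the library defaults keep
#: the full-scale recipe (lr 6e-6, 300 epochs) which is far too slow to learn
#: anything on a 40-subject synthetic cohort
DESK_CONFIG = dict(learning_rate=1e-2, weight_decay=0.0, max_epochs=150)


def cohort_networks(cohort, n_points=64):
    return [m.build_network(sampleset_from_cohort_subject(s), n_points=n_points)
            for s in cohort.subjects]


@pytest.fixture(scope="session")
def small_effect_cohort():
    """12-subject cohort, 8 regions, strong mean shift in regions {1, 4}."""
    effect = m.EffectSpec(effect_regions=frozenset({1, 4}), mean_shift=0.1)
    return m.simulate_cohort(6, 6, 8, effect, voxels_per_region=100, seed=7)


@pytest.fixture(scope="session")
def small_networks(small_effect_cohort):
    return cohort_networks(small_effect_cohort)


@pytest.fixture(scope="session")
def tiny_trained_model(small_networks, small_effect_cohort):
    cfg = m.ModelConfig(d_embed=8, max_epochs=40, seed=3, **{
        k: v for k, v in DESK_CONFIG.items() if k != "max_epochs"})
    return m.train_model(small_networks, small_effect_cohort.labels, cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
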