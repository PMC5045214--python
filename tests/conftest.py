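import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neuromkl import (CohortConfig, extract_features, make_atlas,
                      simulate_cohort)
from neuromkl.synthetic import demo_effects

settings.register_profile(
    "default", derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture(scope="session")
def atlas30():
    """Desk-scale atlas used by the pipeline-level checks."""
    return make_atlas((12, 12, 12), 30)


@pytest.fixture(scope="session")
def separable_setup(atlas30):
    """A 21/28 cohort with strong (d=3) effects in all four channels,
    plus its extracted feature tables and the injected effect list."""
    effects = demo_effects(atlas30, effect_size=3.0, per_channel=2)
    config = CohortConfig(n_patients=21, n_controls=28, n_timepoints=150,
                          volume_shape=(12, 12, 12), n_rois=30,
                          effects=effects, seed=11)
    cohort = simulate_cohort(config)
    import warnings

    with warnings.catch_warnings():
        # boundary ROIs without interior voxels may drop from ReHo
        warnings.simplefilter("ignore")
        tables = extract_features(cohort)
    return tables, effects


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
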