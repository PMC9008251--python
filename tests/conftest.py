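import numpy as np
import pytest

import synadapt as sa


@pytest.fixture(scope="session")
def clean_cohort():
    """Three nearly noise-free users with well-separated gestures.

    No user variability, no drift, no mis-executions: every stage of the
    pipeline should behave ideally on it.
    """
    cfg = sa.SynthConfig(
        users=3,
        gestures=4,
        channels=16,
        repetitions=3,
        burst_ms=1500.0,
        rest_ms=1500.0,
        user_gain_sd=0.0,
        rep_gain_sd=0.0,
        burst_mod_amp=0.0,
        bad_rep_rate=0.0,
        drift_rate=0.0,
        noise_sd=0.001,
        master_seed=42,
    )
    return cfg, sa.generate_cohort(cfg)


@pytest.fixture(scope="session")
def clean_features(clean_cohort):
    _, recs = clean_cohort
    return [sa.extract_features(r, seed=1000 + i) for i, r in enumerate(recs)]


@pytest.fixture(scope="session")
def small_trainset(clean_features):
    train = [f for feats in clean_features[1:] for f in feats]
    return sa.trainset_from_features(train)


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
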