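import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config():
    """Tiny but complete cohort: every grade populated, fast to simulate."""
    from cordssep import CohortConfig

    return CohortConfig(counts=(3, 3, 4, 3), seed=7)


@pytest.fixture(scope="session")
def small_truths(small_config):
    from cordssep import generate_cohort

    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def default_cohort_features():
    """Full-size cohort (10, 35, 57, 34), seed 1: truths plus right-side
    extracted features through the noisy epoch path. Session-scoped because
    several statistical tests reuse it."""
    from cordssep import CohortConfig, extract_features, generate_cohort, generate_epoch_set
    from cordssep.cohort import epoch_seed

    cfg = CohortConfig(seed=1)
    truths = generate_cohort(cfg)
    feats = []
    for truth in truths:
        epochs = generate_epoch_set(
            truth,
            cfg.protocol,
            epoch_seed(cfg.seed, truth, "right"),
            side="right",
            noise_sd_uv=cfg.noise_sd_uv,
        )
        feats.append(extract_features(epochs, stft_params=cfg.stft, region=cfg.region))
    return cfg, truths, feats


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
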