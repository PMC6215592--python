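import numpy as np
import pytest

from transurv import ProgressionConfig, SurvivalData, generate_single_endpoint


@pytest.fixture
def toy_uncensored():
    """20 fully observed records with distinct times."""
    rng = np.random.default_rng(42)
    t = np.sort(rng.uniform(1, 50, 20))
    X = rng.standard_normal((20, 3))
    return SurvivalData(X, t, np.ones(20, dtype=int))


@pytest.fixture
def censored_cohort():
    """Moderate synthetic right-censored cohort (n=120, ~20% events)."""
    cfg = ProgressionConfig(
        n=120,
        d=6,
        beta=np.array([0.8, -0.5, 0.4, 0.3, 0.0, 0.0]),
        progression_beta=np.zeros(6),
        censor_rate_target=0.8,
        seed=7,
    )
    data, _ = generate_single_endpoint(cfg)
    return data


def random_censored(rng, n, d=2, censor_frac=0.4, allow_score_ties=False):
    """Small random fixture for brute-force oracles."""
    t = rng.uniform(1, 20, n).round(1 if allow_score_ties else 6)
    e = (rng.uniform(size=n) > censor_frac).astype(int)
    if e.sum() == 0:
        e[rng.integers(n)] = 1
    X = rng.standard_normal((n, d))
    return SurvivalData(X, t, e)
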