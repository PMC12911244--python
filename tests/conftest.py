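import numpy as np
import pytest

from btsdesign import ArmOutcome, BetaParams, beta_update


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def vague():
    return BetaParams(1, 1)


@pytest.fixture
def case_study_posteriors(vague):
    """Vague priors updated with the expected 6-month PFS counts of a
    40-per-arm trial at anticipated rates 0.55 vs 0.40."""
    post_a = beta_update(vague, ArmOutcome(40, 22))
    post_b = beta_update(vague, ArmOutcome(40, 16))
    return post_a, post_b


def mc_difference_oracle(rng, post_a, post_b, d, n_draws=1_000_000):
    """Brute-force sampling estimate of (PCorr, PAmb) with binomial SEs.

    Independent of the quadrature path: draws from the two Beta
    posteriors and counts events on the difference.
    """
    diff = rng.beta(post_a.alpha, post_a.beta, n_draws) - rng.beta(
        post_b.alpha, post_b.beta, n_draws
    )
    p_corr = float((diff > d).mean())
    p_amb = float(((diff >= -d) & (diff <= d)).mean())
    se = lambda p: float(np.sqrt(max(p * (1 - p), 1e-12) / n_draws))
    return (p_corr, se(p_corr)), (p_amb, se(p_amb))
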