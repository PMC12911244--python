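"""Posterior updating, the selection probabilities and the decision rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from btsdesign import (
    ArmOutcome,
    BetaParams,
    Decision,
    DesignParams,
    ValidationError,
    beta_update,
    decide,
    lambda_star,
    lambda_star_fast,
    lambda_star_grid,
    prob_ambiguous,
    prob_correct,
)
from conftest import mc_difference_oracle

betas = st.floats(min_value=0.5, max_value=60.0)
ds = st.floats(min_value=0.0, max_value=0.9)


class TestBetaUpdate:
    @pytest.mark.parametrize(
        "prior, outcome, expected",
        [
            (BetaParams(1, 1), ArmOutcome(10, 5), BetaParams(6, 6)),
            (BetaParams(1, 1), ArmOutcome(40, 22), BetaParams(23, 19)),
            (BetaParams(2, 8), ArmOutcome(0, 0), BetaParams(2, 8)),
        ],
    )
    def test_conjugate_update(self, prior, outcome, expected):
        assert beta_update(prior, outcome) == expected

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValidationError):
            ArmOutcome(10, 11)
        with pytest.raises(ValidationError):
            ArmOutcome(10, -1)
        with pytest.raises(ValidationError):
            BetaParams(0, 1)


class TestSelectionProbabilities:
    def test_symmetric_uniform_posteriors_split_evenly(self, vague):
        assert prob_correct(vague, vague, 0.0) == pytest.approx(0.5, abs=1e-8)

    def test_difference_cannot_exceed_one(self, vague):
        assert prob_correct(BetaParams(5, 2), BetaParams(2, 5), 1.0) == 0.0

    def test_zero_margin_ambiguity_vanishes(self, vague):
        assert prob_ambiguous(BetaParams(3, 4), BetaParams(4, 3), 0.0) == 0.0

    def test_full_margin_ambiguity_saturates(self):
        assert prob_ambiguous(BetaParams(3, 4), BetaParams(4, 3), 1.0) == pytest.approx(
            1.0, abs=1e-8
        )

    def test_case_study_against_sampling_oracle(self, rng, case_study_posteriors):
        post_a, post_b = case_study_posteriors
        (mc_corr, se_c), (mc_amb, se_a) = mc_difference_oracle(rng, post_a, post_b, 0.10)
        assert prob_correct(post_a, post_b, 0.10) == pytest.approx(mc_corr, abs=3 * se_c)
        assert prob_ambiguous(post_a, post_b, 0.10) == pytest.approx(mc_amb, abs=3 * se_a)

    def test_quadrature_matches_sampling_oracle_on_random_configs(self, rng):
        """Twenty random (alpha, beta, d) configurations: quadrature agrees
        with a 10^6-draw Monte-Carlo estimate within 3 binomial SEs."""
        for _ in range(20):
            post_a = BetaParams(*rng.uniform(0.5, 50, 2))
            post_b = BetaParams(*rng.uniform(0.5, 50, 2))
            d = float(rng.uniform(0.0, 0.5))
            (mc_corr, se_c), (mc_amb, se_a) = mc_difference_oracle(
                rng, post_a, post_b, d
            )
            assert prob_correct(post_a, post_b, d) == pytest.approx(
                mc_corr, abs=max(3 * se_c, 5e-6)
            )
            assert prob_ambiguous(post_a, post_b, d) == pytest.approx(
                mc_amb, abs=max(3 * se_a, 5e-6)
            )

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a1=betas, b1=betas, a2=betas, b2=betas, d=ds)
    def test_conservation_partition(self, a1, b1, a2, b2, d):
        """Correct, ambiguous and wrong selection partition the support."""
        post_a, post_b = BetaParams(a1, b1), BetaParams(a2, b2)
        total = (
            prob_correct(post_a, post_b, d)
            + prob_ambiguous(post_a, post_b, d)
            + prob_correct(post_b, post_a, d)
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(a1=betas, b1=betas, a2=betas, b2=betas, d=ds)
    def test_arm_swap_symmetry(self, a1, b1, a2, b2, d):
        post_a, post_b = BetaParams(a1, b1), BetaParams(a2, b2)
        assert prob_ambiguous(post_a, post_b, d) == pytest.approx(
            prob_ambiguous(post_b, post_a, d), abs=1e-7
        )

    def test_monotone_in_margin(self):
        post_a, post_b = BetaParams(12, 9), BetaParams(7, 13)
        dd = np.linspace(0.0, 0.8, 9)
        corr = [prob_correct(post_a, post_b, d) for d in dd]
        amb = [prob_ambiguous(post_a, post_b, d) for d in dd]
        assert all(x >= y - 1e-10 for x, y in zip(corr, corr[1:]))
        assert all(y >= x - 1e-10 for x, y in zip(amb, amb[1:]))


class TestLambdaStar:
    def test_rho_zero_reduces_to_p_correct(self, case_study_posteriors):
        post_a, post_b = case_study_posteriors
        crit = lambda_star(post_a, post_b, DesignParams(d=0.10, rho=0.0))
        assert crit.lambda_star == crit.p_correct

    def test_case_study_value(self, case_study_posteriors):
        post_a, post_b = case_study_posteriors
        crit = lambda_star(post_a, post_b, DesignParams(d=0.10, rho=0.5))
        assert round(crit.lambda_star, 2) == 0.82

    def test_rho_one_equals_noninferiority_probability(self, rng, case_study_posteriors):
        """With full ambiguity weight the rule is Pr(pi_A - pi_B >= -d)."""
        post_a, post_b = case_study_posteriors
        crit = lambda_star(post_a, post_b, DesignParams(d=0.10, rho=1.0))
        diff = rng.beta(post_a.alpha, post_a.beta, 1_000_000) - rng.beta(
            post_b.alpha, post_b.beta, 1_000_000
        )
        mc = (diff >= -0.10).mean()
        se = np.sqrt(mc * (1 - mc) / 1_000_000)
        assert crit.lambda_star == pytest.approx(mc, abs=3 * se)

    def test_monotone_in_rho(self, case_study_posteriors):
        post_a, post_b = case_study_posteriors
        lams = [
            lambda_star(post_a, post_b, DesignParams(d=0.10, rho=r)).lambda_star
            for r in np.linspace(0, 1, 6)
        ]
        assert all(y > x for x, y in zip(lams, lams[1:]))  # PAmb* > 0 here

    def test_fast_path_matches_quadrature(self, rng):
        for _ in range(10):
            post_a = BetaParams(*rng.uniform(0.5, 80, 2))
            post_b = BetaParams(*rng.uniform(0.5, 80, 2))
            params = DesignParams(d=float(rng.uniform(0, 0.5)), rho=0.5)
            ref = lambda_star(post_a, post_b, params)
            fast = lambda_star_fast(post_a, post_b, params)
            assert fast.p_correct == pytest.approx(ref.p_correct, abs=1e-9)
            assert fast.p_ambiguous == pytest.approx(ref.p_ambiguous, abs=1e-9)

    def test_grid_matches_quadrature(self, rng, vague):
        n = 25
        grid = lambda_star_grid(vague, vague, n, 0.08, 0.5)
        for _ in range(5):
            xa, xb = (int(v) for v in rng.integers(0, n + 1, 2))
            ref = lambda_star(
                beta_update(vague, ArmOutcome(n, xa)),
                beta_update(vague, ArmOutcome(n, xb)),
                DesignParams(d=0.08, rho=0.5),
            )
            assert grid[xa, xb] == pytest.approx(ref.lambda_star, abs=1e-9)


class TestDecide:
    @pytest.mark.parametrize(
        "lam, theta, expected",
        [
            (0.95, 0.90, Decision.SELECT_A),
            (0.90, 0.90, Decision.CONSIDER_OTHER_FACTORS),  # strict inequality
            (0.82, 0.90, Decision.CONSIDER_OTHER_FACTORS),
        ],
    )
    def test_threshold_rule(self, lam, theta, expected):
        from btsdesign import PosteriorCriteria

        crit = PosteriorCriteria(
            p_correct=lam, p_ambiguous=0.0, lambda_star=lam, rho=0.5
        )
        assert decide(crit, theta) is expected

    def test_serialisation_keys(self, case_study_posteriors):
        post_a, post_b = case_study_posteriors
        crit = lambda_star(post_a, post_b, DesignParams(d=0.10, rho=0.5))
        payload = crit.to_dict(theta=0.90)
        assert set(payload) == {"p_correct", "p_ambiguous", "lambda_star", "decision"}
        assert payload["decision"] == "CONSIDER_OTHER_FACTORS"

    def test_design_params_validation(self):
        for bad in (dict(d=1.0), dict(d=-0.1), dict(d=0.1, rho=1.5),
                    dict(d=0.1, theta=1.0)):
            with pytest.raises(ValidationError):
                DesignParams(**bad)
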