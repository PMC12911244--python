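"""Core domain types for the two-arm Bayesian selection design.

Each arm's response rate carries a conjugate Beta prior; observed (or
hypothesised) trial counts update it to a Beta posterior.  The decision
constants — the clinically meaningful difference ``d``, the ambiguity
weight ``rho`` and the selection threshold ``theta`` — are bundled in
:class:`DesignParams` and shared by every downstream criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Any


class ValidationError(ValueError):
    """An input violates a domain constraint (e.g. successes > n)."""


class QuadratureError(RuntimeError):
    """Numerical integration failed to reach the requested tolerance.

    Attributes
    ----------
    achieved : float
        The absolute error estimate actually achieved.
    requested : float
        The tolerance that was asked for.
    """

    def __init__(self, achieved: float, requested: float):
        self.achieved = achieved
        self.requested = requested
        super().__init__(
            f"quadrature reached absolute error {achieved:.3e} "
            f"(requested {requested:.3e})"
        )


class Decision(str, Enum):
    """Outcome of the threshold rule: select arm A outright, or fall back
    to secondary factors (toxicity, cost, ease of administration, ...)."""

    SELECT_A = "SELECT_A"
    CONSIDER_OTHER_FACTORS = "CONSIDER_OTHER_FACTORS"


@dataclass(frozen=True)
class BetaParams:
    """A Beta(alpha, beta) prior or posterior for an arm's response rate.

    ``alpha`` counts pseudo-responders, ``beta`` pseudo-non-responders;
    ``alpha + beta`` is the prior effective sample size.
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValidationError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValidationError(f"beta must be positive and finite, got {self.beta}")

    @property
    def ess(self) -> float:
        """Prior effective sample size alpha + beta."""
        return self.alpha + self.beta

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)


@dataclass(frozen=True)
class ArmOutcome:
    """Observed (or hypothesised) responders out of ``n`` patients on one arm."""

    n: int
    successes: int

    def __post_init__(self) -> None:
        if int(self.n) != self.n or self.n < 0:
            raise ValidationError(f"n must be a non-negative integer, got {self.n}")
        if int(self.successes) != self.successes or self.successes < 0:
            raise ValidationError(
                f"successes must be a non-negative integer, got {self.successes}"
            )
        if self.successes > self.n:
            raise ValidationError(
                f"successes ({self.successes}) cannot exceed n ({self.n})"
            )


@dataclass(frozen=True)
class DesignParams:
    """Decision constants shared by all selection criteria.

    Parameters
    ----------
    d : float
        Clinically meaningful difference in response rates, in [0, 1).
    rho : float
        Weight in [0, 1] placed on the ambiguous zone; the chance that a
        statistically ambiguous trial still selects the proper arm
        (0.5 = fair coin, 1 = non-inferiority-style rule).
    theta : float
        Selection threshold in (0, 1); arm A is chosen outright when
        lambda* strictly exceeds it.
    """

    d: float
    rho: float = 0.5
    theta: float = 0.90

    def __post_init__(self) -> None:
        if not 0 <= self.d < 1:
            raise ValidationError(f"d must lie in [0, 1), got {self.d}")
        if not 0 <= self.rho <= 1:
            raise ValidationError(f"rho must lie in [0, 1], got {self.rho}")
        if not 0 < self.theta < 1:
            raise ValidationError(f"theta must lie in (0, 1), got {self.theta}")


@dataclass(frozen=True)
class PosteriorCriteria:
    """The three posterior selection criteria for a pair of arm posteriors.

    ``lambda_star = p_correct + rho * p_ambiguous`` for the ``rho`` recorded.
    """

    p_correct: float
    p_ambiguous: float
    lambda_star: float
    rho: float

    def decide(self, theta: float) -> Decision:
        """Threshold rule: select A outright iff lambda* > theta (strict)."""
        if not 0 < theta < 1:
            raise ValidationError(f"theta must lie in (0, 1), got {theta}")
        if self.lambda_star > theta:
            return Decision.SELECT_A
        return Decision.CONSIDER_OTHER_FACTORS

    def to_dict(self, theta: float | None = None) -> dict[str, Any]:
        out: dict[str, Any] = {
            "p_correct": self.p_correct,
            "p_ambiguous": self.p_ambiguous,
            "lambda_star": self.lambda_star,
        }
        if theta is not None:
            out["decision"] = self.decide(theta).value
        return out
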