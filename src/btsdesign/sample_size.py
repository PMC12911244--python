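"""Sample-size determination for the two-arm Bayesian selection design.

Two per-group sample-size algorithms are provided, both assuming equal
allocation (``n_A = n_B = n``) and anticipated response rates
``pi_tilde_A > pi_tilde_B``:

* **Deterministic (lambda*)** — plug in the expected responder counts
  ``x_tilde_i = ceil(n * pi_tilde_i)``, update the priors and compute
  ``lambda*`` directly.  Because the ceiling makes the criterion a
  sawtooth in ``n`` at small sizes, the search returns the smallest
  ``n`` from which ``lambda* > gamma*`` holds for *every* larger
  candidate in the search range, not the first crossing.

* **Simulation-based (lambda-bar)** — treat the responder counts as
  random, ``x_i ~ Binomial(n, pi_tilde_i)``, and average ``lambda*``
  over ``m`` replicates.  The resulting curve is smooth and monotone in
  practice, so a plain first crossing of ``gamma*`` defines the minimum
  size.  An exact-enumeration backend computes the same expectation
  ``E[lambda*]`` as a finite double sum over the ``(n+1)^2`` outcome
  pairs and serves as the deterministic arbiter for borderline
  Monte-Carlo cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy.stats import binom

from . import posterior
from .types import ArmOutcome, BetaParams, DesignParams, ValidationError

__all__ = [
    "SampleSizeRequest",
    "SampleSizeResult",
    "expected_responders",
    "lambda_at_n",
    "find_nmin_deterministic",
    "lambda_bar_mc",
    "lambda_bar_exact",
    "find_nmin_simulated",
]

Method = Literal["deterministic", "simulated", "exact"]


@dataclass(frozen=True)
class SampleSizeRequest:
    """Inputs of a per-group sample-size search.

    ``pi_tilde_a`` must exceed ``pi_tilde_b``: arm A is, by convention,
    the treatment anticipated to be better.  ``m`` is the number of
    binomial replicates per candidate ``n`` in the Monte-Carlo backend.
    """

    pi_tilde_a: float
    pi_tilde_b: float
    d: float
    rho: float = 0.5
    gamma_star: float = 0.90
    prior_a: BetaParams = field(default_factory=lambda: BetaParams(1, 1))
    prior_b: BetaParams = field(default_factory=lambda: BetaParams(1, 1))
    n_min_search: int = 2
    n_max_search: int = 1000
    m: int = 100_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pi_tilde_a", "pi_tilde_b"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if self.pi_tilde_a <= self.pi_tilde_b:
            raise ValidationError(
                "pi_tilde_a must exceed pi_tilde_b (arm A is the better treatment); "
                f"got {self.pi_tilde_a} <= {self.pi_tilde_b}"
            )
        if not 0 <= self.d < 1:
            raise ValidationError(f"d must lie in [0, 1), got {self.d}")
        if not 0 <= self.rho <= 1:
            raise ValidationError(f"rho must lie in [0, 1], got {self.rho}")
        if not 0 < self.gamma_star < 1:
            raise ValidationError(f"gamma_star must lie in (0, 1), got {self.gamma_star}")
        if self.n_min_search < 1 or self.n_min_search > self.n_max_search:
            raise ValidationError(
                f"need 1 <= n_min_search <= n_max_search, got "
                f"[{self.n_min_search}, {self.n_max_search}]"
            )
        if self.m < 1:
            raise ValidationError(f"m must be >= 1, got {self.m}")

    @property
    def design(self) -> DesignParams:
        # theta is irrelevant at the design stage; gamma_star plays its role
        return DesignParams(d=self.d, rho=self.rho)


@dataclass(frozen=True)
class SampleSizeResult:
    """Outcome of a search: minimal per-group ``n`` (or None if the
    criterion never stabilises above the threshold in the search range)
    plus the full (n, criterion) trace behind it."""

    n_min: Optional[int]
    trace: tuple[tuple[int, float], ...]
    method: Method
    gamma_star: float

    @property
    def found(self) -> bool:
        return self.n_min is not None

    @property
    def max_criterion(self) -> float:
        """Largest criterion value seen; reported when nothing crossed."""
        return max(v for _, v in self.trace)

    def to_frame(self) -> pd.DataFrame:
        """Trace as a tidy table (the data behind the design curves)."""
        df = pd.DataFrame(self.trace, columns=["n", "criterion"])
        df["method"] = self.method
        df["gamma_star"] = self.gamma_star
        return df


def expected_responders(n: int, pi_tilde: float) -> int:
    """Expected responder count: ``n * pi_tilde`` rounded to the nearest
    integer, with exact halves rounded up (7.5 responders become 8).

    A small guard snaps the product to an integer when it is within
    1e-9 of one, so exact products like 10 * 0.1 are not perturbed by
    floating-point noise.
    """
    if not 0 <= pi_tilde <= 1:
        raise ValidationError(f"pi_tilde must lie in [0, 1], got {pi_tilde}")
    v = n * pi_tilde
    nearest = round(v)
    if abs(v - nearest) < 1e-9:
        return int(nearest)
    return int(np.floor(v + 0.5))


def lambda_at_n(request: SampleSizeRequest, n: int) -> float:
    """Deterministic-method criterion at one candidate ``n``."""
    post_a = posterior.beta_update(
        request.prior_a, ArmOutcome(n, expected_responders(n, request.pi_tilde_a))
    )
    post_b = posterior.beta_update(
        request.prior_b, ArmOutcome(n, expected_responders(n, request.pi_tilde_b))
    )
    return posterior.lambda_star_fast(post_a, post_b, request.design).lambda_star


def find_nmin_deterministic(request: SampleSizeRequest) -> SampleSizeResult:
    """Smallest ``n`` from which ``lambda* > gamma*`` holds through the
    whole remaining search range (look-ahead rule; see module docstring)."""
    ns = range(request.n_min_search, request.n_max_search + 1)
    values = [lambda_at_n(request, n) for n in ns]
    n_min: Optional[int] = None
    ok_from_here = True
    for n, v in zip(reversed(ns), reversed(values)):
        ok_from_here = ok_from_here and (v > request.gamma_star)
        if ok_from_here:
            n_min = n
    return SampleSizeResult(
        n_min=n_min,
        trace=tuple(zip(ns, values)),
        method="deterministic",
        gamma_star=request.gamma_star,
    )


def _grid(request: SampleSizeRequest, n: int) -> np.ndarray:
    return posterior.lambda_star_grid(
        request.prior_a, request.prior_b, n, request.d, request.rho
    )


def _rng_for_candidate(seed: int, n: int) -> np.random.Generator:
    # independent substream per candidate n: traces are invariant to the
    # search range actually scanned
    return np.random.default_rng(np.random.SeedSequence([seed, n]))


def lambda_bar_mc(request: SampleSizeRequest, n: int) -> tuple[float, float]:
    """Monte-Carlo mean of ``lambda*`` over binomial trial outcomes.

    Returns ``(mean, mc_se)``.  Reproducible given ``(seed, n, m)``;
    the ``(x_A, x_B)`` grid of ``lambda*`` is computed once, so each
    replicate is a table lookup.
    """
    grid = _grid(request, n)
    rng = _rng_for_candidate(request.seed, n)
    xa = rng.binomial(n, request.pi_tilde_a, size=request.m)
    xb = rng.binomial(n, request.pi_tilde_b, size=request.m)
    values = grid[xa, xb]
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(request.m)) if request.m > 1 else 0.0
    return mean, se


def lambda_bar_exact(request: SampleSizeRequest, n: int) -> float:
    """Exact ``E[lambda*]`` by enumerating all ``(n+1)^2`` outcome pairs."""
    grid = _grid(request, n)
    x = np.arange(n + 1)
    pa = binom.pmf(x, n, request.pi_tilde_a)
    pb = binom.pmf(x, n, request.pi_tilde_b)
    return float(pa @ grid @ pb)


def find_nmin_simulated(
    request: SampleSizeRequest, *, backend: Literal["mc", "exact"] = "mc"
) -> SampleSizeResult:
    """Smallest ``n`` whose ``lambda-bar`` strictly exceeds ``gamma*``.

    First crossing, no look-ahead: the binomial averaging smooths the
    sawtooth the deterministic rule has to guard against.  With
    ``backend="exact"`` the scan is fully deterministic.
    """
    trace: list[tuple[int, float]] = []
    n_min: Optional[int] = None
    for n in range(request.n_min_search, request.n_max_search + 1):
        if backend == "exact":
            value = lambda_bar_exact(request, n)
        else:
            value, _ = lambda_bar_mc(request, n)
        trace.append((n, value))
        if value > request.gamma_star:
            n_min = n
            break
    return SampleSizeResult(
        n_min=n_min,
        trace=tuple(trace),
        method="exact" if backend == "exact" else "simulated",
        gamma_star=request.gamma_star,
    )
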