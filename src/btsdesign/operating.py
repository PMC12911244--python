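"""Operating characteristics of the Bayesian selection rule.

A designed trial is replayed many times under assumed *true* response
rates: each replicate draws per-arm responder counts ``S_i ~
Binomial(n, pi_i)``, updates the priors, computes ``lambda*`` and applies
the threshold rule.  Two summaries are reported:

* ``xi`` — the proportion of replicates with ``lambda* > theta``, i.e.
  trials that select arm A outright on efficacy.  Desirable to be high
  when A truly is better.
* ``nu = 1 - xi`` — the proportion falling through to the
  secondary-factor decision.  Desirable to be high when the arms truly
  do not differ.

Both a seeded Monte-Carlo backend and an exact enumeration backend (the
finite expectation over the ``(n+1)^2`` outcome grid) are provided; they
share one memoised ``lambda*`` grid, so the exact backend is the
deterministic limit of the Monte-Carlo one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from .posterior import lambda_star_grid
from .types import BetaParams, ValidationError

__all__ = ["OCScenario", "OCResult", "oc_simulate", "oc_exact", "oc_grid"]


@dataclass(frozen=True)
class OCScenario:
    """One evaluation scenario: true rates, priors and decision constants."""

    true_pi_a: float
    true_pi_b: float
    n_per_arm: int
    d: float
    rho: float = 0.5
    theta: float = 0.90
    prior_a: BetaParams = field(default_factory=lambda: BetaParams(1, 1))
    prior_b: BetaParams = field(default_factory=lambda: BetaParams(1, 1))
    k: int = 100_000
    seed: int = 0
    scenario_id: str = ""

    def __post_init__(self) -> None:
        for name in ("true_pi_a", "true_pi_b"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")
        if not 0 <= self.d < 1:
            raise ValidationError(f"d must lie in [0, 1), got {self.d}")
        if not 0 <= self.rho <= 1:
            raise ValidationError(f"rho must lie in [0, 1], got {self.rho}")
        if not 0 < self.theta < 1:
            raise ValidationError(f"theta must lie in (0, 1), got {self.theta}")
        if int(self.n_per_arm) != self.n_per_arm or self.n_per_arm < 1:
            raise ValidationError(
                f"n_per_arm must be a positive integer, got {self.n_per_arm}"
            )
        if self.k < 1:
            raise ValidationError(f"k must be >= 1, got {self.k}")


@dataclass(frozen=True)
class OCResult:
    """Estimated operating characteristics.

    ``nu`` is always ``1 - xi``; ``mc_se`` is the binomial standard error
    ``sqrt(xi (1 - xi) / k)`` for the Monte-Carlo backend and 0 for the
    exact one.
    """

    xi: float
    nu: float
    mc_se: float
    k_used: int
    backend: Literal["mc", "exact"]


def _selection_grid(scenario: OCScenario) -> np.ndarray:
    """Indicator of outright selection, 1(lambda*(S_A, S_B) > theta),
    over the full outcome grid."""
    grid = lambda_star_grid(
        scenario.prior_a,
        scenario.prior_b,
        scenario.n_per_arm,
        scenario.d,
        scenario.rho,
    )
    return grid > scenario.theta


def oc_simulate(scenario: OCScenario) -> OCResult:
    """Seeded Monte-Carlo estimate of ``xi`` from ``k`` simulated trials."""
    select = _selection_grid(scenario)
    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, scenario.n_per_arm]))
    s_a = rng.binomial(scenario.n_per_arm, scenario.true_pi_a, size=scenario.k)
    s_b = rng.binomial(scenario.n_per_arm, scenario.true_pi_b, size=scenario.k)
    xi = float(select[s_a, s_b].mean())
    se = float(np.sqrt(xi * (1.0 - xi) / scenario.k))
    return OCResult(xi=xi, nu=1.0 - xi, mc_se=se, k_used=scenario.k, backend="mc")


def oc_exact(scenario: OCScenario) -> OCResult:
    """Exact ``xi``: the probability mass of the selection region under
    the joint binomial law of the two responder counts."""
    select = _selection_grid(scenario)
    x = np.arange(scenario.n_per_arm + 1)
    pmf_a = binom.pmf(x, scenario.n_per_arm, scenario.true_pi_a)
    pmf_b = binom.pmf(x, scenario.n_per_arm, scenario.true_pi_b)
    xi = float(pmf_a @ select @ pmf_b)
    return OCResult(xi=xi, nu=1.0 - xi, mc_se=0.0, k_used=0, backend="exact")


def oc_grid(
    scenarios: Sequence[OCScenario] | Iterable[OCScenario],
    *,
    backend: Literal["mc", "exact"] = "exact",
) -> pd.DataFrame:
    """Evaluate a list of scenarios into a tidy table.

    Per-scenario failures are recorded in the ``error`` column and the
    grid continues; successful rows leave it empty.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValidationError("scenario list must be non-empty")
    rows = []
    run = oc_exact if backend == "exact" else oc_simulate
    for i, sc in enumerate(scenarios):
        row = {
            "scenario_id": sc.scenario_id or str(i),
            "true_pi_a": sc.true_pi_a,
            "true_pi_b": sc.true_pi_b,
            "alpha_a": sc.prior_a.alpha,
            "beta_a": sc.prior_a.beta,
            "alpha_b": sc.prior_b.alpha,
            "beta_b": sc.prior_b.beta,
            "n": sc.n_per_arm,
            "xi_pct": np.nan,
            "nu_pct": np.nan,
            "mc_se": np.nan,
            "backend": backend,
            "error": "",
        }
        try:
            res = run(sc)
            row.update(
                xi_pct=100.0 * res.xi, nu_pct=100.0 * res.nu, mc_se=res.mc_se
            )
        except Exception as exc:  # pragma: no cover - defensive per-row guard
            row["error"] = f"{type(exc).__name__}: {exc}"
        rows.append(row)
    return pd.DataFrame(rows)
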