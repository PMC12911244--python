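# Methods

## Model

Two treatments A and B are compared on a binary endpoint in a
randomised phase II trial. Response rates `π_A`, `π_B` carry independent
conjugate priors `π_i ~ Beta(α_i, β_i)`; `α_i + β_i` is the prior
effective sample size (pseudo-patients) and `α_i/(α_i+β_i)` the prior
mean. Observed counts update each arm to
`Beta(α_i + S_i, β_i + n_i − S_i)`. By convention arm A denotes the
(anticipated or truly) better treatment; all "correct selection"
language refers to picking A.

The three decision quantities are posterior probabilities of the rate
difference `Δ = π_A − π_B` under the independent posteriors:
`PCorr* = Pr(Δ > d)`, `PAmb* = Pr(|Δ| ≤ d)`, and
`λ* = PCorr* + ρ·PAmb*`. The trial selects A outright iff `λ* > θ`
(strict). `Δ` is continuous, so the open/closed boundaries of the
ambiguity interval carry no probability and `PCorr* + PAmb* +
Pr(Δ < −d) = 1` exactly; this partition is asserted in the tests.

## Numerics

Every quantity reduces to integrals of the form
`Pr(Δ > c) = ∫₀¹ S_A(t + c) f_B(t) dt`, where `S_A` is the Beta survival
function of arm A *clamped to [0, 1]* (`S_A(x) = 1` for `x < 0`, `0` for
`x > 1`) and `f_B` the Beta density of arm B. `PAmb*` is the difference
`Pr(Δ > −d) − Pr(Δ > d)`, clipped into `[0, 1]`.

Two evaluation routes share this formulation:

- **Adaptive quadrature** (`prob_correct`, `prob_ambiguous`,
  `lambda_star`): scipy's QUADPACK with absolute tolerance 1e-8; the
  integration interval is restricted to where the integrand is
  non-constant and the constant head `F_B(max(0, −c))` added in closed
  form. If the integrator cannot certify the tolerance a
  `QuadratureError` carrying the achieved error is raised.
- **Composite Gauss–Legendre** (`lambda_star_fast`,
  `lambda_star_grid`): fixed 16-point panels with breaks at the
  clamping kinks `d` and `1 − d`, and panel density growing like
  `4·sqrt(total count)` so that posterior densities of width
  `~1/sqrt(n)` are fully resolved. This route is vectorised over whole
  `(x_A, x_B)` outcome grids: the criterion factorises as
  `λ* = (1−ρ)·Pr(Δ > d) + ρ·Pr(Δ > −d)`, so a full grid is two matrix
  products over shared nodes. Agreement with the quadrature route is
  asserted to 1e-9 in the unit tests; in practice the two agree to
  machine precision.

Only `(n+1)²` distinct posterior pairs exist for an equal-allocation
trial of size `n`, so simulation backends memoise `λ*` on that grid and
reduce each replicate to a table lookup. This is what keeps
100,000-replicate runs at seconds of CPU.

Degenerate inputs: `d = 0` gives `PAmb* = 0` exactly (computed, not
special-cased, in the quadrature route); `d = 1` is accepted by the bare
probability functions (returning the degenerate 0/1 values) but rejected
by `DesignParams`, which requires `d ∈ [0, 1)` for an actual design.

## Sample-size determination

Both algorithms assume equal allocation `n_A = n_B = n` and anticipated
rates `π̃_A > π̃_B`; candidates run over `[n_min_search, n_max_search]`
(defaults 2–1000, `NOT_FOUND` sentinel beyond).

**Deterministic (λ\*)**. Expected responder counts enter as
`x̃_i = round(n · π̃_i)` — nearest integer, exact halves up (7.5 → 8).
Rounding *up* unconditionally was considered and rejected: it biases
`x̃_B` (small rates) upward by nearly a full responder on average, which
systematically understates the design's λ\* sawtooth and shifts the
stabilised crossing; nearest-integer rounding keeps both arms' plug-in
counts centred on `n·π̃_i` and reproduces the reference sample-size
table. Because the ceiling/rounding makes λ\* a sawtooth in `n` at small
sizes, the search returns the smallest `n` from which `λ* > γ*` holds at
*every* larger candidate in the range (look-ahead), not the first
crossing — a first-crossing rule would return spuriously small `n` at
sawtooth peaks. The sawtooth has inflated as well as deflated teeth, so
a handful of reference cells that sit within ±0.015 of the threshold are
sensitive to the integration details and can land one tooth away; the
four cells checked in the acceptance tests reproduce exactly.

**Simulation-based (λ̄\*)**. Treats the counts as random,
`x_i* ~ Binomial(n, π̃_i)`, and averages λ\* over `m` replicates
(default 100,000). The averaging smooths the sawtooth, so the minimum
size is the plain first `n` whose λ̄\* strictly exceeds `γ*` — a
deliberate asymmetry with the deterministic rule. The Monte-Carlo
backend draws from a per-candidate substream
(`SeedSequence([seed, n])`), making traces invariant to the search
range; the exact backend computes the same expectation as the finite
double sum `Σ BinPmf(x_A)·BinPmf(x_B)·λ*(x_A, x_B)` and is the
deterministic arbiter for borderline cells. Near thresholds the exact
λ̄\* can sit within one Monte-Carlo standard error of `γ*` (e.g.
+2×10⁻⁴ at one reference configuration), where any finite-`m` estimate
flips the crossing by ±1; results at such cells should be quoted with
that caveat.

Raising `γ*` never shrinks the trial, and `ρ > 0` never enlarges it
(λ\* is non-decreasing in ρ); both monotonicities are asserted over
grids in the tests.

## Operating characteristics

Under assumed true rates the designed trial is replayed: `S_i ~
Binomial(n, π_i)`, posteriors updated, `λ*` thresholded at `θ` (strict,
default 0.90). `ξ` is the probability of outright selection of A and
`ν = 1 − ξ` the probability of falling to secondary factors. The exact
backend integrates the selection indicator against the joint binomial
pmf (zero Monte-Carlo error, seed-invariant); the Monte-Carlo backend
(`k` replicates, default 100,000, binomial standard error
`sqrt(ξ(1−ξ)/k)`) exists to mirror the simulation procedure the design
would be validated with in practice. Both share one λ\* grid, so MC
converges to the exact value by construction.

These replays emulate idealised trials: independent binomial sampling
at fixed true rates, no drift, no drop-out, no interim looks, equal
allocation, all patients evaluable. Passing tests certify the decision
machinery, not robustness of a real trial to violations of those
assumptions.

## Frequentist comparator

The Sargent–Goldberg comparator works on observed rates:
`PCorr = Pr(p̂_A − p̂_B > d)` (strict), `PAmb = Pr(|p̂_A − p̂_B| ≤ d)`
(inclusive), `λ = PCorr + ρ·PAmb`, computed by exact enumeration of the
`(n+1)²` joint binomial table. The strict/inclusive convention is the
one under which the comparator agrees with the reference case-study
value; the alternative (`≥`, `<`) convention shifts λ by the whole
diagonal band's mass and was rejected. Comparisons are done in integer
arithmetic (`x_A − x_B` vs `d·n`, with `d·n` snapped to an integer when
within 1e-9) so boundary outcomes are never misclassified.

The required sample size scans candidates where `d·n` is an integer
(default; opt-out available). Rationale: on the integer lattice a
fractional `d·n` strictly inflates λ — the ambiguity band
`|x_A − x_B| ≤ d·n` reaches only `floor(d·n)` and the superiority
margin effectively becomes `ceil(d·n)/n > d` — so λ is sawtoothed in
`n` with its honest values (testing the stated margin exactly) at the
local minima where `d·n` is integral. Restricting the search to those
candidates makes the returned `n` conservative and interpretable at the
stated `d`; the threshold comparison is `≥` with the same look-ahead
stabilisation as the Bayesian deterministic search.

## Defaults and problem sizes

| Parameter | Default | Meaning |
|---|---|---|
| `d` | — (required) | clinically meaningful rate difference |
| `ρ` | 0.5 | ambiguous-zone weight (fair coin) |
| `θ` | 0.90 | post-trial selection threshold |
| `γ*` | 0.90 | design-stage threshold for λ\*/λ̄\* |
| `m` | 100,000 | replicates per candidate `n` (λ̄\* MC backend) |
| `k` | 100,000 | replicates per scenario (operating characteristics) |
| search range | 2–1000 | per-group candidates (SG: 2–500) |

The test suite scales searches down (ranges ≤ 250, MC sizes 5,000–
20,000 where an exact backend provides the reference) — chosen as the
smallest sizes at which the checks are statistically decisive; the
acceptance script uses the full defaults with exact backends.

## Known limitations

- Two arms only; no multi-arm or multi-subgroup selection.
- No interim monitoring or sequential decision rules.
- Equal allocation in the design searches; unequal `n_i` is supported
  only in post-trial analysis.
- Conjugate Beta priors only — no mixture/robust priors and no dynamic
  prior-data-conflict discounting; the operating-characteristics module
  quantifies (but does not correct) the damage an over-confident wrong
  prior does.
- The reference sample-size tables this package reproduces contain a
  few threshold-borderline cells that cannot be pinned down to ±1
  without knowing the original integration and search details; the
  exact-enumeration backends here are the package's source of truth.
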