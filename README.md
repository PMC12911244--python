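# btsdesign

Bayesian treatment-selection design for two-arm randomised phase II
trials with a binary endpoint (tumour response, or progression-free
survival at a landmark time).

## Who this is for

Phase II selection ("pick-the-winner") trials randomise patients between
two candidate regimens and ask which one should advance to a
confirmatory phase III trial. Frequentist selection designs in the
Sargent–Goldberg (SG) tradition decide on the *observed* response-rate
difference and require sample sizes that are often infeasible in early
development. This package implements a Bayesian analogue: decisions are
made on posterior probabilities, prior information can be folded in to
shrink the trial, and every design quantity is computable exactly.

## The model and the decision rule

Each arm's response rate carries a conjugate Beta prior,
`π_i ~ Beta(α_i, β_i)`; observing `S_i` responders among `n_i` patients
gives the posterior `π_i | S_i, n_i ~ Beta(α_i + S_i, β_i + n_i − S_i)`.
With `d` the clinically meaningful difference and arm A the nominally
better treatment, the design computes

- `PCorr* = Pr(π_A − π_B > d | data)` — correct selection,
- `PAmb*  = Pr(−d ≤ π_A − π_B ≤ d | data)` — the ambiguous zone where
  secondary factors (toxicity, cost, ease of administration) decide,
- `λ* = PCorr* + ρ·PAmb*`, `ρ ∈ [0, 1]` the chance an ambiguous trial
  still picks the proper arm (`ρ = ½` ≙ fair coin; `ρ = 1` gives a
  non-inferiority-style rule `λ* = Pr(π_A − π_B ≥ −d)`).

Arm A is selected outright when `λ* > θ` (typically `θ = 0.90`);
otherwise the choice falls to secondary factors.

Two per-group sample-size algorithms support planning: a deterministic
search that plugs in the expected responder counts at each candidate
`n`, and a smoother simulation-based search on
`λ̄* = E[λ*]` under `x_i ~ Binomial(n, π̃_i)` (with an exact-enumeration
backend). Operating characteristics `ξ` (outright-selection rate) and
`ν = 1 − ξ` are computed by simulation or exact enumeration, and the
exact-binomial SG comparator is included for side-by-side comparison.

## Worked example

A phase II RCT in HER2-positive metastatic breast cancer compared
pertuzumab–trastuzumab plus metronomic chemotherapy against
pertuzumab–trastuzumab alone, 40 patients per arm, with 6-month
progression-free survival as the endpoint (anticipated rates 0.55 vs
0.40, `d = 0.10`). Evaluating the design at the expected counts
(22/40 vs 16/40) with vague Beta(1, 1) priors:

```
$ btsdesign evaluate --n-a 40 --s-a 22 --n-b 40 --s-b 16 \
      --d 0.10 --rho 0.5 --theta 0.90
PCorr* = 0.66
PAmb*  = 0.33
lambda* = 0.82  (rho = 0.5)
decision (theta = 0.9): CONSIDER_OTHER_FACTORS
```

The posterior gives a 66% chance that the metronomic arm is better by
more than 10 points and a 33% chance the arms are within 10 points of
each other; `λ* = 0.82` does not clear `θ = 0.90`, so the rule defers to
secondary factors. The frequentist SG comparator at the same
configuration gives `λ = 0.81` and a required size of 40 per group at
the 0.80 threshold:

```
$ btsdesign sg --pi-a 0.55 --pi-b 0.40 --d 0.10 --rho 0.5 --n 40 --threshold 0.80
SG (frequentist), n = 40: PCorr = 0.63, PAmb = 0.36, lambda = 0.81
Bayesian (vague priors, expected counts): lambda* = 0.82
SG required n per group at lambda >= 0.8: 40
```

Designing a new trial at anticipated rates 0.30 vs 0.15
(`d = 0.05, ρ = 0.5, γ* = 0.90`) by the deterministic search:

```
$ btsdesign design --pi-a 0.30 --pi-b 0.15 --d 0.05 --rho 0.5 --gamma 0.90 --n-max 120
deterministic: n per group = 39 (lambda* > 0.9 at the accepted n)
```

The library API mirrors the CLI (`find_nmin_deterministic`,
`find_nmin_simulated`, `oc_exact`, `sg_lambda`, ...); every subcommand
accepts a flat YAML/JSON config file, and runs that write outputs also
write a `run_record.json` (inputs, seed, version) from which they can be
replayed exactly.

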