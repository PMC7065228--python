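# Methods

## Model and statistics

Patients on arm *i* (0 = control, 1..D = treatments) respond
`X ~ N(μ_i, σ_i²)`; the target parameters are `δ_i = μ_i − μ_0` with
elementary hypotheses `H_0i: δ_i = 0` tested one-sided against `δ_i > 0`.
Randomization is treatment:control at ratio `λ_i`, so at analysis *j* with
cumulative control size `n_0j` arm *i* has `n_ij = round(λ_i n_0j)` patients
(nearest integer, half away from zero — the design only fixes the ratios).

The cumulative score statistic is `W_ij = δ̂_ij ℐ_ij` with
`ℐ_ij = n_0j Λ_i`, `Λ_i = (σ_0² + σ_i²/λ_i)⁻¹`. Across stages each arm's
score behaves as Brownian motion (independent increments,
`cov(W_i1, W_i2) = ℐ_i1`); across arms at one stage
`cov(W_ij, W_hj) = Λ_i Λ_h σ_0² n_0j`. The cross-arm covariance is of
*product* form, so the whole array is one common factor (the control arm)
plus independent arm-specific noise, with loadings `a_i = σ_0 √Λ_i`
(`a_i² = 1/2` for equal allocation and variances). This single fact drives
all the numerics (below).

When variances are unknown they are estimated per arm from cumulative
(or, for stage-wise p-values, incremental) data with divisor (n−1), pooled
only within each (arm, control) pair through
`ℐ̂_ij = (σ̂_0j²/n_0j + σ̂_ij²/n_ij)⁻¹`; no pooling across treatment arms.

## Testing procedures

**Cumulative MAMS (closed, adaptive).** Every nonempty subset I of arms is
an intersection hypothesis with its own max-statistic boundaries for
‖I‖ comparisons, solved stage by stage from the error-spending equations
(Lan–DeMets O'Brien–Fleming shape
`f(t) = 2 − 2Φ(Φ⁻¹(1−α/2)/√t)` by default). H_0I is rejected when
`max_{g∈I} w_gj` crosses; rejections are sticky across stages (closed
testing); H_0i falls when every I ∋ i has fallen; the trial stops at the
first elementary rejection. After the stage-1 adaptation — dropping arms
below the selection threshold and changing the stage-2 control increment
while preserving allocation — the later boundary of each live intersection
is recomputed so that the conditional crossing probability given the stage-1
scores, now over the selected subset `I_S` with the new increment
information, equals the original design's conditional error over the full
I. For three-stage designs with adaptation at look 1, the stage-2 and
stage-3 conditional exit probabilities are preserved separately — the
natural stage-wise extension of the two-stage conditional-error equation
(the appendix-level multistage equation was not available; this construction
is validated by the FWER property suite, including the exact-α
known-variance check). Boundary recomputation targets below 1e-14 are
treated as unspendable (infinite boundary); an empty `I_S` makes the
intersection unrejectable after adaptation, which is conservative and never
affects selected arms.

With estimated variances, monitoring uses estimated information plus the
small-sample map `b* = √ℐ̂ · T⁻¹_d(Φ(b/√ℐ̂))` with `d_ij = n_0j + n_ij − 1`
(degrees of freedom taken exactly as the design convention states;
sensitivity to −1 versus −2 is far below Monte-Carlo resolution). This keeps
the FWER at or slightly below α; with known variances the procedure
exhausts α exactly.

**Stage-wise MAMS (inverse-normal combination).** Stage-wise adjusted
p-values `p_I(j)` come from incremental data only: exact Dunnett
(`p = P(max T ≥ max t)` for central multivariate t with
`df = n_0(j) + Σ n_i(j) − ‖I‖ − 1` and allocation-determined correlation) or
Bonferroni/Simes over marginal pooled-variance one-sided t-tests. Stage-1
components always keep the full subset; stage ≥ 2 components restrict to
`I_S` (empty `I_S` ⇒ p = 1). Combination uses prespecified weights
`h_j = √(planned information share)` with interim monitoring of the
renormalized partial sums; p-values are clipped to `[1e-15, 1−1e-15]` before
the quantile transform. The monitoring boundaries are the classical two-arm
(k = 1) boundaries: the cross-arm multiplicity lives entirely in the
p-values.

## Numerical methods

* **One-factor orthants.** `P(all Z_i ≤ u_i)` integrates the product of
  conditional normal CDFs over the common factor with a 96-node
  probabilists' Gauss–Hermite rule (spectral accuracy). The multivariate-t
  analogue adds an exact probability-transformed 64-node Gauss–Legendre
  layer over the chi scale mixture (absolute error ≲ 5e-6).
* **Multistage path probabilities.** Non-crossing probabilities over J ≤ 3
  stages integrate over the per-stage common factors; conditionally on
  those, each arm contributes an exact bivariate-normal rectangle
  (vectorized port of Genz's angular formula, ~1e-14 for |ρ| ≤ 0.925, dense
  conditioning quadrature beyond). J = 2 probabilities are exact up to the
  outer Gauss–Hermite rule; J = 3 adds one truncated inner layer
  (observed error ~3e-5 against an independent Genz integration, entering
  only the cached three-stage boundary constants). A single arm (k = 1)
  drops the factor entirely and is exact.
* **Boundary and conditional-error roots.** Brent's method, bracket [0, 12]
  on the Wald scale (expanding bracket for conditional errors), xtol 1e-9;
  the conditional-error preservation residual is checked below 1e-6 in every
  adapted replicate.
* **Analytic two-dose power.** The cumulative-test integral is a 3-D tensor
  Gauss–Hermite quadrature (64 nodes/dim) over the stage-1 score law with
  exact inner rectangles. The combination-test integral collapses to one
  dimension because its acceptance region depends on stage-1 data only
  through the maximum, whose density is closed-form; the data-dependent
  inner limit `F₍₂₎⁻¹(g)` is inverted on a 6001-point monotone grid.
  Node-doubling agreement is ≲ 2e-8; both surfaces agree with 10⁶-replicate
  simulations within Monte-Carlo error.
* **Determinism.** No Monte-Carlo enters boundaries, p-values or power
  integrals; results are bit-for-bit reproducible. All simulation
  randomness flows from a single seed through spawned `SeedSequence`
  substreams, so per-replicate results are independent of evaluation order.

## Simulation engine and study conditions

The simulator draws patient-level normal responses stage by stage and
applies every requested procedure to the same replicate (common random
numbers), which sharpens power-difference estimates considerably. The
reference design is the SOCRATES-REDUCED reconstruction: three dose arms
versus placebo, σ = 0.52 on all arms, detectable effect δ = 0.187, 97
patients per arm (the 80%-power single-stage Dunnett size at one-sided
α = 0.025), equally spaced analyses (control sizes 49/97 for two stages,
32/65/97 for three — the paper-level description fixes only "equally spaced",
so the error spending uses the realized fractions, e.g. 49/97 = 0.505).
The protocol: at the first interim, stop for efficacy if the closed test
rejects any arm; otherwise drop every arm whose interim effect estimate
falls below the selection threshold (0 by default) and reallocate the
dropped arms' unspent enrollment over the continuing arms (control
included) proportionally to allocation, preserving the planned total via
largest-remainder integer rounding (a no-reallocation variant shrinks the
total instead). If every arm is dropped the trial ends at the interim with
no rejection. Estimated-variance monitoring with the t-scale adjustment is
the default; known-variance mode exists for exact-α studies. Operating
characteristics report global power (≥ 1 elementary rejection), FWER
(≥ 1 true-null rejection), per-arm rates, per-stage stopping frequencies
and average enrolled sample size, each with binomial or replicate-level
standard errors. The bundled acceptance script uses 5000 replicates for
two-stage and 4000 for three-stage configurations (standard error ≤ 0.007
on a rate), chosen as the package's default precision/runtime balance;
tests use 2000 with correspondingly widened tolerances.

The generator emulates exactly the idealized trial the procedures assume:
normal responses, instantaneous outcomes (no accrual lag between enrollment
and response), no dropout, missingness or covariate drift, and a selection
rule driven solely by the interim effect estimates. Passing tests therefore
certify the statistical machinery under its own assumptions, not robustness
to the operational realities of a running trial.

## Design choices on genuinely open points

* **Sticky subset rejections.** An intersection rejected at an earlier look
  stays rejected, as closed testing prescribes; the step-down structure can
  therefore reject elementary hypotheses that plain max-statistic
  monitoring would miss. Global (trial-level) decisions coincide with
  monitoring when there is no adaptation — the consonance property — and
  the simulated difference in per-arm rates is below 1e-4.
* **Three-stage weights** for the inverse-normal combination follow the
  planned incremental information shares (1/√3 each for equally spaced
  looks), with renormalized partial sums at interims — the canonical
  independent-increments construction.
* **Degrees of freedom.** The multivariate-t p-value uses
  `n_0(j) + Σ n_i(j) − ‖I‖ − 1` on incremental data; the boundary t-map
  uses `n_0j + n_ij − 1` on cumulative data. Both follow the stated
  conventions verbatim.
* **Conditional errors on the interim-estimate scale.** At adaptation time
  the information entering the conditional-error equation uses the stage-1
  variance estimates (the final analysis then re-estimates); with known
  variances the identity `b* = b` holds exactly when nothing changes, and
  dropping arms without reallocation can only lower the boundary
  (`b*_I2 ≤ b_I2`), both verified as invariants.

## Known limitations

* Path probabilities (hence boundary construction) are implemented for
  J ≤ 3 stages; adaptation is supported at the first interim only, which
  covers the seamless phase 2–3 use case.
* Point estimation and confidence intervals after adaptation are out of
  scope; the package reports decisions and operating characteristics.
* Binomial and time-to-event endpoints are not implemented; the normal
  score theory applies to them only asymptotically.
* Published boundary constants for the four-comparison design place the
  stage-1 exit probability about 2% (relative) away from the exact LD-OBF
  increment that the corresponding two-arm constants pin down; this
  package solves the spending equations exactly, so its stage-1
  four-comparison constant differs from the commonly quoted one in the
  third decimal (3.3510 vs 3.3453) while the stage-2 constants agree.
* Simulated power differences between the cumulative and stage-wise
  procedures under rarely-triggering dropping rules are smaller here
  (plateau ≈ 8–9 percentage points at δ = (0, 0, 0.187)) than some
  published figures; the no-selection limit of this package's gap is
  confirmed by exact exit-probability integration (cumulative, 0.5602) and
  an independent vectorized simulation of the combination test (0.4729).
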