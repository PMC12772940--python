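# Methods

## Model and inference

`retrodose` infers recent dosing behaviour from one steady-state drug
concentration. The object of inference is a scenario ω: a bitstring over the
last `n` scheduled doses, ordered most-recent-first (the first digit is the
dose immediately preceding the sample; `1` = taken, `0` = missed). All `2^n`
scenarios are enumerated; nonadherence patterns other than wholly missed
doses (delays, partial doses, double doses) are out of scope.

The posterior over scenarios at an observed concentration C is Bayes' rule
with a Monte Carlo likelihood:

- **Prior** `P(ω)`: `equal` (each scenario `2^-n`, the maximum-uncertainty
  default), `per_dose` (independent Bernoulli adherence with probability p
  per dose, `P(ω) = p^(#1) (1-p)^(#0)` — this is how a single "adherence
  percentage" is mapped onto `2^n` scenarios), or `custom` (arbitrary
  nonnegative weights, normalized).
- **Likelihood** `P(C | ω)`: simulated. Virtual patients are drawn from the
  population-PK model (lognormal between-subject variability around the
  covariate-adjusted typical parameters, optionally correlated), each one's
  concentration at the sampling time is computed under the scenario-edited
  dose history, and residual unexplained variability (RUV) is applied as
  `C_obs = C_pred (1 + ε_prop) + ε_add` with independent zero-mean normal
  errors, negatives truncated to zero.
- **Posterior, thresholds, labels**: the posterior is evaluated along a
  shared concentration grid. Crossings between adjacent most-probable
  scenarios are the discrimination thresholds; the induced partition of the
  concentration axis is the clinical readout. Retrodiction is *complete*
  when every scenario's posterior curve peaks at ≥ 80% somewhere, *none*
  when at most one does, and *partial* otherwise.

## Pharmacokinetic engine

Structural models: one-compartment oral (first-order absorption, "Bateman"
term), one-compartment bolus, and two-compartment oral (tri-exponential with
absorption). All are linear, so a dose history is evaluated by superposition
of single-dose closed forms; a missed dose is an amount-0 event, which keeps
the schedule index aligned with the scenario digits. Internal units are
fixed: hours, mg, L, mg/L.

Covariate relations compose multiplicatively on their target parameter in
spec order, restricted to four closed forms: power `(x/ref)^θ` (allometry,
renal function), proportional `1 + θ·x` (with `x` a 0/1 flag for
comedication/sex/formulation tags), linear, and exponential. This covers the
relations reported for the common antiseizure-medication models while
keeping specs statically checkable.

Steady state is reached by an explicit run-in of `ceil(20·t½/τ) + 1` doses
(`t½` the terminal half-life, β-phase for two-compartment models) so the
same code path serves all structures; twenty half-lives leave a relative
accumulation residual near 1e-6, comfortably inside the 1e-4
trough-convergence requirement (ten half-lives would not: their residual is
~1e-3). The analytic steady-state formula is retained only as a test oracle.
Sampling is the trough immediately before the next scheduled dose, plus an
optional offset. An independent ODE integration of the same compartment
system (`scipy.integrate.solve_ivp`, LSODA at rtol 1e-10) ships as a
cross-check; the closed form agrees with it to better than 1e-6 relative.

Numerical guards: specs whose absorption constant collides with the
elimination constant (relative gap < 1e-6) are rejected; gaps below 1e-4 are
nudged by 1e-6 relative to keep the Bateman denominator well-conditioned.
The same nudge is applied per-individual at evaluation time, since sampled
parameters can collide even when the typical values do not.

## Monte Carlo defaults and random numbers

Defaults are the idealized study conditions: 40,000 virtual patients per
scenario; RUV minimized at 0.01 mg/L additive and 0.1% proportional (both
user-adjustable — raising them is also the remedy when an observed value
falls outside every scenario's simulated support); trough sampling.

Common random numbers are on by default: the identical eta and epsilon draws
are reused across scenarios, so paired differences, thresholds and sweeps
reflect the scenario or factor rather than sampling noise. With CRN off,
per-scenario streams are derived from the root seed and the scenario's
canonical index, making results independent of simulation order. Factor
sweeps reuse the root seed across levels for the same reason.

## Density estimation

The conditional density is a Gaussian KDE on log-transformed samples
(Silverman bandwidth), back-transformed (`f(c) = g(ln c)/c`) — concentrations
are positive and right-skewed, and the log-scale KDE makes the estimate
exactly equivariant under dose rescaling. Samples below a near-zero floor of
`max(2·ruv_add, 1e-3)` mg/L are pooled into an explicit probability mass
(fully-missed scenarios with tiny RUV concentrate there), represented as a
uniform density on `[0, floor)` when a density value is needed. A fully
degenerate distribution (no variability at all) becomes an exact point mass;
at such an atom the posterior is computed from atoms alone, which makes the
no-variability case exact rather than bandwidth-limited.

The posterior grid is 512 linearly spaced points from 0 to 1.1× the largest
sample over all scenarios; crossings are interpolated linearly between
bracketing grid points, so grid density is not accuracy-limiting.

Posteriors are only meaningful where the observation could plausibly have
arisen: grid points whose marginal `P(C)` falls below 1e-6 of its peak
(roughly beyond ±5σ of every scenario cluster) are excluded from threshold
finding and label classification, and the Monte Carlo stability statistic
(`curves_sup_distance`) compares curves over the central 95% of the marginal
mass. Outside those regions the KDE is supported by a handful of extreme
samples and no estimator — at any practical simulation size — is
reproducible; at 40,000 vs 80,000 virtual patients the curves agree to
within 0.02 sup-norm on the supported core.

Argmax ties (indistinguishable scenarios) are resolved toward the lower
bitstring, i.e. toward flagging nonadherence — the conservative direction
for an adherence screen — and are flagged as degenerate.

## Synthetic fixtures

The fixture generator emits validated specs in four regimes (a seed applies
a 3% lognormal jitter so distinct seeds give distinct same-regime models):

- `fast_clearance` — stylized rapidly eliminated drug (t½ ≈ 2.3 h at q12h):
  the concentration signal of doses more than one interval back falls below
  the residual-error floor, the regime where retrodiction degrades fastest
  (n=1 complete, n≥2 none).
- `slow_clearance` — phenobarbital-like accumulating drug (t½ ≈ 100 h) with
  modest variability (ω ≈ 0.1): consecutive missed doses stay resolvable the
  longest (partial retrodiction through n=3). Because its trough tracks
  average exposure (`kτ ≈ 0.08`), it is also the regime where a pure
  elimination-clearance multiplier θ moves the thresholds by ≈ 1/θ (the
  residual deviation grows like `(θ-1)·kτ`, so the reciprocal rule is exact
  only in this asymptotic regime; a bioavailability-confounded interaction,
  which scales CL/F and V/F jointly, shifts thresholds by exactly 1/θ at any
  θ).
- `with_covariates` — mid-range elimination (t½ ≈ 9 h) with allometric
  weight scaling, an eGFR power relation on clearance, and enzyme
  inducer/inhibitor comedication tags (CL ×3 and ×0.55, the magnitude class
  of the classic carbamazepine/valproate interactions with lamotrigine). At
  q12h it yields four fully distinct most-probable windows over the last two
  doses.
- `two_cpt` — two-compartment oral model with correlated CL–V variability.

What the fixtures deliberately do not emulate: real drugs' absolute
parameter values and covariate coefficients, inter-occasion variability,
nonlinear (saturable) elimination, autoinduction, and mechanistic
extended-release absorption (a longer dosing interval stands in for the
formulation effect). Passing tests therefore demonstrate the correctness and
internal consistency of the inference machinery under realistic regimes, not
drug-specific threshold values — those require transcribing a published
population-PK model into a spec file.

## Known limitations

- The likelihood is simulation-based; thresholds inherit Monte Carlo noise
  (at the default sizes, well under the 2% used in the equivariance checks).
- KDE tails decay at bandwidth scale, so posteriors in deep inter-scenario
  gaps lean on tail shape; thresholds between *adjacent* scenarios, the
  quantity of clinical interest, sit in well-sampled territory.
- The per-dose prior treats doses as independent; correlated adherence
  (e.g. weekend patterns) must be expressed through custom priors.
- Retrodiction labels near the 80% cutoff can flip with simulation seed when
  a scenario's peak posterior sits within Monte Carlo noise of the cutoff.
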