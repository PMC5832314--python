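# Methods

This note documents the models and numerical choices behind `omtrace`, the
parameters that matter, what the synthetic generator does and does not
emulate, and the known limitations.

## Data model

A *composite sample* is one row of the tracer table: a source sample
(labelled with one of four OM categories — farmyard manures/slurries,
damaged road verges, decaying instream vegetation, human septic waste) or a
channel-bed sediment sample, with a complete vector of tracer values.
Analytical repeat runs are stored as replicate rows and collapsed to their
arithmetic mean before any statistics (`average_replicates`). Missing
tracer cells are an error, not an imputation target: the mixing model needs
complete vectors, and there is no defensible imputation model for tracers.

Group summaries are computed per subcatchment and per category: median,
Qn scale, CV (= sd/mean, sources only), min, max. A tracer whose group
mean is zero (possible for δ values) has an undefined CV; its within-source
weighting falls back to a neutral 1 with a logged warning rather than a
shifted-scale CV, which would silently inflate or deflate its influence.
Values are sorted before summarising so summaries are exactly invariant to
record order.

## Bracket test

A tracer passes when the closed sediment interval [min, max] lies inside
the pooled envelope of **all** source samples of all categories, with
boundary equality counting as a pass. The pooled axis-aligned box was
chosen over per-category range intersections or a convex-hull
(mixing-polygon) test: it is the standard operationalisation of "sediment
inside the source ranges", it is deterministic, and it is monotone (adding
source samples can only turn fail into pass). Multivariate hull tests are
out of scope.

## Signature selection

*Classification %* is the resubstitution (training-set) accuracy of a
linear discriminant fit on the named tracers, in percent. Resubstitution is
the convention behind reported "% classified correctly" figures in this
workflow; leave-one-out is available (`method="loo"`) but is not the
default. The discriminant is linear with pooled covariance; singular
scatter matrices are ridged with 1e-8 × trace(T)/p.

*GA-DFA.* Binary chromosomes over the candidate tracers; fitness is the
Wilks' Λ of the subset, with subsets invalid unless every member passes the
stepwise-entry partial-F test at p ≤ 0.05 (F = ((n−g−q+1)/(g−1)) ·
(Λ_reduced/Λ_full − 1) with df (g−1, n−g−q+1)). Invalid subsets are
penalised by 2 + (number of failing members) so the search can descend
toward validity. Defaults: 200 restarts ("repeat iterations" read as
restarts), population 50, 40 generations, uniform crossover 0.7, per-bit
mutation 0.02, elitism 2, tournament selection of size 3, initial bit
probability min(0.5, 5/n) since real signatures are small. All evaluated
subsets are cached and ranked by (classification % desc, Λ asc, size asc,
lexicographic) — deterministic tie-breaking — and the top three distinct
subsets are returned. For ≤ 4 candidates the search is exhaustive.

*KW-H / PCA.* Tracers are ranked by Kruskal–Wallis H (among those with
p < α = 0.05) or by maximum absolute loading across the first two principal
components of the standardised source matrix. The signature grows from the
top of the ranking until classification % stops increasing, with a minimum
size of 3 (capped at the ranking length): the published workflow shows
5-tracer signatures but states no stopping rule, so this one is a
documented choice. Constant (zero-variance) tracers are excluded from PCA
with a warning; a constant tracer scores H = 0, p = 1.

*TDW.* W_i = %_i / min(%), rounded to 2 decimals; the weakest tracer
carries exactly 1.00. Percentages must lie in (0, 100].

## Unmixing

The printed form of the objective places SV_si inside the product with
S_si, which would distort the predicted mixture concentration and break
mass conservation. The default implemented form keeps the predicted
concentration Ĉ_i = Σ_s P_s S_si and applies SV as a multiplicative weight
on each squared relative error, collapsed to tracer level as the
proportion-weighted mean SV̄_i(P) = Σ_s P_s SV_si. The literal printed
placement is available behind `literal=True` / `--literal-eq3` for fidelity
comparisons.

GOF = 1 − (1/n) Σ_i |C_i − Ĉ_i|/|C_i|, unweighted and clamped below at 0.
It deliberately shares no weights with the objective: it is a separate
absolute-mean-relative-error acceptance criterion, and dividing by n
(unweighted mean) is the simplest reading.

The solver is SLSQP with box bounds [0, 1] and the equality constraint
Σp = 1, run from each simplex vertex plus the centroid (m+1 deterministic
starts; `starts="centroid"` runs one start for Monte Carlo loops). The best
local solution is clipped to [0, 1], renormalised, and validated to lie on
the simplex within 1e-9. Tracers with C_i = 0 are rejected with a message
directing their exclusion (the relative error is undefined). Near-identical
source categories (relative difference < 1e-9 on every tracer) make the
optimum non-unique; the solution is still a valid simplex point but is
flagged `degenerate` and a warning logged.

## Qn scale

Qn = 2.2219 · c(n) · {|x_i − x_j| : i < j}_(k), with k = C(h, 2),
h = ⌊n/2⌋ + 1, and the Rousseeuw–Croux finite-sample factors
(0.399, 0.994, 0.512, 0.844, 0.611, 0.857, 0.669, 0.872 for n = 2…9;
n/(n+1.4) odd, n/(n+3.8) even above that). Up to n = 600 the pairwise
differences are materialised and partitioned; beyond that the k-th order
statistic is located by bisection over the difference value with an
O(n log n) two-pointer count, to 1e-15 relative precision. A constant
sample returns exactly 0.

## Monte Carlo uncertainty

Deviate medians are drawn per tracer from Normal(median, Qn) truncated to
the observed [min, max] — Qn is normal-consistent, and truncation enforces
physical plausibility. Latin hypercube stratification places exactly one
draw in each of n equal-probability strata per tracer, with stratum order
shuffled independently per tracer, so marginal coverage is exact while
tracers remain uncorrelated. One joint row perturbs all source and
sediment medians simultaneously (sediment perturbation can be frozen with
`perturb_sediment=False`). Qn = 0 yields a degenerate constant column.

Solutions with GOF strictly above the threshold (default 0.85) are
accepted until `n_accept` (default 5,000) are collected or the draw budget
(default 100 × n_accept) is exhausted; zero acceptances raise an error
reporting the best GOF seen. Accepted proportions are binned into 100
intervals over [0, 1] — 0.01 resolution, matching two-decimal reporting —
and R = Σ v_i F_i computed from midvalues and relative frequencies.

Per-signature results are combined with α_k = (mean accepted GOF_k) ×
(overall classification %_k), the simplest symmetric product consistent
with "combining goodness-of-fit and discriminatory power"; when either
factor is unavailable it is treated as neutral, so the fallback is an
equal-weight mean. Catchment summaries are unweighted means across
subcatchments, reported as whole percentages.

All randomness flows through `numpy.random.default_rng` from a single
seed; a fixed seed gives a bit-identical accepted-solution stream, and the
pipeline derives per-(subcatchment, signature) seeds from the root seed by
SHA-256, so whole runs are byte-identical.

## SOD

Interval rates (m₁ − m₂)/(t₂ − t₁) are assigned to interval midpoints
(second-order accurate). Blanks are linearly interpolated onto the sample
midpoints and subtracted; the blank must cover the sample's span. Q10
normalisation multiplies by 1.065^(20 − T) and refuses T < 10 °C, outside
the correction's stated validity. SOC₅ and SOC₂₀ integrate the
*normalised* rates (normalisation follows the rate computation in the
measurement chain) by the trapezoid rule on the midpoint series, held
constant beyond the first/last midpoint. SOD = SOC/dry mass; negative
values (blank exceeding sample) are clamped to 0 with a warning while the
negative rates are retained in the result for diagnostics. The core chain
consumes O₂ *mass* directly; an optional ideal-gas helper converts an O₂
volume fraction and headspace volume, keeping sensor calibration out of
the core contract.

## Synthetic data

The generator emulates the sampling design: 4 source categories × 8
composite samples per category per subcatchment, and triplicate sediment
samples. The default panel mirrors the measured quantities (δ¹³C ≈ −28.5‰,
δ¹⁵N ≈ 5.2‰, %TOC, %TN, and 16 NIR constituent bands at order-1 arbitrary
intensities). Category means are the base values displaced by
±35% × separation (fixed seeded draws); within-category spread is
multiplicative normal with CV 0.08 by default — a realistic analytical plus
field spread for composite samples — and sediment is an exact convex
combination of per-category values with 2% multiplicative noise,
redrawn (≤ 100×) if it leaves the source envelope. Separation 0 makes the
categories statistically indistinguishable; separation ≥ ~1 yields the
full-separation regime in which composite signatures classify 100% of
source samples.

What the generator does **not** emulate: continuous NIR spectra (bands are
independent scalars), tracer covariance structure within samples,
non-conservative tracer transformation during transport, and spatial
connectivity of sources. Passing recovery tests therefore demonstrates the
correctness of the numerical machinery under the stated noise model, not
the field identifiability of real source systems.

Incubation series are first-order decays m(t) = m₀ − A(1 − e^(−kt))
calibrated so the temperature-normalised 0–20-day consumption per gram
equals the requested SOD₂₀ target (default k = 0.15 day⁻¹, 25-day series,
0.1-day steps, optional Gaussian measurement noise).

### Test problem sizes

The recovery suite runs 20 designs with Dirichlet(2) true proportions and
400 accepted solutions each (the per-category |R − truth| ≤ 0.1 bound is
checked on every design); sediment is mixed from the observed per-category
sample medians so the design truth is exactly the estimand of the
median-based mixing model, and a 10-tracer signature is used so all four
categories are identifiable. The solver-versus-grid suite checks 100
random 3-source problems against an exhaustive 0.01-resolution simplex
grid. These sizes keep the default test run to a few minutes while
exercising every code path at full fidelity.

## Known limitations

- Resubstitution classification % is optimistic for small samples; it is
  the reporting convention here, and LOO is available for honest accuracy.
- The GA is a heuristic; for large candidate panels it is not guaranteed
  to find the global Wilks-Λ optimum (the exhaustive oracle in the tests
  covers small panels).
- Posterior means of boundary-true proportions are biased inward when the
  source matrix is ill-conditioned on the chosen signature; this is a
  property of the method, not of the implementation.
- The combination weighting α = GOF × classification % is one reasonable
  reading of "combining"; published values are consistent with near-equal
  weights, and the equal-weight fallback reproduces them exactly.
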