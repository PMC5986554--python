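# Methods

## Kinetic model

The package models amyloid-β(1–42) fibrillation as a two-step autocatalytic
scheme: nucleus formation (n monomers → nucleus, first-order rate constant
kₙ, s⁻¹) and aggregate-catalysed elongation (monomer + aggregate → longer
aggregate, second-order rate constant kₑ, L mol⁻¹ s⁻¹). Writing f for the
fibrillar mass fraction and a (mol/L) for the initial monomer
concentration, the fraction obeys the logistic-type rate law

    df/dt = k (1 − f)(ρ + f),   f(0) = 0,   k = kₑ·a,   ρ = kₙ/k,

whose closed form is f(t) = ρ(exp[(1+ρ)kt] − 1)/(1 + ρ·exp[(1+ρ)kt]).
Assumptions inherited from this scheme: constant total peptide mass
(monomer + fibril fractions sum to 1 exactly, by construction), no
secondary nucleation, fragmentation or saturating elongation, and a
nucleus size n that never enters the closed form — n is therefore carried
only as documentation, not as a parameter. ThT fluorescence is assumed
proportional to fibril mass, F(t) = F₀ + ΔF·f(t).

Internal time unit is seconds throughout, because the rate constants are
conventionally quoted in s⁻¹ and L mol⁻¹ s⁻¹; hours are accepted and
produced only at the I/O boundary (CSV columns `time_h`/`time_s`),
converted exactly once.

### Numerical evaluation

The closed form is evaluated as f = −ρ·expm1(−u)/(exp(−u) + ρ) with
u = (1+ρ)kt. This is algebraically identical to the textbook form but
overflow-free for arbitrarily large u (exp(−u) underflows harmlessly to 0,
giving the correct limit f → 1) and exact at u = 0 via expm1.

An independent oracle integrates the rate law directly with
`scipy.integrate.solve_ivp` (LSODA, rtol = user tolerance, atol = rtol/1000).
The oracle never calls the closed form; the test suite requires agreement
within 1e-6 absolute over 0–48 h across 100 random (k, ρ) draws with
k ∈ [10⁻⁶, 10⁻³] s⁻¹, ρ ∈ [10⁻⁴, 1]. Integrator failure raises, it is never
silently truncated.

### Derived timescales

* Half-time: t₅₀ = ln((1+2ρ)/ρ)/((1+ρ)k), from inverting f = 1/2. It
  diverges as ρ → 0 (no nucleation, no aggregation) and scales as 1/k.
* Lag time: the standard tangent-at-maximum-slope construction. df/dt is
  maximal at f* = (1−ρ)/2, an interior point only for ρ < 1, reached at
  t* = ln(1/ρ)/((1+ρ)k) with slope k(1+ρ)²/4; the lag is where that tangent
  crosses f = 0. For ρ ≥ 1 there is no interior inflection and the lag is
  reported as an explicit `None`. The construction is analytically
  non-negative for ρ < 1 (ln(1/ρ) ≥ 2(1−ρ)/(1+ρ)) but is clamped at 0
  defensively against float round-off as ρ → 1.

## Curve fitting

Fits minimize squared residuals with `scipy.optimize.least_squares`
(bounded trust-region reflective). Design choices:

* **Log parameterization.** (ln k, ln ρ) are optimized, with bounds
  [ln 10⁻¹², ln 10³] on each: both constants span orders of magnitude and
  must remain positive. F₀ and ΔF stay linear, bounded generously around
  the observed intensity range.
* **Joint baseline/amplitude.** F₀ and ΔF are fitted jointly rather than
  normalizing by the last observed intensity, because a 48 h endpoint need
  not be at plateau for slow conditions and endpoint normalization would
  bias kₑ. Fraction curves (already on [0, 1]) fix F₀ = 0, ΔF = 1.
* **Initialization.** k₀ = 4 × (max discrete slope) — at the inflection the
  slope equals k(1+ρ)²/4 ≈ k/4 for small ρ — and ρ₀ = (earliest positive
  slope)/k₀, since the initial slope is kρ; both clipped into [10⁻¹², 10³].
  A curve with no point above 20% of its final level cannot be initialized
  and raises the no-signal error.
* **Multi-start.** Default 5 restarts jittering the rate guesses by up to
  ×/÷10 (seeded), keeping the lowest SSE; the k–ρ surface is banana-shaped
  when the lag phase is nearly degenerate.
* **Convergence.** ftol 1e-10 on relative SSE change, at most 2000 residual
  evaluations per start. The `converged` flag reports the optimizer status
  honestly; there is no silent fallback.
* **Standard errors.** Gauss–Newton approximation at the optimum,
  cov = (JᵀJ)⁻¹·SSE/(n−p) on the log scale, delta-method transformed
  (se(k) = k·se(ln k)); reported as absent when JᵀJ is singular.
* **Sigmoidality diagnostic.** A completed fit is flagged non-sigmoidal
  when ΔF ≤ 0 (falling trace — the model cannot decrease), r² < 0.95, or a
  rate parameter sits on a bound; the reason string names the trigger. A
  monotone-decreasing trace is seeded from its mirror image so the
  optimizer can reach the negative-ΔF best fit that the flag then reports.
* **Replicates.** The default pipeline pools replicate points (averaging
  duplicate times) into one fit, matching the experimental practice of
  averaging three measurements per time point; per-replicate fits are
  available by option.

The fitted (kₙ, kₑ) always satisfy kₙ/(kₑ·a) = ρ̂ to machine precision,
since they are derived from (k̂, ρ̂) by the exact inverse transform.

## Synthetic data

The generators stand in for raw measurements that were never published;
they emulate the study conditions, not instrument physics.

* **ThT curves.** intensity = F₀ + ΔF·f(t) + ε, ε ~ N(0, σ_rel·ΔF), i.i.d.
  per point, truncated below at 0 (a fluorimeter reads non-negative).
  Additive Gaussian noise relative to the amplitude is the simplest model
  consistent with plate-reader readout and lets presets transfer across
  amplitude scales; defaults F₀ = 50, ΔF = 400 (arbitrary units),
  σ_rel = 0.02. The default sampling schedule is the experimental
  0/6/12/24/36/48 h grid; denser grids are available. Replicate r uses the
  r-th spawned child of the seed (numpy `SeedSequence.spawn`), so adding
  replicates never perturbs earlier ones and repeat runs are bit-identical.
  What this does not emulate: photobleaching, evaporation drift,
  heteroscedastic plateau noise, or inter-plate effects — parameter-recovery
  results on these data are therefore a best-case statement about the
  estimator, not about any real instrument.
* **AFM particle tables.** Mixtures of aggregate species drawn
  species-first (categorical by weight), then length ~ log-normal (lengths
  are strictly positive and right-skewed in AFM morphometry) and height ~
  normal truncated at 0 (heights are narrow and near-symmetric),
  independently within a species. The distribution shapes are emulation
  choices, not inferences from data. Tip convolution and surface-deposition
  bias are not modelled.
* **Presets.** Frozen in `src/amykin/data/morphology_presets.yaml`
  (documented constants, not fitted values). Two base species — protofibril
  (length median 120 nm, ln-SD 0.28; height 2.3 ± 0.55 nm) and fibril
  (median 430 nm, ln-SD 0.45; height 3.6 ± 0.9 nm) — plus a thin-fibril
  species (fibril lengths, protofibril heights) for the DOPC condition,
  where long aggregates with protofibril-like heights dominate. Weights
  were chosen so the analytic bin/class masses of each mixture match the
  published percentages within ±3 points. One deliberate compromise: for
  the 12 h lipid-free condition the published 82.5% refers to the length
  bin alone, while the package's dominant-species check classifies jointly
  on length and height; a joint class is strictly narrower than either
  marginal, so both cannot equal 82.5% at once. The preset sits at the
  midpoint — analytically 80.5% classified protofibril and 84.5% in the
  50–250 nm length bin, both within ±3 points — which makes the height-bin
  marginal (~94%) run above the published 81.1%; this is a known limitation
  of a two-species emulation with independent axes.

## Morphology classification

Closed intervals on both axes (ranges are quoted inclusively), joint
length-AND-height matching, first match in priority order wins. Fibril
(priority 1) precedes protofibril (priority 2), so the overlapping
200–250 nm × 2–4 nm region is called fibril — the longer species is the
more mature one; the precedence is configurable by supplying a different
rule set. Histograms use half-open bins [eᵢ, eᵢ₊₁) with a closed last bin,
so a particle exactly on the final edge is counted; out-of-range particles
are reported separately, never dropped silently.

## Fold-change comparison

Ratios are computed from the printed, already-rounded constants (that is
what a reader can verify), as max/min with an explicit direction, rounded
half-away-from-zero at two decimals via decimal arithmetic on the shortest
decimal representation (so 2.175 → 2.18, not banker's 2.17). Two published
folds (1.35 and 1.2 for kₙ against the lipid-free control) disagree at the
second decimal with this convention — the printed constants give 1.36 and
1.18, suggesting those folds came from unrounded fit outputs that are not
available; the package reports the recomputed values and documents the
discrepancy rather than matching the printed ones. No uncertainties are
attached to fold changes because the source table reports none.

## Problem sizes and tolerances in the test suite

Self-consistency fits use 25–30 point grids over 48 h and demand relative
1e-6 recovery on noise-free data. The seeded recovery loop runs 100
synthetic triplicate experiments at σ_rel ∈ {0.5%, 2%, 8%} with 2 restarts
per fit; medians must be ≤ 15% at 2% noise and increase monotonically with
σ. Morphology preset checks draw n = 5000 (acceptance) and n = 10⁵
(convergence to analytic mass within 1%). Hypothesis property tests run
derandomized. The single-trace four-parameter fit at 2% noise has a median
kₙ error near 20% — an identifiability limit of a 25-point/48 h design
whose half-time is ≈ 4.4 h, which is why the recovery loop uses the
triplicate-mean design that the experimental protocol itself prescribes.

## Known limitations

* The model excludes secondary nucleation and fragmentation; curves from
  systems where those dominate will fit poorly (low r², flagged).
* ρ and k are weakly identified when the observation window ends before
  the plateau or the lag phase is unresolved by the sampling grid; standard
  errors and the sigmoidality flag surface this but cannot repair it.
* Synthetic AFM mixtures use independent length/height within species;
  real aggregates show correlated length–height growth.
* Nucleus size n is not estimable from f(t) and is not reported.
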