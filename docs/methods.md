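# Methods

## Model

The telegraph model is a promoter with two states. Off→On at rate k_on,
On→Off at rate k_off, transcription at k_m while On, first-order mRNA decay
at δ. All analysis is done at stationarity in δ-normalized units (δ = 1
defines the time unit): α = k_on/δ, β = k_off/δ, λ = k_m/δ. The stationary
copy-number law is the beta-Poisson mixture p(n) = ∫ Poisson(n; λx)
Beta(x; α, β) dx, equivalently the confluent-hypergeometric closed form
p(n) = λⁿ/n! · B(α+n, β)/B(α, β) · ₁F₁(α+n; α+β+n; −λ). Exact moments:
mean = λα/(α+β), variance = mean + λ²αβ/[(α+β)²(α+β+1)].

Because only the stationary distribution is observed, the identified
parameter combinations are the burst size b = λ/β = k_m/k_off and the burst
frequency f = α = k_on/δ, with λ fixed (assumed shared across integration
sites) and δ fixed externally (measured by an inhibition time course).
δ enters only through the units of f; rescaling every rate by a constant
leaves the PMF and all derived quantities unchanged. The model deliberately
excludes transient dynamics, extrinsic-noise covariates (cell size/cycle),
and promoters with more than two states. Both f and its reciprocal (the
mean wait between bursts) are exposed; all regressions here use f.

## Numerical evaluation of the PMF

The closed form is evaluated after the Kummer transformation
₁F₁(α+n; α+β+n; −λ) = e^(−λ) ₁F₁(β; α+β+n; λ), whose series has only
positive terms; the terms are summed in log space (streaming logsumexp), so
there is no cancellation and no overflow anywhere in the parameter ranges
exercised (α, β up to ~10⁴, λ up to ~10³). The term ratio is bounded by
λ/(k+1), so truncating at K = λ + 12√λ + 40 terms leaves a tail far below
double precision. Because the three gamma-function families involved differ
only by integer offsets, each evaluation needs just three 1-D `gammaln`
sweeps plus indexing, making a full likelihood evaluation ~1–3 ms at
λ = 1000.

A fixed-order Gauss–Jacobi quadrature of the mixture integral (order
≈ 1.1λ + 15√λ + 60, chosen so the e^(−λx) factor is resolved) is kept as an
independent evaluation route and is used as the oracle in tests. It is not
the primary path because `roots_jacobi` overflows for β ≳ 10³ and its
node/weight roundoff floors near 10⁻⁷ relative error when both α, β < 1.
Degenerate boundaries are exact branches, not limits: β = 0 is Poisson(λ);
α = 0 or λ = 0 is a point mass at zero.

`stationary_pmf` truncates support where the omitted tail mass is below
`tail_tol` (default 10⁻¹⁰), starting from mean + 10 SD + 25 and doubling
until the computed mass qualifies, then renormalizes. Likelihood code
evaluates log-PMF directly at the observed counts instead (unique values
with multiplicities), flooring log p at the smallest representable double
so a stray far-tail count can never produce a non-finite likelihood.

## Stochastic-simulation oracle

`gillespie_simulate` is an exact SSA over the reactions Off↔On,
On→On+mRNA, mRNA→∅, optionally mRNA→mRNA+P (k_p·m) and P→∅ (δ_p·p) for a
fluorescent-reporter stage. The inner loop is numba-jitted; 10⁵ replicate
endpoints at moderate rates take ~2 s, which is what makes the
total-variation comparison against the analytic PMF (< 0.01 at 10⁵
replicates) affordable as a routine test. Trajectories start Off and empty;
callers should use t_end ≥ 10/min(δ, k_on+k_off) (and ≥ 10/δ_p with
protein) so endpoints are effectively stationary.

## Maximum-likelihood fitting

Per clone, the NLL is minimized over (log10 b, log10 f) within
log10 b ∈ [−2, 4], log10 f ∈ [−3, 3] by Nelder–Mead (NLL tolerance 10⁻⁸)
from a method-of-moments start (b₀ = Fano − 1, f₀ = mean/b₀, clipped into
bounds) plus four seeded jittered restarts; the reported optimum is the
best of the five and is flagged if within 10⁻³ of a bound. PMF evaluations
are memoized per clone keyed by (b, f) rounded to 10 decimals, which makes
profiling cheap. All-zero count vectors return a flagged boundary result
rather than a silent fit; the moment start sorts counts first so the result
is exactly invariant to cell order.

95% CIs are profile likelihood at offset 1.92 (= χ²₁(0.95)/2): the other
parameter is re-optimized at each profile point (bounded 1-D search), the
endpoint bracket grows geometrically, and bisection stops when
|ΔNLL − 1.92| < 10⁻³. Intervals that hit the optimization bounds are
flagged open-ended. For very low-expression clones (mean ≪ 1) the
intervals widen substantially — by design; the parameters are then weakly
identified and the fit must not claim spurious precision.

The degradation-rate estimator converts an inhibition time course to
relative abundance 2^(−ΔCt) normalized to t = 0 and fits ln(abundance)
against time by OLS; δ = −slope, half-life = ln 2/δ, with a non-decaying
flag when the fitted slope is non-negative.

## Synthetic cohort

The generator encodes the study conditions the analysis assumes, so every
downstream stage is testable without external data:

* **Counts.** 200 clones × 600 cells by default. log10 b ~ Normal(0.9,
  0.4), log10 f ~ Normal(−0.4, 0.283), independently drawn, truncated at
  ±2σ; λ = 1000 so the bursty regime (mean ≪ λ) holds everywhere. The 2:1
  log-variance ratio puts the variance-vs-mean log-log slope at
  (2σ_b² + σ_f²)/(σ_b² + σ_f²) ≈ 1.67 asymptotically; the finite-burst
  correction (variance ∝ mean·(1 + b), and log(1+b) flattens at small b)
  pulls the realized slope to ≈ 1.56, inside the expected [1.5, 1.8] band.
  The CV-vs-f slope sits near the burst-limit −1/2.
* **Protein readout.** GFP = scale·P + lognormal autofluorescence, with P
  from the exact SSA using a long-lived reporter (δ_p = δ/50, k_p = 5).
  A documented fast approximation (P ∝ mean of K = δ/δ_p independent
  stationary mRNA draws, i.e. the reporter time-averages ~K mRNA
  lifetimes) is available as `method="moment"` for cohort-scale use.
  Scatter channels (FSC/SSC) are lognormal and independent of GFP by
  default — the extrinsic-noise control — with an optional coupling knob
  for gate-robustness testing.
* **Chromatin.** Per site, log10 I = a0 + a1·log10 f + ε, clamped to
  (0, 1]. Defaults: Nuc-1 (a0 = −0.85, a1 = −0.63, σ_ε = 0.15), HSS
  (−0.60, −0.40, 0.25), Nuc-0 (−0.70, −0.30, 0.30), so Nuc-1 is the
  strongest, cleanest predictor of burst frequency. Note the attenuation
  algebra: regressing log f̂ on log I yields slope a1σ_f²/(a1²σ_f² + σ_ε²)
  ≈ −0.9 and R² ≈ 0.55–0.6 under these defaults — the intended ordering
  across sites, not a specific slope value, is the calibrated property.
* **qPCR.** Ct values are built to invert exactly under the ΔCt estimator
  at zero noise: treated Ct = untreated Ct − log2(I·R_ref) at promoter
  sites, − log2(R_ref) at the reference locus (R_ref = 0.9), plus
  Normal(0, 0.1) triplicate noise.
* **Seeding.** One cohort seed spawns per-purpose streams via
  `SeedSequence((seed, tag, index))` (tag 0 clone-level draws, 1 counts,
  2 flow, 3 qPCR, 4 decay), so any single clone is regenerable in
  isolation and results are independent of evaluation order.

What the generator does **not** emulate: integration-site genomic
preferences, extrinsic noise coupled to cell state, microscopy/segmentation
artifacts, amplification-efficiency differences between amplicons, or
transient (non-stationary) expression. Passing tests therefore demonstrate
correctness of the inference chain under the model's own assumptions, not
robustness to real-data violations of them.

## Flow processing

The density-mode gate evaluates a Gaussian KDE (Silverman bandwidth per
axis) of (FSC, SSC) on a 128×128 grid, assigns each event its grid-cell
density, and keeps the ceil(fraction·n) densest events — exactly the
smallest highest-density region containing the requested fraction, with
deterministic tie-breaking and guaranteed nesting across fractions. If the
gate would retain fewer than `min_cells` events (default 4000) it is
enlarged and flagged. Clone clustering is Ward agglomerative clustering on
standardized (log10 mean, log10 CV), with labels renumbered by ascending
mean expression for determinism; pair selection is exhaustive within
cluster: among pairs with |Δlog10 mean| ≤ 0.1 (≈ ±26%, the default
matched-mean tolerance) take the pair maximizing |Δlog10 CV|, ties broken
lexicographically.

## Statistics

Moment CIs are percentile bootstrap (B = 1000, 2.5%/97.5% quantiles), not
BCa. Scaling fits are unweighted OLS on log10-transformed values (base 10
throughout; slopes are base-invariant), with Spearman rank correlation on
the untransformed values reported alongside — the slope t-test and the
Spearman test answer slightly different questions, so both p-values are
reported. Spearman p-values use the exact permutation distribution below
n = 10 and the t-approximation otherwise. Errors-in-variables is *not*
handled: sampling noise in per-clone moments attenuates slopes slightly
(visible in the 1.56 vs 1.67 cohort slope above); a Deming-type correction
is out of scope and flagged as a limitation. Subset-representativeness uses
a nested-model F-test (group indicator + group×slope interaction); because
subset rows also appear in the pooled full set, the test is conservative.
Chromatin PCA standardizes columns (correlation scale — the sites have
different dynamic ranges) and fixes signs by making the largest-magnitude
loading of each component positive.

## Problem sizes and tolerances

Routine test sizes are chosen to make sampling error negligible relative to
the asserted tolerances: 10⁵ replicates for TV < 0.01 SSA checks; 200
clones × 600 cells for cohort slopes (matching the default conditions); the
profile-CI coverage study runs 60 clones × 600 cells with a 3σ binomial
band around 95%, and the bootstrap coverage study 400 repetitions.
PMF-vs-moment agreement is asserted at 10⁻⁶ relative error with
tail_tol = 10⁻¹²; series-vs-quadrature agreement at 2×10⁻⁷ (the
quadrature's roundoff floor); profile endpoints at |ΔNLL − 1.92| < 10⁻³.
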