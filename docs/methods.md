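# Methods

## The model

`gelbayes` fits a two-layer hierarchical Bayesian model to case–control
2D PAGE spot-intensity tables and classifies differentially expressed (DE)
proteins from the marginal posteriors.

### Data scale and missingness

Analysis is on **log2 relative percentage volumes**: a spot's raw volume
divided by its gel's total observed volume, times 100, log2-transformed.
No value can exceed ν = log2(100) ≈ 6.64.  A missing cell ("NA") has two
possible causes — the protein was not expressed on that gel, or it was
expressed below the limit of detection *d* (default −8.67, the value used
throughout the validation studies).  Raw zeros are mapped to missing: a
zero volume is indistinguishable from non-detection.

### Local layer

Each spot *s* carries four parameters: the control mean intensity μ_s, the
case-minus-control difference δ_s (the case mean is μ_s + δ_s), and
logit-scale expression propensities κ_s (control) and τ_s (difference), so
p0 = logit⁻¹(κ_s) and p1 = logit⁻¹(κ_s + τ_s).  All spots share one
standard deviation σ_s = ψ·σ_g.  An observed intensity *c* contributes

    ρ_x · φ((c − μ_x)/σ_s) / (σ_s · λ),   λ = Φ((ν − μ_x)/σ_s) − Φ((d − μ_x)/σ_s),

a truncated-normal density weighted by the expression probability ρ_x; a
missing cell contributes the mixture mass (1 − ρ_x) + ρ_x·Φ((d − μ_x)/σ_s).
Note the asymmetry, kept deliberately: the censored-missing branch uses the
*untruncated* lower-tail mass while the observed branch normalises over
[d, ν].  The per-observation law therefore carries total mass
1 + ρ_x·Φ((d − μ_x)/σ_s) rather than exactly 1; the excess is ≤ ρ·Φ((d−μ)/σ),
about 1e−7 at typical Sim-1 values (μ = −5, σ = 0.7) and immaterial for
inference, but the quadrature test asserts the exact identity rather than
pretending the density normalises.

### Global layer and priors

μ_s ~ Normal(μ_g, σ_g); δ_s ~ modified (asymmetric) Laplace with rate λ_δ
and up-regulated proportion ϕ_δ, each side an exponential carrying weight
ϕ_δ / (1 − ϕ_δ); κ_s ~ Normal(μ_κ, σ_κ); τ_s ~ Normal(μ_τ, σ_τ).  Priors:
μ_g ~ N(−3, 5) (1000 equal spots sit at ≈ −3.3); σ_g², σ_κ², σ_τ² ~
InverseGamma(0.001, 0.001) on the **variance** scale; ψ ~ U(0.001, 2);
λ_δ ~ Exp(1); ϕ_δ ~ Beta(2, 2); μ_κ, μ_τ ~ N(0, 3) (deliberately tight —
distinguishing expression probabilities beyond 0.95, i.e. κ beyond ≈ 2.94,
is biologically meaningless and invites false positives).

## Numerical evaluation

Everything is computed in log space.  The truncation mass λ is evaluated
via erfc on whichever tail avoids catastrophic cancellation: a naive CDF
difference underflows to zero when the detection window lies ~8σ or more
below the mean, which turns log λ into an artificial floor of ≈ −690 and
corrupts the posterior by hundreds of log units.  Probability masses are
floored at 1e−300 before logs; −∞ appears only at the Metropolis–Hastings
comparison, never inside sums.

The likelihood depends on the data only through per-spot, per-group
sufficient statistics (Σc, Σc², observed and missing counts), so one full
likelihood evaluation is O(S) regardless of gel count.  The sampler's
iteration loop is compiled with numba (`gelbayes._kernel`); the recorded
log posterior is cross-checked in the tests against an independent
non-vectorised reference to ~1e−7.

## The sampler

Adaptive random-walk Metropolis–Hastings with block updating and parameter
expansion.

**Blocks.**  Eight global blocks — (μ_g′, σ_g²′), α_μ, (λ_δ, ϕ_δ), ψ,
(μ_κ′, σ_κ²′), α_κ, (μ_τ′, σ_τ²′), α_τ — followed by the two local blocks
(μ_s, δ_s) and (κ_s, τ_s) for every spot.  Each block makes one joint
accept/reject decision.  Because spots are conditionally independent given
the globals, all spots' local blocks are proposed and decided
simultaneously in one vectorised sweep per block kind (same invariant
distribution as a sequential sweep, deterministic under the seed).

**Proposals.**  Plain normals for unbounded parameters; truncated normals
for variances, scales and the expansion multipliers, with the exact
truncation-mass Hastings correction; a logit-scale normal with its Jacobian
correction for ϕ_δ ∈ (0, 1).  Support constraints — μ_g ∈ [d, ν] and
σ_g, σ_κ, σ_τ, λ_δ ≥ 0.01 (the theoretical lower limit is 0, but values
below 0.01 are implausible for real gels and invite underflow) — are
enforced on the **natural** scale by rejection.

**Tuning.**  Every 500 burn-in iterations each block's proposal sd is
rescaled by `Φ⁻¹(ρ_opt/2) / Φ⁻¹(ρ_cur/2)`, with ρ_cur averaged over a
3000-iteration window and clamped away from {0, 1}; targets are 0.44 for
single-parameter blocks and 0.234 for multi-parameter blocks.  Adaptation
freezes at the end of burn-in so the retained chain comes from a fixed
kernel.  Local blocks share one tuned sd per block kind across spots,
keeping the tuning state O(1) in S.

**Parameter expansion.**  Each (mean, variance) pair is stored as primed
parameters times a redundant multiplier: μ_g = α_μ·μ_g′, σ_g² = α_μ²·σ_g²′
(likewise α_κ, α_τ), with α ~ U(0.01, 10).  Three correctness details are
easy to get wrong and are fixed here deliberately:

1. the expanded target carries the change-of-variables Jacobian α³, which
   enters the α-block acceptance ratio as 3·log(α*/α).  With it, every
   α-slice of the expanded target is exactly the natural-scale posterior
   (the marginal-augmentation construction); without it the natural
   posterior is provably biased — a toy model with a quadrature-computable
   posterior shows the variance parameter inflating by ~25%;
2. support bounds live on the natural scale (above).  Truncating the
   *primed* proposals instead makes the feasible α-range depend on the
   natural value and shifts the posterior;
3. primed-block proposal sds are divided by α (α² for variances), so the
   effective natural-scale step is α-invariant and slice mixing does not
   collapse when α drifts from 1.

The package validates all of this by running the sampler with and without
expansion on a common fixture and requiring the natural-scale posteriors to
agree within Monte Carlo error; expansion markedly improves the effective
sample size of the variance parameters (e.g. ~9× for σ_τ on a 5-spot
fixture).

**Initialisation.**  μ_s from each spot's observed mean (fallback −3);
κ_s from the logit of the observed expression fraction clamped to ±2.94;
δ_s = τ_s = 0; globals by method of moments over those locals with
prior-centre fallbacks (λ_δ = 1, ϕ_δ = 0.5, σ_τ = 1); all α = 1; initial
proposal sd 0.5.  A non-finite starting posterior falls back to a generic
in-support state.

## Summaries and classification

- **HPD**: contiguous interval by the shortest window of ⌈0.95·n⌉
  consecutive order statistics (ties → lowest lower bound).  The marginal
  posteriors here are unimodal in practice, where the smallest-region
  definition reduces to this interval.
- **ESS**: n / (1 + 2Σρ̂_k) with autocorrelations (FFT-estimated) summed
  until the first non-positive value, capped at n; a constant chain is
  reported as ESS = n with a flag.  The conventional ESS > 1000 target is a
  reported diagnostic, not a gate — the CLI warns below it.
- **Classification**: a spot is DE when the 95% HPD of δ_s and/or τ_s
  excludes zero (three scenarios: intensity, expression probability, both);
  direction is the sign of the δ_s HPD.  Prior/posterior density curves are
  exported as plot-ready tables; no figures are rendered.

## The LRT baseline

The predecessor univariate method: each spot's censored-mixture likelihood
is maximised independently over (μ, δ, κ, τ, σ) — per-spot σ free, unlike
the hierarchical model's shared ψσ_g — and 2(lnL_full − lnL_null) with
δ = τ = 0 under the null is referred to χ²(2), α = 0.05.  Multi-start
Nelder–Mead (moment-based start plus jittered restarts, default 6) with
|κ|, |τ| ≤ 10 to avoid the flat saturation ridge.  A spot observed on no
gel sits at the ML boundary p → 0 with log likelihood 0 ("never
expressed", not significant).  With very few observed gels the per-spot σ̂
is biased low, making the LRT anti-conservative exactly where the shared
variance helps the hierarchical model — visible in the comparison tests.

## The simulator

`simulate()` draws per-spot parameters from configurable global laws,
expresses each spot per gel with probability p0/p1, draws intensities from
Normal(μ_s or μ_s + δ_s, σ_s), records values below d as missing with a
censoring indicator (each missing cell has exactly one cause), and replaces
draws above ν — impossible as relative percentages — by exact draws from
the normal truncated to (−∞, ν] (inverse CDF in the body, an exponential
rejection tail sampler when the admissible region is a far tail; a
redraw-until-valid loop would not terminate for the Laplace-tailed δ_s).

Presets encode the four validation studies: **sim1** μ_s ~ N(−5, 1),
σ_s = 0.7, δ ~ mod-Laplace(0.5, 0.5), κ ~ N(1, 1), τ ~ N(0, 2), d = −8.67;
**sim2** κ ~ U(−1, 3), τ ~ U(−2, 2); **sim3** λ_δ = 0.7 (a gap of ~1.5
spot standard deviations; 0.66 is available by override), κ ~ N(1, 0.25),
τ split half/half between N(−3, 0.25) and N(2, 0.25); **sim4** δ_s = τ_s = 0
(null / false-positive study).  Group sizes default to 12 + 12 gels (one
gel per subject in a 24-subject experiment); sim4 is also meaningful at
18 + 18 and 24 + 24.

What the generator does **not** emulate: gel-image artefacts, spot-matching
errors, spatially correlated noise, and unequal group variances.  Passing
tests therefore demonstrate correctness of the inference under the model's
own assumptions, not robustness to real-gel pathologies.

## Problem sizes used in tests and the acceptance script

The original validation ran 50 million iterations per chain (about a day
per dataset).  This package's validation uses reduced-scale chains chosen
to exercise the same claims: recovery runs use the study-scale 100 spots
with 500 k iterations (thinning 500, 10% burn-in) in five seeded
replicates — the generative values of μ_g, σ_g, ψ, λ_δ and ϕ_δ fall inside
their 95% HPDs in ≥ 4/5 replicates; the null study uses 300 k iterations
(zero DE calls expected); the comparison study uses 1 M iterations.  At
these lengths the DE counts on Sim-1 land around 62–73 of 100 spots for
the hierarchical model and 62–68 for the LRT — the hierarchical model
consistently flags at least as many spots, with most LRT calls shared.
Longer chains sharpen but do not qualitatively change these counts.

## Known limitations

- Equal Case/Control variances by assumption; spots violating it are
  better served by the per-spot LRT.
- One global distribution per parameter: protein clusters with distinct
  abundance regimes are absorbed into wider normals (the sim3 study shows
  this failure mode is graceful: σ_τ inflates to cover a bimodal truth).
- Contiguous HPDs only; a genuinely multimodal marginal would need the
  fragmented smallest-region definition.
- Single-chain inference; convergence assessment across independent seeds
  is the user's responsibility (`ChainConfig(seed=...)` makes this cheap).
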