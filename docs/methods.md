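# Methods

## Model

Observations are modelled as i.i.d. draws from a delta-gamma (zero-inflated
gamma) law `DG(α, β, δ)`: an exact zero with probability `δ`, otherwise a
gamma deviate with shape `α > 0` and **rate** `β > 0`. The CDF is `δ` at
`x = 0` and `δ + (1−δ)G(x; α, β)` for `x > 0`. The estimand throughout is the
population mean `τ = (1−δ)·α/β`, and for two independent populations the
difference `ψ = τ₁ − τ₂`.

An observation counts as a zero iff it equals `0.0` exactly; there is no
epsilon thresholding. This matches instruments (e.g. rain gauges) that report
true zeros; data with "near-zero" noise should be cleaned before use.

## Cube-root (Wilson–Hilferty) scale

Inference for the positive part runs on cube roots: `G^{1/3}` is approximately
`N(μ, σ²)` with `μ = M^{1/3}(1 − 1/(9βM))` and `σ² = 1/(9βM^{1/3})`, where
`M = α/β`. Solving for `M` gives the exact inverse

    M = (μ/2 + √(μ²/4 + σ²))³,

an algebraic identity (for `t = M^{1/3}`, `c = 1/(9βM)`: `μ²/4 + σ² =
t²(1+c)²/4`), so the round trip recovers `α/β` to machine precision; the test
suite asserts this over 1,000 random parameter pairs. The map is applied as
printed for any real `μ`, including `μ < 0`, which can arise in posterior
draws from very small samples.

The sufficient statistics per sample are `n₀` (zeros), `n₁` (positives),
`ȳ` (mean of cube-rooted positives) and `ss` (their sum of squared
deviations).

## The five interval methods

All five are Monte-Carlo intervals from `ndraws` (default 5,000) draws of
`τ = (1−δ)(μ/2 + √(μ²/4 + σ²))³`.

**Jeffreys-rule prior** (`p(δ) ∝ δ^{−1/2}(1−δ)^{1/2}`, `p(σ²) ∝ σ^{−3}`):
`δ|x ∼ Beta(n₀+½, n₁+3/2)`, `σ²|x ∼ InvGamma(n₁/2, ss/2)` (sampled as
`ss/χ²_{n₁}` for transparency), `μ|σ²,x ∼ N(ȳ, σ²/n₁)` with a fresh normal
deviate per draw, paired with that draw's `σ²` (joint sampling). Requires
`n₁ ≥ 1` and `ss > 0`, hence effectively `n₁ ≥ 2`. The `δ` prior is the form
stated for this model family (it is not the classical Jeffreys binomial
prior); it is implemented as stated.

**Uniform prior** (`p(δ), p(μ), p(σ²) ∝ 1`): `δ|x ∼ Beta(n₀+1, n₁+1)`,
`σ²|x ∼ InvGamma((n₁−3)/2, ss/2)` — proper only for `n₁ ≥ 4`, enforced with
an explicit error. At small `n₁` (shape `(n₁−3)/2` close to 0) the `σ²` draws
are extremely heavy-tailed and the cubing in the mean map amplifies them;
expected lengths for the uniform methods at `n₁ ≲ 8` can be dominated by rare
huge draws. This is a real property of the printed construction, not a bug.

**Fiducial quantities (FQ)**: per draw one `Z ∼ N(0,1)` and one
`C ∼ χ²_{n₁−1}` are drawn and *shared* between `F_{σ²} = ss/C` and
`F_μ = ȳ + Z/√C · √(ss/n₁)` (the standard generalized-pivotal construction —
the joint law of the pair is what the mean map consumes).
`F_{1−δ} ∼ ½Beta(n₁, n₀+1) + ½Beta(n₁+1, n₀)` is read as a **mixture**: a
fair coin selects the component per draw. When `n₀ = 0` the second component
`Beta(n₁+1, 0)` is taken as its weak limit, a point mass at 1; when `n₁ = 0`
the mean is not estimable and an error is raised. `F_τ = F_{1−δ}·F_M` with
`F_M` the mean map applied to `(F_μ, F_{σ²})`.

**Interval extraction.** Equal-tailed intervals use the interpolated
order-statistic quantile rule `h = 1 + (N−1)p` (the common software default;
the draws' provenance makes finer quantile conventions immaterial at
N = 5,000). HPD intervals sort the draws and take the shortest window of size
`g = max(1, min(N−1, round(N(1−γ))))`, first minimum on ties — the semantics
of the widely used coda-style routine, cross-checked against `arviz.hdi` in
the tests and against a brute-force window search. Only unimodal draw vectors
are expected; no union-of-intervals HPD is attempted. Defaults: `γ = 0.05`,
`ndraws = 5,000`.

**Two-sample pairing.** `ψ` draws are index-paired differences of per-sample
`τ` draws on independent substreams. When a seed (rather than a live
generator) is supplied, each sample's substream is keyed on
`(seed, blake2 hash of the sample bytes)`. Content-keying makes the
construction exactly antisymmetric — swapping the inputs replays each
sample's own draws, so the interval flips sign exactly, and byte-identical
inputs give `ψ ≡ 0`. The cost is that byte-identical samples share a stream
(perfectly correlated draws), which is the degenerate case the antisymmetry
property requires anyway; distinct data get independent streams.

## Point estimation

`δ̂ = n₀/n`. The gamma part is fit on the positives by Newton iteration on
the digamma equation `log a − ψ(a) = log(mean) − mean(log)`, initialized at
the method-of-moments shape, tolerance 1e-10, at most 100 iterations; the
rate is `α̂/mean`. This is cross-checked against `scipy.stats.gamma.fit`
(fixed location) in the tests. `τ̂ = (1−δ̂)·α̂/β̂` by definition.

## Simulation engine

`run_scenario` replicates: draw a sample (or pair), build each requested
interval from fresh draws, record containment of the true `τ` (or `ψ`,
convention `L ≤ θ ≤ U`) and the width; report per method the coverage
probability CP, expected length EL, the binomial standard error
`√(CP(1−CP)/reps)`, and `n_failed` — replicates whose sample violates a
method's preconditions (no positives, zero spread, `n₁ ≤ 3` for the uniform
prior). Failed replicates are excluded from that method's CP/EL, never
silently dropped; at the default study settings the event has negligible
probability (e.g. `P(n₁ ≤ 1) ≈ 1e-4` at `n = 30, δ = 0.7`).

The engine is vectorized over replicates in fixed 1,024-replicate chunks with
one stream per draw family spawned from the master seed; results are a pure
function of the seed and independent of any execution details. Zero counts
per replicate are binomial, exactly as the generative model prescribes.
Defaults `reps = 15,000`, `ndraws = 5,000`; the test suite uses 200–3,000
replicates with tolerances widened by the corresponding `1/√reps` factor.

`run_grid` crosses scenario axes (lists in the YAML config) and emits one
tidy row per scenario × method; `wide_table` formats the CP/(EL) layout used
in the field's reports.

## What the synthetic generator does and does not emulate

The generator *is* the model: exact zeros at rate `δ`, gamma positives. Real
rainfall series depart from it in ways the simulations do not probe — serial
dependence between months, measurement rounding near zero, and positive parts
that are only approximately gamma (the AIC check exists precisely to assess
that last point on real data). Passing coverage tests therefore certify the
procedures under the model, not robustness to these departures.

## Reproducibility of previously published tables

Published coverage/length tables exist for exactly these five methods on the
same design grids, and this package's simulations were compared against them
cell by cell. The coverage probabilities agree to within a few hundredths
(every method lands near the nominal 0.95 here), but the published expected
lengths are systematically shorter — by a factor of ~1.4 for the Bayes
methods and ~1.15 for FQ — and the published FQ coverage is distinctly
conservative (~0.98) where this implementation is calibrated (~0.95).

Controlled experiments reproduce the published numbers almost exactly (FQ
length ratios 0.997–1.008 across all cells tested) only under three joint
deviations from the constructions stated above: (i) data generated with a
*fixed* zero count `n₀ = δn` instead of binomial zeros; (ii) the Bayes mean
map applied with the plug-in `δ̂ = n₀/n` instead of posterior `δ` draws;
(iii) `F_{1−δ}` taken as the *average* `(B₁+B₂)/2` of two independent betas
instead of the mixture. Under binomial zeros, a published cell like CP 0.944
with EL 1.55 (n = 30, δ = 0.2, α = 5.5, β = 1) is arithmetically impossible —
a 95% interval there must be about 2.1 wide. This package deliberately
implements the stated constructions, which are self-consistent and
well-calibrated; its expected lengths are correspondingly larger than the
published ones, and its FQ intervals are approximately calibrated rather than
conservative. The qualitative ranking is unaffected: the Jeffreys HPD
interval has the smallest mean expected length across the design grid here
too, so the headline recommendation stands.

## Numerical conventions and edge cases

- β is a rate everywhere; the CLI's `--scale` flag reciprocates it on input
  (`make-fixture`) and output (`estimate`) for interoperability with
  scale-parameterized software.
- Summary statistics use sums of squared deviations computed directly on the
  cube-rooted positives; `ss` is clamped at 0 against rounding.
- `cube_var = ss/(n₁−1)` is defined only for `n₁ ≥ 2`; accessing it otherwise
  raises.
- Quantile/HPD routines require ≥ 2 finite draws; constant draw vectors give
  the degenerate interval `(c, c)`.
- All randomness flows through explicitly seeded `numpy.random.Generator`
  objects; no global state. Grid cells derive per-scenario seeds from the
  master seed and the cell index.
- CSV I/O: single column, optional header, `#` comment lines carry metadata;
  missing or negative values are rejected with line numbers.

## Known limitations

- No censoring, covariates, or serial dependence; mean functional only (no
  variance or quantile intervals).
- The uniform-prior methods are unstable for very few positives (see above);
  the Jeffreys or FQ methods are preferable there.
- HPD extraction assumes unimodal draws.
- The cube-root normal approximation degrades for very small shape `α`
  (heaviest visible at `α ≈ 1.25` in the coverage tables, where Bayes
  coverage dips to ~0.94).
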