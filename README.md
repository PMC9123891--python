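# dgmean

Interval estimation for the mean of **zero-inflated gamma** (delta-gamma) data,
and for the difference of two such means.

Many non-negative environmental and biomedical measurements — monthly rainfall
totals, biomass, per-claim costs — contain exact zeros mixed with skewed
positive values. The delta-gamma law `DG(α, β, δ)` models this as a point mass
`δ` at zero plus, with probability `1 − δ`, a gamma distribution with shape `α`
and rate `β`. Its mean is

    τ = (1 − δ) · α / β

`dgmean` builds five interval estimates for `τ` (and for `ψ = τ₁ − τ₂` in the
two-sample problem), evaluates them by Monte-Carlo simulation, and checks the
gamma assumption for the positive part by AIC. It is aimed at applied
statisticians and hydrologists who need a calibrated interval for the mean of
zero-heavy skewed data.

## Methods

Inference runs on the cube-root scale: if `G` is gamma then `G^{1/3}` is
approximately normal (Wilson–Hilferty) with

    μ = M^{1/3}(1 − 1/(9βM)),   σ² = 1/(9βM^{1/3}),   M = α/β,

and the map inverts exactly: `M = (μ/2 + √(μ²/4 + σ²))³`. Monte-Carlo draws of
`(μ, σ², δ)` are pushed through `τ = (1 − δ)(μ/2 + √(μ²/4 + σ²))³`:

| method tag          | draws of (μ, σ², δ)                                            | interval |
|---------------------|----------------------------------------------------------------|----------|
| `jeffreys_credible` | Jeffreys-rule posterior: δ∼Beta(n₀+½, n₁+3/2), σ²∼InvGamma(n₁/2, ss/2), μ\|σ²∼N(ȳ, σ²/n₁) | equal-tailed |
| `jeffreys_hpd`      | same draws                                                     | shortest window (HPD) |
| `uniform_credible`  | uniform prior: δ∼Beta(n₀+1, n₁+1), σ²∼InvGamma((n₁−3)/2, ss/2), μ\|σ²∼N(ȳ, σ²/n₁) | equal-tailed |
| `uniform_hpd`       | same draws                                                     | HPD |
| `fq`                | fiducial quantities: F_σ²=ss/χ²ₙ₁₋₁, F_μ=ȳ+Z/√χ²·√(ss/n₁) (shared Z, χ²), F₁₋δ ∼ ½Beta(n₁, n₀+1)+½Beta(n₁+1, n₀) mixture | equal-tailed |

Here `n₀`/`n₁` count zeros/positives and `ȳ`, `ss` are the mean and sum of
squared deviations of the cube-rooted positives. Two-sample intervals are built
from index-paired draws `ψᵢ = τᵢ(A) − τᵢ(B)` on independent substreams.

## Worked example

Generate a synthetic monthly-rainfall-like sample (50 observations, 54% zeros,
gamma(5.3, rate 2.06) positives — true mean τ = 0.46·5.3/2.06 ≈ 1.18) and
estimate its mean:

```sh
$ dgmean make-fixture --alpha 5.3 --beta 2.06 --delta 0.54 --n 50 --seed 4 --out rainfall.csv
$ dgmean estimate rainfall.csv --seed 11
n=50  n_zero=25  n_pos=25
delta_hat=0.5000  alpha_hat=6.2679  beta_hat(rate)=2.5929  tau_hat=1.2087
           method         kind  level    lower    upper    width  ndraws
jeffreys_credible equal_tailed   0.95 0.876533 1.656942 0.780409    5000
     jeffreys_hpd          hpd   0.95 0.857033 1.627934 0.770901    5000
 uniform_credible equal_tailed   0.95 0.847790 1.637388 0.789598    5000
      uniform_hpd          hpd   0.95 0.833644 1.614961 0.781317    5000
               fq equal_tailed   0.95 0.834355 1.636572 0.802217    5000
```

The first line counts zeros and positives; the second is the ML fit
(`tau_hat = (1−δ̂)·α̂/β̂`, here 1.21 against a true mean of 1.18). Each row is a
95% interval for τ by one method — all five cover the truth here, and the
Jeffreys HPD interval is the narrowest, which is the typical ordering.
`dgmean compare a.csv b.csv` produces the same table for the difference of two
means, and `dgmean fit-check` ranks normal/lognormal/Cauchy/gamma fits of the
positive part by AIC:

```sh
$ dgmean fit-check big.csv          # 500-point fixture from the same law
   family      loglik  k        aic  best
   normal -368.316402  2 740.632805 False
lognormal -355.755624  2 715.511247 False
   cauchy -402.430959  2 808.861918 False
    gamma -351.588537  2 707.177073  True
best: gamma
```

Coverage studies over parameter grids run from a YAML config:

```sh
$ dgmean simulate grid.yaml --out results.csv --wide-out table.csv
```

with keys `design, n, m, alpha, beta, delta, gamma, reps, ndraws, methods,
master_seed` (lists are cross-product axes; several blocks can be given under
`grids:`). Everything is deterministic given the seed.

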