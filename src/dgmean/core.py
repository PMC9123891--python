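"""Delta-gamma (zero-inflated gamma) distribution primitives.

The delta-gamma law ``DG(alpha, beta, delta)`` places probability ``delta`` on an
exact zero and, with probability ``1 - delta``, draws from a gamma distribution
with shape ``alpha`` and *rate* ``beta`` (mean of the positive part
``alpha / beta``).  Its population mean is ``tau = (1 - delta) * alpha / beta``.

Inference in this package runs on the cube-root scale: if ``G`` is gamma, then
``G**(1/3)`` is approximately normal (the Wilson-Hilferty approximation) with

    mu     = M**(1/3) * (1 - 1 / (9 * beta * M))
    sigma2 = 1 / (9 * beta * M**(1/3))

where ``M = alpha / beta`` is the gamma mean.  Solving that pair for ``M`` gives
the exact inverse map

    M = (mu / 2 + sqrt(mu**2 / 4 + sigma2))**3

which is applied to posterior and fiducial draws of ``(mu, sigma2)`` elsewhere
in the package.

An observation is treated as a zero if and only if it equals ``0.0`` exactly;
there is no epsilon thresholding (rain gauges and similar instruments report
true zeros).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "DeltaGammaParams",
    "SampleSummary",
    "NormalApproxParams",
    "FittedParams",
    "dg_cdf",
    "sample_delta_gamma",
    "summarize",
    "gamma_to_normal_approx",
    "normal_to_gamma_mean",
    "gamma_mean_wh",
    "population_mean",
    "fit_gamma_mle",
    "mle",
]


@dataclass(frozen=True)
class DeltaGammaParams:
    """Generative triple of a delta-gamma law.

    alpha : gamma shape (> 0, dimensionless)
    beta  : gamma rate (> 0, reciprocal measurement units)
    delta : probability of an exact zero (in [0, 1])
    """

    alpha: float
    beta: float
    delta: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be > 0, got {self.alpha}")
        if not (self.beta > 0):
            raise ValueError(f"beta must be > 0, got {self.beta}")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must be in [0, 1], got {self.delta}")

    @property
    def mean(self) -> float:
        """Population mean tau = (1 - delta) * alpha / beta."""
        return (1.0 - self.delta) * self.alpha / self.beta


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics of one sample on the cube-root scale.

    n         : total observation count
    n_zero    : count of exact zeros
    n_pos     : count of strictly positive observations
    cube_mean : mean of cube-rooted positives (``nan`` when n_pos == 0)
    cube_ss   : sum of squared deviations of cube-rooted positives
    """

    n: int
    n_zero: int
    n_pos: int
    cube_mean: float
    cube_ss: float

    def __post_init__(self) -> None:
        if self.n != self.n_zero + self.n_pos:
            raise ValueError("n must equal n_zero + n_pos")
        if self.cube_ss < 0:
            raise ValueError("cube_ss must be non-negative")

    @property
    def cube_var(self) -> float:
        """Sample variance s**2 of the cube-rooted positives (needs n_pos >= 2)."""
        if self.n_pos < 2:
            raise ValueError(
                f"cube_var requires at least 2 positive observations, have {self.n_pos}"
            )
        return self.cube_ss / (self.n_pos - 1)


@dataclass(frozen=True)
class NormalApproxParams:
    """Cube-root-scale location and variance of the normal approximation."""

    mu: float
    sigma2: float

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")


@dataclass(frozen=True)
class FittedParams:
    """Maximum-likelihood point estimates for a delta-gamma sample."""

    delta_hat: float
    alpha_hat: float
    beta_hat: float

    @property
    def tau_hat(self) -> float:
        return (1.0 - self.delta_hat) * self.alpha_hat / self.beta_hat


def dg_cdf(x, params: DeltaGammaParams):
    """Delta-gamma distribution function.

    Returns ``delta`` at x == 0 and ``delta + (1 - delta) * G(x; alpha, beta)``
    for x > 0, where G is the gamma CDF with shape alpha and rate beta.
    Accepts scalars or arrays; negative x raises.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("dg_cdf is defined on x >= 0 only")
    pos = params.delta + (1.0 - params.delta) * stats.gamma.cdf(
        x, a=params.alpha, scale=1.0 / params.beta
    )
    out = np.where(x > 0, pos, params.delta)
    return float(out) if out.ndim == 0 else out


def sample_delta_gamma(
    params: DeltaGammaParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` observations from DG(alpha, beta, delta).

    Each element is 0 with probability delta, otherwise a gamma(alpha, rate beta)
    deviate.  All randomness comes from ``rng``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    zero = rng.random(n) < params.delta
    g = rng.standard_gamma(params.alpha, size=n) / params.beta
    return np.where(zero, 0.0, g)


def _summarize_matrix(obs: np.ndarray):
    """Row-wise cube-root summaries of a (reps, n) observation matrix.

    Returns ``(n_zero, n_pos, cube_mean, cube_ss)`` as arrays; ``cube_mean`` is
    nan and ``cube_ss`` zero for rows with no positives.
    """
    pos = obs > 0
    n_pos = pos.sum(axis=-1)
    n_zero = obs.shape[-1] - n_pos
    y = np.where(pos, np.cbrt(obs), 0.0)
    s1 = y.sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ybar = np.where(n_pos > 0, s1 / np.maximum(n_pos, 1), np.nan)
    dev = np.where(pos, y - ybar[..., None], 0.0)
    ss = np.maximum((dev * dev).sum(axis=-1), 0.0)
    return n_zero, n_pos, ybar, ss


def summarize(observations) -> SampleSummary:
    """Compute counts and cube-root-scale statistics of one sample."""
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 1 or obs.size == 0:
        raise ValueError("observations must be a non-empty 1-D vector")
    if np.any(np.isnan(obs)):
        raise ValueError("observations contain missing values")
    if np.any(obs < 0):
        raise ValueError("observations must be non-negative")
    n_zero, n_pos, ybar, ss = _summarize_matrix(obs[None, :])
    return SampleSummary(
        n=obs.size,
        n_zero=int(n_zero[0]),
        n_pos=int(n_pos[0]),
        cube_mean=float(ybar[0]),
        cube_ss=float(ss[0]),
    )


def gamma_to_normal_approx(alpha: float, beta: float) -> NormalApproxParams:
    """Cube-root normal approximation of a gamma(alpha, rate beta) law."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    mu = (alpha / beta) ** (1.0 / 3.0) * (1.0 - 1.0 / (9.0 * alpha))
    sigma2 = 1.0 / (9.0 * alpha ** (1.0 / 3.0) * beta ** (2.0 / 3.0))
    return NormalApproxParams(mu=mu, sigma2=sigma2)


def gamma_mean_wh(mu, sigma2):
    """Gamma mean implied by cube-root-scale (mu, sigma2), array-aware.

    M = (mu/2 + sqrt(mu**2/4 + sigma2))**3.  Exact inverse of the
    Wilson-Hilferty parameter map; applied as printed for any real mu.
    """
    mu = np.asarray(mu, dtype=float)
    sigma2 = np.asarray(sigma2, dtype=float)
    root = 0.5 * mu + np.sqrt(0.25 * mu * mu + sigma2)
    return root**3


def normal_to_gamma_mean(approx: NormalApproxParams) -> float:
    """Scalar wrapper of :func:`gamma_mean_wh` over a parameter pair."""
    return float(gamma_mean_wh(approx.mu, approx.sigma2))


def population_mean(params: DeltaGammaParams) -> float:
    """Delta-gamma population mean tau = (1 - delta) * alpha / beta."""
    return params.mean


def fit_gamma_mle(positives, tol: float = 1e-10, maxiter: int = 100):
    """Gamma MLE (shape, rate) by Newton iteration on the digamma equation.

    Solves ``log(a) - psi(a) = log(mean(x)) - mean(log(x))`` starting from the
    method-of-moments shape estimate.  Requires >= 2 strictly positive values
    with nonzero spread.
    """
    x = np.asarray(positives, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("gamma MLE needs at least 2 positive observations")
    if np.any(x <= 0):
        raise ValueError("gamma MLE requires strictly positive observations")
    m = x.mean()
    v = x.var(ddof=1)
    if v <= 0:
        raise ValueError("gamma MLE requires observations with nonzero spread")
    s = np.log(m) - np.log(x).mean()
    a = m * m / v  # method-of-moments start
    for _ in range(maxiter):
        f = np.log(a) - special.digamma(a) - s
        fprime = 1.0 / a - special.polygamma(1, a)
        a_new = a - f / fprime
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) <= tol * max(1.0, abs(a)):
            a = a_new
            break
        a = a_new
    return float(a), float(a / m)


def mle(observations) -> FittedParams:
    """Maximum-likelihood fit of DG(alpha, beta, delta) to one sample.

    ``delta_hat = n_zero / n``; the gamma part is fit on the positives by
    :func:`fit_gamma_mle`.
    """
    obs = np.asarray(observations, dtype=float)
    summary = summarize(obs)
    if summary.n_pos < 2:
        raise ValueError(
            "MLE needs at least 2 positive observations, "
            f"have {summary.n_pos} of {summary.n}"
        )
    alpha_hat, beta_hat = fit_gamma_mle(obs[obs > 0])
    return FittedParams(
        delta_hat=summary.n_zero / summary.n,
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
    )
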