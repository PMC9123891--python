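"""Closed-form posterior sampling for the delta-gamma mean.

Under both priors the three blocks of the model are conditionally independent
given the data, so the joint posterior is sampled directly (no MCMC):

Jeffreys-rule prior (p(delta) prop. delta^(-1/2) (1-delta)^(1/2),
p(sigma2) prop. sigma^-3):

    delta  | x ~ Beta(n0 + 1/2, n1 + 3/2)
    sigma2 | x ~ InvGamma(n1 / 2, ss / 2)        (= ss / chi2_{n1})
    mu | sigma2, x ~ Normal(ybar, sigma2 / n1)

Uniform prior (p(delta), p(mu), p(sigma2) all prop. 1):

    delta  | x ~ Beta(n0 + 1, n1 + 1)
    sigma2 | x ~ InvGamma((n1 - 3) / 2, ss / 2)  (= ss / chi2_{n1 - 3}; needs n1 >= 4)
    mu | sigma2, x ~ Normal(ybar, sigma2 / n1)

where n0/n1 are the zero/positive counts, ybar the mean and ss the sum of
squared deviations of the cube-rooted positives.  Each mu draw is conditioned
on its own sigma2 draw (joint sampling).  A posterior draw of the mean is

    tau = (1 - delta) * (mu/2 + sqrt(mu**2/4 + sigma2))**3
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SampleSummary, gamma_mean_wh

__all__ = [
    "PosteriorDraws",
    "DegeneratePosteriorError",
    "ImproperPosteriorError",
    "draw_jeffreys",
    "draw_uniform",
    "tau_from_posterior",
    "psi_from_posteriors",
]

PRIORS = ("jeffreys", "uniform")


class DegeneratePosteriorError(ValueError):
    """The sample admits no proper posterior (no positives, or zero spread)."""


class ImproperPosteriorError(ValueError):
    """Uniform-prior variance posterior is improper (needs n_pos >= 4)."""


@dataclass(frozen=True)
class PosteriorDraws:
    """Paired Monte-Carlo draws of (mu, sigma2, delta) from one marginal posterior."""

    mu: np.ndarray
    sigma2: np.ndarray
    delta: np.ndarray
    prior: str

    def __post_init__(self) -> None:
        if not (len(self.mu) == len(self.sigma2) == len(self.delta)):
            raise ValueError("draw vectors must have equal length")
        if self.prior not in PRIORS:
            raise ValueError(f"prior must be one of {PRIORS}")

    def __len__(self) -> int:
        return len(self.mu)


def _check_summary(summary: SampleSummary, prior: str) -> None:
    if summary.n_pos == 0:
        raise DegeneratePosteriorError(
            "posterior for the mean is degenerate: the sample has no positive values"
        )
    if summary.cube_ss <= 0:
        raise DegeneratePosteriorError(
            "posterior for sigma2 is degenerate: cube-root positives have zero spread"
        )
    if prior == "uniform" and summary.n_pos <= 3:
        raise ImproperPosteriorError(
            "the uniform-prior posterior for sigma2 has inverse-gamma shape "
            f"(n_pos - 3)/2 = {(summary.n_pos - 3) / 2}, which is not positive; "
            f"need at least 4 positive observations, have {summary.n_pos}"
        )


def _beta_params(n_zero, n_pos, prior: str):
    if prior == "jeffreys":
        return n_zero + 0.5, n_pos + 1.5
    return n_zero + 1.0, n_pos + 1.0


def _posterior_matrices(n_zero, n_pos, cube_mean, cube_ss, prior, ndraws, rng):
    """Vectorized posterior draws for k samples at once.

    Inputs are (k,) arrays of summary statistics; returns (mu, sigma2, delta)
    each of shape (k, ndraws).  Preconditions are the caller's responsibility.
    """
    n_zero = np.asarray(n_zero, dtype=float)[:, None]
    n_pos = np.asarray(n_pos, dtype=float)[:, None]
    cube_mean = np.asarray(cube_mean, dtype=float)[:, None]
    cube_ss = np.asarray(cube_ss, dtype=float)[:, None]
    shape = (n_zero.shape[0], ndraws)

    a, b = _beta_params(n_zero, n_pos, prior)
    delta = rng.beta(a, b, size=shape)
    df = n_pos if prior == "jeffreys" else n_pos - 3.0
    sigma2 = cube_ss / rng.chisquare(df, size=shape)
    mu = cube_mean + np.sqrt(sigma2 / n_pos) * rng.standard_normal(shape)
    return mu, sigma2, delta


def _draw(summary: SampleSummary, prior: str, ndraws: int, rng) -> PosteriorDraws:
    _check_summary(summary, prior)
    if ndraws < 1:
        raise ValueError("ndraws must be >= 1")
    rng = np.random.default_rng(rng)
    mu, sigma2, delta = _posterior_matrices(
        [summary.n_zero], [summary.n_pos], [summary.cube_mean], [summary.cube_ss],
        prior, ndraws, rng,
    )
    return PosteriorDraws(mu=mu[0], sigma2=sigma2[0], delta=delta[0], prior=prior)


def draw_jeffreys(summary: SampleSummary, ndraws: int, rng) -> PosteriorDraws:
    """Sample (mu, sigma2, delta) from the Jeffreys-rule posterior."""
    return _draw(summary, "jeffreys", ndraws, rng)


def draw_uniform(summary: SampleSummary, ndraws: int, rng) -> PosteriorDraws:
    """Sample (mu, sigma2, delta) from the uniform-prior posterior."""
    return _draw(summary, "uniform", ndraws, rng)


def tau_from_posterior(draws: PosteriorDraws) -> np.ndarray:
    """Map posterior triples elementwise to delta-gamma mean draws."""
    return (1.0 - draws.delta) * gamma_mean_wh(draws.mu, draws.sigma2)


def psi_from_posteriors(draws_a: PosteriorDraws, draws_b: PosteriorDraws) -> np.ndarray:
    """Index-paired draws of the difference of means, tau(A) - tau(B)."""
    if len(draws_a) != len(draws_b):
        raise ValueError(
            f"draw counts differ: {len(draws_a)} vs {len(draws_b)}"
        )
    return tau_from_posterior(draws_a) - tau_from_posterior(draws_b)
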