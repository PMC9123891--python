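"""Fiducial (generalized pivotal) quantities for the delta-gamma mean.

For one sample with n1 cube-rooted positives of mean ybar and sum of squared
deviations ss = (n1 - 1) s**2, each fiducial draw shares one standard normal Z
and one chi-square deviate C with n1 - 1 degrees of freedom:

    F_sigma2 = ss / C
    F_mu     = ybar + Z / sqrt(C) * sqrt(ss / n1)
    F_M      = (F_mu/2 + sqrt(F_mu**2/4 + F_sigma2))**3
    F_1mdelta ~ 1/2 Beta(n1, n0 + 1) + 1/2 Beta(n1 + 1, n0)   (mixture)
    F_tau    = F_1mdelta * F_M

Sharing Z and C within a draw is the standard generalized-pivotal construction;
the joint law of (F_mu, F_sigma2) is what F_M depends on.  The half-half weights
of F_1mdelta are read as component selection by a fair coin.  When n0 == 0 the
second mixture component Beta(n1 + 1, 0) is improper and is taken as its weak
limit, a point mass at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import SampleSummary, gamma_mean_wh

__all__ = ["FiducialDraws", "draw_fiducial_single", "draw_fiducial_difference"]


@dataclass(frozen=True)
class FiducialDraws:
    """Paired fiducial draws for one sample."""

    fmu: np.ndarray
    fsigma2: np.ndarray
    f_one_minus_delta: np.ndarray
    ftau: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.fmu)
        if not (len(self.fsigma2) == len(self.f_one_minus_delta) == len(self.ftau) == n):
            raise ValueError("draw vectors must have equal length")

    def __len__(self) -> int:
        return len(self.fmu)


def _check_summary(summary: SampleSummary) -> None:
    if summary.n_pos == 0:
        raise ValueError("fiducial mean is undefined: the sample has no positive values")
    if summary.n_pos < 2:
        raise ValueError(
            "fiducial quantities need at least 2 positive observations, "
            f"have {summary.n_pos}"
        )
    if summary.cube_ss <= 0:
        raise ValueError("fiducial quantities require nonzero spread in the positives")


def _fiducial_matrices(n_zero, n_pos, cube_mean, cube_ss, ndraws, rng):
    """Vectorized fiducial draws for k samples at once.

    Inputs are (k,) arrays; returns (fmu, fsigma2, f_one_minus_delta) of shape
    (k, ndraws).  Z and the chi-square deviate are shared within each draw.
    """
    n_zero = np.asarray(n_zero, dtype=float)[:, None]
    n_pos = np.asarray(n_pos, dtype=float)[:, None]
    cube_mean = np.asarray(cube_mean, dtype=float)[:, None]
    cube_ss = np.asarray(cube_ss, dtype=float)[:, None]
    shape = (n_zero.shape[0], ndraws)

    chi2 = rng.chisquare(n_pos - 1.0, size=shape)
    z = rng.standard_normal(shape)
    fsigma2 = cube_ss / chi2
    fmu = cube_mean + z / np.sqrt(chi2) * np.sqrt(cube_ss / n_pos)

    comp1 = rng.beta(n_pos, n_zero + 1.0, size=shape)
    # Beta(n1 + 1, 0) is improper; substitute parameter 1 then overwrite with
    # the weak limit (point mass at 1) for rows with no zeros.
    comp2 = rng.beta(n_pos + 1.0, np.maximum(n_zero, 1.0), size=shape)
    comp2 = np.where(n_zero == 0, 1.0, comp2)
    coin = rng.random(shape) < 0.5
    f1md = np.where(coin, comp1, comp2)
    return fmu, fsigma2, f1md


def draw_fiducial_single(summary: SampleSummary, ndraws: int, rng) -> FiducialDraws:
    """Generate paired fiducial draws F_mu, F_sigma2, F_{1-delta}, F_tau."""
    _check_summary(summary)
    if ndraws < 1:
        raise ValueError("ndraws must be >= 1")
    rng = np.random.default_rng(rng)
    fmu, fsigma2, f1md = _fiducial_matrices(
        [summary.n_zero], [summary.n_pos], [summary.cube_mean], [summary.cube_ss],
        ndraws, rng,
    )
    ftau = f1md[0] * gamma_mean_wh(fmu[0], fsigma2[0])
    return FiducialDraws(
        fmu=fmu[0], fsigma2=fsigma2[0], f_one_minus_delta=f1md[0], ftau=ftau
    )


def draw_fiducial_difference(
    summary_a: SampleSummary,
    summary_b: SampleSummary,
    ndraws: int,
    rng_a,
    rng_b,
) -> np.ndarray:
    """Index-paired fiducial draws of psi = tau(A) - tau(B).

    Each sample consumes its own random stream so the construction is
    symmetric: swapping the samples (with their streams) negates every draw.
    """
    a = draw_fiducial_single(summary_a, ndraws, rng_a)
    b = draw_fiducial_single(summary_b, ndraws, rng_b)
    return a.ftau - b.ftau
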