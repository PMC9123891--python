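"""AIC-based adequacy check for the positive part of a zero-inflated sample.

Fits normal, lognormal, Cauchy and gamma laws to the strictly positive
observations by maximum likelihood and ranks them by

    AIC = -2 ln L + 2 k

with k = 2 parameters for every family (location/scale or shape/rate); the
family with the smallest AIC is flagged as best.  Normal and lognormal MLEs
are closed form; the gamma MLE is the package's Newton solver on the digamma
equation; the Cauchy MLE is found by direct numeric maximization started at
(median, IQR / 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import fit_gamma_mle

__all__ = ["FAMILIES", "FamilyFit", "AICTable", "aic", "fit_positive_families", "qq_pairs"]

FAMILIES = ("normal", "lognormal", "cauchy", "gamma")


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, -2 loglik + 2 k."""
    if k < 0:
        raise ValueError("k must be >= 0")
    return -2.0 * loglik + 2.0 * k


@dataclass(frozen=True)
class FamilyFit:
    """One family's ML fit: parameters, log-likelihood and AIC."""

    family: str
    params: tuple
    loglik: float
    k: int

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.k)


@dataclass(frozen=True)
class AICTable:
    """Per-family fits plus the AIC-best family."""

    fits: dict  # family -> FamilyFit

    @property
    def best(self) -> str:
        return min(self.fits.values(), key=lambda f: f.aic).family

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "family": f.family,
                "loglik": f.loglik,
                "k": f.k,
                "aic": f.aic,
                "best": f.family == self.best,
            }
            for f in self.fits.values()
        ]
        return pd.DataFrame(rows)


def _fit_normal(x: np.ndarray) -> FamilyFit:
    mu, sigma = x.mean(), x.std(ddof=0)
    ll = stats.norm.logpdf(x, loc=mu, scale=sigma).sum()
    return FamilyFit("normal", (mu, sigma), float(ll), 2)


def _fit_lognormal(x: np.ndarray) -> FamilyFit:
    logs = np.log(x)
    meanlog, sdlog = logs.mean(), logs.std(ddof=0)
    ll = stats.lognorm.logpdf(x, s=sdlog, scale=np.exp(meanlog)).sum()
    return FamilyFit("lognormal", (meanlog, sdlog), float(ll), 2)


def _fit_cauchy(x: np.ndarray) -> FamilyFit:
    loc0 = float(np.median(x))
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    scale0 = max(iqr / 2.0, 1e-8)
    loc, scale = stats.cauchy.fit(x, loc=loc0, scale=scale0)
    ll = stats.cauchy.logpdf(x, loc=loc, scale=scale).sum()
    return FamilyFit("cauchy", (loc, scale), float(ll), 2)


def _fit_gamma(x: np.ndarray) -> FamilyFit:
    shape, rate = fit_gamma_mle(x)
    ll = stats.gamma.logpdf(x, a=shape, scale=1.0 / rate).sum()
    return FamilyFit("gamma", (shape, rate), float(ll), 2)


_FITTERS = {
    "normal": _fit_normal,
    "lognormal": _fit_lognormal,
    "cauchy": _fit_cauchy,
    "gamma": _fit_gamma,
}


def fit_positive_families(values) -> AICTable:
    """ML-fit all four candidate families to strictly positive data."""
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("need at least 3 observations to compare families")
    if np.any(x <= 0):
        raise ValueError("values must be strictly positive (lognormal/gamma undefined)")
    if x.std(ddof=0) == 0:
        raise ValueError("values must have nonzero spread")
    return AICTable(fits={fam: _FITTERS[fam](x) for fam in FAMILIES})


def qq_pairs(values, family: str, table: AICTable | None = None) -> pd.DataFrame:
    """Theoretical-vs-empirical quantile pairs for one fitted family.

    Plotting positions are (i - 0.5) / n on the sorted data.  Rendering is left
    to the caller; the frame is ready to write as CSV.
    """
    x = np.sort(np.asarray(values, dtype=float))
    if table is None:
        table = fit_positive_families(x)
    fit = table.fits[family]
    p = (np.arange(1, x.size + 1) - 0.5) / x.size
    if family == "normal":
        theo = stats.norm.ppf(p, loc=fit.params[0], scale=fit.params[1])
    elif family == "lognormal":
        theo = stats.lognorm.ppf(p, s=fit.params[1], scale=np.exp(fit.params[0]))
    elif family == "cauchy":
        theo = stats.cauchy.ppf(p, loc=fit.params[0], scale=fit.params[1])
    elif family == "gamma":
        theo = stats.gamma.ppf(p, a=fit.params[0], scale=1.0 / fit.params[1])
    else:
        raise ValueError(f"unknown family {family!r}")
    return pd.DataFrame({"theoretical": theo, "empirical": x})
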