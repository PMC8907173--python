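"""Tweedie compound Poisson-gamma utilities.

For power ``1 < p < 2`` the Tweedie exponential-dispersion family is a
compound Poisson sum of gamma variables: it places positive probability
mass at zero while remaining continuous on the positive half-line, and
its variance follows the power law ``Var(Y) = phi * mu**p``.  Those two
properties make it the natural model for compositionality-corrected
metagenomic abundances, which are zero-inflated, right-skewed and
overdispersed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TweedieFit",
    "tweedie_zero_probability",
    "sample_tweedie",
    "compound_poisson_rate",
]


@dataclass(frozen=True)
class TweedieFit:
    """Result of a log-log mean/variance (Taylor's law) regression.

    Attributes
    ----------
    p : float
        Power parameter (the Taylor-law slope).  ``1 < p < 2`` is the
        zero-inflated regime; callers relying on the zero-mass formula
        must enforce that range.
    phi : float
        Dispersion, ``exp`` of the regression intercept.  Always > 0.
    slope_se, intercept_se : float
        OLS standard errors of slope and intercept.
    n_features_used : int
        Features with strictly positive mean and variance that entered
        the regression.
    """

    p: float
    phi: float
    slope_se: float
    intercept_se: float
    n_features_used: int


def compound_poisson_rate(mu, phi: float, p: float):
    """Poisson rate ``lambda = mu**(2-p) / (phi * (2-p))`` of the
    compound representation.  ``P(Y=0) = exp(-lambda)``."""
    mu = np.asarray(mu, dtype=float)
    _check_domain(mu, phi, p)
    return mu ** (2.0 - p) / (phi * (2.0 - p))


def tweedie_zero_probability(mu, phi: float, p: float):
    """Probability mass at zero of a Tweedie(mu, phi, p) variable.

    ``P(Y = 0) = exp(-mu**(2-p) / (phi * (2-p)))``, valid for
    ``1 < p < 2`` only.  Strictly decreasing in ``mu`` and strictly
    increasing in ``phi``.

    Parameters
    ----------
    mu : float or array-like
        Mean(s), strictly positive.
    phi : float
        Dispersion, strictly positive.
    p : float
        Power parameter in the open interval (1, 2).

    Returns
    -------
    float or ndarray in (0, 1)
    """
    lam = compound_poisson_rate(mu, phi, p)
    out = np.exp(-lam)
    return float(out) if np.ndim(out) == 0 else out


def sample_tweedie(mu, phi: float, p: float, rng: np.random.Generator, size=None):
    """Draw Tweedie variates via the compound Poisson-gamma construction.

    ``N ~ Poisson(lambda)`` with ``lambda = mu**(2-p)/(phi*(2-p))``;
    given ``N >= 1``, ``Y`` is a sum of ``N`` gamma variables with shape
    ``(2-p)/(p-1)`` and scale ``phi*(p-1)*mu**(p-1)``; ``N = 0`` gives
    ``Y = 0`` exactly.  The draw has mean ``mu`` and variance
    ``phi * mu**p``.

    Parameters
    ----------
    mu : float or array-like
        Mean(s); broadcast against ``size``.
    phi, p : float
        Dispersion (> 0) and power (1 < p < 2).
    rng : numpy.random.Generator
        Source of randomness; the only one used.
    size : optional
        Output shape; defaults to the broadcast shape of ``mu``.
    """
    mu = np.asarray(mu, dtype=float)
    _check_domain(mu, phi, p)
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    if size is None:
        size = lam.shape
    n = rng.poisson(np.broadcast_to(lam, size))
    shape = (2.0 - p) / (p - 1.0)
    scale = phi * (p - 1.0) * np.broadcast_to(mu, size) ** (p - 1.0)
    # Gamma(n*shape, scale) is the distribution of a sum of n iid
    # Gamma(shape, scale); rng.gamma(0) returns 0, matching N=0 -> Y=0.
    out = rng.gamma(n * shape, scale)
    return float(out) if np.ndim(out) == 0 else out


def _check_domain(mu, phi, p):
    if not (1.0 < p < 2.0):
        raise ValueError(
            f"Tweedie power p={p} outside (1, 2); the zero-mass compound "
            "Poisson-gamma form only holds there (p > 2 has no mass at zero)."
        )
    if phi <= 0:
        raise ValueError(f"dispersion phi={phi} must be > 0")
    if np.any(np.asarray(mu) <= 0):
        raise ValueError("mu must be strictly positive")
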