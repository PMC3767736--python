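"""Binomial-mixture observation layer for repeated spotlight counts.

Observed counts ``y_ijk`` (transect *i*, survey *j*, season *k*) are binomial
thinnings of a latent abundance ``N_ik`` with detection probability
``p_ijk``.  Detection is logit-linear in standardized transect length with
season-specific intercepts and per-survey Gaussian random errors:

    logit(p_ijk) = alpha_k + beta1 * TL_i + beta2 * TL_i**2 + delta_ijk
    delta_ijk ~ Normal(0, gamma)

Repeat surveys within a season (the closed secondary periods of a robust
design) are what make ``N`` and ``p`` separately identifiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

__all__ = [
    "DetectionParams",
    "standardize_lengths",
    "detection_prob",
    "observation_loglik",
    "binomial_loglik",
    "collapse_within_season",
    "mean_detection",
    "solve_alpha_for_mean_detection",
    "DegenerateInputError",
    "LatentStateError",
]


class DegenerateInputError(ValueError):
    """Input is formally valid but statistically degenerate (e.g. zero spread)."""


class LatentStateError(RuntimeError):
    """A latent-state configuration is impossible given the data (y > N).

    Raised so samplers can reject the offending proposal instead of crashing.
    """


@dataclass
class DetectionParams:
    """Parameters of the logit-linear detection model for one species.

    Parameters
    ----------
    alpha : array-like
        Season-specific logit intercepts, one per season.
    beta1, beta2 : float
        Linear and quadratic coefficients of standardized transect length.
    gamma : float
        Standard deviation of the survey-level random errors ``delta``.
    delta : ndarray, optional
        Realized random errors, one per transect x survey x season.  Only
        populated for simulated or fitted datasets; under the model
        ``delta ~ Normal(0, gamma)``.
    """

    alpha: np.ndarray
    beta1: float = 0.0
    beta2: float = 0.0
    gamma: float = 0.0
    delta: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.alpha = np.atleast_1d(np.asarray(self.alpha, dtype=float))
        if self.gamma < 0:
            raise ValueError(f"gamma must be >= 0, got {self.gamma}")


def standardize_lengths(lengths_km) -> np.ndarray:
    """Center and scale transect lengths to mean 0, sample SD 1 (ddof=1).

    Raises
    ------
    DegenerateInputError
        If all lengths are equal (the SD is zero or undefined).
    """
    x = np.asarray(lengths_km, dtype=float)
    vals = x[np.isfinite(x)]
    if vals.size < 2 or np.ptp(vals) == 0:
        raise DegenerateInputError(
            "transect lengths have no spread; standardization is undefined"
        )
    return (x - vals.mean()) / vals.std(ddof=1)


def detection_prob(alpha_k, beta1, beta2, tl_std, delta=0.0):
    """Per-survey detection probability on the probability scale.

    ``inverse-logit(alpha_k + beta1*tl + beta2*tl**2 + delta)``; finite
    inputs always map into the open interval (0, 1).
    """
    eta = np.asarray(alpha_k, dtype=float) + beta1 * np.asarray(tl_std) \
        + beta2 * np.square(tl_std) + delta
    return expit(eta)


def binomial_loglik(y, n, p):
    """Vectorized log Binomial(y | n, p) via gammaln; no support checks.

    ``p`` is clipped away from {0, 1} so saturated detection parameters
    degrade gracefully rather than producing NaN.
    """
    y = np.asarray(y, dtype=float)
    n = np.asarray(n, dtype=float)
    p = np.clip(np.asarray(p, dtype=float), 1e-12, 1 - 1e-12)
    with np.errstate(invalid="ignore"):
        return (
            gammaln(n + 1.0)
            - gammaln(y + 1.0)
            - gammaln(n - y + 1.0)
            + y * np.log(p)
            + (n - y) * np.log1p(-p)
        )


def observation_loglik(y, N, p) -> float:
    """Log-likelihood of one observed count given latent abundance.

    Missing counts (NaN) contribute 0.  A count exceeding the latent
    abundance raises :class:`LatentStateError`: inside a sampler this means
    the latent-abundance proposal must be rejected.
    """
    if y is None or (np.isscalar(y) and np.isnan(y)):
        return 0.0
    y = float(y)
    if not float(y).is_integer() or y < 0:
        raise ValueError(f"count must be a nonnegative integer, got {y}")
    if not 0 <= p <= 1:
        raise ValueError(f"detection probability must lie in [0, 1], got {p}")
    if y > N:
        raise LatentStateError(f"count {y} exceeds latent abundance {N}")
    return float(binomial_loglik(y, N, p))


def collapse_within_season(blocks):
    """Collapse multiple within-season visit-blocks to one count per species.

    When a transect was surveyed in more than one repeat-visit block within a
    single season, the retained per-season estimate for each species is the
    highest count that species attained over the blocks (a minimum-number-
    known-alive rule).  Species maxima are taken independently, so the result
    may mix blocks between species.

    Parameters
    ----------
    blocks : sequence
        One entry per visit-block, each a per-species tuple/array of counts
        (NaN allowed for missing).  Empty sequence returns None (a missing
        marker, not an error).

    Returns
    -------
    ndarray or None
        Per-species collapsed counts, or None for an empty season.
    """
    blocks = list(blocks)
    if not blocks:
        return None
    arr = np.asarray(blocks, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    if np.all(np.isnan(arr)):
        return None
    with np.errstate(invalid="ignore"):
        out = np.nanmax(arr, axis=0)
    return out


def mean_detection(alpha, beta1, beta2, gamma, tl_std, n_quad: int = 41):
    """E[p] marginal over delta ~ Normal(0, gamma), by Gauss-Hermite quadrature.

    Averaged over the supplied standardized transect lengths (and seasons if
    ``alpha`` is a vector).  Used both to summarize fitted detection and to
    calibrate the synthetic-data generator to a target species mean.
    """
    alpha = np.atleast_1d(np.asarray(alpha, dtype=float))
    tl = np.atleast_1d(np.asarray(tl_std, dtype=float))
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    w = weights / weights.sum()
    base = alpha[:, None] + beta1 * tl[None, :] + beta2 * tl[None, :] ** 2
    # shape (seasons, transects, quad nodes)
    eta = base[:, :, None] + gamma * nodes[None, None, :]
    return float(np.mean(expit(eta) @ w))


def solve_alpha_for_mean_detection(
    target, beta1, beta2, gamma, tl_std, lo=-10.0, hi=10.0
) -> float:
    """Find the common logit intercept giving a target species-mean detection.

    Inverts :func:`mean_detection` in its (monotone) intercept argument with
    Brent's method.
    """
    from scipy.optimize import brentq

    if not 0 < target < 1:
        raise ValueError("target mean detection must lie in (0, 1)")

    def f(a):
        return mean_detection(a, beta1, beta2, gamma, tl_std) - target

    return float(brentq(f, lo, hi, xtol=1e-10))
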