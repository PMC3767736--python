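"""Seasonal Gompertz state-space dynamics with a prey-to-predator coupling.

On the log scale the Gompertz model is the linear recursion

    log N_k = a_season(k) + b * log N_{k-1} + eps_k,   eps_k ~ Normal(0, sigma)

with a season-specific intercept (breeding vs non-breeding) and a single
density-dependence coefficient ``b`` shared across seasons.  ``b = 1`` is a
density-independent random walk, ``0 < b < 1`` negative density dependence,
``b < 0`` increasingly positive (boom-bust) density dependence.

For the predator the mean gains a numerical-response term
``c_season(k) * log Nprey_{k-1}``: predator abundance in one season responds
to prey abundance in the immediately preceding season.  Seasonal intercepts
and coupling coefficients are indexed by the season being *predicted* (the
destination step of the transition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BREEDING",
    "NONBREEDING",
    "ProcessParams",
    "gompertz_mean_prey",
    "gompertz_mean_predator",
    "process_loglik",
    "classify_density_dependence",
    "seasonal_fixed_point",
]

BREEDING = "breeding"
NONBREEDING = "nonbreeding"

_LOG_2PI = float(np.log(2.0 * np.pi))


def _check_season(season_type: str) -> str:
    if season_type not in (BREEDING, NONBREEDING):
        raise ValueError(
            f"season_type must be '{BREEDING}' or '{NONBREEDING}', got {season_type!r}"
        )
    return season_type


@dataclass
class ProcessParams:
    """Gompertz process parameters for one species.

    ``a_b``/``a_nb`` are the breeding/non-breeding intercepts, ``b`` the
    shared density-dependence coefficient and ``sigma`` the process-error SD.
    ``c_b``/``c_nb`` are the seasonal numerical-response coefficients on the
    log prey abundance of the previous season; they are meaningful for the
    predator only and default to 0 (decoupled dynamics).
    """

    a_b: float = 0.0
    a_nb: float = 0.0
    b: float = 1.0
    sigma: float = 0.0
    c_b: float = 0.0
    c_nb: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"sigma must be >= 0, got {self.sigma}")

    def a(self, season_type: str) -> float:
        return self.a_b if _check_season(season_type) == BREEDING else self.a_nb

    def c(self, season_type: str) -> float:
        return self.c_b if _check_season(season_type) == BREEDING else self.c_nb


def gompertz_mean_prey(logN_prev, season_type: str, params: ProcessParams):
    """Expected log abundance one step ahead for the prey (uncoupled) model.

    The intercept is chosen by the season being predicted (the current step).
    """
    return params.a(season_type) + params.b * np.asarray(logN_prev, dtype=float)


def gompertz_mean_predator(logN_prev, logPrey_prev, season_type: str,
                           params: ProcessParams):
    """Expected predator log abundance: Gompertz plus lagged-prey response.

    ``c_nb`` applies when predicting a non-breeding season from the preceding
    breeding season, and vice versa.
    """
    return (
        params.a(season_type)
        + params.b * np.asarray(logN_prev, dtype=float)
        + params.c(season_type) * np.asarray(logPrey_prev, dtype=float)
    )


def process_loglik(logN_curr, mean, sigma):
    """Normal log-density of the realized log abundance given its mean.

    ``sigma = 0`` makes the state equation deterministic and the density
    degenerate, which is rejected.
    """
    sigma = float(sigma)
    if sigma <= 0:
        raise ValueError("process error sigma must be > 0 for a proper density")
    z = (np.asarray(logN_curr, dtype=float) - np.asarray(mean, dtype=float)) / sigma
    return -0.5 * z * z - np.log(sigma) - 0.5 * _LOG_2PI


def classify_density_dependence(b: float) -> str:
    """Qualitative reading of the Gompertz coefficient.

    1 -> "none" (random walk); 0 < b < 1 -> "negative"; b < 0 -> "positive";
    anything else (b = 0 or b > 1) -> "other (b=...)".
    """
    b = float(b)
    if not np.isfinite(b):
        raise ValueError("b must be finite")
    if b == 1.0:
        return "none"
    if 0.0 < b < 1.0:
        return "negative"
    if b < 0.0:
        return "positive"
    return f"other (b={b:g})"


def seasonal_fixed_point(params: ProcessParams,
                         first_season: str = BREEDING) -> tuple[float, float]:
    """Fixed point of the deterministic two-season Gompertz cycle.

    Solves the 2-cycle linear system x_b = a_b + b*x_nb, x_nb = a_nb + b*x_b
    (requires |b| != 1).  Returns (x at first_season, x at the other season),
    i.e. the stationary log abundances visited in alternation.
    """
    b = params.b
    if abs(abs(b) - 1.0) < 1e-12:
        raise ValueError("two-season map has no unique fixed point when |b| = 1")
    x_b = (params.a_b + b * params.a_nb) / (1.0 - b * b)
    x_nb = (params.a_nb + b * params.a_b) / (1.0 - b * b)
    if _check_season(first_season) == BREEDING:
        return x_b, x_nb
    return x_nb, x_b
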