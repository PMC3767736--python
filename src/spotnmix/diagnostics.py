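"""Posterior summaries, convergence diagnostics and goodness-of-fit checks.

Implements the classic Gelman-Rubin potential scale reduction factor,
central credible intervals with the CI-overlap significance rule, the
chi-squared posterior-predictive Bayesian p-value, and per-km density
indices derived from latent abundance draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "gelman_rubin",
    "credible_interval",
    "is_significant",
    "bayesian_p_value",
    "density_index",
    "summarize",
    "FitSummary",
]


def gelman_rubin(chains) -> float:
    """Potential scale reduction factor (PSRF) for one parameter.

    For m chains of length n with within-chain variance W (mean of the
    per-chain sample variances) and between-chain variance
    B = n * Var(chain means), the pooled posterior-variance estimate is
    Vhat = (n-1)/n * W + B/n and the PSRF is sqrt(Vhat / W).  Values near 1
    indicate the chains have mixed; > ~1.1 is the usual warning level.
    """
    x = np.asarray(chains, dtype=float)
    if x.ndim != 2:
        raise ValueError("chains must be a 2-D (n_chains, n_draws) array")
    m, n = x.shape
    if m < 2:
        raise ValueError("at least 2 chains are required for the PSRF")
    if n < 10:
        raise ValueError("at least 10 retained draws per chain are required")
    means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0 if B == 0 else np.inf
    vhat = (n - 1) / n * W + B / n
    return float(np.sqrt(vhat / W))


def credible_interval(draws, level: float = 0.95) -> tuple[float, float]:
    """Central (equal-tailed) credible interval from posterior draws."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    x = np.asarray(draws, dtype=float).ravel()
    if x.size < 100:
        raise ValueError("at least 100 retained draws are required")
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(x, [tail, 1.0 - tail])
    return float(lo), float(hi)


def is_significant(interval, null_value: float = 0.0) -> bool:
    """CI-overlap decision rule: significant iff the CI excludes the null.

    The conventional null is 0; for the density-dependence coefficient the
    relevant null is 1 (no density dependence).
    """
    lo, hi = interval
    if lo > hi:
        raise ValueError("interval must satisfy lo <= hi")
    return bool(null_value < lo or null_value > hi)


# ---------------------------------------------------------------------------


def _flat_draws(results, species: str, max_draws: int | None = 2000):
    """Flatten chains and (optionally) thin to at most ``max_draws`` draws.

    Returns dict of per-draw arrays: alpha (n, K), beta1/beta2 (n,),
    N (n, I, K), delta (n, I, J, K).
    """
    if species not in results.latents:
        raise ValueError(f"no latent draws stored for species {species!r}")
    alpha = results.draws[f"{species}.alpha"]
    m, kept, K = alpha.shape
    n = m * kept
    sel = slice(None)
    if max_draws is not None and n > max_draws:
        stride = int(np.ceil(n / max_draws))
        sel = slice(0, None, stride)
    out = {
        "alpha": alpha.reshape(n, K)[sel],
        "beta1": results.draws[f"{species}.beta1"].reshape(n)[sel],
        "beta2": results.draws[f"{species}.beta2"].reshape(n)[sel],
        "N": results.latents[species]["N"].reshape((n,) + results.latents[species]["N"].shape[2:])[sel].astype(np.int64),
        "delta": results.latents[species]["delta"].reshape((n,) + results.latents[species]["delta"].shape[2:])[sel].astype(float),
    }
    return out


def detection_prob_draws(results, species: str, max_draws: int | None = 2000):
    """Per-draw detection probabilities p_ijk, shape (n, I, J, K)."""
    d = _flat_draws(results, species, max_draws)
    tl = results.meta["tl_std"]                     # (I, K)
    eta = (d["alpha"][:, None, None, :]
           + d["beta1"][:, None, None, None] * tl[None, :, None, :]
           + d["beta2"][:, None, None, None] * tl[None, :, None, :] ** 2
           + d["delta"])
    return expit(eta), d["N"]


def bayesian_p_value(results, species: str, seed: int | None = None,
                     eps: float = 0.5, max_draws: int | None = 2000) -> float:
    """Chi-squared posterior-predictive check.

    For each retained draw, the realized discrepancy
    D(y, theta) = sum (y - E)^2 / (E + eps) with E = N * p over non-missing
    cells is compared with the same discrepancy for one replicate dataset
    y_rep ~ Binomial(N, p) drawn from that posterior draw.  The returned
    p-value is the fraction of draws where the predicted discrepancy exceeds
    the realized one; ~0.5 under perfect fit, with (0.1, 0.9) the customary
    good-fit band.
    """
    y = results.data.y[species]
    mask = np.isfinite(y)
    if not mask.any():
        raise ValueError(f"no observed counts for species {species!r}")
    p, N = detection_prob_draws(results, species, max_draws)
    if p.shape[0] == 0:
        raise ValueError("no retained draws")
    if seed is None:
        seed = int(results.meta["seed"]) + 99_000
    rng = np.random.default_rng(seed)
    E = N[:, :, None, :] * p
    y0 = np.nan_to_num(y)[None]
    d_real = np.where(mask[None], (y0 - E) ** 2 / (E + eps), 0.0).sum(axis=(1, 2, 3))
    y_rep = rng.binomial(np.broadcast_to(N[:, :, None, :], p.shape), p)
    d_rep = np.where(mask[None], (y_rep - E) ** 2 / (E + eps), 0.0).sum(axis=(1, 2, 3))
    return float(np.mean(d_rep > d_real))


def density_index(N_draws, length_km):
    """Per-km density: latent abundance draws divided by transect length."""
    L = np.asarray(length_km, dtype=float)
    if np.any(L <= 0):
        raise ValueError("transect length must be positive")
    return np.asarray(N_draws, dtype=float) / L


@dataclass
class FitSummary:
    """Collated posterior summaries.

    ``parameters``: one row per scalar parameter with median, 95% CI, PSRF
    and the CI-rule significance flag (null 1 for density dependence, 0
    otherwise).  ``detection``: per-species mean/SD of posterior-mean
    per-survey detection across transect-survey-season cells.
    ``pvalues``: per-species chi-squared Bayesian p-value.  ``density``:
    per transect-season median density index (individuals per km).
    """

    parameters: pd.DataFrame
    detection: pd.DataFrame
    pvalues: dict
    density: pd.DataFrame

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = ["Posterior summary", "=" * 72,
                 self.parameters.to_string(index=False), "",
                 "Species-mean per-survey detection:",
                 self.detection.to_string(index=False), "",
                 "Bayesian p-values: "
                 + ", ".join(f"{s}={v:.3f}" for s, v in self.pvalues.items())]
        return "\n".join(lines)

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.parameters.to_csv(out / "parameters.csv", index=False)
        self.detection.to_csv(out / "detection.csv", index=False)
        pd.DataFrame([{"species": s, "bayesian_p": v}
                      for s, v in self.pvalues.items()]).to_csv(
            out / "pvalues.csv", index=False)
        self.density.to_csv(out / "density_by_transect_season.csv", index=False)


def summarize(results, level: float = 0.95, pvalue_seed: int | None = None,
              rhat_warn: float = 1.1) -> FitSummary:
    """Build a :class:`FitSummary` from fitted results.

    Warns (does not fail) when any PSRF exceeds ``rhat_warn``.
    """
    import warnings

    rows = []
    worst = 0.0
    for name in sorted(results.flat_params):
        x = results.get(name)
        lo, hi = credible_interval(x, level)
        rhat = gelman_rubin(x)
        worst = max(worst, rhat)
        null = 1.0 if name.endswith(".b") else 0.0
        rows.append({
            "parameter": name,
            "median": float(np.median(x)),
            "ci_lo": lo,
            "ci_hi": hi,
            "rhat": rhat,
            "null_value": null,
            "significant": is_significant((lo, hi), null),
        })
    if worst > rhat_warn:
        warnings.warn(
            f"largest PSRF = {worst:.3f} exceeds {rhat_warn}; chains may not "
            "have converged", RuntimeWarning, stacklevel=2)
    params = pd.DataFrame(rows)

    det_rows, pvals, dens_rows = [], {}, []
    for sp in results.species:
        mean_p, sd_p = results.mean_detection(sp)
        det_rows.append({"species": sp, "mean_detection": mean_p,
                         "sd_detection": sd_p})
        pvals[sp] = bayesian_p_value(results, sp, seed=pvalue_seed)
        dens = results.density_index(sp)
        dens_rows.append(dens.assign(species=sp))
    detection = pd.DataFrame(det_rows)
    density = pd.concat(dens_rows, ignore_index=True)
    return FitSummary(parameters=params, detection=detection, pvalues=pvals,
                      density=density)
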