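"""Metropolis-within-Gibbs sampler for the joint hierarchical model.

The posterior couples, per species, a binomial N-mixture observation layer
(latent abundances, logit-linear detection with survey random errors) to a
seasonal Gompertz state equation on the log abundance; the predator's state
equation additionally regresses on the prey's lagged log abundance, so the
two species are sampled jointly.

The latent state is the *continuous* log abundance ``x_ik``; the binomial
layer thins the integer abundance ``N = max(1, round(exp(x)))`` (the same
lognormal-rounding bridge the synthetic generator uses, so the fitted model
is exactly the generating process).  Update blocks per iteration and
species:

* latent ``x_ik``: Gaussian random-walk Metropolis, swept over seasons in an
  even/odd checkerboard so vectorized updates never touch interacting
  neighbours (transitions only couple adjacent seasons).
* season translations: a joint proposal shifting all of one season's log
  abundances by ``u`` while moving that season's detection intercept by
  ``-u`` — a move along the classic abundance-detection ridge of N-mixture
  models, without which the level mixes pathologically slowly.
* a global translation shifting every ``x`` by ``u`` with the Gompertz
  intercepts moved by ``(1-b)u`` (and the predator intercepts by ``-c_s u``
  when the prey is shifted), leaving the process likelihood exactly
  invariant; only the binomial layer, the season-0 prior and the parameter
  priors decide acceptance.
* survey errors ``delta_ijk``: elementwise Gaussian random-walk Metropolis.
* ``gamma`` and ``sigma``: conjugate inverse-gamma draws on the variance
  (flat prior on the SD, truncated at an upper bound).
* season intercepts ``alpha_k``: scalar Metropolis, vectorized across
  seasons (their likelihood contributions are disjoint).
* ``beta1``, ``beta2``: scalar Metropolis on the full dataset.
* Gompertz coefficients (a_b, a_nb, b and, for the predator, c_b, c_nb):
  joint conjugate Gaussian draw from the linear model on latent log
  abundances.

Proposal scales adapt toward standard acceptance targets during burn-in
only, so the retained chain is a valid (non-adaptive) Markov chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .data import CountData
from .process import BREEDING

__all__ = ["PriorConfig", "FitConfig", "run_mcmc"]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PriorConfig:
    """Vague priors for every top-level parameter (declared, not inherited).

    Gaussians with SD 10 on all regression-type coefficients, uniform on
    (0, upper) for the two error SDs, and a Normal(init_mu, init_sd) prior
    on the season-0 log abundance.  ``flat_init=True`` replaces the latter
    with a uniform prior on log N over the latent support — the neutral
    choice for single-season (closed N-mixture) fits.
    """

    sd_alpha: float = 10.0
    sd_beta: float = 10.0
    sd_a: float = 10.0
    sd_b: float = 10.0
    sd_c: float = 10.0
    gamma_max: float = 10.0
    sigma_max: float = 10.0
    init_mu: float = 0.0
    init_sd: float = 10.0
    flat_init: bool = False


@dataclass
class FitConfig:
    """MCMC settings.

    The default is a desk-scale run (3 chains x 20 000 iterations, half
    discarded, thinned by 5).  ``FitConfig.fullscale()`` gives the
    original survey analysis's schedule (3 x 420 000, 400 000 burn-in,
    thin 10).  ``fix`` maps parameter
    names (optionally species-qualified, e.g. ``"rabbit.beta1"`` or just
    ``"beta1"`` for every species) to constants excluded from sampling.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: int = 10_000
    thin: int = 5
    seed: int = 0
    priors: PriorConfig = field(default_factory=PriorConfig)
    nmax: int | None = None
    nmax_factor: float = 10.0
    nmax_floor: int = 30
    fix: dict = field(default_factory=dict)
    store_latent: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("at least 2 chains are required (convergence diagnostics)")
        if not 0 <= self.burn_in < self.n_iter:
            raise ValueError("burn_in must satisfy 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def fullscale(cls, **kw) -> "FitConfig":
        kw.setdefault("n_chains", 3)
        kw.setdefault("n_iter", 420_000)
        kw.setdefault("burn_in", 400_000)
        kw.setdefault("thin", 10)
        return cls(**kw)

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def _normal_logpdf(x, mu, sd):
    z = (x - mu) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def _p_part_ll(y, n, eta):
    """Binomial log-likelihood terms that depend on p only.

    The binomial coefficient cancels from Metropolis ratios in which the
    latent N and the data are held fixed, so detection-parameter updates can
    skip the gammaln terms:  y*log(p) + (n-y)*log(1-p) with
    log p = -log(1+e^-eta), log(1-p) = -log(1+e^eta) (numerically stable).
    """
    log_p = -np.logaddexp(0.0, -eta)
    log_q = -np.logaddexp(0.0, eta)
    return y * log_p + (n - y) * log_q


def _full_bin_ll(y, n, eta):
    """Masked-input binomial log-likelihood incl. coefficient; -inf if y > n."""
    with np.errstate(invalid="ignore"):
        out = (gammaln(n + 1.0) - gammaln(y + 1.0) - gammaln(n - y + 1.0)
               + _p_part_ll(y, n, eta))
    return np.where(y <= n, out, -np.inf)


def _trunc_invgamma_sd(rng, shape, scale, upper, current):
    """Draw an SD whose square is InvGamma(shape, scale), truncated at upper.

    Falls back to the current value if repeated draws land above the bound
    (only happens when the posterior mass sits against it).
    """
    if shape <= 0 or scale <= 0:
        return current
    for _ in range(50):
        v = scale / rng.gamma(shape)
        sd = float(np.sqrt(v))
        if sd < upper:
            return sd
    return current


def _round_abund(x):
    return np.maximum(1.0, np.rint(np.exp(x)))


class _SpeciesBlock:
    """Mutable sampler state for one species within one chain."""

    def __init__(self, name, y, tl_std, season_is_b, cfg: FitConfig,
                 is_predator: bool, rng):
        self.name = name
        self.cfg = cfg
        self.pri = cfg.priors
        self.y = y                                   # (I, J, K) with NaN
        self.mask = np.isfinite(y)                   # (I, J, K)
        self.cell_mask = self.mask.any(axis=1)       # (I, K)
        self.y0 = np.nan_to_num(y)
        self.tl = tl_std                             # (I, K)
        self.season_is_b = season_is_b               # (K,) bool
        self.is_predator = is_predator
        I, J, K = y.shape
        self.I, self.J, self.K = I, J, K

        ymax_cell = np.where(self.cell_mask,
                             np.max(np.where(self.mask, y, 0.0), axis=1), 0.0)
        per_transect_max = ymax_cell.max(axis=1)
        if cfg.nmax is not None:
            nmax = np.full(I, int(cfg.nmax), dtype=np.int64)
            if np.any(per_transect_max > cfg.nmax):
                raise ValueError("an observed count exceeds the configured Nmax")
        else:
            nmax = np.maximum(np.ceil(cfg.nmax_factor * per_transect_max),
                              cfg.nmax_floor).astype(np.int64)
        # bounds on the continuous log-abundance state
        self.x_hi = np.log(np.repeat(nmax[:, None], K, axis=1) + 0.49)
        self.x_lo = np.log(np.where(ymax_cell > 0, ymax_cell - 0.49, 0.5))

        fx = {}
        for key, val in cfg.fix.items():
            if "." in key:
                sp, par = key.split(".", 1)
                if sp != name:
                    continue
            else:
                par = key
            fx[par] = float(val)
        self.fixed = fx

        # --- initial values: mildly overdispersed across chains ---
        p_guess = rng.uniform(0.3, 0.8)
        self.alpha = (np.log(p_guess / (1 - p_guess))
                      + 0.3 * rng.standard_normal(K))
        self.beta1 = 0.2 * rng.standard_normal()
        self.beta2 = 0.2 * rng.standard_normal()
        self.gamma = rng.uniform(0.2, 1.0)
        self.delta = np.zeros((I, J, K))
        self.a_b = 0.5 * rng.standard_normal()
        self.a_nb = 0.5 * rng.standard_normal()
        self.b = rng.uniform(0.2, 1.1)
        self.sigma = rng.uniform(0.2, 1.0)
        self.c_b = 0.3 * rng.standard_normal() if is_predator else 0.0
        self.c_nb = 0.3 * rng.standard_normal() if is_predator else 0.0
        for par, val in fx.items():
            if par == "alpha":
                self.alpha[:] = val
            elif hasattr(self, par):
                setattr(self, par, val)
        if self.gamma == 0:
            self.delta[:] = 0.0

        n_init = np.maximum(ymax_cell / p_guess, 1.0)
        fill = float(np.median(n_init[self.cell_mask])) if self.cell_mask.any() else 5.0
        n_init = np.where(self.cell_mask, n_init, max(fill, 2.0))
        self.x = np.clip(np.log(n_init), self.x_lo, self.x_hi)

        # proposal scales (adapted during burn-in only)
        self.s_alpha = np.full(K, 0.3)
        self.s_beta = np.array([0.1, 0.1])
        self.s_delta = 0.6
        self.s_x = 0.3
        self.s_trans = np.full(K, 0.2)
        self.s_glob = 0.1
        self.s_lgam = 0.4
        self._acc = {"alpha": np.zeros(K), "beta": np.zeros(2), "delta": 0.0,
                     "x": 0.0, "trans": np.zeros(K), "glob": 0.0, "lgam": 0.0}
        self._try = {"alpha": np.zeros(K), "beta": np.zeros(2), "delta": 0.0,
                     "x": 0.0, "trans": np.zeros(K), "glob": 0.0, "lgam": 0.0}

    # ---------- likelihood pieces ----------

    @property
    def N(self):
        return _round_abund(self.x)

    def eta_base(self):
        return (self.alpha[None, None, :] + self.beta1 * self.tl[:, None, :]
                + self.beta2 * self.tl[:, None, :] ** 2)

    def obs_ll(self, n=None, eta=None):
        """Masked per-cell binomial log-likelihood, shape (I, J, K)."""
        if n is None:
            n = self.N[:, None, :]
        if eta is None:
            eta = self.eta_base() + self.delta
        return np.where(self.mask, _full_bin_ll(self.y0, n, eta), 0.0)

    def init_logprior(self, x0):
        if self.pri.flat_init:
            return np.zeros_like(x0)
        return _normal_logpdf(x0, self.pri.init_mu, self.pri.init_sd)

    def _a_vec(self, k_idx):
        return np.where(self.season_is_b[k_idx], self.a_b, self.a_nb)

    def _c_vec(self, k_idx):
        return np.where(self.season_is_b[k_idx], self.c_b, self.c_nb)

    def trans_mean(self, x_prev, k_idx, x_prey_prev=None):
        """Gompertz mean for destination seasons ``k_idx`` (array)."""
        mu = self._a_vec(k_idx)[None, :] + self.b * x_prev
        if self.is_predator:
            mu = mu + self._c_vec(k_idx)[None, :] * x_prey_prev
        return mu

    # ---------- latent-state updates ----------

    def _latent_delta_ll(self, ks, x_new, x_old, prey_block, predator_block):
        """Log-ratio terms from changing x at seasons ``ks`` (shape (I, |ks|))."""
        K = self.K
        d = np.zeros_like(x_new)
        n_new = _round_abund(x_new)[:, None, :]
        n_old = _round_abund(x_old)[:, None, :]
        eta = (self.eta_base() + self.delta)[:, :, ks]
        y = self.y0[:, :, ks]
        m = self.mask[:, :, ks]
        with np.errstate(invalid="ignore"):
            d += np.where(m, _full_bin_ll(y, n_new, eta) - _full_bin_ll(y, n_old, eta),
                          0.0).sum(axis=1)
        first = ks == 0
        if first.any():
            d[:, first] += (self.init_logprior(x_new[:, first])
                            - self.init_logprior(x_old[:, first]))
        inner = ks > 0
        if self.sigma > 0 and inner.any():
            kk = ks[inner]
            prev = self.x[:, kk - 1]
            xp = prey_block.x[:, kk - 1] if self.is_predator else None
            mu = self.trans_mean(prev, kk, xp)
            d[:, inner] += (_normal_logpdf(x_new[:, inner], mu, self.sigma)
                            - _normal_logpdf(x_old[:, inner], mu, self.sigma))
        fwd = ks < K - 1
        if self.sigma > 0 and fwd.any():
            kk = ks[fwd]
            nxt = self.x[:, kk + 1]
            xp = prey_block.x[:, kk] if self.is_predator else None
            mu_new = self.trans_mean(x_new[:, fwd], kk + 1, xp)
            mu_old = self.trans_mean(x_old[:, fwd], kk + 1, xp)
            d[:, fwd] += (_normal_logpdf(nxt, mu_new, self.sigma)
                          - _normal_logpdf(nxt, mu_old, self.sigma))
        if predator_block is not None and predator_block.sigma > 0 and fwd.any():
            # prey log abundance feeds the predator's next-season mean
            kk = ks[fwd]
            pb = predator_block
            nxt = pb.x[:, kk + 1]
            mu_new = pb.trans_mean(pb.x[:, kk], kk + 1, x_new[:, fwd])
            mu_old = pb.trans_mean(pb.x[:, kk], kk + 1, x_old[:, fwd])
            d[:, fwd] += (_normal_logpdf(nxt, mu_new, pb.sigma)
                          - _normal_logpdf(nxt, mu_old, pb.sigma))
        return d

    def update_x(self, rng, prey_block=None, predator_block=None):
        """Checkerboard sweep of per-cell random-walk updates."""
        for parity in (0, 1):
            ks = np.arange(parity, self.K, 2)
            if ks.size == 0:
                continue
            cur = self.x[:, ks]
            prop = cur + self.s_x * rng.standard_normal(cur.shape)
            ok = (prop >= self.x_lo[:, ks]) & (prop <= self.x_hi[:, ks])
            d = self._latent_delta_ll(ks, prop, cur, prey_block, predator_block)
            logr = np.where(ok, d, -np.inf)
            acc = np.log(rng.random(cur.shape)) < logr
            self.x[:, ks] = np.where(acc, prop, cur)
            self._acc["x"] += acc.sum()
            self._try["x"] += acc.size

    def update_season_translation(self, rng, prey_block=None,
                                  predator_block=None):
        """Shift one season's log abundances by u and its alpha_k by -u.

        Moves along the abundance-detection ridge.  Skipped when the
        detection intercepts are fixed (nothing to compensate with).
        """
        if "alpha" in self.fixed:
            return
        for parity in (0, 1):
            ks = np.arange(parity, self.K, 2)
            if ks.size == 0:
                continue
            u = self.s_trans[ks] * rng.standard_normal(ks.size)
            cur = self.x[:, ks]
            prop = cur + u[None, :]
            ok = ((prop >= self.x_lo[:, ks]) & (prop <= self.x_hi[:, ks])).all(axis=0)
            d = self._latent_delta_ll(ks, prop, cur, prey_block, predator_block)
            # the binomial part inside d used the *old* alpha; correct the
            # observation term by recomputing with the shifted intercept
            n_new = _round_abund(prop)[:, None, :]
            eta_old = (self.eta_base() + self.delta)[:, :, ks]
            y = self.y0[:, :, ks]
            m = self.mask[:, :, ks]
            with np.errstate(invalid="ignore"):
                d_alpha = np.where(
                    m, _full_bin_ll(y, n_new, eta_old - u[None, None, :])
                    - _full_bin_ll(y, n_new, eta_old), 0.0)
            logr = d.sum(axis=0) + d_alpha.sum(axis=(0, 1))
            a_new = self.alpha[ks] - u
            logr += (_normal_logpdf(a_new, 0.0, self.pri.sd_alpha)
                     - _normal_logpdf(self.alpha[ks], 0.0, self.pri.sd_alpha))
            acc = ok & (np.log(rng.random(ks.size)) < logr)
            if acc.any():
                sel = ks[acc]
                self.x[:, sel] += u[acc][None, :]
                self.alpha[sel] -= u[acc]
            self._acc["trans"][ks] += acc
            self._try["trans"][ks] += 1

    def update_global_translation(self, rng, predator_block=None):
        """Shift every x by u, compensating intercepts so the process part is
        exactly invariant: a_s -> a_s + (1-b) u, alpha_k -> alpha_k - u, and
        (when a predator is coupled to this prey) the predator's
        a_s -> a_s - c_s u.  A unit-Jacobian shear proposal, so the
        acceptance ratio involves only the binomial layer, the season-0
        prior and the parameter priors.
        """
        if self.K < 2 or "alpha" in self.fixed or "a_b" in self.fixed \
                or "a_nb" in self.fixed:
            return
        if predator_block is not None and (
                "a_b" in predator_block.fixed or "a_nb" in predator_block.fixed):
            return
        u = self.s_glob * rng.standard_normal()
        prop = self.x + u
        if np.any(prop < self.x_lo) or np.any(prop > self.x_hi):
            return
        n_new = _round_abund(prop)[:, None, :]
        eta_new = self.eta_base() + self.delta - u
        logr = (self.obs_ll(n=n_new, eta=eta_new) - self.obs_ll()).sum()
        logr += (self.init_logprior(prop[:, 0]) - self.init_logprior(self.x[:, 0])).sum()
        a_new = np.array([self.a_b + (1 - self.b) * u,
                          self.a_nb + (1 - self.b) * u])
        a_old = np.array([self.a_b, self.a_nb])
        logr += (_normal_logpdf(a_new, 0.0, self.pri.sd_a)
                 - _normal_logpdf(a_old, 0.0, self.pri.sd_a)).sum()
        al_new = self.alpha - u
        logr += (_normal_logpdf(al_new, 0.0, self.pri.sd_alpha)
                 - _normal_logpdf(self.alpha, 0.0, self.pri.sd_alpha)).sum()
        if predator_block is not None:
            pb = predator_block
            pa_new = np.array([pb.a_b - pb.c_b * u, pb.a_nb - pb.c_nb * u])
            pa_old = np.array([pb.a_b, pb.a_nb])
            logr += (_normal_logpdf(pa_new, 0.0, pb.pri.sd_a)
                     - _normal_logpdf(pa_old, 0.0, pb.pri.sd_a)).sum()
        if np.log(rng.random()) < logr:
            self.x = prop
            self.alpha = al_new
            self.a_b, self.a_nb = float(a_new[0]), float(a_new[1])
            if predator_block is not None:
                predator_block.a_b = float(pa_new[0])
                predator_block.a_nb = float(pa_new[1])
            self._acc["glob"] += 1
        self._try["glob"] += 1

    # ---------- detection updates ----------

    def update_delta(self, rng):
        if self.gamma <= 0:
            return
        prop = self.delta + self.s_delta * rng.standard_normal(self.delta.shape)
        base = self.eta_base()
        n = self.N[:, None, :]
        d_ll = (_p_part_ll(self.y0, n, base + prop)
                - _p_part_ll(self.y0, n, base + self.delta))
        g2 = self.gamma ** 2
        logr = d_ll - 0.5 * (prop ** 2 - self.delta ** 2) / g2
        acc = (np.log(rng.random(prop.shape)) < logr) & self.mask
        self.delta = np.where(acc, prop, self.delta)
        self._acc["delta"] += acc.sum()
        self._try["delta"] += self.mask.sum()

    def update_gamma(self, rng):
        """Ancillarity-sufficiency interweaving for the survey-error SD.

        A conjugate draw in the centered parameterization (gamma | delta)
        followed by a log-scale Metropolis step in the non-centered one
        (gamma | z = delta/gamma, rescaling delta), which escapes the
        gamma -> 0 funnel that traps a purely centered sampler.
        """
        if "gamma" in self.fixed or self.gamma <= 0:
            return
        d = self.delta[self.mask]
        self.gamma = _trunc_invgamma_sd(
            rng, (d.size - 1) / 2.0, float(d @ d) / 2.0,
            self.pri.gamma_max, self.gamma)
        # non-centered leg: z fixed, gamma' = gamma * e^v, delta' = gamma' z;
        # repeated a few times — the move is cheap and gamma is the slowest
        # direction of the posterior
        base = self.eta_base()
        n = self.N[:, None, :]
        for _ in range(3):
            v = self.s_lgam * rng.standard_normal()
            gam_new = self.gamma * np.exp(v)
            if gam_new < self.pri.gamma_max:
                scale = gam_new / self.gamma
                d_cells = (_p_part_ll(self.y0, n, base + self.delta * scale)
                           - _p_part_ll(self.y0, n, base + self.delta))
                # flat prior on gamma; log-RW proposal asymmetry adds +v
                logr = np.where(self.mask, d_cells, 0.0).sum() + v
                if np.log(rng.random()) < logr:
                    self.delta = self.delta * scale
                    self.gamma = float(gam_new)
                    self._acc["lgam"] += 1
            self._try["lgam"] += 1

    def update_alpha(self, rng):
        if "alpha" in self.fixed:
            return
        step = self.s_alpha * rng.standard_normal(self.K)
        eta_old = self.eta_base() + self.delta
        n = self.N[:, None, :]
        d_cells = (_p_part_ll(self.y0, n, eta_old + step[None, None, :])
                   - _p_part_ll(self.y0, n, eta_old))
        d_ll = np.where(self.mask, d_cells, 0.0).sum(axis=(0, 1))
        prop = self.alpha + step
        d_pri = (_normal_logpdf(prop, 0.0, self.pri.sd_alpha)
                 - _normal_logpdf(self.alpha, 0.0, self.pri.sd_alpha))
        acc = np.log(rng.random(self.K)) < d_ll + d_pri
        self.alpha = np.where(acc, prop, self.alpha)
        self._acc["alpha"] += acc
        self._try["alpha"] += 1

    def update_beta(self, rng):
        n = self.N[:, None, :]
        covs = {"beta1": self.tl[:, None, :],
                "beta2": self.tl[:, None, :] ** 2}
        for idx, par in enumerate(("beta1", "beta2")):
            if par in self.fixed:
                continue
            cur = getattr(self, par)
            step = self.s_beta[idx] * rng.standard_normal()
            eta_old = self.eta_base() + self.delta
            d_cells = (_p_part_ll(self.y0, n, eta_old + step * covs[par])
                       - _p_part_ll(self.y0, n, eta_old))
            d_ll = np.where(self.mask, d_cells, 0.0).sum()
            d_pri = (_normal_logpdf(cur + step, 0.0, self.pri.sd_beta)
                     - _normal_logpdf(cur, 0.0, self.pri.sd_beta))
            if np.log(rng.random()) < d_ll + d_pri:
                setattr(self, par, cur + step)
                self._acc["beta"][idx] += 1
            self._try["beta"][idx] += 1

    # ---------- process updates ----------

    def update_process(self, rng, prey_block=None):
        """Conjugate Gaussian draw for the Gompertz coefficients, then sigma."""
        if self.K < 2 or self.sigma <= 0:
            return
        ks = np.arange(1, self.K)
        x = self.x[:, ks].ravel()
        prev = self.x[:, ks - 1].ravel()
        is_b = np.repeat(self.season_is_b[ks][None, :], self.I, axis=0).ravel()
        cols, names, prior_sd = [], [], []
        cols.append(is_b.astype(float));          names.append("a_b")
        cols.append((~is_b).astype(float));       names.append("a_nb")
        cols.append(prev);                        names.append("b")
        prior_sd += [self.pri.sd_a, self.pri.sd_a, self.pri.sd_b]
        if self.is_predator:
            lp = prey_block.x[:, ks - 1].ravel()
            cols.append(lp * is_b);               names.append("c_b")
            cols.append(lp * (~is_b));            names.append("c_nb")
            prior_sd += [self.pri.sd_c, self.pri.sd_c]
        X = np.column_stack(cols)
        offset = np.zeros_like(x)
        free = []
        for j, nm in enumerate(names):
            if nm in self.fixed:
                offset += self.fixed[nm] * X[:, j]
            else:
                free.append(j)
        resp = x - offset
        if free:
            Xf = X[:, free]
            psd = np.array([prior_sd[j] for j in free])
            prec = Xf.T @ Xf / self.sigma ** 2 + np.diag(1.0 / psd ** 2)
            chol = np.linalg.cholesky(prec)
            rhs = Xf.T @ resp / self.sigma ** 2
            mean = np.linalg.solve(prec, rhs)
            z = rng.standard_normal(len(free))
            theta = mean + np.linalg.solve(chol.T, z)
            for val, j in zip(theta, free):
                setattr(self, names[j], float(val))
        if "sigma" not in self.fixed:
            beta_now = np.array([getattr(self, nm) for nm in names])
            resid = x - X @ beta_now
            self.sigma = _trunc_invgamma_sd(
                rng, (resid.size - 1) / 2.0, float(resid @ resid) / 2.0,
                self.pri.sigma_max, self.sigma)

    # ---------- burn-in adaptation ----------

    def adapt(self):
        def tune(scale, rate, target):
            return np.clip(scale * np.exp(rate - target), 1e-3, 25.0)

        if np.all(self._try["alpha"] > 0):
            self.s_alpha = tune(self.s_alpha,
                                self._acc["alpha"] / self._try["alpha"], 0.44)
        if np.all(self._try["beta"] > 0):
            self.s_beta = tune(self.s_beta,
                               self._acc["beta"] / self._try["beta"], 0.44)
        if self._try["delta"] > 0:
            self.s_delta = float(tune(self.s_delta,
                                      self._acc["delta"] / self._try["delta"], 0.44))
        if self._try["x"] > 0:
            self.s_x = float(tune(self.s_x, self._acc["x"] / self._try["x"], 0.44))
        if np.all(self._try["trans"] > 0):
            self.s_trans = tune(self.s_trans,
                                self._acc["trans"] / self._try["trans"], 0.3)
        if self._try["glob"] > 0:
            self.s_glob = float(tune(self.s_glob,
                                     self._acc["glob"] / self._try["glob"], 0.3))
        if self._try["lgam"] > 0:
            self.s_lgam = float(tune(self.s_lgam,
                                     self._acc["lgam"] / self._try["lgam"], 0.44))
        for key in self._acc:
            self._acc[key] = np.zeros_like(self._acc[key])
            self._try[key] = np.zeros_like(self._try[key])

    def scalar_state(self) -> dict:
        out = {"gamma": self.gamma, "beta1": self.beta1, "beta2": self.beta2,
               "a_b": self.a_b, "a_nb": self.a_nb, "b": self.b,
               "sigma": self.sigma}
        if self.is_predator:
            out["c_b"] = self.c_b
            out["c_nb"] = self.c_nb
        return out


def _standardized_lengths(data: CountData, need_lengths: bool) -> np.ndarray:
    L = data.lengths_km
    obs = data.obs_mask
    vals = L[obs & np.isfinite(L)]
    if not need_lengths or vals.size < 2 or np.ptp(vals) == 0:
        return np.zeros_like(L)
    mu, sd = vals.mean(), vals.std(ddof=1)
    return (L - mu) / sd


def run_mcmc(data: CountData, cfg: FitConfig, prey: str, predator: str | None):
    """Run all chains; return (draws, latents, meta).

    ``draws`` maps parameter names (``"<species>.<param>"``) to arrays of
    shape (chains, kept) or (chains, kept, K) for the season intercepts;
    ``latents`` maps species to dicts with ``N`` (chains, kept, I, K) and
    ``delta`` (chains, kept, I, J, K) float32 arrays.
    """
    species = [prey] + ([predator] if predator else [])
    for s in species:
        ys = data.y[s]
        vals = ys[np.isfinite(ys)]
        if np.any(vals < 0) or np.any(vals != np.rint(vals)):
            raise ValueError("counts must be nonnegative integers")
    season_is_b = np.array([st == BREEDING for st in data.season_type])
    both_beta_fixed = all(
        any(k in cfg.fix for k in (f"{s}.beta1", "beta1")) and
        any(k in cfg.fix for k in (f"{s}.beta2", "beta2"))
        for s in species)
    tl_std = _standardized_lengths(data, need_lengths=not both_beta_fixed)

    kept = cfg.n_kept
    if kept < 1:
        raise ValueError("no retained iterations: increase n_iter or reduce burn_in/thin")
    K = data.n_seasons
    draws: dict[str, np.ndarray] = {}
    for s in species:
        draws[f"{s}.alpha"] = np.empty((cfg.n_chains, kept, K))
        for par in ("beta1", "beta2", "gamma", "a_b", "a_nb", "b", "sigma"):
            draws[f"{s}.{par}"] = np.empty((cfg.n_chains, kept))
        if predator and s == predator:
            draws[f"{s}.c_b"] = np.empty((cfg.n_chains, kept))
            draws[f"{s}.c_nb"] = np.empty((cfg.n_chains, kept))
    latents: dict[str, dict] = {}
    if cfg.store_latent:
        I, J = data.n_transects, data.n_surveys
        for s in species:
            latents[s] = {
                "N": np.empty((cfg.n_chains, kept, I, K), dtype=np.float32),
                "delta": np.empty((cfg.n_chains, kept, I, J, K), dtype=np.float32),
            }

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng(cfg.seed + chain)
        blocks = {
            s: _SpeciesBlock(s, data.y[s], tl_std, season_is_b, cfg,
                             is_predator=(s == predator), rng=rng)
            for s in species
        }
        prey_blk = blocks[prey]
        pred_blk = blocks[predator] if predator else None
        idx = 0
        for it in range(cfg.n_iter):
            prey_blk.update_x(rng, predator_block=pred_blk)
            prey_blk.update_season_translation(rng, predator_block=pred_blk)
            prey_blk.update_global_translation(rng, predator_block=pred_blk)
            if pred_blk is not None:
                pred_blk.update_x(rng, prey_block=prey_blk)
                pred_blk.update_season_translation(rng, prey_block=prey_blk)
                pred_blk.update_global_translation(rng)
            for s in species:
                blk = blocks[s]
                blk.update_delta(rng)
                blk.update_gamma(rng)
                blk.update_alpha(rng)
                blk.update_beta(rng)
                blk.update_process(rng, prey_block=prey_blk)
            if it < cfg.burn_in:
                if (it + 1) % 200 == 0:
                    for blk in blocks.values():
                        blk.adapt()
                continue
            if (it - cfg.burn_in) % cfg.thin == 0 and idx < kept:
                for s, blk in blocks.items():
                    draws[f"{s}.alpha"][chain, idx] = blk.alpha
                    for par, val in blk.scalar_state().items():
                        draws[f"{s}.{par}"][chain, idx] = val
                    if cfg.store_latent:
                        latents[s]["N"][chain, idx] = blk.N
                        latents[s]["delta"][chain, idx] = blk.delta
                idx += 1

    meta = {
        "n_chains": cfg.n_chains, "n_iter": cfg.n_iter, "burn_in": cfg.burn_in,
        "thin": cfg.thin, "seed": cfg.seed, "n_kept": kept,
        "species": species, "prey": prey, "predator": predator,
        "tl_std": tl_std,
    }
    return draws, latents, meta
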