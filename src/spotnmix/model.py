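"""Model and Results objects for the predator-prey spotlight-count analysis.

:class:`NumericalResponseModel` binds a robust-design count dataset to the
joint hierarchical model — a binomial N-mixture observation layer per
species on top of seasonal Gompertz state-space dynamics, with the
predator's dynamics regressed on lagged prey log abundance.  ``fit()`` runs
the MCMC sampler and returns a :class:`NumericalResponseResults` carrying
posterior draws, convergence diagnostics, significance calls and
goodness-of-fit checks.

Example
-------
>>> from spotnmix import synthetic, NumericalResponseModel
>>> design = synthetic.make_survey_design(30, 12, 23.1, 5.9, 0.1, seed=1)
>>> counts, truth = synthetic.simulate_dataset(design, synthetic.default_config(design, seed=1))
>>> res = NumericalResponseModel(counts).fit(n_iter=4000, burn_in=2000, seed=1)
>>> print(res.summary())                                    # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import diagnostics
from .data import CountData
from .mcmc import FitConfig, PriorConfig, run_mcmc

__all__ = ["NumericalResponseModel", "NumericalResponseResults",
           "FitConfig", "PriorConfig"]


class NumericalResponseModel:
    """Joint state-space N-mixture model for a prey and optional predator.

    Parameters
    ----------
    data : CountData
        Robust-design counts for one or two species.
    prey : str
        Species name driving the uncoupled Gompertz dynamics.
    predator : str, "auto" or None
        Species whose dynamics include the numerical-response terms
        (c_b, c_nb) on lagged prey log abundance.  "auto" picks the first
        non-prey species in the data, or none.
    """

    def __init__(self, data: CountData, prey: str = "rabbit",
                 predator: str | None = "auto"):
        if prey not in data.y:
            raise ValueError(f"prey species {prey!r} not present in data")
        if predator == "auto":
            others = [s for s in data.species if s != prey]
            predator = others[0] if others else None
        if predator is not None and predator not in data.y:
            raise ValueError(f"predator species {predator!r} not present in data")
        self.data = data
        self.prey = prey
        self.predator = predator

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kw) -> "NumericalResponseModel":
        return cls(CountData.from_dataframe(df), **kw)

    @classmethod
    def from_csv(cls, path, **kw) -> "NumericalResponseModel":
        return cls.from_dataframe(pd.read_csv(path), **kw)

    def fit(self, config: FitConfig | None = None, **overrides
            ) -> "NumericalResponseResults":
        """Sample the joint posterior by MCMC.

        Keyword overrides are applied on top of ``config`` (or the desk-scale
        default), e.g. ``fit(n_iter=5000, seed=3)``.
        """
        if config is None:
            config = FitConfig(**overrides)
        elif overrides:
            config = replace(config, **overrides)
        draws, latents, meta = run_mcmc(self.data, config, self.prey,
                                        self.predator)
        return NumericalResponseResults(self, config, draws, latents, meta)


class NumericalResponseResults:
    """Posterior draws and derived summaries for a fitted model."""

    def __init__(self, model: NumericalResponseModel, config: FitConfig,
                 draws: dict, latents: dict, meta: dict):
        self.model = model
        self.config = config
        self.draws = draws
        self.latents = latents
        self.meta = meta

    # ---------- basic accessors ----------

    @property
    def data(self) -> CountData:
        return self.model.data

    @property
    def species(self) -> list[str]:
        return list(self.meta["species"])

    @property
    def flat_params(self) -> list[str]:
        """Scalar parameter names; season intercepts as ``sp.alpha[k]``."""
        out = []
        for name, arr in self.draws.items():
            if arr.ndim == 3:
                out.extend(f"{name}[{k}]" for k in range(arr.shape[2]))
            else:
                out.append(name)
        return out

    def get(self, name: str) -> np.ndarray:
        """Draws for one scalar parameter, shape (n_chains, n_kept)."""
        if name in self.draws and self.draws[name].ndim == 2:
            return self.draws[name]
        if name.endswith("]") and "[" in name:
            base, idx = name[:-1].split("[")
            if base in self.draws and self.draws[base].ndim == 3:
                return self.draws[base][:, :, int(idx)]
        raise KeyError(f"unknown parameter {name!r}")

    # ---------- inference summaries ----------

    def posterior_median(self, name: str) -> float:
        return float(np.median(self.get(name)))

    def credible_interval(self, name: str, level: float = 0.95):
        return diagnostics.credible_interval(self.get(name), level)

    def gelman_rubin(self, name: str) -> float:
        return diagnostics.gelman_rubin(self.get(name))

    def is_significant(self, name: str, null_value: float = 0.0,
                       level: float = 0.95) -> bool:
        return diagnostics.is_significant(
            self.credible_interval(name, level), null_value)

    @property
    def rhat_max(self) -> float:
        return max(self.gelman_rubin(p) for p in self.flat_params)

    def summary(self, level: float = 0.95) -> diagnostics.FitSummary:
        return diagnostics.summarize(self, level=level)

    # ---------- goodness of fit and derived quantities ----------

    def bayesian_p_value(self, species: str, seed: int | None = None) -> float:
        return diagnostics.bayesian_p_value(self, species, seed=seed)

    def mean_detection(self, species: str, max_draws: int | None = 2000):
        """(mean, sd) of posterior-mean per-survey detection across cells.

        The mean is taken over all observed transect-survey-season cells;
        the SD measures how much detection varies between cells (transect
        length, season and survey random errors combined).
        """
        p, _ = diagnostics.detection_prob_draws(self, species, max_draws)
        mask = np.isfinite(self.data.y[species])
        pbar = p.mean(axis=0)[mask]
        return float(pbar.mean()), float(pbar.std(ddof=1))

    def density_draws(self, species: str) -> np.ndarray:
        """Per-km density draws, shape (chains, kept, transects, seasons)."""
        N = self.latents[species]["N"]
        return diagnostics.density_index(
            N, self.data.lengths_km[None, None, :, :])

    def density_index(self, species: str) -> pd.DataFrame:
        """Posterior-median density index per transect-season (per km)."""
        med = np.median(self.density_draws(species), axis=(0, 1))
        I, K = med.shape
        rows = [{"transect_id": self.data.transect_ids[i], "season_index": k,
                 "season_type": self.data.season_type[k],
                 "density_per_km": float(med[i, k])}
                for i in range(I) for k in range(K)]
        return pd.DataFrame(rows)

    def seasonal_density_trajectory(self, species: str) -> pd.DataFrame:
        """Per-season mean density across transects (plus per-transect medians)."""
        med = np.median(self.density_draws(species), axis=(0, 1))
        return pd.DataFrame({
            "season_index": np.arange(med.shape[1]),
            "season_type": self.data.season_type,
            "mean_density_per_km": med.mean(axis=0),
        })

    def plot_density(self, species: str, ax=None):  # pragma: no cover - optional
        """Spaghetti plot of per-transect density traces with the cross-transect mean."""
        import matplotlib.pyplot as plt

        med = np.median(self.density_draws(species), axis=(0, 1))
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(med.T, color="0.7", lw=0.6)
        ax.plot(med.mean(axis=0), color="k", lw=2)
        ax.set_xlabel("season")
        ax.set_ylabel(f"{species} density (per km)")
        return ax

    # ---------- persistence ----------

    def save(self, path) -> None:
        """Serialize draws + metadata to a self-describing .npz archive."""
        import json

        payload = {f"draws/{k}": v for k, v in self.draws.items()}
        for sp, d in self.latents.items():
            payload[f"latent/{sp}/N"] = d["N"]
            payload[f"latent/{sp}/delta"] = d["delta"]
        meta = {k: v for k, v in self.meta.items() if k != "tl_std"}
        payload["tl_std"] = self.meta["tl_std"]
        payload["meta_json"] = np.array(json.dumps(meta))
        np.savez_compressed(path, **payload)

    @classmethod
    def load(cls, path, data: CountData | None = None,
             model: NumericalResponseModel | None = None
             ) -> "NumericalResponseResults":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta_json"]))
            meta["tl_std"] = z["tl_std"]
            draws = {k[len("draws/"):]: z[k] for k in z.files
                     if k.startswith("draws/")}
            latents: dict = {}
            for k in z.files:
                if k.startswith("latent/"):
                    _, sp, what = k.split("/")
                    latents.setdefault(sp, {})[what] = z[k]
        if model is None:
            if data is None:
                raise ValueError("provide either the original data or model")
            model = NumericalResponseModel(data, prey=meta["prey"],
                                           predator=meta["predator"])
        cfg = FitConfig(n_chains=meta["n_chains"], n_iter=meta["n_iter"],
                        burn_in=meta["burn_in"], thin=meta["thin"],
                        seed=meta["seed"])
        return cls(model, cfg, draws, latents, meta)
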