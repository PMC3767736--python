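"""Sampler contracts: configuration validation, smoke behaviour, degenerate
sub-models with known posteriors."""

import numpy as np
import pytest

import spotnmix as sx
from spotnmix import FitConfig, PriorConfig


class TestFitConfig:
    @pytest.mark.parametrize("kw", [
        dict(n_chains=1),
        dict(burn_in=5000, n_iter=4000),
        dict(thin=0),
    ])
    def test_invalid_settings(self, kw):
        with pytest.raises(ValueError):
            FitConfig(**kw)

    def test_fullscale_preset_schedule(self):
        cfg = FitConfig.fullscale(seed=1)
        assert (cfg.n_chains, cfg.n_iter, cfg.burn_in, cfg.thin) == \
            (3, 420_000, 400_000, 10)

    def test_retained_count(self):
        cfg = FitConfig(n_iter=1000, burn_in=400, thin=3)
        assert cfg.n_kept == 200


class TestFitContracts:
    def test_smoke_tiny_dataset_converges_finitely(self):
        # 3 transects x 4 seasons, ~50 counts: completes with finite PSRF
        design = sx.make_survey_design(3, 4, 23.1, 5.9, 0.0, seed=12)
        counts, _ = sx.simulate_dataset(design, sx.default_config(design, seed=12))
        data = sx.CountData(y={"rabbit": counts.y["rabbit"]},
                            lengths_km=counts.lengths_km,
                            season_type=counts.season_type)
        res = sx.NumericalResponseModel(data).fit(
            n_chains=2, n_iter=2000, burn_in=1000, thin=2, seed=1)
        for p in res.flat_params:
            assert np.isfinite(res.gelman_rubin(p))

    def test_count_exceeding_nmax_rejected(self):
        design = sx.make_survey_design(3, 4, 20, 0, 0.0, seed=1)
        counts, _ = sx.simulate_dataset(design, sx.default_config(design, seed=1))
        data = sx.CountData(y={"rabbit": counts.y["rabbit"]},
                            lengths_km=counts.lengths_km,
                            season_type=counts.season_type)
        with pytest.raises(ValueError):
            sx.NumericalResponseModel(data).fit(n_chains=2, n_iter=200,
                                                burn_in=100, nmax=1, seed=1)

    def test_noninteger_counts_rejected(self):
        data = sx.CountData(y={"rabbit": np.full((2, 2, 2), 1.5)},
                            lengths_km=np.array([10.0, 12.0]),
                            season_type=["breeding", "nonbreeding"])
        with pytest.raises(ValueError):
            sx.NumericalResponseModel(data).fit(n_chains=2, n_iter=200,
                                                burn_in=100, seed=1)

    def test_perfect_detection_pins_latent_abundance(self):
        # detection fixed at ~1: the posterior for N_ik must sit on the
        # per-cell maximum count
        design = sx.make_survey_design(6, 3, 20, 0, 0.0, seed=4)
        N = np.array([[8, 3, 11]] * 6)
        ab = sx.LatentAbundance(N=N, logN=np.log(N).astype(float))
        y = sx.simulate_counts(ab, sx.DetectionParams(alpha=np.full(3, 50.0)),
                               design, seed=4)
        data = sx.CountData(y={"rabbit": y}, lengths_km=design.lengths_km,
                            season_type=list(design.season_type))
        res = sx.NumericalResponseModel(data).fit(
            n_chains=2, n_iter=1500, burn_in=500, thin=2, seed=2,
            fix={"alpha": 50.0, "beta1": 0.0, "beta2": 0.0, "gamma": 0.0})
        ymax = np.nanmax(y, axis=1)
        n_draws = res.latents["rabbit"]["N"]
        assert np.all(n_draws == ymax[None, None, :, :])

    def test_fixed_seed_reproduces_posterior_exactly(self):
        design = sx.make_survey_design(4, 4, 23.1, 5.9, 0.0, seed=8)
        counts, _ = sx.simulate_dataset(design, sx.default_config(design, seed=8))
        data = sx.CountData(y={"rabbit": counts.y["rabbit"]},
                            lengths_km=counts.lengths_km,
                            season_type=counts.season_type)
        model = sx.NumericalResponseModel(data)
        r1 = model.fit(n_chains=2, n_iter=800, burn_in=400, thin=2, seed=33)
        r2 = model.fit(n_chains=2, n_iter=800, burn_in=400, thin=2, seed=33)
        for p in ("rabbit.b", "rabbit.sigma", "rabbit.gamma"):
            np.testing.assert_array_equal(r1.get(p), r2.get(p))

    def test_prey_only_and_joint_share_prey_structure(self, small_dataset):
        counts, _ = small_dataset
        model = sx.NumericalResponseModel(counts)
        assert model.prey == "rabbit"
        assert model.predator == "cat"
        res = model.fit(n_chains=2, n_iter=600, burn_in=300, thin=3, seed=2)
        assert "cat.c_nb" in res.draws
        assert "rabbit.c_nb" not in res.draws


class TestThinningStability:
    def test_doubling_thin_with_doubled_iterations_is_consistent(self):
        design = sx.make_survey_design(6, 6, 23.1, 5.9, 0.0, seed=14)
        counts, _ = sx.simulate_dataset(design, sx.default_config(design, seed=14))
        data = sx.CountData(y={"rabbit": counts.y["rabbit"]},
                            lengths_km=counts.lengths_km,
                            season_type=counts.season_type)
        model = sx.NumericalResponseModel(data)
        r1 = model.fit(n_chains=2, n_iter=4000, burn_in=2000, thin=2, seed=6)
        r2 = model.fit(n_chains=2, n_iter=8000, burn_in=4000, thin=4, seed=6)
        for p in ("rabbit.b", "rabbit.sigma"):
            m1, m2 = np.mean(r1.get(p)), np.mean(r2.get(p))
            pooled_sd = np.std(np.concatenate([r1.get(p).ravel(),
                                               r2.get(p).ravel()]))
            assert abs(m1 - m2) < 5 * pooled_sd / np.sqrt(100)
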