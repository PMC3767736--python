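"""Synthetic-data generator: survey designs, latent dynamics, counts."""

import dataclasses

import numpy as np
import pytest
from scipy.stats import binom

import spotnmix as sx
from spotnmix import (
    BREEDING,
    NONBREEDING,
    DetectionParams,
    ProcessParams,
    make_survey_design,
    seasonal_fixed_point,
    simulate_abundance,
    simulate_counts,
)


class TestMakeSurveyDesign:
    def test_length_distribution_matches_field_protocol(self):
        d = make_survey_design(66, 12, 23.1, 5.9, 0.0, seed=1)
        assert d.n_transects == 66
        se = 5.9 / np.sqrt(66)
        assert abs(d.lengths_km.mean() - 23.1) < 3 * se
        assert np.all(d.lengths_km >= sx.synthetic.MIN_LENGTH_KM)

    def test_zero_variance_lengths(self):
        d = make_survey_design(5, 4, 20.0, 0.0, 0.0, seed=1)
        np.testing.assert_array_equal(d.lengths_km, np.full(5, 20.0))

    def test_missingness_within_binomial_bounds(self):
        d = make_survey_design(10, 6, 23.1, 5.9, 0.3, seed=7)
        n_cells = 10 * 6
        frac = d.missing_mask.mean()
        lo = binom.ppf(0.005, n_cells, 0.3) / n_cells
        hi = binom.ppf(0.995, n_cells, 0.3) / n_cells
        assert lo <= frac <= hi

    def test_seasons_alternate(self):
        d = make_survey_design(4, 7, 20, 2, 0.0, seed=0)
        for a, b in zip(d.season_type, d.season_type[1:]):
            assert a != b

    def test_no_transect_fully_missing(self):
        d = make_survey_design(40, 4, 20, 2, 0.6, seed=3)
        assert not d.missing_mask.all(axis=1).any()

    @pytest.mark.parametrize("kw", [
        dict(n_transects=0, n_seasons=4, length_mean_km=20, length_sd_km=1,
             missing_prob=0.0, seed=1),
        dict(n_transects=5, n_seasons=4, length_mean_km=20, length_sd_km=1,
             missing_prob=1.0, seed=1),
        dict(n_transects=5, n_seasons=4, length_mean_km=-3, length_sd_km=1,
             missing_prob=0.0, seed=1),
    ])
    def test_invalid_arguments(self, kw):
        with pytest.raises(ValueError):
            make_survey_design(**kw)


def _config(design, rabbit=None, cat=None, **kw):
    base = sx.default_config(design, seed=kw.pop("seed", 0))
    if rabbit is not None:
        base = dataclasses.replace(base, rabbit_process=rabbit)
    if cat is not None:
        base = dataclasses.replace(base, cat_process=cat)
    for k, v in kw.items():
        base = dataclasses.replace(base, **{k: v})
    return base


class TestSimulateAbundance:
    def test_zero_noise_random_walk_is_constant(self):
        d = make_survey_design(6, 8, 20, 2, 0.0, seed=1)
        rw = ProcessParams(a_b=0, a_nb=0, b=1.0, sigma=0.0)
        cfg = _config(d, rabbit=rw, cat=dataclasses.replace(rw, c_b=0.0, c_nb=0.0))
        r, c = simulate_abundance(d, cfg)
        for traj in (r.logN, c.logN):
            np.testing.assert_allclose(traj, np.broadcast_to(traj[:, [0]],
                                                             traj.shape))

    def test_immediate_fixed_point_when_b_zero(self):
        d = make_survey_design(4, 6, 20, 2, 0.0, seed=2)
        p = ProcessParams(a_b=2.0, a_nb=2.0, b=0.0, sigma=0.0)
        cfg = _config(d, rabbit=p, cat=dataclasses.replace(p, c_b=0.0, c_nb=0.0))
        r, _ = simulate_abundance(d, cfg)
        np.testing.assert_allclose(r.logN[:, 1:], 2.0)

    def test_long_run_mean_matches_deterministic_fixed_point(self):
        # linear AR recursion: the stationary mean per season equals the
        # deterministic two-season fixed point
        d = make_survey_design(50, 200, 20, 2, 0.0, seed=3)
        p = ProcessParams(a_b=1.19, a_nb=1.98, b=0.6, sigma=0.3)
        cfg = _config(d, rabbit=p, seed=3)
        r, _ = simulate_abundance(d, cfg)
        x_first, x_second = seasonal_fixed_point(p, first_season=d.season_type[0])
        sim_first = r.logN[:, 20::2].mean()
        sim_second = r.logN[:, 21::2].mean()
        assert sim_first == pytest.approx(x_first, abs=0.05)
        assert sim_second == pytest.approx(x_second, abs=0.05)

    def test_discretization_bridge(self, small_dataset):
        _, truth = small_dataset
        ab = truth["rabbit"]["abundance"]
        np.testing.assert_array_equal(
            ab.N, np.maximum(1, np.rint(np.exp(ab.logN))))

    def test_control_event_scales_prey(self):
        d = make_survey_design(8, 10, 20, 2, 0.0, seed=5)
        cfg = _config(d, seed=5)
        cfg_ev = dataclasses.replace(cfg, control_event=(4, 0.8))
        r0, _ = simulate_abundance(d, cfg)
        r1, _ = simulate_abundance(d, cfg_ev)
        np.testing.assert_allclose(r1.logN[:, 4], r0.logN[:, 4] + np.log(0.2))
        np.testing.assert_array_equal(
            r1.N[:, 4], np.maximum(1, np.rint(0.2 * np.exp(r0.logN[:, 4]))))
        # pre-event seasons identical, post-event dynamics diverge
        np.testing.assert_array_equal(r1.N[:, :4], r0.N[:, :4])

    def test_invalid_reduction(self):
        d = make_survey_design(3, 4, 20, 2, 0.0, seed=1)
        with pytest.raises(ValueError):
            _config(d, control_event=(2, 1.5))


class TestSimulateCounts:
    def _flat_abundance(self, d, n):
        N = np.full((d.n_transects, d.n_seasons), n, dtype=np.int64)
        return sx.LatentAbundance(N=N, logN=np.log(N).astype(float))

    def test_perfect_detection_returns_abundance(self):
        d = make_survey_design(6, 4, 20, 2, 0.0, seed=1)
        ab = self._flat_abundance(d, 17)
        det = DetectionParams(alpha=np.full(4, 50.0), gamma=0.0)
        y = simulate_counts(ab, det, d, seed=1)
        np.testing.assert_array_equal(y, np.full((6, 2, 4), 17.0))

    def test_zero_detection_returns_zeros(self):
        d = make_survey_design(6, 4, 20, 2, 0.0, seed=1)
        ab = self._flat_abundance(d, 17)
        det = DetectionParams(alpha=np.full(4, -50.0), gamma=0.0)
        y = simulate_counts(ab, det, d, seed=1)
        np.testing.assert_array_equal(y, np.zeros((6, 2, 4)))

    def test_binomial_mean_at_rabbit_detection(self):
        # 10,000 replicate surveys of N=100 at p=0.69
        d = make_survey_design(5000, 1, 20, 0, 0.0, seed=2)
        ab = self._flat_abundance(d, 100)
        p = 0.69
        det = DetectionParams(alpha=np.log(p / (1 - p)), gamma=0.0)
        y = simulate_counts(ab, det, d, seed=2)
        n_surveys = y.size
        se = np.sqrt(100 * p * (1 - p) / n_surveys)
        assert abs(y.mean() - 69.0) < 3 * se

    def test_marginal_mean_equals_N_times_Ep(self):
        # with survey errors, E[count] = N * E[p] with E[p] by quadrature
        d = make_survey_design(3000, 1, 20, 0, 0.0, seed=4)
        ab = self._flat_abundance(d, 50)
        det = DetectionParams(alpha=0.3, beta1=0.0, beta2=0.0, gamma=0.7)
        y = simulate_counts(ab, det, d, seed=4)
        ep = sx.mean_detection(0.3, 0.0, 0.0, 0.7, np.zeros(1))
        assert y.mean() / 50 == pytest.approx(ep, abs=0.01)

    def test_missing_cells_are_nan(self):
        d = make_survey_design(20, 6, 20, 2, 0.4, seed=6)
        ab = self._flat_abundance(d, 10)
        det = DetectionParams(alpha=np.zeros(6), gamma=0.2)
        y = simulate_counts(ab, det, d, seed=6)
        missing = np.isnan(y).all(axis=1)
        np.testing.assert_array_equal(missing, d.missing_mask)

    def test_negative_abundance_rejected(self):
        d = make_survey_design(2, 2, 20, 2, 0.0, seed=1)
        ab = sx.LatentAbundance(N=np.array([[-1, 2], [1, 1]]),
                                logN=np.zeros((2, 2)))
        with pytest.raises(ValueError):
            simulate_counts(ab, DetectionParams(alpha=np.zeros(2)), d, seed=1)


class TestDeterminism:
    def test_fixed_seed_reproduces_dataset_byte_for_byte(self, tmp_path):
        d = make_survey_design(12, 6, 23.1, 5.9, 0.2, seed=9)
        cfg = sx.default_config(d, seed=9)
        for name in ("a.csv", "b.csv"):
            counts, _ = sx.simulate_dataset(d, cfg)
            sx.write_counts_csv(counts, tmp_path / name)
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()

    def test_different_seeds_differ(self):
        d = make_survey_design(12, 6, 23.1, 5.9, 0.0, seed=9)
        c1, _ = sx.simulate_dataset(d, sx.default_config(d, seed=1))
        c2, _ = sx.simulate_dataset(d, sx.default_config(d, seed=2))
        assert not np.array_equal(c1.y["rabbit"], c2.y["rabbit"],
                                  equal_nan=True)
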