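"""Semi-synthetic generator: distributions, hazard model, sign control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import survite as sv
from survite.simulate import (SimulationParameters, default_parameters,
                              generate_covariates, generate_semi_synthetic,
                              gompertz_time, sample_potential_outcomes,
                              treatment_probability)

NAMES = ["AGE", "CD40", "CD80", "Z30", "RACE", "GENDER", "STE"]


class TestCovariates:
    def test_seeded_reproducibility(self):
        a = generate_covariates(200, seed=9)
        b = generate_covariates(200, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_age_matches_truncated_normal_mean(self):
        X = generate_covariates(10_000, seed=1)
        a, b = (18 - 35) / 8, (70 - 35) / 8
        mean, var = stats.truncnorm.stats(a, b, loc=35, scale=8,
                                          moments="mv")
        se = np.sqrt(float(var) / len(X))
        assert abs(X["AGE"].mean() - float(mean)) < 3 * se

    def test_binary_columns_support_and_lognormal_medians(self):
        X = generate_covariates(20_000, seed=2)
        for c in ("Z30", "RACE", "GENDER", "STE"):
            assert set(np.unique(X[c])) <= {0.0, 1.0}
        assert abs(np.median(X["CD40"]) / 350.0 - 1) < 0.05
        assert abs(np.median(X["CD80"]) / 800.0 - 1) < 0.05

    def test_unknown_distribution_errors(self):
        with pytest.raises(ValueError, match="unknown distribution"):
            generate_covariates(10, {"X": {"dist": "cauchy"}}, seed=0)


class TestTreatmentModel:
    def test_balanced_patient_gets_half(self):
        p = default_parameters(d1=2.0, d2=0.5)
        X = pd.DataFrame({"AGE": [35.0], "CD40": [350.0]})
        # at the cohort means the sigmoid argument is 0
        prob = treatment_probability(X, p, mean_age=35.0, mean_cd40=350.0)
        assert prob[0] == pytest.approx((0.5 + 0.5) / 2.0)

    def test_probability_limits_and_clipping(self):
        p = default_parameters(d1=1.0, d2=1.0)
        X = pd.DataFrame({"AGE": [90.0], "CD40": [5000.0]})
        with pytest.warns(UserWarning, match="clipped"):
            prob = treatment_probability(X, p, mean_age=35.0, mean_cd40=350.0)
        assert prob[0] == 1.0
        p0 = default_parameters(d1=2.0, d2=0.0)
        X = pd.DataFrame({"AGE": [-500.0], "CD40": [0.0]})
        prob = treatment_probability(X, p0, mean_age=35.0, mean_cd40=350.0)
        assert prob[0] == pytest.approx(0.0, abs=1e-12)

    def test_degenerate_scale_errors(self):
        with pytest.raises(ValueError):
            treatment_probability(pd.DataFrame({"AGE": [1.0], "CD40": [1.0]}),
                                  default_parameters(d1=0.0))


class TestGompertzTime:
    def test_hand_value(self):
        # kappa=1, chi*exp(x'eta)=1, z=e^-1 -> log(2)
        t = gompertz_time(np.zeros(1), 1.0, 1.0, np.zeros(1), np.exp(-1.0))
        assert t == pytest.approx(np.log(2.0), rel=1e-12)

    def test_z_near_one_gives_vanishing_time(self):
        t = gompertz_time(np.zeros(1), 0.5, 1.0, np.zeros(1), 1 - 1e-12)
        assert 0 < t < 1e-9

    def test_exponential_limit_matches_tiny_kappa(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(0.01, 0.99, 1000)
        lin = rng.normal(0, 1, 1000)
        x = lin[:, None]
        eta = np.ones(1)
        tiny = np.array([gompertz_time(x[i], 1e-12, 0.3, eta, z[i])
                         for i in range(1000)])
        limit = np.array([gompertz_time(x[i], 0.0, 0.3, eta, z[i])
                          for i in range(1000)])
        np.testing.assert_allclose(tiny, limit, atol=1e-8)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            gompertz_time(np.zeros(1), 1.0, -1.0, np.zeros(1), 0.5)
        with pytest.raises(ValueError):
            gompertz_time(np.zeros(1), 1.0, 1.0, np.zeros(1), 1.5)


class TestPotentialOutcomes:
    def test_zero_effect_region_is_exact(self):
        p = default_parameters()
        x = np.array([40.0, 300, 700, 0, 0, 0, 0])
        y1, y0 = sample_potential_outcomes(x, "D3", p, 0.37, NAMES)
        assert y1 == y0

    def test_hazard_reduction_guarantees_benefit(self):
        p = default_parameters(rho=0.5)
        rng = np.random.default_rng(1)
        for _ in range(200):
            x = np.array([rng.uniform(18, 70), rng.uniform(100, 800),
                          rng.uniform(100, 1500), 1, 1, 1, 1])
            y1, y0 = sample_potential_outcomes(x, "D1", p, rng.uniform(), NAMES)
            assert y1 > y0

    def test_invalid_rho_for_positive_region(self):
        p = default_parameters(rho=1.5)
        with pytest.raises(ValueError, match="rho"):
            sample_potential_outcomes(np.zeros(7), "D1", p, 0.5, NAMES)


class TestGeneration:
    def test_bit_reproducible(self):
        a_ds, a_truth = generate_semi_synthetic(300, default_parameters(seed=5))
        b_ds, b_truth = generate_semi_synthetic(300, default_parameters(seed=5))
        np.testing.assert_array_equal(a_ds.covariates, b_ds.covariates)
        np.testing.assert_array_equal(a_ds.time, b_ds.time)
        pd.testing.assert_frame_equal(a_truth, b_truth)

    def test_region_signs_and_censoring_consistency(self, small_cohort):
        ds, truth = small_cohort
        gamma = truth[truth.region == "D3"]
        omega = truth[truth.region.isin(["D1", "D2"])]
        assert (gamma.delta_Y == 0).all()
        assert (omega.delta_Y > 0).all()
        y_fact = np.where(ds.treatment == 1, truth.Y1, truth.Y0)
        # delta=1 exactly when the factual time was observed (y < censoring)
        assert np.array_equal(ds.event == 1, ds.time == y_fact)
        assert (ds.time <= y_fact + 1e-12).all()

    def test_degenerate_censoring_distribution(self):
        p = default_parameters(seed=3, mu_c=2.0, sigma2_c=0.0)
        ds, truth = generate_semi_synthetic(100, p)
        y_fact = np.where(ds.treatment == 1, truth.Y1, truth.Y0)
        cen = ds.time[ds.event == 0]
        np.testing.assert_allclose(cen, np.exp(2.0), rtol=1e-12)
        assert (y_fact[ds.event == 0] >= np.exp(2.0)).all()

    def test_no_censoring_when_horizon_is_far(self):
        p = default_parameters(seed=3, mu_c=30.0)
        ds, _ = generate_semi_synthetic(200, p)
        assert (ds.event == 1).all()

    def test_censoring_fraction_monotone_in_horizon(self):
        fracs = []
        for mu_c in (2.0, 3.0, 4.0, 5.0):
            ds, _ = generate_semi_synthetic(
                1500, default_parameters(seed=7, mu_c=mu_c))
            fracs.append(1.0 - ds.event.mean())
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_region_mix_matches_benchmark_order(self):
        """Region shares should be of the same order as the reference cohort
        split (about a fifth positive-effect, a third zero-effect)."""
        _, truth = generate_semi_synthetic(2139, default_parameters(seed=0))
        shares = truth.region.value_counts(normalize=True)
        pos = shares.get("D1", 0) + shares.get("D2", 0)
        assert 0.10 < pos < 0.35
        assert 0.20 < shares.get("D3", 0) < 0.45
        assert 0.30 < shares.get("D4", 0) < 0.65

    def test_ground_truth_not_leaked_into_dataset(self, small_cohort):
        ds, _ = small_cohort
        assert set(ds.covariate_names) == set(NAMES)
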