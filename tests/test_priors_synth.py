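"""Prior calibration (analytic) and synthetic dataset generation."""

import math

import numpy as np
import pytest
from scipy import stats

from t2relax import (
    PriorConfig,
    calibrate_s0_prior,
    calibrate_t2_prior,
    generate_fixed_snr_testset,
    generate_sampleset,
    sample_echo_config,
)


class TestT2PriorCalibration:
    def test_closed_form_solution(self):
        # independent derivation: log_sd solves s^2 + z95*s = ln(205/45)
        log_mu, log_sd = calibrate_t2_prior(5.0, 50.0, 210.0)
        z95 = stats.norm.ppf(0.95)
        residual_mode = math.exp(log_mu - log_sd**2) - 45.0
        residual_q95 = stats.lognorm.cdf(205.0, s=log_sd, scale=math.exp(log_mu)) - 0.95
        assert abs(residual_mode) < 1e-10 * 45
        assert abs(residual_q95) < 1e-10
        assert log_sd == pytest.approx(0.658, abs=1e-3)
        assert log_mu == pytest.approx(4.240, abs=1e-3)

    def test_implied_tail_probability(self, prior_config):
        # the two-constraint calibration also reproduces the third printed
        # probability P(T2 < 500 ms) ~ 99.8%
        assert prior_config.t2_cdf(500.0) == pytest.approx(0.998, abs=1e-3)

    def test_mode_by_density_maximization(self, prior_config):
        t = np.linspace(5.01, 200, 200000)
        pdf = stats.lognorm.pdf(t - 5.0, s=prior_config.t2_log_sd,
                                scale=math.exp(prior_config.t2_log_mu))
        assert t[np.argmax(pdf)] == pytest.approx(50.0, abs=0.05)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            calibrate_t2_prior(50.0, 5.0, 210.0)


class TestS0PriorCalibration:
    def test_tail_scale_closed_form(self):
        assert calibrate_s0_prior(500.0, 1700.0) == pytest.approx(
            1200.0 / math.log(10), rel=1e-12
        )

    def test_printed_probabilities(self, prior_config):
        assert prior_config.s0_cdf(500.0) == pytest.approx(0.50, abs=1e-12)
        assert prior_config.s0_cdf(1700.0) == pytest.approx(0.95, abs=1e-12)
        assert prior_config.s0_cdf(2500.0) == pytest.approx(0.99, abs=2e-3)


class TestEchoConfig:
    def test_deterministic_under_seed(self, prior_config):
        a = sample_echo_config(np.random.default_rng(5), prior_config)
        b = sample_echo_config(np.random.default_rng(5), prior_config)
        assert a == b

    def test_ranges(self, prior_config):
        rng = np.random.default_rng(0)
        te0, step, n = sample_echo_config(rng, prior_config, size=10**5)
        assert 5.0 < te0.min() and te0.max() < 15.0
        assert 2.0 < step.min() and step.max() < 15.0
        assert set(np.unique(n)) == set(range(5, 16))

    def test_seven_echo_scheme(self):
        # te_start=10, te_step=10, n=7 reproduces the 10..70 ms acquisition
        te = 10.0 + 10.0 * np.arange(7)
        np.testing.assert_allclose(te, [10, 20, 30, 40, 50, 60, 70])


class TestGenerateSampleset:
    def test_reproducible(self, prior_config):
        a = generate_sampleset((100, 10, 10), prior_config, rng=42)
        b = generate_sampleset((100, 10, 10), prior_config, rng=42)
        np.testing.assert_array_equal(a.magnitude, b.magnitude)
        np.testing.assert_array_equal(a.te, b.te)
        np.testing.assert_array_equal(a.t2, b.t2)

    def test_sample_invariants(self, prior_config):
        ss = generate_sampleset((500, 50, 50), prior_config, rng=1)
        assert len(ss) == 600
        assert np.all(ss.s0 > 0)
        assert np.all((ss.n >= 5) & (ss.n <= 15))
        assert np.all(ss.sigma > 0) and np.all(ss.sigma <= 300)
        # padding beyond n is exactly -1
        k = np.arange(15)[None, :]
        pad_region = k >= ss.n[:, None]
        assert np.all(ss.magnitude[pad_region] == -1)
        assert np.all(ss.te[pad_region] == -1)
        # magnitudes inside the train are non-negative
        assert np.all(ss.magnitude[~pad_region] >= 0)

    def test_t2_median_matches_prior(self, prior_config):
        ss = generate_sampleset({"train": 10**6}, prior_config, rng=3)
        expected = 5.0 + math.exp(prior_config.t2_log_mu)
        med = np.median(ss.t2)
        assert med == pytest.approx(expected, rel=0.01)

    def test_splits_and_subset(self, prior_config):
        ss = generate_sampleset({"train": 50, "val": 20, "test": 30}, prior_config, rng=0)
        assert len(ss.subset("train")) == 50
        assert len(ss.subset("val")) == 20
        assert len(ss.subset("test")) == 30

    def test_roundtrip_persistence(self, prior_config, tmp_path):
        ss = generate_sampleset((50, 5, 5), prior_config, rng=9)
        ss.save(tmp_path / "ds")
        back = type(ss).load(tmp_path / "ds")
        np.testing.assert_array_equal(back.magnitude, ss.magnitude)
        np.testing.assert_array_equal(back.split, ss.split)
        df = ss.to_frame()
        assert len(df) == 60 and "mag_14" in df.columns


class TestFixedSnrTestset:
    def test_exact_snr(self, prior_config):
        ss = generate_fixed_snr_testset(5.0, 1000, prior_config, rng=7)
        np.testing.assert_allclose(ss.s0 / ss.sigma, 5.0, rtol=1e-12)
        np.testing.assert_allclose(ss.snr, 5.0, rtol=1e-12)

    def test_infinite_snr_is_noise_free(self, prior_config):
        ss = generate_fixed_snr_testset(np.inf, 200, prior_config, rng=7)
        assert np.all(ss.sigma == 0)
        k = np.arange(15)[None, :]
        valid = k < ss.n[:, None]
        clean = ss.s0[:, None] * np.exp(-ss.te / ss.t2[:, None])
        np.testing.assert_allclose(ss.magnitude[valid], clean[valid], rtol=1e-12)

    def test_reproducible(self, prior_config):
        a = generate_fixed_snr_testset(5.0, 100, prior_config, rng=13)
        b = generate_fixed_snr_testset(5.0, 100, prior_config, rng=13)
        np.testing.assert_array_equal(a.magnitude, b.magnitude)

    def test_invalid_snr(self, prior_config):
        with pytest.raises(ValueError):
            generate_fixed_snr_testset(0.0, 10, prior_config, rng=0)
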