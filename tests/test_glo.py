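"""GLO generative model: simulator, model autocorrelogram, fit, taxonomy."""

import numpy as np
import pytest

from dastride.burst import burst_stats, detect_bursts
from dastride.glo import (GLOFitConfig, GLOParams, classify_pattern, fit_glo,
                          model_ach, simulate_glo)
from dastride.spiketrain import autocorrelogram, isi_stats

from conftest import poisson_train


class TestSimulator:
    def test_noise_free_limit_is_periodic(self):
        p = GLOParams(mu=0.25, s=0.0, beta=1.0, sigma2=0.0)
        tr = simulate_glo(p, 60.0, seed=0, burst_size_law="fixed")
        assert isi_stats(tr).cv == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(np.diff(tr.times), 0.25)

    def test_rate_is_beta_over_mu(self):
        p = GLOParams(mu=0.25, s=0.03, beta=1.0, sigma2=0.01)
        rates = [simulate_glo(p, 600.0, seed=k).n_spikes / 600.0
                 for k in range(50)]
        # SE of the mean rate over 50 x 600 s
        se = np.std(rates, ddof=1) / np.sqrt(50)
        assert abs(np.mean(rates) - 4.0) < 3 * se + 0.02

    def test_bursty_params_drive_sfb(self):
        p = GLOParams(mu=0.25, s=0.02, beta=3.0, sigma2=0.005)
        hits = 0
        for k in range(10):
            tr = simulate_glo(p, 600.0, seed=k)
            if burst_stats(tr, detect_bursts(tr)).sfb > 50:
                hits += 1
        assert hits >= 8

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            GLOParams(mu=-0.1, s=0.0, beta=1.0, sigma2=0.0)
        with pytest.raises(ValueError):
            simulate_glo(GLOParams(0.25, 0.0, 1.0, 0.0), duration=1.0)


class TestModelACH:
    def test_periodic_limit_peaks(self):
        p = GLOParams(mu=0.25, s=0.0, beta=1.0, sigma2=1e-5)
        ach = model_ach(p, bin_width=0.01, max_lag=1.0)
        lags = ach.lag_centers
        dist_to_multiple = np.abs(np.abs(lags) / 0.25
                                  - np.round(np.abs(lags) / 0.25)) * 0.25
        far = (dist_to_multiple > 0.05) & (np.abs(lags) > 0.05)
        for k in (1, 2, 3):
            near = np.abs(np.abs(lags) - k * 0.25) < 0.015
            assert ach.rate[near].max() > 50 * max(ach.rate[far].max(), 1e-9)

    def test_matches_simulated_ach(self):
        p = GLOParams(mu=0.20, s=0.02, beta=2.0, sigma2=0.01)
        tr = simulate_glo(p, 600.0, seed=5)
        emp = autocorrelogram(tr, 0.01, 2.0)
        mod = model_ach(p, 0.01, 2.0)
        rel = np.linalg.norm(mod.rate - emp.rate) / np.linalg.norm(emp.rate)
        assert rel < 0.10

    def test_poisson_limit_flat(self):
        # large period variability washes out all structure: flat at beta/mu
        p = GLOParams(mu=0.25, s=0.25, beta=1.0, sigma2=0.01)
        ach = model_ach(p, 0.01, 2.0)
        lags = ach.lag_centers
        flat = 1.0 / 0.25
        outer = np.abs(lags) > 0.3  # beyond the residual central component
        assert np.all(np.abs(ach.rate[outer] - flat) / flat < 0.05)


class TestFit:
    def test_recovers_known_parameters(self):
        truth = GLOParams(mu=0.25, s=0.02, beta=1.0, sigma2=0.01)
        fits = [fit_glo(simulate_glo(truth, 600.0, seed=k)) for k in range(5)]
        mus = [f.params.mu for f in fits]
        betas = [f.params.beta for f in fits]
        assert abs(np.median(mus) - 0.25) / 0.25 < 0.02
        assert abs(np.median(betas) - 1.0) < 0.10
        assert all(f.converged for f in fits)

    def test_periodic_train_degenerate_fit(self):
        tr = simulate_glo(GLOParams(0.25, 0.0, 1.0, 0.0), 120.0, seed=0,
                          burst_size_law="fixed")
        f = fit_glo(tr)
        assert f.params.mu == pytest.approx(0.25, abs=0.01)
        assert f.params.s < 0.02 and f.params.sigma2 < 0.02

    def test_poisson_train_flagged_non_oscillatory(self, rng):
        tr = poisson_train(4.0, 600.0, rng)
        f = fit_glo(tr)
        assert not f.oscillatory_ach
        assert f.params.s == pytest.approx(GLOFitConfig().s_upper)

    def test_log_sigma2_monotone_and_floored(self):
        cfg = GLOFitConfig()
        sigmas = [0.0005, 0.002, 0.01, 0.05]
        logs = [np.log(max(s, cfg.sigma2_floor)) for s in sigmas]
        assert logs == sorted(logs)
        tr = simulate_glo(GLOParams(0.25, 0.01, 1.0, 0.0), 600.0, seed=1,
                          burst_size_law="fixed")
        assert np.isfinite(fit_glo(tr).log_sigma2)


class TestClassify:
    def _fit_for(self, params, seed=0, law="poisson", duration=600.0):
        tr = simulate_glo(params, duration, seed=seed, burst_size_law=law)
        cfg = GLOFitConfig()
        return fit_glo(tr, cfg), autocorrelogram(tr, cfg.bin_width,
                                                 cfg.max_lag)

    def test_pacemaker(self):
        f, ach = self._fit_for(GLOParams(0.25, 0.01, 1.0, 0.005), law="fixed")
        assert classify_pattern(f, ach).label == "single-spike-oscillatory"

    def test_bursty_irregular(self):
        f, ach = self._fit_for(GLOParams(0.25, 0.125, 3.0, 0.008))
        lab = classify_pattern(f, ach).label
        assert lab == "bursty-irregular"

    def test_bursty_oscillatory(self):
        f, ach = self._fit_for(GLOParams(0.4, 0.03, 3.0, 0.008))
        assert classify_pattern(f, ach).label == "bursty-oscillatory"

    def test_poisson_single_spike_irregular(self, rng):
        tr = poisson_train(4.0, 600.0, rng)
        cfg = GLOFitConfig()
        f = fit_glo(tr, cfg)
        ach = autocorrelogram(tr, cfg.bin_width, cfg.max_lag)
        assert classify_pattern(f, ach).label == "single-spike-irregular"

    def test_time_rescaling_invariance(self):
        # relative thresholds: scaling all times must not change the label
        f1, a1 = self._fit_for(GLOParams(0.2, 0.01, 1.0, 0.004), law="fixed")
        f2, a2 = self._fit_for(GLOParams(0.4, 0.02, 1.0, 0.008), law="fixed")
        assert classify_pattern(f1, a1).label == classify_pattern(f2, a2).label
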