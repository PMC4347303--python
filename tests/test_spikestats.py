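"""Spike-count statistics against brute-force references and Poisson
closed forms."""

import numpy as np
import pytest

from conftest import poisson_ensemble
from cpnet.protocol import TrialResult
from cpnet.spikestats import (spike_counts, population_rate, fano_factor,
                              noise_correlation, correlation_matrix,
                              CountMatrix, default_grid)


def _naive_counts(trial_spikes, t, T):
    """Reference: closed window [t - T/2, t + T/2] by direct enumeration."""
    return sum(1 for s in trial_spikes if t - T / 2 <= s <= t + T / 2)


class TestSpikeCounts:
    def test_window_edges(self, rng):
        ens = poisson_ensemble([0.0], 1, duration=2000.0)
        ens.trials[0].spike_neurons = np.array([0, 0, 0], np.int32)
        ens.trials[0].spike_times = np.array([10.0, 60.0, 110.0])
        cm = spike_counts(ens, [0], T=100.0, centres=np.array([60.0]))
        assert cm.counts[0, 0, 0] == 3

    def test_empty_raster_all_zero(self):
        ens = poisson_ensemble([0.0, 0.0], 3, duration=2000.0)
        cm = spike_counts(ens, [0, 1], T=250.0)
        assert np.all(cm.counts == 0)

    def test_matches_naive_enumeration(self, rng):
        ens = poisson_ensemble([15.0, 40.0, 5.0, 25.0], 12, duration=2000.0,
                               seed=7)
        centres = default_grid(2000.0, 250.0)
        cm = spike_counts(ens, [0, 1, 2, 3], T=250.0, centres=centres)
        for a, k in enumerate([0, 1, 2, 3]):
            for l, trial in enumerate(ens.trials):
                st = trial.spike_times[trial.spike_neurons == k]
                for b, t in enumerate(centres):
                    assert cm.counts[a, l, b] == _naive_counts(st, t, 250.0)

    def test_oversized_window_rejected(self):
        ens = poisson_ensemble([10.0], 2, duration=500.0)
        with pytest.raises(ValueError):
            spike_counts(ens, [0], T=1e6)

    def test_adjusted_windows_near_T_for_stationary_rates(self):
        ens = poisson_ensemble([20.0, 20.0], 60, duration=2000.0, seed=3)
        cm = spike_counts(ens, [0, 1], T=250.0, mode="adjusted")
        # homogeneous Poisson: realized windows within 10% of nominal
        inner = cm.windows[:, 1:-1]  # edge bins clip against the trial
        assert np.all(np.abs(inner - 250.0) < 25.0)
        # and mean counts hit the target r_k * T
        target = cm.counts.mean(axis=(1, 2))
        for a in range(2):
            got = cm.counts[a, :, 1:-1].mean()
            assert got == pytest.approx(target[a], rel=0.15)

    def test_fixed_and_adjusted_agree_for_stationary(self):
        ens = poisson_ensemble([30.0], 80, duration=2000.0, seed=11)
        fixed = spike_counts(ens, [0], T=250.0)
        adj = spike_counts(ens, [0], T=250.0, mode="adjusted")
        m_f = fixed.counts.mean(axis=1)[0]
        m_a = adj.counts.mean(axis=1)[0]
        assert np.allclose(m_f[1:-1], m_a[1:-1], rtol=0.15)


class TestPopulationRate:
    def test_regular_trains_give_flat_rate(self):
        ens = poisson_ensemble([0.0] * 4, 1, duration=2000.0)
        nrn = np.tile(np.arange(4, dtype=np.int32), 20)
        t = np.repeat(np.arange(55.0, 2000.0, 100.0), 4)
        ens.trials[0].spike_neurons = nrn
        ens.trials[0].spike_times = np.sort(t)
        times, r = population_rate(ens, "E1", T=100.0, grid_dt=100.0)
        inner = r[0][(times > 100) & (times < 1900)]
        assert np.allclose(inner, 10.0, atol=0.01)

    def test_choice_conditioning_splits_trials(self):
        ens = poisson_ensemble([20.0, 20.0], 30, duration=1000.0, seed=5,
                               choices=[1, 2] * 15)
        t, r1, r2 = population_rate(ens, "E1", T=100.0,
                                    condition_on_choice=True)
        assert r1.shape == r2.shape == t.shape

    def test_half_population_rates_average_to_whole(self):
        ens = poisson_ensemble([10.0, 30.0, 20.0, 20.0], 5, duration=1000.0,
                               seed=8)
        _, r_e1 = population_rate(ens, "E1", T=200.0)
        _, r_e2 = population_rate(ens, "E2", T=200.0)
        # pooled mean rate equals the average of the two halves
        assert np.mean(r_e1) + np.mean(r_e2) == pytest.approx(
            2 * 20.0, rel=0.2)


def _count_matrix(counts):
    counts = np.asarray(counts, float)
    B = counts.shape[2] if counts.ndim == 3 else 1
    counts = counts.reshape(counts.shape[0], -1, B)
    return CountMatrix(counts=counts, neurons=np.arange(counts.shape[0]),
                       centres=np.arange(B, dtype=float), T=100.0,
                       mode="fixed")


class TestFano:
    def test_identical_counts_zero_fano(self):
        cm = _count_matrix(np.full((2, 10, 3), 7.0))
        assert np.all(fano_factor(cm) == 0.0)

    def test_poisson_counts_unit_fano(self, rng):
        counts = rng.poisson(8.0, size=(3, 5000, 2)).astype(float)
        ff = fano_factor(_count_matrix(counts))
        assert np.all(np.abs(ff - 1.0) < 0.05)

    def test_shift_correction_removes_across_trial_drift(self, rng):
        drift = np.linspace(4.0, 16.0, 4000)
        counts = rng.poisson(drift[None, :, None],
                             size=(2, 4000, 2)).astype(float)
        raw = fano_factor(_count_matrix(counts))
        corrected = fano_factor(_count_matrix(counts), shift_correct=True)
        assert np.all(raw > 1.5)
        assert np.all(np.abs(corrected - 1.0) < 0.1)

    def test_zero_mean_masked(self):
        cm = _count_matrix(np.zeros((1, 10, 1)))
        assert np.isnan(fano_factor(cm)[0, 0])


class TestNoiseCorrelation:
    def test_self_correlation_is_one(self, rng):
        x = rng.poisson(5.0, 200).astype(float)
        assert noise_correlation(x, x) == pytest.approx(1.0)

    def test_independent_pair_near_zero(self, rng):
        x = rng.poisson(6.0, 5000).astype(float)
        y = rng.poisson(6.0, 5000).astype(float)
        assert abs(noise_correlation(x, y)) < 0.03

    def test_matches_numpy_pearson(self, rng):
        x = rng.poisson(4.0, 50).astype(float)
        y = x + rng.poisson(2.0, 50)
        assert noise_correlation(x, y) == pytest.approx(
            np.corrcoef(x, y)[0, 1])

    def test_common_modulation_matches_doubly_stochastic_oracle(self, rng):
        # both neurons driven by one Gamma-distributed rate across trials:
        # Monte-Carlo oracle for the expected count correlation
        n = 8000
        lam = rng.gamma(10.0, 1.0, n)  # mean 10, var 10
        x = rng.poisson(lam).astype(float)
        y = rng.poisson(lam).astype(float)
        rho = noise_correlation(x, y)
        # analytic: Var(lam) / (Var(lam) + E(lam)) = 10 / 20 = 0.5
        assert rho == pytest.approx(0.5, abs=0.05)

    def test_zero_variance_masked(self):
        assert np.isnan(noise_correlation(np.ones(10), np.arange(10.0)))


class TestCorrelationMatrix:
    def test_independent_ensemble_near_zero(self):
        ens = poisson_ensemble([20.0] * 8, 300, duration=2000.0, seed=2)
        cm = correlation_matrix(ens, list(range(8)), T=250.0, pair_set="EE")
        assert np.all(np.abs(cm.matrix) < 0.06)
        assert cm.matrix == pytest.approx(cm.matrix.T)

    def test_common_drive_creates_positive_within_pairs(self):
        ens = poisson_ensemble([20.0] * 8, 250, duration=2000.0, seed=4,
                               common_sd=8.0)
        within = correlation_matrix(ens, list(range(8)), T=250.0,
                                    pair_set="EiEi")
        assert np.mean(within.instantaneous) > 0.05

    def test_too_few_pairs_rejected(self):
        ens = poisson_ensemble([20.0, 20.0], 20, duration=2000.0, seed=1)
        with pytest.raises(ValueError):
            correlation_matrix(ens, [0], T=250.0, pair_set="EiEi")
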