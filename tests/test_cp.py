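"""Choice probability: ROC areas vs brute force, selection rules,
population averaging and the CP-stability matrix."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import poisson_ensemble
from cpnet.cp import (roc_area, cp_timecourse, select_units, population_cp,
                      cp_correlation_matrix, _cp_from_counts)


def _brute_force_roc(pref, null):
    wins = sum((p > q) + 0.5 * (p == q) for p in pref for q in null)
    return wins / (len(pref) * len(null))


class TestROCArea:
    def test_chance_level_for_identical_multisets(self):
        assert roc_area([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert roc_area([5, 6, 7], [1, 2, 3]) == 1.0
        assert roc_area([1, 2], [5, 6]) == 0.0

    def test_half_credit_ties(self):
        assert roc_area([2, 3], [1, 2]) == pytest.approx(0.875)

    @settings(max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 6), min_size=1, max_size=8),
           st.lists(st.integers(0, 6), min_size=1, max_size=8))
    def test_matches_exhaustive_pair_enumeration(self, pref, null):
        assert roc_area(pref, null) == pytest.approx(
            _brute_force_roc(pref, null))

    def test_vectorized_form_matches_scalar(self, rng):
        counts = rng.poisson(3.0, size=(5, 40, 3)).astype(float)
        pref = rng.random((5, 40)) < 0.5
        cp = _cp_from_counts(counts, pref)
        for k in range(5):
            for b in range(3):
                expected = roc_area(counts[k, pref[k], b],
                                    counts[k, ~pref[k], b])
                assert cp[k, b] == pytest.approx(expected)


class TestCPTimecourse:
    def test_shuffled_labels_give_chance_level(self, rng):
        choices = rng.permutation([1] * 40 + [2] * 40)
        ens = poisson_ensemble([12.0] * 4, 80, duration=2000.0, seed=6,
                               choices=choices)
        traces = [cp_timecourse(ens, k, T=250.0).cp for k in range(4)]
        mean_cp = np.nanmean(traces)
        # permutation band around 0.5 for 4 neurons x 80 label-shuffled trials
        assert abs(mean_cp - 0.5) < 0.05

    def test_too_few_trials_masked(self):
        ens = poisson_ensemble([10.0, 10.0], 8, duration=2000.0, seed=1,
                               choices=[1] * 6 + [2] * 2)
        tc = cp_timecourse(ens, 0, T=250.0)
        assert np.all(np.isnan(tc.cp))

    def test_rate_difference_by_choice_raises_cp(self, rng):
        # neuron 0 fires more on choice-1 trials: CP must exceed 0.5
        choices = np.array([1, 2] * 60)
        ens = poisson_ensemble([10.0, 10.0], 120, duration=2000.0, seed=2,
                               choices=choices)
        for trial in ens.trials:
            if trial.choice == 1:
                extra = rng.random(14) * 2000.0
                times = np.concatenate([trial.spike_times, extra])
                nrn = np.concatenate([trial.spike_neurons,
                                      np.zeros(14, np.int32)])
                order = np.argsort(times)
                trial.spike_times = times[order]
                trial.spike_neurons = nrn[order]
                trial._indptr = None
        tc = cp_timecourse(ens, 0, T=250.0)
        assert np.nanmean(tc.cp) > 0.55


class TestSelectUnits:
    def _ens(self, n_trials, choices, rates):
        return poisson_ensemble(rates, n_trials, duration=2000.0, seed=3,
                                choices=choices)

    def test_minimum_trial_count_is_strict(self):
        ens = self._ens(20, [1, 2] * 10, [20.0, 20.0])
        kept, excl = select_units(ens)
        assert len(kept) == 0 and excl["n_trials"] == 2

    def test_choice_balance_rule(self):
        ens = self._ens(30, [1] * 26 + [2] * 4, [20.0, 20.0])
        kept, excl = select_units(ens)
        assert len(kept) == 0 and excl["per_choice"] == 2

    def test_rate_rule(self):
        ens = self._ens(30, [1, 2] * 15, [0.5, 20.0])
        kept, excl = select_units(ens)
        assert 0 not in kept and 1 in kept
        assert excl["rate"] >= 1

    def test_spike_count_rule(self):
        # 1.2 sp/s passes the rate rule but 30 trials x 2 s ~ 72 < 100 spikes
        ens = self._ens(30, [1, 2] * 15, [1.2, 20.0])
        kept, excl = select_units(ens)
        assert 0 not in kept


class TestPopulationCP:
    def test_sem_zero_for_identical_traces(self):
        # identical trains for every E1 neuron; E2 silent (ineligible), so
        # all sampled neurons share one CP trace exactly
        ens = poisson_ensemble([15.0, 15.0, 15.0, 0.0, 0.0, 0.0], 60,
                               duration=2000.0, seed=9, choices=[1, 2] * 30)
        for trial in ens.trials:
            m = trial.spike_neurons == 0
            times = trial.spike_times[m]
            trial.spike_neurons = np.repeat(np.arange(3, dtype=np.int32),
                                            len(times))
            trial.spike_times = np.tile(times, 3)
            order = np.argsort(trial.spike_times)
            trial.spike_neurons = trial.spike_neurons[order]
            trial.spike_times = trial.spike_times[order]
            trial._indptr = None
        centres, mean, sem, ids = population_cp(ens, T=250.0, n_neurons=3,
                                                min_rate=1.0, seed=0)
        assert np.all(sem[~np.isnan(mean)] < 1e-12)

    def test_disjoint_samples_agree(self):
        ens = poisson_ensemble([15.0] * 12, 80, duration=2000.0, seed=10,
                               choices=[1, 2] * 40)
        _, m1, s1, ids1 = population_cp(ens, T=250.0, n_neurons=5, seed=1)
        _, m2, s2, ids2 = population_cp(ens, T=250.0, n_neurons=5, seed=2)
        joint = np.sqrt(s1**2 + s2**2)
        ok = ~np.isnan(m1) & ~np.isnan(m2)
        assert np.all(np.abs(m1[ok] - m2[ok]) <= 3 * joint[ok] + 1e-9)


class TestCPCorrelationMatrix:
    def test_shared_ranking_gives_unit_matrix(self, rng):
        # neuron k fires at rate 5 + k with choice-dependent gain: the CP
        # ranking across neurons is identical at every bin
        K, L = 8, 120
        choices = np.array([1, 2] * (L // 2))
        ens = poisson_ensemble([0.0] * K, L, duration=2000.0, seed=4,
                               choices=choices)
        for l, trial in enumerate(ens.trials):
            nrn, times = [], []
            for k in range(K):
                boost = 1.0 + 0.12 * k if trial.choice == 1 else 1.0
                n = rng.poisson(2.0 * 8.0 * boost)
                times.extend(rng.random(n) * 2000.0)
                nrn.extend([k] * n)
            order = np.argsort(times)
            trial.spike_times = np.asarray(times)[order]
            trial.spike_neurons = np.asarray(nrn, np.int32)[order]
            trial._indptr = None
        m = cp_correlation_matrix(ens, list(range(K)), T=250.0,
                                  n_trials_subsample=80, n_resamples=40,
                                  seed=0, n_permutations=200)
        off = m.matrix[np.triu_indices_from(m.matrix, k=1)]
        assert np.mean(off) > 0.5

    def test_independent_rankings_give_zero(self):
        ens = poisson_ensemble([15.0] * 8, 100, duration=2000.0, seed=5,
                               choices=[1, 2] * 50)
        m = cp_correlation_matrix(ens, list(range(8)), T=250.0,
                                  n_trials_subsample=60, n_resamples=40,
                                  seed=0, n_permutations=200)
        off = m.matrix[np.triu_indices_from(m.matrix, k=1)]
        assert abs(np.mean(off)) < 0.15

    def test_oversized_subsample_rejected(self):
        ens = poisson_ensemble([15.0] * 4, 30, duration=2000.0, seed=5,
                               choices=[1, 2] * 15)
        with pytest.raises(ValueError):
            cp_correlation_matrix(ens, [0, 1, 2, 3],
                                  n_trials_subsample=1000)
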