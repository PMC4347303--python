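"""Trial protocol: choice readout, batches, replicate filtering,
heterogeneity and bound-crossing classification."""

import dataclasses

import numpy as np
import pytest

from cpnet.config import NetworkConfig, StimulusConfig, ConfigurationError
from cpnet.network import build_network, CLS
from cpnet.stimulus import make_stimulus
from cpnet.protocol import (read_choice, run_batch, run_trial,
                            filter_replicate_stimuli, make_heterogeneous,
                            classify_bound_trials, TrialResult,
                            TrialEnsemble)


def _fake_trial(choice, spikes=None, pre=0.0, dur=2000.0, sid=0, coh=0.0):
    nrn, t = spikes if spikes is not None else (np.empty(0, np.int32),
                                                np.empty(0))
    return TrialResult(spike_neurons=np.asarray(nrn, np.int32),
                       spike_times=np.asarray(t, float), choice=choice,
                       coherence=coh, stimulus_id=sid, stimulus_seed=sid,
                       pre=pre, stim_duration=dur,
                       s_e1=np.zeros(int(dur)), s_e2=np.zeros(int(dur)))


def _fake_ensemble(trials, mode="replicate", offsets=None):
    return TrialEnsemble(trials=trials, mode=mode,
                         network_config=NetworkConfig(),
                         stimulus_config=StimulusConfig(),
                         offsets=offsets if offsets is not None
                         else np.array([0, 2, 4, 4, 6, 8, 8, 8]))


class TestReadChoice:
    # population layout: D1 = neurons [4, 6), D2 = [6, 8)
    OFFSETS = np.array([0, 2, 4, 4, 6, 8, 8, 8])

    def test_higher_rate_population_wins(self):
        nrn = np.array([4, 4, 4, 5, 6], np.int32)
        t = np.array([1990., 1995., 1998., 1992., 1991.])
        assert read_choice(nrn, t, self.OFFSETS, pre=0.0,
                           stim_duration=2000.0) == 1

    def test_only_last_window_counts(self):
        # D2 spikes massively but before the last 50 ms
        nrn = np.array([6] * 50 + [4], np.int32)
        t = np.concatenate([np.linspace(0, 1940, 50), [1999.0]])
        assert read_choice(nrn, t, self.OFFSETS, pre=0.0,
                           stim_duration=2000.0) == 1

    def test_tie_broken_by_seeded_coin(self):
        nrn = np.array([4, 6], np.int32)
        t = np.array([1990.0, 1991.0])
        picks = {read_choice(nrn, t, self.OFFSETS, 0.0, 2000.0, tie_seed=s)
                 for s in range(20)}
        assert picks == {1, 2}  # both outcomes occur over seeds
        a = read_choice(nrn, t, self.OFFSETS, 0.0, 2000.0, tie_seed=7)
        b = read_choice(nrn, t, self.OFFSETS, 0.0, 2000.0, tie_seed=7)
        assert a == b


class TestReplicateFilter:
    def _ens(self, split_per_stim):
        trials = []
        for sid, (n1, n2) in enumerate(split_per_stim, start=1):
            trials += [_fake_trial(1, sid=sid) for _ in range(n1)]
            trials += [_fake_trial(2, sid=sid) for _ in range(n2)]
        return _fake_ensemble(trials)

    def test_strictly_above_threshold_excluded(self):
        ens = self._ens([(96, 4), (95, 5), (50, 50), (2, 98)])
        kept, excluded = filter_replicate_stimuli(ens)
        assert excluded == [1, 4]
        assert kept == [2, 3]
        assert len(kept) + len(excluded) == 4

    def test_non_replicate_rejected(self):
        ens = self._ens([(10, 10)])
        ens = dataclasses.replace(ens, mode="non-replicate")
        with pytest.raises(ConfigurationError):
            filter_replicate_stimuli(ens)


@pytest.fixture(scope="module")
def quick():
    cfg = NetworkConfig.reduced(master_seed=1)
    net = build_network(cfg)
    stim = StimulusConfig(sigma=1.0, duration=300.0)
    return net, stim


class TestBatches:

    def test_replicate_bookkeeping(self, quick):
        net, stim = quick
        ens = run_batch(net, stim, 12, mode="replicate", n_stimuli=4,
                        master_seed=2, pre=200.0)
        ids = ens.stimulus_ids
        assert sorted(np.unique(ids)) == [1, 2, 3, 4]
        assert all(np.sum(ids == s) == 3 for s in (1, 2, 3, 4))

    def test_non_replicate_distinct_seeds(self, quick):
        net, stim = quick
        ens = run_batch(net, stim, 6, mode="non-replicate", master_seed=2,
                        pre=200.0)
        seeds = [t.stimulus_seed for t in ens.trials]
        assert len(set(seeds)) == 6

    def test_batch_reproducible_from_master_seed(self, quick):
        net, stim = quick
        a = run_batch(net, stim, 3, master_seed=5, pre=200.0)
        b = run_batch(net, stim, 3, master_seed=5, pre=200.0)
        for ta, tb in zip(a.trials, b.trials):
            assert np.array_equal(ta.spike_times, tb.spike_times)
            assert ta.choice == tb.choice

    def test_zero_duration_stimulus_flagged_degenerate(self, quick):
        net, _ = quick
        stim = make_stimulus(StimulusConfig(sigma=0.0, duration=0.0),
                             net.config.size_e1, net.config.size_e2)
        res = run_trial(net, stim, pre=300.0, init_seed=1, background_seed=2)
        assert res.degenerate
        assert res.choice in (1, 2)


class TestHeterogeneity:
    def test_equal_groups_and_factors(self):
        net = build_network(NetworkConfig.reduced(master_seed=4, b_fb=1.0))
        hmap = make_heterogeneous(net, seed=9)
        n1 = net.config.size_e1
        for lo, n in ((0, n1), (n1, net.config.size_e2)):
            counts = np.bincount(hmap.group[lo:lo + n], minlength=4)
            assert np.all(counts == n // 4)
        spfp = hmap.neurons_in_group("S+FB+")
        smfm = hmap.neurons_in_group("S-FB-")
        assert np.all(hmap.fb_factor[spfp] == 2.0)
        assert np.all(hmap.sigma_stim_factor[spfp] == pytest.approx(np.sqrt(2)))
        assert np.all(hmap.sigma_ind_factor[spfp] == 0.0)
        assert np.all(hmap.fb_factor[smfm] == 0.0)
        assert np.all(hmap.sigma_stim_factor[smfm] == 0.0)

    def test_input_current_sd_preserved(self):
        # per-neuron stimulus-current s.d. matches the homogeneous value in
        # every group (the sqrt(2) compensation): estimate over a long path
        net = build_network(NetworkConfig.reduced(master_seed=4, b_fb=1.0))
        hmap = make_heterogeneous(net, seed=9)
        cfg = StimulusConfig(sigma=1.0, duration=60_000.0, stimulus_seed=3)
        het = make_stimulus(cfg, net.config.size_e1, net.config.size_e2,
                            sigma_stim_factor=hmap.sigma_stim_factor,
                            sigma_ind_factor=hmap.sigma_ind_factor)
        hom = make_stimulus(cfg, net.config.size_e1, net.config.size_e2)
        sd_hom = np.std(hom.currents, axis=1).mean()
        for g in ("S+FB+", "S+FB-", "S-FB+", "S-FB-"):
            idx = hmap.neurons_in_group(g)
            sd_g = np.std(het.currents[idx], axis=1).mean()
            assert sd_g == pytest.approx(sd_hom, rel=0.05)

    def test_population_sizes_divisible_by_four(self):
        # scaling always rounds sizes to a multiple of four so the split is
        # well defined at any scale
        for scale in (0.25, 0.3, 0.77, 1.0):
            cfg = NetworkConfig.reduced(scale=scale)
            assert cfg.size_e1 % 4 == 0 and cfg.size_e2 % 4 == 0


class TestBoundClassification:
    OFFSETS = np.array([0, 0, 0, 0, 2, 4, 4, 4])  # D1 = {0,1}, D2 = {2,3}

    def _trial_with_rates(self, d1_times, d2_times, choice):
        nrn = np.array([0] * len(d1_times) + [2] * len(d2_times), np.int32)
        t = np.array(list(d1_times) + list(d2_times))
        order = np.argsort(t)
        return _fake_trial(choice, (nrn[order], t[order]), pre=0.0,
                           dur=2000.0)

    def test_infinite_bound_all_no_crossing(self):
        d1 = np.linspace(0, 1999, 80)
        ens = _fake_ensemble([self._trial_with_rates(d1, [], 1)],
                             offsets=self.OFFSETS)
        ba = classify_bound_trials(ens, theta=np.inf)
        assert ba.fraction_no_crossing == 1.0
        assert ba.fraction_reversal == 0.0

    def test_reversal_detected(self):
        # D1 bursts at ~0.8 s (crosses), final choice is 2
        d1 = np.linspace(780, 830, 30)
        d2 = np.linspace(1900, 1999, 30)
        ens = _fake_ensemble([self._trial_with_rates(d1, d2, 2)],
                             offsets=self.OFFSETS)
        ba = classify_bound_trials(ens, theta=100.0)
        assert ba.classes[0] == 2  # reversal
        assert ba.first_crossing_pop[0] == 1
        assert 750 < ba.first_crossing_time[0] < 860

    def test_consistent_crossing(self):
        d1 = np.linspace(500, 1999, 200)
        ens = _fake_ensemble([self._trial_with_rates(d1, [], 1)],
                             offsets=self.OFFSETS)
        ba = classify_bound_trials(ens, theta=50.0)
        assert ba.classes[0] == 1
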