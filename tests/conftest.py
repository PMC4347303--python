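"""Shared fixtures: fabricated ensembles for the statistics modules and
session-scoped simulated ensembles for the model-signature tests.

Simulated ensembles run on the quarter-scale calibrated network
(`NetworkConfig.reduced`) with warm-started batches; problem sizes are the
package's reduced-scale reference sizes (see docs/methods.md).
"""

import numpy as np
import pytest

from cpnet.config import NetworkConfig, StimulusConfig
from cpnet.network import build_network
from cpnet.presets import get_preset
from cpnet.protocol import (TrialResult, TrialEnsemble, run_batch,
                            make_heterogeneous)

MASTER_SEED = 3  # network/protocol seed of the simulated test ensembles


# ---------------------------------------------------------------------------
# fabricated ensembles (no simulation)
# ---------------------------------------------------------------------------

def poisson_ensemble(rates, n_trials, duration=2000.0, pre=0.0, seed=0,
                     common_sd=0.0, choices=None, coherences=None,
                     tau_common=200.0):
    """Build a TrialEnsemble of (doubly stochastic) Poisson spike trains.

    rates: per-neuron mean rates (sp/s) for the E1+E2 block; neuron k of
    trial l fires Poisson with rate r_k * exp-free modulation; with
    common_sd > 0 an Ornstein-Uhlenbeck rate modulation (sp/s) shared by all
    neurons of the same population is added and clipped at zero.
    """
    rates = np.asarray(rates, float)
    K = len(rates)
    half = K // 2
    rng = np.random.default_rng(seed)
    offsets = np.array([0, half, K, K, K, K, K, K])
    dt = 5.0  # ms resolution of the rate modulation
    n_bins = int(duration / dt)
    trials = []
    for l in range(n_trials):
        mods = []
        for _ in range(2):  # one OU modulation per population
            z = np.empty(n_bins)
            rho = np.exp(-dt / tau_common)
            amp = np.sqrt(1 - rho**2)
            z[0] = rng.standard_normal()
            for i in range(1, n_bins):
                z[i] = z[i - 1] * rho + amp * rng.standard_normal()
            mods.append(z * common_sd)
        nrn_all, t_all = [], []
        for k in range(K):
            lam = np.clip(rates[k] + mods[0 if k < half else 1], 0, None)
            counts = rng.poisson(lam * dt * 1e-3)
            for b in np.nonzero(counts)[0]:
                for _ in range(counts[b]):
                    t_all.append(pre + b * dt + rng.random() * dt)
                    nrn_all.append(k)
        order = np.argsort(t_all) if t_all else []
        trials.append(TrialResult(
            spike_neurons=np.asarray(nrn_all, np.int32)[order] if len(t_all)
            else np.empty(0, np.int32),
            spike_times=np.asarray(t_all, float)[order] if len(t_all)
            else np.empty(0),
            choice=int(choices[l]) if choices is not None
            else int(rng.integers(1, 3)),
            coherence=float(coherences[l]) if coherences is not None else 0.0,
            stimulus_id=0, stimulus_seed=l, pre=pre, stim_duration=duration,
            s_e1=np.zeros(int(duration)), s_e2=np.zeros(int(duration))))
    return TrialEnsemble(trials=trials, mode="non-replicate",
                         network_config=NetworkConfig(),
                         stimulus_config=StimulusConfig(),
                         offsets=offsets)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


# ---------------------------------------------------------------------------
# simulated ensembles (session-scoped; shared across signature tests)
# ---------------------------------------------------------------------------

def _run_preset(name, n_trials, seed=MASTER_SEED, n_stimuli=0, **overrides):
    p = get_preset(name, reduced=True, master_seed=seed, **overrides)
    net = build_network(p.network)
    if p.heterogeneous:
        make_heterogeneous(net)
    return run_batch(net, p.stimulus, n_trials, mode=p.mode,
                     n_stimuli=n_stimuli or (p.n_stimuli and
                                             max(8, n_trials // 10)),
                     master_seed=seed, warm_start=True)


@pytest.fixture(scope="session")
def ens_bottomup():
    """Non-replicate, no feedback: bottom-up CP condition."""
    return _run_preset("fig2_bottomup", 150)


@pytest.fixture(scope="session")
def ens_topdown():
    """Replicate stimuli + global background, b_FB=1: top-down condition."""
    return _run_preset("fig2_topdown", 140, n_stimuli=14)


@pytest.fixture(scope="session")
def ens_combined():
    """Non-replicate with feedback: the combined (default) condition."""
    return _run_preset("fig3_combined", 85)


@pytest.fixture(scope="session")
def ens_slow():
    """Slower decision dynamics (g_FF x 0.75, sigma = 1.33)."""
    return _run_preset("fig3_slow", 85)


@pytest.fixture(scope="session")
def ens_hetero():
    """Heterogeneous stimulus / top-down input groups (b_FB = 1)."""
    return _run_preset("fig5_heterogeneous", 150)


@pytest.fixture(scope="session")
def ens_bounds():
    """sigma = 2.7 ensembles without and with strong feedback."""
    weak = _run_preset("fig7_bounds", 32, b_fb=0.0)
    strong = _run_preset("fig7_bounds", 32, b_fb=4.0)
    return {0.0: weak, 4.0: strong}


@pytest.fixture(scope="session")
def tiny_network():
    """A small, quick network for engine-level tests (quarter scale)."""
    cfg = NetworkConfig.reduced(master_seed=1)
    return build_network(cfg)
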