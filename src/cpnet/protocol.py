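"""Trial protocol: run single trials and batches, read out choices, build the
heterogeneous-input network variant and classify bound-crossing trials.

A trial consists of a 3-s pre-stimulus interval (to wash out initial
conditions) followed by a 2-s stimulus epoch.  The choice is the decision
population (D1 or D2) with the higher population rate over the last 50 ms of
the stimulus.  Batches are embarrassingly parallel over trials with per-trial
seeds derived from a master seed, so an ensemble is reproducible regardless
of worker count.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from .config import (NetworkConfig, StimulusConfig, ConfigurationError,
                     derive_seed)
from .network import HierarchicalNetwork, build_network, POPULATIONS, CLS
from .engine import init_state, run, poisson_background, events_to_step_csr
from .stimulus import StimulusTrace, make_stimulus, replicate_bank

__all__ = ["TrialResult", "TrialEnsemble", "HeterogeneityMap", "BoundAnalysis",
           "run_trial", "read_choice", "run_batch",
           "filter_replicate_stimuli", "make_heterogeneous",
           "classify_bound_trials", "GROUP_NAMES"]

GROUP_NAMES = ("S+FB+", "S+FB-", "S-FB+", "S-FB-")


@dataclass
class TrialResult:
    """Spikes and labels of one completed trial.

    Spike times are in ms relative to trial start; the stimulus epoch is
    [pre, pre + stim_duration].
    """

    spike_neurons: np.ndarray
    spike_times: np.ndarray
    choice: int  # 1 or 2
    coherence: float
    stimulus_id: int
    stimulus_seed: int
    pre: float
    stim_duration: float
    s_e1: np.ndarray  # common stimulus term of E1 per stimulus sample
    s_e2: np.ndarray
    stim_dt: float = 1.0
    trial_seed: int = 0
    degenerate: bool = False  # e.g. zero-length stimulus epoch

    _indptr: np.ndarray | None = None
    _sorted_times: np.ndarray | None = None

    def neuron_spikes(self, n_neurons: int):
        """(indptr, times): per-neuron sorted spike times (CSR layout)."""
        if self._indptr is None:
            order = np.lexsort((self.spike_times, self.spike_neurons))
            nrn = self.spike_neurons[order]
            self._sorted_times = self.spike_times[order]
            self._indptr = np.searchsorted(nrn, np.arange(n_neurons + 1))
        return self._indptr, self._sorted_times


@dataclass
class TrialEnsemble:
    """A set of trials of one network: the common currency of all statistics."""

    trials: list
    mode: str  # "replicate" or "non-replicate"
    network_config: NetworkConfig
    stimulus_config: StimulusConfig
    offsets: np.ndarray  # global population offsets (len 8)
    group_labels: np.ndarray | None = None  # heterogeneity groups per E neuron
    master_seed: int = 0

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_neurons(self) -> int:
        return int(self.offsets[-1])

    def population_slice(self, name: str) -> slice:
        i = CLS[name]
        return slice(int(self.offsets[i]), int(self.offsets[i + 1]))

    @property
    def choices(self) -> np.ndarray:
        return np.array([t.choice for t in self.trials])

    @property
    def coherences(self) -> np.ndarray:
        return np.array([t.coherence for t in self.trials])

    @property
    def stimulus_ids(self) -> np.ndarray:
        return np.array([t.stimulus_id for t in self.trials])

    @property
    def stim_duration(self) -> float:
        return self.trials[0].stim_duration if self.trials else 0.0

    @property
    def pre(self) -> float:
        return self.trials[0].pre if self.trials else 0.0

    def preferred_choice(self, neuron: int) -> int:
        """Structural preferred choice: 1 for E1 neurons, 2 for E2."""
        if self.population_slice("E1").start <= neuron < self.population_slice("E1").stop:
            return 1
        if self.population_slice("E2").start <= neuron < self.population_slice("E2").stop:
            return 2
        raise ValueError(f"neuron {neuron} is not a sensory E neuron")


# ---------------------------------------------------------------------------
# choice readout
# ---------------------------------------------------------------------------

def read_choice(spike_neurons, spike_times, offsets, pre, stim_duration,
                window: float = 50.0, tie_seed: int = 0) -> int:
    """Choice = argmax over {D1, D2} of population rate in the last `window`
    ms of the stimulus period; exact ties broken by a seeded fair coin."""
    t_end = pre + stim_duration
    t_lo = t_end - window
    sel = (spike_times > t_lo) & (spike_times <= t_end)
    nrn = spike_neurons[sel]
    d1 = slice(int(offsets[CLS["D1"]]), int(offsets[CLS["D1"] + 1]))
    d2 = slice(int(offsets[CLS["D2"]]), int(offsets[CLS["D2"] + 1]))
    c1 = np.count_nonzero((nrn >= d1.start) & (nrn < d1.stop)) / max(1, d1.stop - d1.start)
    c2 = np.count_nonzero((nrn >= d2.start) & (nrn < d2.stop)) / max(1, d2.stop - d2.start)
    if c1 > c2:
        return 1
    if c2 > c1:
        return 2
    return 1 + int(np.random.default_rng(tie_seed).integers(0, 2))


# ---------------------------------------------------------------------------
# single trial
# ---------------------------------------------------------------------------

def warm_state(network: HierarchicalNetwork, duration: float = 2000.0,
               seed: int = 0):
    """Advance a freshly initialized network through `duration` ms of
    background-only activity and return the resulting state.

    Used to split the pre-stimulus interval of a batch: a shared burn-in
    absorbs the initialization transient once, and each trial then runs its
    own pre-stimulus segment with fresh background input (the state memory
    of the network decays on the ~100 ms NMDA time-scale, so trials remain
    effectively independent).
    """
    compiled = network.compiled()
    c = network.config
    state = init_state(compiled, derive_seed(seed, "initial_conditions", 0))
    n_steps = int(round(duration / c.dt))
    x_times, x_ids = poisson_background(
        c.nu_ext_x, c.size_x, duration,
        seed=derive_seed(seed, "background", 0))
    run(compiled, state, n_steps,
        x_events=events_to_step_csr(x_times, x_ids, c.dt, n_steps),
        ext_seed=derive_seed(seed, "background", 1))
    return state


def run_trial(network: HierarchicalNetwork, stim: StimulusTrace,
              pre: float = 3000.0, init_seed: int = 0,
              background_seed: int = 0, tie_seed: int = 0,
              initial_state=None) -> TrialResult:
    """Simulate one fixed-duration trial.

    Background Poisson streams (X and the integration circuit's external
    input) are freshly drawn from `background_seed`; the stimulus current is
    applied only during the stimulus epoch.  If `initial_state` is given
    (see `warm_state`) it is used instead of random initial membrane
    potentials, and `pre` is the per-trial pre-stimulus segment simulated on
    top of it.
    """
    compiled = network.compiled()
    c = network.config
    stim_duration = stim.n_samples * stim.dt
    duration = pre + stim_duration
    n_steps = int(round(duration / c.dt))
    if initial_state is not None:
        state = initial_state.copy()
    else:
        state = init_state(compiled, init_seed)
    base_step = state.step  # nonzero when continuing from a warm state
    x_times, x_ids = poisson_background(
        c.nu_ext_x, c.size_x, duration, seed=background_seed)
    x_events = events_to_step_csr(x_times, x_ids, c.dt, n_steps)
    steps_per_sample = max(1, int(round(stim.dt / c.dt)))
    stim_start_step = base_step + int(round(pre / c.dt))
    spike_n, spike_t = run(
        compiled, state, n_steps, i_stim=stim.currents,
        stim_start_step=stim_start_step, steps_per_sample=steps_per_sample,
        x_events=x_events, ext_seed=derive_seed(background_seed, "background", 1))
    if base_step:
        spike_t = spike_t - base_step * c.dt
    choice = read_choice(spike_n, spike_t, network.offsets, pre,
                         stim_duration, tie_seed=tie_seed)
    return TrialResult(
        spike_neurons=spike_n, spike_times=spike_t, choice=choice,
        coherence=stim.config.coherence, stimulus_id=stim.stimulus_id,
        stimulus_seed=stim.stimulus_seed, pre=pre,
        stim_duration=stim_duration, s_e1=stim.s_e1, s_e2=stim.s_e2,
        stim_dt=stim.dt, degenerate=(stim_duration <= 0))


# ---------------------------------------------------------------------------
# batches
# ---------------------------------------------------------------------------

def _one_trial(network, stim_cfg, mode, bank, j, master_seed, pre,
               sigma_factors, initial_state=None):
    if mode == "replicate":
        sid = bank.ids[j % len(bank)]
        cfg = dataclasses.replace(bank.config,
                                  stimulus_seed=bank.seeds[j % len(bank)],
                                  replicate=True)
    else:
        sid = 0
        cfg = dataclasses.replace(stim_cfg, replicate=False,
                                  stimulus_seed=derive_seed(master_seed,
                                                            "stimulus", j))
    ssf, sif = sigma_factors
    stim = make_stimulus(cfg, network.config.size_e1, network.config.size_e2,
                         sigma_stim_factor=ssf, sigma_ind_factor=sif,
                         stimulus_id=sid)
    res = run_trial(
        network, stim, pre=pre,
        init_seed=derive_seed(master_seed, "initial_conditions", j),
        background_seed=derive_seed(master_seed, "background", j),
        tie_seed=derive_seed(master_seed, "tie_break", j),
        initial_state=initial_state)
    res.trial_seed = j
    return res


def run_batch(network: HierarchicalNetwork | NetworkConfig,
              stimulus_config: StimulusConfig, n_trials: int,
              mode: str = "non-replicate", master_seed: int = 0,
              n_stimuli: int = 0, pre: float = 3000.0,
              warm_start: bool = False, progress: bool = False
              ) -> TrialEnsemble:
    """Run `n_trials` trials of the same network (same connectivity).

    replicate mode cycles through a bank of `n_stimuli` frozen stimuli
    (each presented n_trials/n_stimuli times); non-replicate mode draws a
    fresh stimulus seed per trial.  Trial j is a pure function of
    (network, master_seed, j).

    warm_start=True splits the pre-stimulus interval: a single 2-s burn-in
    of the network is shared by all trials and each trial then simulates the
    remaining pre-stimulus segment with its own background realization
    (cheaper; see `warm_state`).
    """
    if n_trials < 1:
        raise ConfigurationError("n_trials must be >= 1")
    if mode not in ("replicate", "non-replicate"):
        raise ConfigurationError("mode must be 'replicate' or 'non-replicate'")
    if isinstance(network, NetworkConfig):
        network = build_network(network)
    bank = None
    if mode == "replicate":
        if n_stimuli < 1:
            raise ConfigurationError("replicate mode needs n_stimuli >= 1")
        bank = replicate_bank(stimulus_config, n_stimuli,
                              seed=derive_seed(master_seed, "stimulus", 0))
    sigma_factors = (network.sigma_stim_factor, network.sigma_ind_factor)
    state0 = None
    if warm_start:
        burn = min(2000.0, max(0.0, pre - 500.0))
        state0 = warm_state(network, burn, seed=master_seed)
        pre = pre - burn
    trials = []
    for j in range(n_trials):
        trials.append(_one_trial(network, stimulus_config, mode, bank, j,
                                 master_seed, pre, sigma_factors,
                                 initial_state=state0))
        if progress and (j + 1) % 25 == 0:
            print(f"  trial {j + 1}/{n_trials}", flush=True)
    return TrialEnsemble(trials=trials, mode=mode,
                         network_config=network.config,
                         stimulus_config=stimulus_config,
                         offsets=network.offsets,
                         group_labels=network.group_labels,
                         master_seed=master_seed)


def filter_replicate_stimuli(ensemble: TrialEnsemble, threshold: float = 0.95):
    """Exclude replicate stimuli with overly consistent choices.

    A stimulus id is excluded iff the fraction of choices in its majority
    direction strictly exceeds `threshold`.  Returns (kept_ids, excluded_ids).
    """
    if ensemble.mode != "replicate":
        raise ConfigurationError("stimulus filtering requires a replicate ensemble")
    ids = ensemble.stimulus_ids
    choices = ensemble.choices
    kept, excluded = [], []
    for sid in np.unique(ids):
        ch = choices[ids == sid]
        frac1 = np.mean(ch == 1)
        if max(frac1, 1.0 - frac1) > threshold:
            excluded.append(int(sid))
        else:
            kept.append(int(sid))
    return kept, excluded


# ---------------------------------------------------------------------------
# heterogeneous network variant
# ---------------------------------------------------------------------------

@dataclass
class HeterogeneityMap:
    """Per-sensory-E-neuron input heterogeneity.

    Four equally sized groups per population: S+FB+ receives stimulus and
    top-down input, S+FB- stimulus only, S-FB+ top-down only, S-FB- neither.
    Compensations keep the per-neuron input-current s.d. and the
    population-mean top-down drive equal to the homogeneous network:
    S+ neurons carry the full modulation on the common term
    (sigma_stim,k = sqrt(2)*0.212*sigma, sigma_ind,k = 0), S- neurons on the
    individual term, and FB+ neurons receive doubled feedback strength.
    """

    group: np.ndarray  # int in 0..3 per sensory E neuron, order E1 then E2
    fb_factor: np.ndarray
    sigma_stim_factor: np.ndarray
    sigma_ind_factor: np.ndarray

    def group_name(self, k: int) -> str:
        return GROUP_NAMES[self.group[k]]

    def neurons_in_group(self, name: str) -> np.ndarray:
        return np.nonzero(self.group == GROUP_NAMES.index(name))[0]


def make_heterogeneous(network: HierarchicalNetwork,
                       seed: int | None = None) -> HeterogeneityMap:
    """Split each sensory E population into the four input groups (seeded,
    equal sizes) and attach the per-neuron factors to the network."""
    c = network.config
    n1, n2 = c.size_e1, c.size_e2
    if n1 % 4 or n2 % 4:
        raise ConfigurationError("population size must be divisible by 4")
    if seed is None:
        seed = derive_seed(c.master_seed, "connectivity", 3)
    rng = np.random.default_rng(seed)
    group = np.empty(n1 + n2, np.int8)
    for lo, n in ((0, n1), (n1, n2)):
        g = np.repeat(np.arange(4, dtype=np.int8), n // 4)
        rng.shuffle(g)
        group[lo:lo + n] = g
    s_plus = np.isin(group, [0, 1])
    fb_plus = np.isin(group, [0, 2])
    fb_factor = np.where(fb_plus, 2.0, 0.0)
    sigma_stim_factor = np.where(s_plus, np.sqrt(2.0), 0.0)
    sigma_ind_factor = np.where(s_plus, 0.0, np.sqrt(2.0))
    hmap = HeterogeneityMap(group=group, fb_factor=fb_factor,
                            sigma_stim_factor=sigma_stim_factor,
                            sigma_ind_factor=sigma_ind_factor)
    network.fb_factor = fb_factor
    network.sigma_stim_factor = sigma_stim_factor
    network.sigma_ind_factor = sigma_ind_factor
    network.group_labels = group
    network._compiled = None  # feedback weights changed
    return hmap


# ---------------------------------------------------------------------------
# bound-crossing analysis
# ---------------------------------------------------------------------------

@dataclass
class BoundAnalysis:
    theta: float  # sp/s
    classes: np.ndarray  # 0 = no-crossing, 1 = consistent, 2 = reversal
    first_crossing_time: np.ndarray  # ms from stimulus onset, nan if none
    first_crossing_pop: np.ndarray  # 1, 2 or 0
    confidence: np.ndarray  # mean D1-D2 rate over second half of stimulus
    choices: np.ndarray

    CLASS_NAMES = ("no-crossing", "consistent", "reversal")

    @property
    def fraction_reversal(self) -> float:
        return float(np.mean(self.classes == 2))

    @property
    def fraction_no_crossing(self) -> float:
        return float(np.mean(self.classes == 0))


def _d_rates(trial: TrialResult, offsets, T: float = 50.0, grid_dt: float = 10.0):
    """Smoothed D1/D2 population rates on a grid over the stimulus epoch."""
    lo = trial.pre
    hi = trial.pre + trial.stim_duration
    centres = np.arange(lo, hi + 1e-9, grid_dt)
    rates = []
    for pop in ("D1", "D2"):
        i = CLS[pop]
        a, b = int(offsets[i]), int(offsets[i + 1])
        sel = (trial.spike_neurons >= a) & (trial.spike_neurons < b)
        times = np.sort(trial.spike_times[sel])
        n_hi = np.searchsorted(times, centres + T / 2, side="right")
        n_lo = np.searchsorted(times, centres - T / 2, side="left")
        rates.append((n_hi - n_lo) / ((b - a) * T * 1e-3))
    return centres - lo, rates[0], rates[1]


def classify_bound_trials(ensemble: TrialEnsemble, theta: float,
                          T: float = 50.0) -> BoundAnalysis:
    """Classify each trial by its first crossing of a non-absorbing rate
    bound theta: reversal iff the final choice population differs from the
    first-crossing population; no-crossing iff neither D population reaches
    theta during the stimulus."""
    n = ensemble.n_trials
    classes = np.zeros(n, np.int8)
    tc = np.full(n, np.nan)
    pc = np.zeros(n, np.int8)
    conf = np.empty(n)
    choices = ensemble.choices
    for j, trial in enumerate(ensemble.trials):
        t, r1, r2 = _d_rates(trial, ensemble.offsets, T=T)
        half = t >= trial.stim_duration / 2
        conf[j] = np.mean(r1[half] - r2[half])
        cross1 = np.nonzero(r1 >= theta)[0]
        cross2 = np.nonzero(r2 >= theta)[0]
        i1 = cross1[0] if len(cross1) else np.inf
        i2 = cross2[0] if len(cross2) else np.inf
        if np.isinf(i1) and np.isinf(i2):
            classes[j] = 0
            continue
        pop = 1 if i1 <= i2 else 2
        idx = int(min(i1, i2))
        tc[j] = t[idx]
        pc[j] = pop
        classes[j] = 1 if pop == choices[j] else 2
    return BoundAnalysis(theta=theta, classes=classes, first_crossing_time=tc,
                         first_crossing_pop=pc, confidence=conf,
                         choices=choices)
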