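"""Time-varying stimulus currents modelling random-dot motion evidence.

Each sensory neuron k of population beta receives the injected current

    I_k(t) = I0 * (1 + s_beta(t) + s_ind_k(t))

where s_beta(t) = gamma_beta * c + sigma_stim * z_beta(t) carries the
coherence signal plus a common temporal modulation, and
s_ind_k(t) = sigma_ind * z_ind_k(t) is an individual modulation.  The z's
are independent unit-variance Ornstein-Uhlenbeck processes (tau = 20 ms)
emulating the frame-by-frame fluctuations in motion energy of a random-dot
kinematogram.  The stimulus is injected as a current, not as spikes, so the
replicate condition carries literally zero stimulus-borne trial-to-trial
variability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import StimulusConfig, ConfigurationError

__all__ = ["ou_path", "make_stimulus", "replicate_bank", "StimulusTrace",
           "StimulusBank"]

# sub-seed roles for stream derivation
_ROLE_COMMON_E1 = 0
_ROLE_COMMON_E2 = 1
_ROLE_INDIVIDUAL = 2


def _sub_rng(stimulus_seed: int, role: int, index: int = 0) -> np.random.Generator:
    """Stable per-(seed, role, index) stream: adding neurons or populations
    never perturbs existing streams."""
    ss = np.random.SeedSequence(entropy=int(stimulus_seed) & 0x7FFFFFFF,
                                spawn_key=(role, index))
    return np.random.default_rng(ss)


def ou_path(tau: float, duration: float, dt: float,
            seed: int | np.random.Generator) -> np.ndarray:
    """Stationary zero-mean, unit-s.d. Ornstein-Uhlenbeck path.

    Uses the exact discretization x(t+dt) = x e^(-dt/tau)
    + sqrt(1 - e^(-2 dt/tau)) eta, so the unit variance holds at any dt.
    """
    if dt > tau:
        raise ConfigurationError(f"dt={dt} exceeds tau={tau}")
    n = int(round(duration / dt))
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(int(seed) & 0x7FFFFFFF)
    if n == 0:
        return np.empty(0)
    rho = np.exp(-dt / tau)
    noise = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = noise[0]  # stationary start
    amp = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        out[i] = out[i - 1] * rho + amp * noise[i]
    return out


def _ou_matrix(tau: float, n_samples: int, dt: float,
               stimulus_seed: int, n_paths: int) -> np.ndarray:
    """n_paths independent OU paths, one per-neuron stream each."""
    rho = np.exp(-dt / tau)
    amp = np.sqrt(1.0 - rho * rho)
    noise = np.empty((n_paths, n_samples))
    for k in range(n_paths):
        noise[k] = _sub_rng(stimulus_seed, _ROLE_INDIVIDUAL, k
                            ).standard_normal(n_samples)
    out = np.empty_like(noise)
    out[:, 0] = noise[:, 0]
    for i in range(1, n_samples):
        out[:, i] = out[:, i - 1] * rho + amp * noise[:, i]
    return out


@dataclass
class StimulusTrace:
    """Realized stimulus for one trial (or one replicate-bank entry)."""

    config: StimulusConfig
    stimulus_id: int
    stimulus_seed: int
    s_e1: np.ndarray  # common term of E1: gamma*c + sigma_stim*z_E1, per sample
    s_e2: np.ndarray
    currents: np.ndarray  # (n_e1 + n_e2, n_samples) float32, nA

    @property
    def n_samples(self) -> int:
        return self.s_e1.shape[0]

    @property
    def dt(self) -> float:
        return self.config.dt

    def evidence(self) -> np.ndarray:
        """The controlled evidence variable d(t) = s_E1(t) - s_E2(t)."""
        return self.s_e1 - self.s_e2


def make_stimulus(config: StimulusConfig, n_e1: int, n_e2: int,
                  sigma_stim_factor: np.ndarray | None = None,
                  sigma_ind_factor: np.ndarray | None = None,
                  stimulus_id: int = 0) -> StimulusTrace:
    """Generate the stimulus currents for all sensory E neurons.

    The two common modulations z_E1, z_E2 and all individual modulations are
    mutually independent streams derived from config.stimulus_seed.  Optional
    per-neuron factors (length n_e1 + n_e2) rescale the common and individual
    modulation amplitudes (used by the heterogeneous network).
    """
    config.validate()
    n_samples = int(round(config.duration / config.dt))
    seed = config.stimulus_seed
    z1 = ou_path(config.tau_stim, config.duration, config.dt,
                 _sub_rng(seed, _ROLE_COMMON_E1))
    z2 = ou_path(config.tau_stim, config.duration, config.dt,
                 _sub_rng(seed, _ROLE_COMMON_E2))
    gamma1, gamma2 = config.gamma, -config.gamma
    s_e1 = gamma1 * config.coherence + config.sigma_stim * z1
    s_e2 = gamma2 * config.coherence + config.sigma_stim * z2
    n_e = n_e1 + n_e2
    if sigma_stim_factor is None:
        sigma_stim_factor = np.ones(n_e)
    if sigma_ind_factor is None:
        sigma_ind_factor = np.ones(n_e)
    y = _ou_matrix(config.tau_stim, n_samples, config.dt, seed, n_e) \
        if n_samples else np.empty((n_e, 0))
    mean1 = gamma1 * config.coherence
    mean2 = gamma2 * config.coherence
    s_common = np.empty((n_e, n_samples))
    s_common[:n_e1] = mean1 + (config.sigma_stim
                               * sigma_stim_factor[:n_e1, None]) * z1[None, :]
    s_common[n_e1:] = mean2 + (config.sigma_stim
                               * sigma_stim_factor[n_e1:, None]) * z2[None, :]
    currents = config.I0 * (1.0 + s_common
                            + (config.sigma_ind
                               * sigma_ind_factor[:, None]) * y)
    return StimulusTrace(config=config, stimulus_id=stimulus_id,
                         stimulus_seed=seed, s_e1=s_e1, s_e2=s_e2,
                         currents=currents.astype(np.float32))


@dataclass
class StimulusBank:
    """A frozen set of replicate stimuli, stored as (id, seed) pairs.

    Traces are reconstructed bit-identically from (config, seed) on demand,
    so replaying an entry injects the exact same currents on every trial.
    """

    config: StimulusConfig
    ids: list = field(default_factory=list)
    seeds: list = field(default_factory=list)

    def realize(self, stimulus_id: int, n_e1: int, n_e2: int,
                **kw) -> StimulusTrace:
        i = self.ids.index(stimulus_id)
        cfg = _with_seed(self.config, self.seeds[i], replicate=True)
        return make_stimulus(cfg, n_e1, n_e2, stimulus_id=stimulus_id, **kw)

    def __len__(self):
        return len(self.ids)


def _with_seed(config: StimulusConfig, seed: int, replicate: bool
               ) -> StimulusConfig:
    import dataclasses
    return dataclasses.replace(config, stimulus_seed=int(seed),
                               replicate=replicate)


def replicate_bank(config: StimulusConfig, n_stimuli: int,
                   seed: int) -> StimulusBank:
    """Generate `n_stimuli` frozen replicate stimuli (ids 1..n)."""
    if n_stimuli < 1:
        raise ConfigurationError("n_stimuli must be >= 1")
    rng = np.random.default_rng(int(seed) & 0x7FFFFFFF)
    seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_stimuli)]
    return StimulusBank(config=config, ids=list(range(1, n_stimuli + 1)),
                        seeds=seeds)
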