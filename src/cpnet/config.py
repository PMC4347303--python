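"""Model configuration: neuron, synapse, connectivity and stimulus parameters.

The hierarchical network consists of a sensory circuit (populations E1, E2, I
plus an external Poisson population X) and an integration circuit (selective
populations D1, D2, non-selective Dn and inhibitory I), reciprocally coupled
by topographic feedforward (E1->D1, E2->D2) and feedback (D1->E1, D2->E2)
projections.

Units: time in ms, voltage in mV, conductance in nS, capacitance in nF,
current in nA, rates in spikes/s.  All parameter values are collected here so
that a single config object fully determines a simulation.

The LIF and synaptic kinetic constants follow the standard conductance-based
attractor-network parameterization (integration circuit) and the same LIF
frame with the printed sensory efficacies for the balanced sensory circuit;
values not fixed by the published description are calibration choices and are
documented in docs/methods.md.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "NeuronParams",
    "SynapseParams",
    "StimulusConfig",
    "NetworkConfig",
    "load_config",
    "save_config",
    "derive_seed",
    "seed_sequence",
]


class ConfigurationError(ValueError):
    """Raised when a configuration violates an invariant."""


@dataclass
class NeuronParams:
    """Leaky integrate-and-fire neuron constants."""

    capacitance: float  # nF
    leak_conductance: float  # nS
    leak_reversal: float = -70.0  # mV
    spike_threshold: float = -50.0  # mV
    reset_potential: float = -55.0  # mV
    refractory_period: float = 2.0  # ms

    @property
    def membrane_time_constant(self) -> float:
        """tau_m = C_m / g_L in ms."""
        return 1e3 * self.capacitance / self.leak_conductance

    def validate(self) -> None:
        if not self.spike_threshold > self.reset_potential:
            raise ConfigurationError("spike_threshold must exceed reset_potential")
        if self.capacitance <= 0 or self.leak_conductance <= 0:
            raise ConfigurationError("capacitance and leak conductance must be > 0")
        if self.refractory_period < 0:
            raise ConfigurationError("refractory_period must be >= 0")


@dataclass
class SynapseParams:
    """Kinetics of one receptor class."""

    receptor: str  # "AMPA", "NMDA" or "GABA_A"
    decay_time: float  # ms
    rise_time: float = 0.0  # ms, NMDA only
    reversal: float = 0.0  # mV
    voltage_dependence: bool = False  # NMDA Mg2+ block
    transmission_delay: float = 0.5  # ms

    def validate(self) -> None:
        if self.decay_time <= 0:
            raise ConfigurationError("decay_time must be > 0")


# Receptor kinetics shared by both circuits.
AMPA = SynapseParams("AMPA", decay_time=2.0, reversal=0.0)
NMDA = SynapseParams("NMDA", decay_time=100.0, rise_time=2.0, reversal=0.0,
                     voltage_dependence=True)
GABA_A = SynapseParams("GABA_A", decay_time=5.0, reversal=-70.0)

#: NMDA second-messenger coupling (1/ms) in ds/dt = -s/tau_d + alpha*x*(1-s)
NMDA_ALPHA = 0.5
#: Extracellular magnesium concentration (mM) for the NMDA voltage block.
MG_CONCENTRATION = 1.0


def _excitatory_neuron() -> NeuronParams:
    return NeuronParams(capacitance=0.5, leak_conductance=25.0,
                        refractory_period=2.0)


def _inhibitory_neuron() -> NeuronParams:
    return NeuronParams(capacitance=0.2, leak_conductance=20.0,
                        refractory_period=1.0)


def _sensory_excitatory_neuron() -> NeuronParams:
    # calibrated: more excitable than the integration E cells so that the
    # balanced sensory circuit fires at cortical sensory rates and tracks
    # the stimulus modulations with appreciable gain
    return NeuronParams(capacitance=0.5, leak_conductance=25.0,
                        leak_reversal=-62.0, refractory_period=2.0)


def _sensory_inhibitory_neuron() -> NeuronParams:
    return NeuronParams(capacitance=0.2, leak_conductance=20.0,
                        leak_reversal=-62.0, refractory_period=1.0)


@dataclass
class StimulusConfig:
    """Time-varying stimulus current parameters.

    The current injected into sensory neuron k of population beta is

        I(t) = I0 * (1 + s_beta(t) + s_ind_k(t))

    with s_beta(t) = gamma_beta * c + sigma_stim * z_beta(t) and
    s_ind_k(t) = sigma_ind * z_ind_k(t), where z are independent unit-variance
    Ornstein-Uhlenbeck processes with correlation time tau_stim, c is the
    motion coherence and gamma_E2 = -gamma_E1.
    """

    I0: float = 0.08  # nA, mean input at zero coherence
    coherence: float = 0.0  # signed, in [-1, 1]
    gamma: float = 0.6  # gamma_E1 (calibrated); gamma_E2 = -gamma
    sigma: float = 1.0  # dimensionless modulation strength
    tau_stim: float = 20.0  # ms
    duration: float = 2000.0  # ms
    dt: float = 1.0  # ms, stimulus sampling step
    replicate: bool = False
    stimulus_seed: int = 0

    #: sigma_stim = sigma_ind = SIGMA_UNIT * sigma
    SIGMA_UNIT = 0.212

    @property
    def sigma_stim(self) -> float:
        return self.SIGMA_UNIT * self.sigma

    @property
    def sigma_ind(self) -> float:
        return self.SIGMA_UNIT * self.sigma

    def validate(self) -> None:
        if self.tau_stim <= 0:
            raise ConfigurationError("tau_stim must be > 0")
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if not -1.0 <= self.coherence <= 1.0:
            raise ConfigurationError("coherence must lie in [-1, 1]")
        if self.dt > self.tau_stim:
            raise ConfigurationError("stimulus dt must not exceed tau_stim")


@dataclass
class NetworkConfig:
    """Full parameterization of both circuits and their coupling."""

    # --- population sizes (full scale) -----------------------------------
    n_e1: int = 800
    n_e2: int = 800
    n_i_sens: int = 400
    n_x: int = 1000
    n_d1: int = 240
    n_d2: int = 240
    n_dn: int = 1120
    n_i_int: int = 400

    #: global size scale for reduced-scale runs.  Neuron counts of both
    #: circuits are multiplied by `scale`; the external population X keeps
    #: its full size and the sparse connection probabilities are raised by
    #: 1/scale (capped at 1), so every neuron keeps its full-scale in-degree
    #: and synaptic efficacies -- per-neuron input statistics are preserved
    #: and only the population counts shrink.  The all-to-all integration
    #: circuit cannot preserve its in-degree, so its recurrent efficacies
    #: are divided by `scale` instead.
    scale: float = 1.0

    # --- sensory circuit --------------------------------------------------
    p_sens: float = 0.2  # recurrent connection probability
    p_x: float = 0.32  # X -> sensory
    g_ee_sens: float = 0.76  # nS, E -> E
    g_ei_sens: float = 1.52  # nS, E -> I
    g_ie_sens: float = 12.6  # nS, I -> E and I -> I
    g_x: float = 1.71  # nS, X -> sensory (AMPA)
    w_plus_sens: float = 1.3
    w_minus_sens: float = 0.7
    nu_ext_x: float = 12.5  # sp/s per X cell
    background_mode: str = "global"  # or "local"

    # --- integration circuit (all-to-all) --------------------------------
    w_plus_int: float = 1.6
    #: depression on cross/non-selective -> selective links (None = derive
    #: from the excitation-conserving rule)
    w_minus_int_value: float | None = None
    g_ampa_rec_e: float = 0.05  # nS, E -> E AMPA
    g_ampa_rec_i: float = 0.04  # nS, E -> I AMPA
    g_nmda_e: float = 0.20  # nS, E -> E NMDA (calibrated, see docs/methods.md)
    g_nmda_i: float = 0.158  # nS, E -> I NMDA
    g_gaba_e: float = 1.60  # nS, I -> E
    g_gaba_i: float = 1.23  # nS, I -> I
    g_ext_e: float = 2.1  # nS, external AMPA onto integration E
    g_ext_i: float = 1.62  # nS, onto integration I
    nu_ext_d: float = 2392.0  # sp/s onto D1 and D2
    nu_ext_n: float = 2400.0  # sp/s onto Dn and I

    # --- coupling ---------------------------------------------------------
    p_ff: float = 0.2
    p_fb: float = 0.2
    g_ff: float = 0.55  # nS, calibrated feedforward AMPA efficacy
    g_fb_unit: float = 0.0668  # nS per unit of b_fb
    b_fb: float = 0.0  # dimensionless feedback strength, 0..6

    #: "binomial": independent Bernoulli links per pair; "fixed_in": exact
    #: per-target in-degree with random sources (variance reduction for
    #: reduced-scale networks)
    degree_mode: str = "binomial"

    # --- dynamics ---------------------------------------------------------
    dt: float = 0.1  # ms, Euler step
    delay: float = 0.5  # ms, uniform transmission delay

    neuron_e: NeuronParams = field(default_factory=_excitatory_neuron)
    neuron_i: NeuronParams = field(default_factory=_inhibitory_neuron)
    neuron_e_sens: NeuronParams = field(
        default_factory=_sensory_excitatory_neuron)
    neuron_i_sens: NeuronParams = field(
        default_factory=_sensory_inhibitory_neuron)

    master_seed: int = 0

    # ------------------------------------------------------------------
    def validate(self) -> None:
        for name in ("p_sens", "p_x", "p_ff", "p_fb"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name}={p} outside [0, 1]")
        for name in ("g_ee_sens", "g_ei_sens", "g_ie_sens", "g_x", "g_ff",
                     "g_fb_unit", "g_ampa_rec_e", "g_nmda_e", "g_gaba_e"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.b_fb < 0:
            raise ConfigurationError("b_fb must be >= 0")
        if self.scale <= 0:
            raise ConfigurationError("scale must be > 0")
        if self.background_mode not in ("global", "local"):
            raise ConfigurationError("background_mode must be 'global' or 'local'")
        if self.degree_mode not in ("binomial", "fixed_in"):
            raise ConfigurationError("degree_mode must be 'binomial' or 'fixed_in'")
        if self.nu_ext_x < 0 or self.nu_ext_d < 0 or self.nu_ext_n < 0:
            raise ConfigurationError("external rates must be >= 0")
        self.neuron_e.validate()
        self.neuron_i.validate()
        self.neuron_e_sens.validate()
        self.neuron_i_sens.validate()

    # --- realized (scaled) sizes ------------------------------------------
    def _scaled(self, n: int) -> int:
        m = int(round(n * self.scale))
        return max(4, m - m % 4)  # keep divisible by 4 (heterogeneous groups)

    @property
    def size_e1(self) -> int:
        return self._scaled(self.n_e1)

    @property
    def size_e2(self) -> int:
        return self._scaled(self.n_e2)

    @property
    def size_i_sens(self) -> int:
        return self._scaled(self.n_i_sens)

    @property
    def size_x(self) -> int:
        return self.n_x  # X is never scaled down

    @property
    def size_d1(self) -> int:
        return self._scaled(self.n_d1)

    @property
    def size_d2(self) -> int:
        return self._scaled(self.n_d2)

    @property
    def size_dn(self) -> int:
        return self._scaled(self.n_dn)

    @property
    def size_i_int(self) -> int:
        return self._scaled(self.n_i_int)

    @property
    def efficacy_scale(self) -> float:
        """Compensation for the all-to-all integration circuit only."""
        return 1.0 / self.scale

    def p_eff(self, p: float) -> float:
        """In-degree-preserving connection probability at reduced scale."""
        return min(1.0, p / self.scale)

    @property
    def w_minus_int(self) -> float:
        """Depression factor on connections from outside onto a selective
        population.

        Defaults to the calibrated value `w_minus_int_value`; setting it to
        None instead uses the excitation-conserving compensation
        w- = 1 - f (w+ - 1) / (1 - f) with f the fraction of excitatory
        cells in one selective population.
        """
        if self.w_minus_int_value is not None:
            return self.w_minus_int_value
        n_e = self.n_d1 + self.n_d2 + self.n_dn
        f = self.n_d1 / n_e
        return 1.0 - f * (self.w_plus_int - 1.0) / (1.0 - f)

    @property
    def g_fb(self) -> float:
        """Realized feedback efficacy g_FB = g_fb_unit * b_fb (nS)."""
        return self.g_fb_unit * self.b_fb

    def replace(self, **kw) -> "NetworkConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def reduced(cls, **overrides) -> "NetworkConfig":
        """Quarter-scale configuration with its own calibrated operating
        point (see docs/methods.md).

        Down-scaling the populations shifts both circuits' fluctuation
        regimes, so the sensory excitability and the integration-circuit
        NMDA/GABA_A efficacies are re-calibrated at scale 0.25 to preserve
        the full-scale phenomenology: a stable spontaneous state over the
        3-s pre-stimulus interval, categorical decisions within about 1 s
        of stimulus onset, and stimulus-correlated choices.
        """
        kw = dict(
            scale=0.25,
            degree_mode="fixed_in",
            g_nmda_e=0.26, g_nmda_i=0.2054,
            g_gaba_e=2.08, g_gaba_i=1.599,
            g_ff=1.3,
        )
        kw.update(overrides)
        return cls(**kw)


# ---------------------------------------------------------------------------
# seeding
# ---------------------------------------------------------------------------

#: stream identifiers of the counter-based seed derivation
STREAMS = {
    "connectivity": 0,
    "initial_conditions": 1,
    "background": 2,
    "stimulus": 3,
    "analysis": 4,
    "tie_break": 5,
}


def seed_sequence(master_seed: int, stream: str, *indices: int) -> np.random.SeedSequence:
    """Derive an independent SeedSequence for (stream, indices)."""
    return np.random.SeedSequence(
        entropy=int(master_seed) & 0x7FFFFFFF,
        spawn_key=(STREAMS[stream], *[int(i) for i in indices]),
    )


def derive_seed(master_seed: int, stream: str, *indices: int) -> int:
    """A 31-bit integer seed for (stream, indices), stable across runs."""
    state = seed_sequence(master_seed, stream, *indices).generate_state(1)
    return int(state[0]) & 0x7FFFFFFF


# ---------------------------------------------------------------------------
# (de)serialization
# ---------------------------------------------------------------------------

def _to_dict(cfg) -> dict:
    return asdict(cfg)


def save_config(network: NetworkConfig, stimulus: StimulusConfig, path) -> None:
    """Write both configs to a single YAML file."""
    doc = {"schema": "cpnet-config-1",
           "network": _to_dict(network),
           "stimulus": _to_dict(stimulus)}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def _from_dict(cls, data: dict, nested=()):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigurationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kw = dict(data)
    for name, sub in nested:
        if name in kw and isinstance(kw[name], dict):
            kw[name] = _from_dict(sub, kw[name])
    return cls(**kw)


NETWORK_NESTED = [("neuron_e", NeuronParams), ("neuron_i", NeuronParams),
                  ("neuron_e_sens", NeuronParams),
                  ("neuron_i_sens", NeuronParams)]


def load_config(path) -> tuple[NetworkConfig, StimulusConfig]:
    """Load and validate configs from YAML; unknown keys are rejected."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or doc.get("schema") != "cpnet-config-1":
        raise ConfigurationError("not a cpnet-config-1 file")
    net = _from_dict(NetworkConfig, doc.get("network", {}),
                     nested=NETWORK_NESTED)
    stim = _from_dict(StimulusConfig, doc.get("stimulus", {}))
    net.validate()
    stim.validate()
    return net, stim
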