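"""Construction of the sensory and integration circuits and their coupling.

The sensory circuit is a sparsely, randomly connected balanced E/I network
(populations E1, E2 selective for opposite motion directions, shared
inhibitory pool, external Poisson population X).  The integration circuit is
an all-to-all connected winner-take-all attractor network with selective
populations D1/D2, a non-selective pool Dn and an inhibitory pool.

Builders return explicit connection lists (source, target index pairs) so
that realized topology is inspectable and exportable; the simulation engine
consumes a compiled arrays view (`CompiledNetwork`) in which the all-to-all
integration circuit is represented by class-structured weights, which is
algebraically equivalent to per-edge delivery for uniform efficacies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig, ConfigurationError, derive_seed

__all__ = [
    "POPULATIONS",
    "SensoryCircuit",
    "IntegrationCircuit",
    "HierarchicalNetwork",
    "build_sensory_circuit",
    "build_integration_circuit",
    "couple_circuits",
    "build_network",
]

#: population order used for global neuron indexing
POPULATIONS = ("E1", "E2", "I_sens", "D1", "D2", "Dn", "I_int")
CLS = {name: i for i, name in enumerate(POPULATIONS)}


def _random_pairs(rng, n_src, n_tgt, p, exclude_self=False,
                  degree_mode="binomial"):
    """Random links for every ordered (src, tgt) pair.

    degree_mode="binomial": each pair is linked independently with
    probability p.  degree_mode="fixed_in": every target draws exactly
    round(p * n_src) distinct random sources; this removes the binomial
    in-degree variance, the dominant quenched-disorder term in reduced-scale
    networks (see docs/methods.md), while keeping sources random.
    """
    if p <= 0 or n_src == 0 or n_tgt == 0:
        return np.empty(0, np.int32), np.empty(0, np.int32)
    if p >= 1.0:
        src = np.repeat(np.arange(n_src, dtype=np.int32), n_tgt)
        tgt = np.tile(np.arange(n_tgt, dtype=np.int32), n_src)
    elif degree_mode == "fixed_in":
        k = int(round(p * (n_src - 1 if exclude_self else n_src)))
        scores = rng.random((n_tgt, n_src))
        if exclude_self:
            scores[np.arange(min(n_tgt, n_src)), np.arange(min(n_tgt, n_src))] = np.inf
        sel = np.argpartition(scores, k, axis=1)[:, :k]
        src = sel.ravel().astype(np.int32)
        tgt = np.repeat(np.arange(n_tgt, dtype=np.int32), k)
        return src, tgt
    else:
        mask = rng.random((n_src, n_tgt)) < p
        src, tgt = np.nonzero(mask)
        src = src.astype(np.int32)
        tgt = tgt.astype(np.int32)
    if exclude_self:
        keep = src != tgt
        src, tgt = src[keep], tgt[keep]
    return src, tgt


@dataclass
class Projection:
    """A realized pathway: parallel arrays of local source/target indices."""

    source_pop: str
    target_pop: str
    src: np.ndarray
    tgt: np.ndarray
    efficacy: float  # nS per synapse
    receptor: str  # "AMPA", "NMDA+AMPA" handled at circuit level, "GABA_A"

    def __len__(self):
        return len(self.src)


@dataclass
class SensoryCircuit:
    config: NetworkConfig
    seed: int
    projections: dict = field(default_factory=dict)
    #: X -> sensory background projection; in local mode X is split in halves
    #: targeting E1 and E2 exclusively (probability rescaled to keep each
    #: neuron's in-degree, hence mean and variance of drive, unchanged).
    x_projection: Projection | None = None

    @property
    def sizes(self):
        c = self.config
        return {"E1": c.size_e1, "E2": c.size_e2, "I_sens": c.size_i_sens,
                "X": c.size_x}


@dataclass
class IntegrationCircuit:
    config: NetworkConfig
    seed: int

    @property
    def sizes(self):
        c = self.config
        return {"D1": c.size_d1, "D2": c.size_d2, "Dn": c.size_dn,
                "I_int": c.size_i_int}

    def connections(self, source_pop: str, target_pop: str) -> Projection:
        """Explicit all-to-all connection list (self-links excluded)."""
        n_src, n_tgt = self.sizes[source_pop], self.sizes[target_pop]
        src = np.repeat(np.arange(n_src, dtype=np.int32), n_tgt)
        tgt = np.tile(np.arange(n_tgt, dtype=np.int32), n_src)
        if source_pop == target_pop:
            keep = src != tgt
            src, tgt = src[keep], tgt[keep]
        g = self.mean_efficacy(source_pop, target_pop)
        receptor = "GABA_A" if source_pop == "I_int" else "NMDA+AMPA"
        return Projection(source_pop, target_pop, src, tgt, g, receptor)

    def structure_factor(self, source_pop: str, target_pop: str) -> float:
        """w+ within a selective population, w- onto it from outside, 1 else."""
        c = self.config
        if target_pop in ("D1", "D2") and source_pop in ("D1", "D2", "Dn"):
            return c.w_plus_int if source_pop == target_pop else c.w_minus_int
        return 1.0

    def mean_efficacy(self, source_pop: str, target_pop: str,
                      receptor: str = "NMDA") -> float:
        c = self.config
        if source_pop == "I_int":
            base = c.g_gaba_i if target_pop == "I_int" else c.g_gaba_e
            return base * c.efficacy_scale
        base = {"NMDA": (c.g_nmda_e, c.g_nmda_i),
                "AMPA": (c.g_ampa_rec_e, c.g_ampa_rec_i)}[receptor]
        g = base[1] if target_pop == "I_int" else base[0]
        return g * self.structure_factor(source_pop, target_pop) * c.efficacy_scale


def build_sensory_circuit(config: NetworkConfig, seed: int | None = None) -> SensoryCircuit:
    """Realize the sparse random connectivity of the sensory circuit.

    Every ordered neuron pair of a connected pathway is linked independently
    with the pathway's probability; within-population E links are potentiated
    by w+ and across-population E links weakened by w-.
    """
    config.validate()
    if seed is None:
        seed = derive_seed(config.master_seed, "connectivity", 0)
    rng = np.random.default_rng(seed)
    c = config
    dm = c.degree_mode
    p_rec = c.p_eff(c.p_sens)
    circ = SensoryCircuit(config=c, seed=int(seed))
    sizes = circ.sizes
    pops_e = ("E1", "E2")
    # recurrent E -> E / E -> I / I -> all
    for sp in pops_e:
        for tp in pops_e:
            w = c.w_plus_sens if sp == tp else c.w_minus_sens
            s, t = _random_pairs(rng, sizes[sp], sizes[tp], p_rec,
                                 exclude_self=(sp == tp), degree_mode=dm)
            circ.projections[(sp, tp)] = Projection(
                sp, tp, s, t, w * c.g_ee_sens, "AMPA")
        s, t = _random_pairs(rng, sizes[sp], sizes["I_sens"], p_rec,
                             degree_mode=dm)
        circ.projections[(sp, "I_sens")] = Projection(
            sp, "I_sens", s, t, c.g_ei_sens, "AMPA")
    for tp in ("E1", "E2", "I_sens"):
        s, t = _random_pairs(rng, sizes["I_sens"], sizes[tp], p_rec,
                             exclude_self=(tp == "I_sens"), degree_mode=dm)
        circ.projections[("I_sens", tp)] = Projection(
            "I_sens", tp, s, t, c.g_ie_sens, "GABA_A")
    # external background X -> sensory
    n_x = sizes["X"]
    n_sens = sizes["E1"] + sizes["E2"] + sizes["I_sens"]
    if c.background_mode == "global":
        s, t = _random_pairs(rng, n_x, n_sens, c.p_x, degree_mode=dm)
    else:
        # local mode: first half of X targets E1 only, second half E2 only,
        # with doubled probability so each E neuron keeps in-degree p_x*n_x;
        # I neurons keep global background from the whole of X.
        half = n_x // 2
        p_loc = min(1.0, c.p_x * n_x / half)
        s1, t1 = _random_pairs(rng, half, sizes["E1"], p_loc, degree_mode=dm)
        s2, t2 = _random_pairs(rng, n_x - half, sizes["E2"], p_loc,
                               degree_mode=dm)
        s3, t3 = _random_pairs(rng, n_x, sizes["I_sens"], c.p_x,
                               degree_mode=dm)
        s = np.concatenate([s1, s2 + half, s3])
        t = np.concatenate([t1, t2 + sizes["E1"],
                            t3 + sizes["E1"] + sizes["E2"]]).astype(np.int32)
        s = s.astype(np.int32)
    circ.x_projection = Projection("X", "sensory", s, t, c.g_x, "AMPA")
    return circ


def build_integration_circuit(config: NetworkConfig, seed: int | None = None
                              ) -> IntegrationCircuit:
    """All-to-all integration circuit (connection lists realized lazily)."""
    config.validate()
    if seed is None:
        seed = derive_seed(config.master_seed, "connectivity", 1)
    return IntegrationCircuit(config=config, seed=int(seed))


@dataclass
class HierarchicalNetwork:
    config: NetworkConfig
    sensory: SensoryCircuit
    integration: IntegrationCircuit
    ff: dict  # {("E1","D1"): Projection, ("E2","D2"): Projection}
    fb: dict  # {("D1","E1"): Projection, ("D2","E2"): Projection}
    #: per sensory-E-neuron feedback factor (1 = homogeneous b_fb)
    fb_factor: np.ndarray | None = None
    #: per sensory-E-neuron stimulus modulation factors (heterogeneous net)
    sigma_stim_factor: np.ndarray | None = None
    sigma_ind_factor: np.ndarray | None = None
    group_labels: np.ndarray | None = None  # heterogeneity groups, see protocol

    _compiled: object = None

    # global index offsets, in POPULATIONS order
    @property
    def offsets(self):
        c = self.config
        sizes = [c.size_e1, c.size_e2, c.size_i_sens, c.size_d1, c.size_d2,
                 c.size_dn, c.size_i_int]
        off = np.concatenate([[0], np.cumsum(sizes)])
        return off

    @property
    def n_neurons(self):
        return int(self.offsets[-1])

    @property
    def n_sens_e(self):
        return self.config.size_e1 + self.config.size_e2

    def population_slice(self, name: str) -> slice:
        i = CLS[name]
        off = self.offsets
        return slice(int(off[i]), int(off[i + 1]))

    def compiled(self):
        from .engine import compile_network
        if self._compiled is None:
            self._compiled = compile_network(self)
        return self._compiled


def couple_circuits(sensory: SensoryCircuit, integration: IntegrationCircuit,
                    p_ff: float | None = None, p_fb: float | None = None,
                    b_fb: float | None = None, seed: int | None = None
                    ) -> HierarchicalNetwork:
    """Topographic coupling: E1->D1 and E2->D2 feedforward, D1->E1 and
    D2->E2 feedback (no cross-coupling)."""
    c = sensory.config
    if integration.config is not c and integration.config != c:
        raise ConfigurationError("sensory and integration configs differ")
    if p_ff is None:
        p_ff = c.p_ff
    if p_fb is None:
        p_fb = c.p_fb
    if b_fb is not None:
        c = c.replace(b_fb=b_fb)
        sensory.config = c
        integration.config = c
    if seed is None:
        seed = derive_seed(c.master_seed, "connectivity", 2)
    rng = np.random.default_rng(seed)
    ssz, isz = sensory.sizes, integration.sizes
    ff = {}
    fb = {}
    dm = c.degree_mode
    for e_pop, d_pop in (("E1", "D1"), ("E2", "D2")):
        s, t = _random_pairs(rng, ssz[e_pop], isz[d_pop], c.p_eff(p_ff),
                             degree_mode=dm)
        ff[(e_pop, d_pop)] = Projection(e_pop, d_pop, s, t, c.g_ff, "AMPA")
        s, t = _random_pairs(rng, isz[d_pop], ssz[e_pop], c.p_eff(p_fb),
                             degree_mode=dm)
        fb[(d_pop, e_pop)] = Projection(d_pop, e_pop, s, t, c.g_fb, "AMPA")
    return HierarchicalNetwork(config=c, sensory=sensory,
                               integration=integration, ff=ff, fb=fb)


def build_network(config: NetworkConfig) -> HierarchicalNetwork:
    """Build the full hierarchical network from a config (seeded from
    config.master_seed via the connectivity stream)."""
    sens = build_sensory_circuit(config)
    integ = build_integration_circuit(config)
    return couple_circuits(sens, integ)
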