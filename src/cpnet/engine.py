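"""Forward-Euler integration of the coupled spiking circuits.

The kernel advances all leaky integrate-and-fire neurons with a fixed step
(default dt = 0.1 ms).  Synapses are conductance based: AMPA and GABA_A
conductances decay exponentially and jump on (delayed) spike arrival; NMDA
channels follow the two-variable saturating gating scheme with a
voltage-dependent magnesium block.  Sparse pathways (sensory recurrent,
X background, feedforward, feedback) are delivered through per-edge CSR
adjacency; the all-to-all integration circuit is evaluated through
per-presynaptic-neuron gating traces combined with class-structured weight
sums, which is exact for uniform efficacies.

All randomness inside a run is drawn from seeds passed in explicitly, so a
trial is a pure function of (network, stimulus, seeds).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .network import CLS, HierarchicalNetwork

__all__ = ["compile_network", "NetworkState", "init_state", "run",
           "NumericalDivergenceError", "poisson_background",
           "events_to_step_csr"]

V_EXC = 0.0  # mV, AMPA/NMDA reversal
V_INH = -70.0  # mV, GABA_A reversal


class NumericalDivergenceError(RuntimeError):
    """A state variable became non-finite during integration."""

    def __init__(self, neuron: int, time_ms: float):
        self.neuron = int(neuron)
        self.time_ms = float(time_ms)
        super().__init__(
            f"non-finite state variable at neuron {neuron}, t={time_ms:.1f} ms")


# ---------------------------------------------------------------------------
# compiled arrays view
# ---------------------------------------------------------------------------

@dataclass
class CompiledNetwork:
    config: object
    n: int
    n_sens: int  # number of sensory neurons (E1+E2+I)
    n_sens_e: int
    cls: np.ndarray  # int8 population class per neuron
    cm: np.ndarray
    gl: np.ndarray
    el: np.ndarray
    vth: np.ndarray
    vr: np.ndarray
    ref_steps: np.ndarray
    indptr: np.ndarray  # CSR over all neurons (sparse pathways)
    targets: np.ndarray
    weights: np.ndarray
    is_gaba_src: np.ndarray
    x_indptr: np.ndarray  # CSR over X cells
    x_targets: np.ndarray
    x_weights: np.ndarray
    gA: np.ndarray  # (7,) postsyn recurrent AMPA base efficacy by class
    gN: np.ndarray
    gG: np.ndarray
    g_ext: np.ndarray  # (7,) external AMPA efficacy by class
    lam_ext: np.ndarray  # (7,) Poisson mean per step by class
    wcoef: np.ndarray  # (7, 3) structure weights over source classes D1,D2,Dn
    delay_steps: int
    dt: float


def compile_network(net: HierarchicalNetwork) -> CompiledNetwork:
    c = net.config
    off = net.offsets
    n = net.n_neurons
    sizes = np.diff(off).astype(np.int64)
    cls = np.repeat(np.arange(7, dtype=np.int8), sizes)
    n_sens = int(off[3])
    n_sens_e = int(off[2])

    # per-class neuron parameters: sensory E (E1, E2), sensory I, then the
    # integration circuit's E (D1, D2, Dn) and I cells
    by_cls = [c.neuron_e_sens, c.neuron_e_sens, c.neuron_i_sens,
              c.neuron_e, c.neuron_e, c.neuron_e, c.neuron_i]

    def percls(attr):
        return np.array([getattr(p, attr) for p in by_cls])[cls]

    cm = percls("capacitance")
    gl = percls("leak_conductance")
    el = percls("leak_reversal")
    vth = percls("spike_threshold")
    vr = percls("reset_potential")
    ref_steps = np.round(percls("refractory_period") / c.dt).astype(np.int32)

    # ---- sparse pathways: sensory recurrent + FF + FB -------------------
    src_list, tgt_list, w_list = [], [], []

    def add(proj, src_pop, tgt_pop, weight=None, per_target_factor=None):
        if len(proj) == 0:
            return
        s = proj.src.astype(np.int64) + off[CLS[src_pop]]
        t = proj.tgt.astype(np.int64) + off[CLS[tgt_pop]]
        w = np.full(len(s), proj.efficacy if weight is None else weight)
        if per_target_factor is not None:
            w = w * per_target_factor[proj.tgt.astype(np.int64)
                                      + off[CLS[tgt_pop]]]
        src_list.append(s)
        tgt_list.append(t)
        w_list.append(w)

    for (sp, tp), proj in net.sensory.projections.items():
        add(proj, sp, tp)
    for (sp, tp), proj in net.ff.items():
        add(proj, sp, tp)
    fb_factor = None
    if net.fb_factor is not None:
        fb_factor = np.zeros(n)
        fb_factor[:n_sens_e] = net.fb_factor
    for (sp, tp), proj in net.fb.items():
        add(proj, sp, tp, per_target_factor=fb_factor)

    if src_list:
        src = np.concatenate(src_list)
        tgt = np.concatenate(tgt_list)
        wts = np.concatenate(w_list)
        order = np.argsort(src, kind="stable")
        src, tgt, wts = src[order], tgt[order], wts[order]
        indptr = np.searchsorted(src, np.arange(n + 1)).astype(np.int64)
        targets = tgt.astype(np.int32)
        weights = wts.astype(np.float64)
    else:
        indptr = np.zeros(n + 1, np.int64)
        targets = np.empty(0, np.int32)
        weights = np.empty(0, np.float64)
    is_gaba_src = (cls == CLS["I_sens"])

    # ---- X background CSR ------------------------------------------------
    xp = net.sensory.x_projection
    xs = xp.src.astype(np.int64)
    xt = xp.tgt.astype(np.int64)  # already global sensory index (0..n_sens)
    order = np.argsort(xs, kind="stable")
    xs, xt = xs[order], xt[order]
    n_x = c.size_x
    x_indptr = np.searchsorted(xs, np.arange(n_x + 1)).astype(np.int64)
    x_targets = xt.astype(np.int32)
    x_weights = np.full(len(xt), xp.efficacy, np.float64)

    # ---- integration class parameters ------------------------------------
    es = c.efficacy_scale
    gA = np.zeros(7)
    gN = np.zeros(7)
    gG = np.zeros(7)
    g_ext = np.zeros(7)
    lam = np.zeros(7)
    for pop in ("D1", "D2", "Dn"):
        i = CLS[pop]
        gA[i] = c.g_ampa_rec_e * es
        gN[i] = c.g_nmda_e * es
        gG[i] = c.g_gaba_e * es
        g_ext[i] = c.g_ext_e
    i = CLS["I_int"]
    gA[i] = c.g_ampa_rec_i * es
    gN[i] = c.g_nmda_i * es
    gG[i] = c.g_gaba_i * es
    g_ext[i] = c.g_ext_i
    lam[CLS["D1"]] = lam[CLS["D2"]] = c.nu_ext_d * c.dt * 1e-3
    lam[CLS["Dn"]] = lam[CLS["I_int"]] = c.nu_ext_n * c.dt * 1e-3

    wcoef = np.zeros((7, 3))  # source classes D1, D2, Dn
    wp, wm = c.w_plus_int, c.w_minus_int
    wcoef[CLS["D1"]] = (wp, wm, wm)
    wcoef[CLS["D2"]] = (wm, wp, wm)
    wcoef[CLS["Dn"]] = (1.0, 1.0, 1.0)
    wcoef[CLS["I_int"]] = (1.0, 1.0, 1.0)

    delay_steps = max(1, int(round(c.delay / c.dt)))
    return CompiledNetwork(
        config=c, n=n, n_sens=n_sens, n_sens_e=n_sens_e, cls=cls, cm=cm,
        gl=gl, el=el, vth=vth, vr=vr, ref_steps=ref_steps, indptr=indptr,
        targets=targets, weights=weights, is_gaba_src=is_gaba_src,
        x_indptr=x_indptr, x_targets=x_targets, x_weights=x_weights,
        gA=gA, gN=gN, gG=gG, g_ext=g_ext, lam_ext=lam, wcoef=wcoef,
        delay_steps=delay_steps, dt=c.dt)


# ---------------------------------------------------------------------------
# network state
# ---------------------------------------------------------------------------

@dataclass
class NetworkState:
    """Dynamic variables of every neuron plus pending delayed spikes."""

    v: np.ndarray
    g_ampa: np.ndarray  # postsynaptic AMPA conductance (nS)
    g_gaba: np.ndarray  # postsynaptic GABA_A conductance, sensory neurons
    a_trace: np.ndarray  # presynaptic AMPA gating, integration E neurons
    x_nmda: np.ndarray
    s_nmda: np.ndarray
    gab_trace: np.ndarray  # presynaptic GABA gating, integration I neurons
    ref_count: np.ndarray
    ring: np.ndarray  # pending delayed spikes (slot, idx)
    ring_count: np.ndarray
    step: int = 0

    def copy(self) -> "NetworkState":
        return NetworkState(*(x.copy() if isinstance(x, np.ndarray) else x
                              for x in (self.v, self.g_ampa, self.g_gaba,
                                        self.a_trace, self.x_nmda, self.s_nmda,
                                        self.gab_trace, self.ref_count,
                                        self.ring, self.ring_count, self.step)))


def init_state(compiled: CompiledNetwork, seed: int) -> NetworkState:
    """Fresh state; membrane potentials uniform in [reset, threshold)."""
    rng = np.random.default_rng(seed)
    n = compiled.n
    v = compiled.vr + rng.random(n) * (compiled.vth - compiled.vr)
    rb_len = compiled.delay_steps + 1
    return NetworkState(
        v=v,
        g_ampa=np.zeros(n), g_gaba=np.zeros(n),
        a_trace=np.zeros(n), x_nmda=np.zeros(n), s_nmda=np.zeros(n),
        gab_trace=np.zeros(n),
        ref_count=np.zeros(n, np.int32),
        ring=np.zeros((rb_len, n), np.int32),
        ring_count=np.zeros(rb_len, np.int32),
        step=0)


# ---------------------------------------------------------------------------
# Poisson background utilities
# ---------------------------------------------------------------------------

def poisson_background(rate: float, n_sources: int, duration: float,
                       seed: int):
    """Independent homogeneous Poisson spike trains.

    Returns (times_ms, source_ids), sorted by time.  rate is per source in
    spikes/s, duration in ms.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * duration * 1e-3, size=n_sources)
    total = int(counts.sum())
    times = rng.random(total) * duration
    ids = np.repeat(np.arange(n_sources, dtype=np.int32), counts)
    order = np.argsort(times, kind="stable")
    return times[order], ids[order]


def events_to_step_csr(times_ms: np.ndarray, ids: np.ndarray, dt: float,
                       n_steps: int):
    """Bucket spike events into simulation steps: (offsets, ids)."""
    steps = np.minimum((times_ms / dt).astype(np.int64), n_steps - 1)
    order = np.argsort(steps, kind="stable")
    steps, ids = steps[order], ids[order]
    offsets = np.searchsorted(steps, np.arange(n_steps + 1)).astype(np.int64)
    return offsets, ids.astype(np.int32)


# ---------------------------------------------------------------------------
# the Euler kernel
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_core(n_steps, step0, dt, delay_steps,
              cls, cm, gl, el, vth, vr, ref_steps,
              indptr, targets, weights, is_gaba_src,
              x_indptr, x_targets, x_weights, xs_offsets, xs_ids,
              gA, gN, gG, g_ext, lam_ext, wcoef,
              i_stim, stim_start_step, steps_per_sample, n_sens_e,
              v, g_ampa, g_gaba, a_trace, x_nmda, s_nmda, gab_trace,
              ref_count, ring, ring_count,
              ext_seed, spike_n, spike_t, rec_idx, v_rec):
    np.random.seed(ext_seed)
    n = v.shape[0]
    rb_len = delay_steps + 1
    dA = np.exp(-dt / 2.0)      # AMPA decay (tau = 2 ms)
    dG = np.exp(-dt / 5.0)      # GABA_A decay (tau = 5 ms)
    dX = np.exp(-dt / 2.0)      # NMDA rise variable (tau = 2 ms)
    tau_nmda = 100.0
    alpha = 0.5
    mg = 1.0
    n_samples = i_stim.shape[1]
    stim_end_step = stim_start_step + n_samples * steps_per_sample
    n_spikes = 0
    cap = spike_n.shape[0]
    n_rec = rec_idx.shape[0]

    for it in range(n_steps):
        step = step0 + it
        t = step * dt
        # 1) exponential decay of conductances and gating traces
        for i in range(n):
            g_ampa[i] *= dA
            g_gaba[i] *= dG
            a_trace[i] *= dA
            x_nmda[i] *= dX
            s_nmda[i] += dt * (-s_nmda[i] / tau_nmda
                               + alpha * x_nmda[i] * (1.0 - s_nmda[i]))
            gab_trace[i] *= dG
        # 2) delayed recurrent spikes due now
        slot = step % rb_len
        for q in range(ring_count[slot]):
            j = ring[slot, q]
            for e in range(indptr[j], indptr[j + 1]):
                tg = targets[e]
                if is_gaba_src[j]:
                    g_gaba[tg] += weights[e]
                else:
                    g_ampa[tg] += weights[e]
            cj = cls[j]
            if cj == 3 or cj == 4 or cj == 5:  # integration E
                a_trace[j] += 1.0
                x_nmda[j] += 1.0
            elif cj == 6:  # integration I
                gab_trace[j] += 1.0
        ring_count[slot] = 0
        # 3) external X background spikes (shared among sensory targets)
        for q in range(xs_offsets[it], xs_offsets[it + 1]):
            xc = xs_ids[q]
            for e in range(x_indptr[xc], x_indptr[xc + 1]):
                g_ampa[x_targets[e]] += x_weights[e]
        # 4) independent external Poisson onto integration neurons
        for i in range(n):
            li = lam_ext[cls[i]]
            if li > 0.0:
                k = np.random.poisson(li)
                if k > 0:
                    g_ampa[i] += k * g_ext[cls[i]]
        # 5) population sums of integration gating
        S_a0 = 0.0
        S_a1 = 0.0
        S_a2 = 0.0
        S_s0 = 0.0
        S_s1 = 0.0
        S_s2 = 0.0
        S_g = 0.0
        for i in range(n):
            ci = cls[i]
            if ci == 3:
                S_a0 += a_trace[i]
                S_s0 += s_nmda[i]
            elif ci == 4:
                S_a1 += a_trace[i]
                S_s1 += s_nmda[i]
            elif ci == 5:
                S_a2 += a_trace[i]
                S_s2 += s_nmda[i]
            elif ci == 6:
                S_g += gab_trace[i]
        # 6) membrane update
        in_stim = (step >= stim_start_step) and (step < stim_end_step)
        if in_stim:
            samp = (step - stim_start_step) // steps_per_sample
        else:
            samp = 0
        wslot = (step + delay_steps) % rb_len
        for i in range(n):
            if ref_count[i] > 0:
                ref_count[i] -= 1
                v[i] = vr[i]
                continue
            vi = v[i]
            ci = cls[i]
            i_syn = g_ampa[i] * (vi - 0.0) + g_gaba[i] * (vi + 70.0)
            if ci >= 3:  # integration circuit: recurrent via traces
                wa = (wcoef[ci, 0] * S_a0 + wcoef[ci, 1] * S_a1
                      + wcoef[ci, 2] * S_a2)
                ws = (wcoef[ci, 0] * S_s0 + wcoef[ci, 1] * S_s1
                      + wcoef[ci, 2] * S_s2)
                wg = S_g
                if ci == 3:
                    wa -= wcoef[ci, 0] * a_trace[i]
                    ws -= wcoef[ci, 0] * s_nmda[i]
                elif ci == 4:
                    wa -= wcoef[ci, 1] * a_trace[i]
                    ws -= wcoef[ci, 1] * s_nmda[i]
                elif ci == 5:
                    wa -= wcoef[ci, 2] * a_trace[i]
                    ws -= wcoef[ci, 2] * s_nmda[i]
                else:
                    wg -= gab_trace[i]
                b_mg = 1.0 / (1.0 + mg * np.exp(-0.062 * vi) / 3.57)
                i_syn += (gA[ci] * wa * (vi - 0.0)
                          + gN[ci] * ws * b_mg * (vi - 0.0)
                          + gG[ci] * wg * (vi + 70.0))
            i_ext = 0.0
            if in_stim and i < n_sens_e:
                i_ext = i_stim[i, samp]
            # dV/dt = (-gL (V-EL) - I_syn)/Cm + I_ext/Cm ; nS*mV = pA, Cm in nF
            v_new = vi + dt * ((-gl[i] * (vi - el[i]) - i_syn) * 1e-3
                               + i_ext) / cm[i]
            if v_new >= vth[i]:
                if n_spikes < cap:
                    spike_n[n_spikes] = i
                    spike_t[n_spikes] = t
                n_spikes += 1
                v[i] = vr[i]
                ref_count[i] = ref_steps[i]
                ring[wslot, ring_count[wslot]] = i
                ring_count[wslot] += 1
            else:
                v[i] = v_new
        for r in range(n_rec):
            v_rec[it, r] = v[rec_idx[r]]
        # 7) divergence check
        if it % 200 == 199:
            for i in range(n):
                if not np.isfinite(v[i]):
                    return -1, i, t
    return n_spikes, -1, 0.0


def run(compiled: CompiledNetwork, state: NetworkState, n_steps: int,
        i_stim: np.ndarray | None = None, stim_start_step: int = 0,
        steps_per_sample: int = 10,
        x_events: tuple[np.ndarray, np.ndarray] | None = None,
        ext_seed: int = 0, record_v: np.ndarray | None = None,
        spike_cap_rate: float = 120.0):
    """Advance `state` by `n_steps`; returns (spike_neurons, spike_times_ms).

    i_stim: per-sensory-E-neuron stimulus current samples (nA), shape
    (n_sens_e, n_samples), each sample held for `steps_per_sample` steps
    starting at `stim_start_step` (relative to state.step at entry? no:
    absolute step index of this run segment).
    x_events: per-step CSR (offsets over this run's steps, X cell ids).
    """
    n = compiled.n
    if i_stim is None:
        i_stim = np.zeros((compiled.n_sens_e, 0), np.float32)
    if x_events is None:
        offsets = np.zeros(n_steps + 1, np.int64)
        ids = np.empty(0, np.int32)
    else:
        offsets, ids = x_events
    cap = int(spike_cap_rate * n * n_steps * compiled.dt * 1e-3) + 10000
    spike_n = np.empty(cap, np.int32)
    spike_t = np.empty(cap, np.float64)
    if record_v is None:
        rec_idx = np.empty(0, np.int32)
        v_rec = np.empty((n_steps, 0), np.float64)
    else:
        rec_idx = np.asarray(record_v, np.int32)
        v_rec = np.empty((n_steps, len(rec_idx)), np.float64)
    count, bad_neuron, bad_t = _run_core(
        n_steps, state.step, compiled.dt, compiled.delay_steps,
        compiled.cls, compiled.cm, compiled.gl, compiled.el, compiled.vth,
        compiled.vr, compiled.ref_steps,
        compiled.indptr, compiled.targets, compiled.weights,
        compiled.is_gaba_src,
        compiled.x_indptr, compiled.x_targets, compiled.x_weights,
        offsets, ids,
        compiled.gA, compiled.gN, compiled.gG, compiled.g_ext,
        compiled.lam_ext, compiled.wcoef,
        np.ascontiguousarray(i_stim, dtype=np.float32), stim_start_step,
        steps_per_sample, compiled.n_sens_e,
        state.v, state.g_ampa, state.g_gaba, state.a_trace, state.x_nmda,
        state.s_nmda, state.gab_trace, state.ref_count, state.ring,
        state.ring_count,
        int(ext_seed) & 0x7FFFFFFF, spike_n, spike_t, rec_idx, v_rec)
    if count < 0:
        raise NumericalDivergenceError(bad_neuron, bad_t)
    if count > cap:
        raise RuntimeError("spike buffer overflow; raise spike_cap_rate")
    state.step += n_steps
    out = (spike_n[:count].copy(), spike_t[:count].copy())
    if record_v is not None:
        return out[0], out[1], v_rec
    return out
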