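# Model and methods

`cpnet` simulates a two-stage spiking-circuit model of a fixed-duration,
two-alternative motion discrimination task and quantifies how bottom-up
stimulus co-fluctuations and top-down decision feedback shape the
choice-related variability of sensory neurons.

## Architecture

**Sensory circuit (MT-like).** A balanced, sparsely connected E/I network:
two excitatory populations E1 and E2 (800 cells each at full scale)
selective for opposite motion directions, a shared inhibitory pool (400
cells), and an external population X of 1,000 independent Poisson units at
ν_ext = 12.5 sp/s driving all sensory neurons through AMPA synapses
(p_x = 0.32, g_x = 1.71 nS). Recurrent connectivity has probability
p = 0.2; within-population excitatory links are potentiated (w+ = 1.3) and
across-population links depressed (w− = 0.7); efficacies are
g_EE = 0.76 nS, g_EI = 1.52 nS and g_I = 12.6 nS (AMPA and GABA_A
kinetics, τ = 2 ms and 5 ms). In the *local background* variant the X
population is split into two halves that project exclusively to E1 and E2
(connection probability rescaled so each neuron's background in-degree is
unchanged), turning shared background noise into a bottom-up correlation
source.

**Integration circuit (LIP/FEF-like).** An all-to-all conductance-based
winner-take-all attractor network: selective populations D1 and D2 (240
cells each), a non-selective pool Dn (1,120) and an inhibitory pool (400),
with AMPA + saturating NMDA recurrent excitation, GABA_A inhibition, a
potentiation factor w+ = 1.6 within D1 and D2, the excitation-conserving
depression w− = 1 − f(w+ − 1)/(1 − f) (f = 0.15) on connections onto a
selective population, and per-neuron external Poisson drive (2,392 sp/s
onto D1/D2, 2,400 sp/s onto Dn and I, g_ext = 2.1/1.62 nS).

**Coupling.** Topographic feedforward AMPA projections E1→D1 and E2→D2
(p_FF = 0.2, calibrated efficacy g_FF) and weak feedback D1→E1, D2→E2
(p_FB = 0.2) with efficacy g_FB = 0.0668 nS · b_FB, b_FB ∈ [0, 6].

**Neurons.** Leaky integrate-and-fire with conductance synapses, forward
Euler at dt = 0.1 ms, a uniform 0.5 ms transmission delay, and NMDA
voltage dependence through the standard magnesium block
B(V) = 1/(1 + [Mg]e^(−0.062V)/3.57).

## Stimulus model

Each sensory neuron k of population β receives the injected current

    I_k(t) = I0 (1 + s_β(t) + s_ind,k(t)),    I0 = 0.08 nA

with s_β(t) = γ_β c + σ_stim z_β(t) and s_ind,k(t) = σ_ind z_ind,k(t).
c is the signed motion coherence, γ_E2 = −γ_E1, and the z's are mutually
independent unit-variance Ornstein–Uhlenbeck processes (τ = 20 ms, exact
discretization, so unit variance holds at any sampling step) emulating
frame-to-frame motion-energy fluctuations of a random-dot kinematogram.
σ_stim = σ_ind = 0.212 σ, where σ is the per-experiment modulation
strength (σ = 1 default, 1.33 for the slow variant, 2.7 for the
bound-crossing analyses). *Replicate* stimuli freeze one realization (the
bank stores seeds; currents are reconstructed bit-identically), so the
stimulus contributes literally zero trial-to-trial variability;
*non-replicate* mode draws a fresh realization every trial. Because the
stimulus is a current, not input spikes, this distinction is exact.

## Protocol

A trial is a 3-s pre-stimulus interval followed by a 2-s stimulus epoch.
The choice is the decision population with the higher rate over the last
50 ms of the stimulus; exact ties fall to a seeded fair coin. Batches
derive all per-trial randomness (initial conditions, background spikes,
stimulus seeds, tie-breaks) from a master seed through counter-based
streams, so an ensemble is bit-reproducible and independent of worker
count. Replicate stimuli whose choice split exceeds 95% in one direction
are excluded from CP analysis. The heterogeneous variant splits each
sensory population into four equal groups (S±FB±); S+ cells carry the full
modulation on the common term (σ_stim,k = √2·0.212σ, σ_ind,k = 0), S−
cells on the individual term, and FB+ cells receive doubled feedback —
preserving each neuron's input-current s.d. and the population-mean
top-down drive exactly.

## Analyses

Spike counts are box-kernel counts on a closed window [t − T/2, t + T/2]
over raw spike times; *adjusted* windows vary T′ per neuron and time so the
cross-trial mean count equals r_k·T. Fano factors and Pearson spike-count
correlations support a shift correction that subtracts the symmetrized
cyclic lag-1 across-trial predictor, removing slow nonstationarity.
Correlation matrices ρ(t_i, t_j) use the non-overlapping grid
t_i = (i − ½)T, T = 250 ms, computed within coherence and averaged.
CP_k(t;T) is the ROC area (Mann–Whitney with half-credit ties) between
choice-conditioned count distributions; the preferred choice of model
neurons is structural (E1 → choice 1). CP stability is the Spearman rank
correlation across neurons of CP between time-bin pairs, averaged over
trial resamples. Psychophysical kernels are the choice-conditioned
difference of the common evidence term d(t) = s_E1 − s_E2; the integration
window is the onset-anchored interval holding 85% of the positive-part
kernel area (negative excursions clipped; both conventions available as
flags). Psychometric curves are fitted by binomial maximum likelihood to
P(c) = 1 − 0.5 exp(−(c/α)^β); the discrimination threshold solves
P(c) = 0.82 exactly.

## Calibration of unprinted parameters

Only some parameters of the circuits are fixed by the published
description; the remaining constants were calibrated once against the
target phenomenology (stable spontaneous state over the 3-s pre-interval,
categorical decisions within ~1 s of stimulus onset at c = 0, σ = 1,
approximately linear sensory rate vs. coherence) and then frozen:

- Integration-circuit efficacies start from the canonical decision-network
  set (AMPA 0.05/0.04 nS, NMDA 0.165/0.13 nS, GABA_A 1.3/1.0 nS for E/I
  targets). With the printed w+ = 1.6 that set leaves the symmetric state
  too stable (no decisions); NMDA and GABA_A were scaled up together
  (g_NMDA,E = 0.20 nS, g_GABA,E = 1.60 nS, I-target values in proportion),
  which restores the decision instability while keeping spontaneous rates
  (D ≈ 2–3 sp/s, I ≈ 8 sp/s) unchanged.
- Sensory LIF constants use the same frame as the integration circuit
  (C_m = 0.5/0.2 nF, g_L = 25/20 nS, θ = −50 mV, V_r = −55 mV, t_ref =
  2/1 ms) with the leak reversal raised to −62 mV, placing the balanced
  circuit at low cortical rates (~1–3 sp/s; the 1 sp/s minimum-rate unit
  selection threshold is consistent with such rates) where it tracks the
  stimulus differentially through the w+/w− competition structure.
- γ_E1 = 0.6 and g_FF = 0.55 nS (full scale) put zero-coherence decisions
  at ~0.5–1 s and keep the pre-interval stable.

All of these are explicit config fields and should be revisited if an
independently verified parameter table becomes available.

## Reduced-scale operating point

Full-scale ensembles (2,000+ trials of a 5,000-neuron network) take many
CPU-hours. The test suite and the acceptance script therefore run a
quarter-scale configuration (`NetworkConfig.reduced()`):

- Population counts shrink by 4; the X population keeps its full size and
  sparse connection probabilities are raised by 4 (capped at 1), so every
  neuron keeps its full-scale in-degree and efficacies — per-neuron input
  statistics are preserved and only population counts shrink.
- The all-to-all integration circuit cannot preserve its in-degree; its
  recurrent efficacies carry the 1/scale compensation and its NMDA/GABA_A
  pair is recalibrated (0.26/2.08 nS) to restore the same decision
  phenomenology; g_FF = 1.3 nS compensates the lower reduced-scale sensory
  evoked rate.
- Reduced-scale connectivity uses fixed per-target in-degrees with random
  sources instead of per-pair Bernoulli links: at quarter scale binomial
  in-degree variance is the dominant quenched disorder and can push the
  zero-coherence choice split past 90/10 on unlucky wirings; removing it
  restores near-symmetric choices while keeping sources random. Full-scale
  builds keep independent Bernoulli links.
- Batches split the 3-s pre-interval into one shared 2-s burn-in plus a
  1-s per-trial segment with fresh background input; network state memory
  decays on the ~100 ms NMDA scale, so trials remain effectively
  independent.

What reduced-scale runs do and do not show: the qualitative machinery —
decaying early-weighted psychophysical kernels, the EiEi > 0 > EiEj
correlation sign structure with a near-zero all-pair mean, decaying
bottom-up CP, rising top-down CP and rate boosts, fewer reversals with
stronger feedback, window ordering between slow and default dynamics — is
reproduced, but effect magnitudes are compressed: with a quarter of the
neurons, pooled-rate shot noise doubles relative to the stimulus signal, so
CP amplitudes are ~0.51–0.54 rather than ~0.55, pair correlations are a few
×10⁻³ rather than a few ×10⁻², and the attractor stabilizes decisions more
slowly, lengthening the 85% integration window (≈1.5–1.7 s vs. 0.675/1.057 s
at full scale). Absolute window values and effect amplitudes should be
measured at full scale; the reduced configuration is for mechanism and
regression testing.

## Numerical choices and degenerate inputs

Forward Euler at dt = 0.1 ms (spike threshold crossing detected per step;
refractory neurons clamp at reset). Counts use closed windows on raw spike
times; window-edge coincidences have measure zero for simulated spikes.
Empty choice classes mask CP bins (minimum five trials per class); bins
with zero count variance mask correlations; zero-mean bins mask Fano
factors. Zero-length stimulus epochs flag the trial degenerate but still
read out a choice from spontaneous activity. Ties in Spearman rankings use
average ranks. Non-finite state variables abort the run with the neuron
index and time. The adjusted-window search inverts the pooled
|spike − t| distribution by linear interpolation and caps windows at twice
the available epoch.

## Known limitations

- No reaction-time (free-response) protocol; fixed duration only.
- No motion-energy filtering of pixel-level stimuli; evidence enters as the
  controlled OU current.
- The simulator is the only data source wired in; externally recorded trial
  ensembles can be analysed by constructing `TrialEnsemble` objects (spike
  times plus per-trial labels), but no archive-specific parser is included.
- Calibrated constants are provisional stand-ins for the unavailable
  published parameter table; full-scale runs reproduce the phenomenology
  but were validated on far fewer trials than the reduced configuration.
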