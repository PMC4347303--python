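"""Spike-count statistics: counts, population rates, Fano factors and
spike-count noise correlations, with shift correction and adjusted windows.

Counts are defined by a box kernel of width T centred on the bin time; the
window is closed, [t - T/2, t + T/2], evaluated on raw spike times (spikes
never fall exactly on window edges in simulation output).  The adjusted-
window mode varies the window length per neuron and time so that the mean
count across trials equals n_k = r_k * T, removing rate confounds from
dispersion and correlation measures.

Shift correction subtracts a trial-shifted predictor (cyclic lag-1 across
trials) from variances and covariances, removing slow across-trial
nonstationarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .protocol import TrialEnsemble

__all__ = ["CountMatrix", "CorrelationMatrix", "spike_counts",
           "population_rate", "fano_factor", "noise_correlation",
           "correlation_matrix", "default_grid"]


def default_grid(stim_duration: float, T: float) -> np.ndarray:
    """Non-overlapping bin centres t_i = (i - 1/2) T covering the stimulus."""
    n = int(stim_duration // T)
    return (np.arange(1, n + 1) - 0.5) * T


@dataclass
class CountMatrix:
    """Spike counts n_k^l(t;T): neurons x trials x bins."""

    counts: np.ndarray  # (K, L, B) float (adjusted windows are non-integer only in window length; counts stay integer)
    neurons: np.ndarray  # global neuron ids (K,)
    centres: np.ndarray  # bin centres, ms relative to stimulus onset (B,)
    T: float
    mode: str  # "fixed" or "adjusted"
    windows: np.ndarray | None = None  # realized T' per (K, B) when adjusted

    @property
    def n_trials(self):
        return self.counts.shape[1]


def _counts_fixed(ensemble, neurons, centres_abs, T):
    K, L, B = len(neurons), ensemble.n_trials, len(centres_abs)
    out = np.zeros((K, L, B))
    lo = centres_abs - T / 2
    hi = centres_abs + T / 2
    n_tot = ensemble.n_neurons
    for l, trial in enumerate(ensemble.trials):
        indptr, times = trial.neuron_spikes(n_tot)
        for a, k in enumerate(neurons):
            st = times[indptr[k]:indptr[k + 1]]
            out[a, l] = (np.searchsorted(st, hi, side="right")
                         - np.searchsorted(st, lo, side="left"))
    return out


def spike_counts(ensemble: TrialEnsemble, neurons, T: float,
                 centres: np.ndarray | None = None,
                 mode: str = "fixed") -> CountMatrix:
    """Spike counts per neuron, trial and bin centre (centres relative to
    stimulus onset, ms).

    mode="adjusted": per (neuron, bin) the window length T' is chosen so the
    cross-trial mean count equals r_k*T, with r_k the trial-averaged rate
    over the stimulus; windows are clipped to at most twice the available
    epoch.
    """
    if T > ensemble.pre + ensemble.stim_duration:
        raise ValueError("count window exceeds trial duration")
    neurons = np.asarray(neurons, int)
    if centres is None:
        centres = default_grid(ensemble.stim_duration, T)
    centres = np.asarray(centres, float)
    centres_abs = centres + ensemble.pre
    if mode == "fixed":
        counts = _counts_fixed(ensemble, neurons, centres_abs, T)
        return CountMatrix(counts, neurons, centres, T, "fixed")
    if mode != "adjusted":
        raise ValueError("mode must be 'fixed' or 'adjusted'")

    K, L, B = len(neurons), ensemble.n_trials, len(centres)
    n_tot = ensemble.n_neurons
    # trial-averaged rate over the stimulus epoch
    dur = ensemble.stim_duration
    stim_lo, stim_hi = ensemble.pre, ensemble.pre + dur
    per_trial = [trial.neuron_spikes(n_tot) for trial in ensemble.trials]
    counts = np.zeros((K, L, B))
    windows = np.zeros((K, B))
    t_max = 2.0 * max(T, dur)
    for a, k in enumerate(neurons):
        sts = [times[indptr[k]:indptr[k + 1]] for indptr, times in per_trial]
        n_stim = sum(np.searchsorted(st, stim_hi, side="right")
                     - np.searchsorted(st, stim_lo, side="left") for st in sts)
        target = (n_stim / L / dur) * T  # = r_k * T
        for b, t in enumerate(centres_abs):
            # pooled |spike - t| over trials; mean count(T') is the step
            # function #{d <= T'/2}/L, inverted by interpolation
            d = np.sort(np.concatenate([np.abs(st - t) for st in sts]))
            m = target * L
            if len(d) == 0 or m <= 0:
                windows[a, b] = t_max
                continue
            if m >= len(d):
                half = min(d[-1], t_max / 2)
            else:
                i = int(np.floor(m))
                frac = m - i
                lo_d = d[i - 1] if i >= 1 else 0.0
                hi_d = d[i]
                half = lo_d + frac * (hi_d - lo_d)
                half = min(half, t_max / 2)
            windows[a, b] = 2 * half
            for l, st in enumerate(sts):
                counts[a, l, b] = (np.searchsorted(st, t + half, side="right")
                                   - np.searchsorted(st, t - half, side="left"))
    return CountMatrix(counts, neurons, centres, T, "adjusted", windows)


def population_rate(ensemble: TrialEnsemble, population: str, T: float = 50.0,
                    grid_dt: float = 10.0, condition_on_choice: bool = False):
    """Instantaneous population rate r^l_beta(t) (sp/s), per trial.

    Returns (times_ms_from_stim_onset, rates (L, B)); with
    condition_on_choice=True returns instead the two choice-conditioned
    averages (times, r_choice1, r_choice2); for population E1/D1, choice 1
    trials are the "preferred" condition.
    """
    sl = ensemble.population_slice(population)
    n_pop = sl.stop - sl.start
    if n_pop == 0:
        raise ValueError(f"population {population} is empty")
    lo = ensemble.pre
    hi = ensemble.pre + ensemble.stim_duration
    centres = np.arange(lo, hi + 1e-9, grid_dt)
    L = ensemble.n_trials
    rates = np.empty((L, len(centres)))
    for l, trial in enumerate(ensemble.trials):
        sel = (trial.spike_neurons >= sl.start) & (trial.spike_neurons < sl.stop)
        times = np.sort(trial.spike_times[sel])
        rates[l] = ((np.searchsorted(times, centres + T / 2, side="right")
                     - np.searchsorted(times, centres - T / 2, side="left"))
                    / (n_pop * T * 1e-3))
    t = centres - lo
    if not condition_on_choice:
        return t, rates
    ch = ensemble.choices
    out = []
    for alpha in (1, 2):
        m = ch == alpha
        out.append(rates[m].mean(axis=0) if m.any() else None)
    return t, out[0], out[1]


def _shift_cov(x: np.ndarray, y: np.ndarray) -> float:
    """Symmetrized cyclic lag-1 trial-shift predictor of Cov(x, y)."""
    xc = x - x.mean()
    yc = y - y.mean()
    L = len(x)
    c1 = np.dot(xc, np.roll(yc, -1)) / (L - 1)
    c2 = np.dot(np.roll(xc, -1), yc) / (L - 1)
    return 0.5 * (c1 + c2)


def fano_factor(counts: CountMatrix, shift_correct: bool = False) -> np.ndarray:
    """FF_k(t;T) = Var_l[n] / Mean_l[n]; bins with zero mean are masked (nan).

    shift_correct subtracts the cyclic lag-1 across-trial autocovariance
    from the variance, removing slow across-trial rate drift.
    """
    c = counts.counts
    if c.shape[1] < 2:
        raise ValueError("need >= 2 trials")
    mean = c.mean(axis=1)
    var = c.var(axis=1, ddof=1)
    if shift_correct:
        K, L, B = c.shape
        shift = np.empty((K, B))
        for a in range(K):
            for b in range(B):
                shift[a, b] = _shift_cov(c[a, :, b], c[a, :, b])
        var = var - shift
    with np.errstate(invalid="ignore", divide="ignore"):
        ff = var / mean
    ff[mean == 0] = np.nan
    return ff


def noise_correlation(counts_k: np.ndarray, counts_kp: np.ndarray,
                      shift_correct: bool = False) -> float:
    """Pearson correlation across trials of two count series (one bin each).

    With shift correction, the symmetrized cyclic trial-shift predictor is
    subtracted from the covariance and from each variance before forming the
    ratio.  Returns nan if a variance is non-positive.
    """
    x = np.asarray(counts_k, float)
    y = np.asarray(counts_kp, float)
    if len(x) < 2:
        raise ValueError("need >= 2 trials")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    cov = np.dot(x - x.mean(), y - y.mean()) / (len(x) - 1)
    if shift_correct:
        cov -= _shift_cov(x, y)
        vx -= _shift_cov(x, x)
        vy -= _shift_cov(y, y)
    if vx <= 0 or vy <= 0:
        return np.nan
    return float(cov / np.sqrt(vx * vy))


@dataclass
class CorrelationMatrix:
    """Pair-averaged spike-count correlations rho(t_i, t_j)."""

    matrix: np.ndarray  # (B, B)
    centres: np.ndarray
    T: float
    pair_set: str
    n_pairs: int
    #: per-pair least-squares slope of the adjacent-bin lagged correlation
    #: rho_kk'(t_i, t_{i+1}) against time (1/s), used to split pairs into
    #: rising vs decaying lagged correlations
    pair_lag_slopes: np.ndarray | None = None

    @property
    def instantaneous(self) -> np.ndarray:
        return np.diag(self.matrix)

    @property
    def lagged(self) -> np.ndarray:
        """First off-diagonal rho(t_i, t_{i+1})."""
        return np.diag(self.matrix, k=1)


def _pairs_for(ensemble: TrialEnsemble, neurons, pair_set: str):
    e1 = ensemble.population_slice("E1")
    neurons = np.asarray(neurons)
    in_e1 = (neurons >= e1.start) & (neurons < e1.stop)
    idx = np.arange(len(neurons))
    a1, a2 = idx[in_e1], idx[~in_e1]
    pairs = []
    if pair_set in ("EiEi", "EE"):
        for grp in (a1, a2):
            for i in range(len(grp)):
                for j in range(i + 1, len(grp)):
                    pairs.append((grp[i], grp[j]))
    if pair_set in ("EiEj", "EE"):
        for i in a1:
            for j in a2:
                pairs.append((i, j))
    return np.array(pairs, int).reshape(-1, 2)


def correlation_matrix(ensemble: TrialEnsemble, neurons, T: float = 250.0,
                       pair_set: str = "EE", mode: str = "fixed",
                       per_coherence: bool = True,
                       counts: CountMatrix | None = None) -> CorrelationMatrix:
    """8x8 (or B x B) correlation matrix averaged over a pair set.

    Correlations are computed within each coherence level present and then
    averaged with equal weights.  pair_set: "EiEi" (within-population pairs),
    "EiEj" (across), or "EE" (all).
    """
    if counts is None:
        counts = spike_counts(ensemble, neurons, T, mode=mode)
    c = counts.counts  # (K, L, B)
    pairs = _pairs_for(ensemble, counts.neurons, pair_set)
    if len(pairs) < 1:
        raise ValueError("need >= 1 pair")
    coh = ensemble.coherences
    levels = np.unique(coh) if per_coherence else [None]
    B = c.shape[2]
    acc = np.zeros((B, B))
    acc_slopes = np.zeros(len(pairs))
    n_lev = 0
    for lev in levels:
        m = np.ones(len(coh), bool) if lev is None else coh == lev
        if m.sum() < 2:
            continue
        sub = c[:, m, :]
        mu = sub.mean(axis=1, keepdims=True)
        sd = sub.std(axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (sub - mu) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = 0.0
        L = sub.shape[1]
        # per-pair correlation matrices, averaged over the pair set
        zi = z[pairs[:, 0]]  # (P, L, B)
        zj = z[pairs[:, 1]]
        mats = np.einsum("plb,pld->pbd", zi, zj) / (L - 1)
        mats = 0.5 * (mats + np.transpose(mats, (0, 2, 1)))
        acc += mats.mean(axis=0)
        lag = np.stack([np.diagonal(m_, offset=1) for m_ in mats])  # (P, B-1)
        tmid = (counts.centres[:-1] + counts.centres[1:]) / 2 * 1e-3  # s
        acc_slopes += np.polyfit(tmid, lag.T, 1)[0]
        n_lev += 1
    if n_lev == 0:
        raise ValueError("no coherence level has >= 2 trials")
    return CorrelationMatrix(matrix=acc / n_lev, centres=counts.centres, T=T,
                             pair_set=pair_set, n_pairs=len(pairs),
                             pair_lag_slopes=acc_slopes / n_lev)
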