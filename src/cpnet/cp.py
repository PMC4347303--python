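"""Choice probability (CP) analysis: ROC areas, CP time-courses, unit
selection, population averaging and the CP-stability (rank-correlation)
matrix.

CP_k(t;T) is the area under the ROC curve that separates neuron k's spike
counts on trials ending in its preferred choice from counts on trials ending
in the other choice; 0.5 is chance.  For model neurons the preferred choice
is structural (population E1 -> choice 1, E2 -> choice 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .protocol import TrialEnsemble
from .spikestats import spike_counts, CountMatrix, default_grid

__all__ = ["roc_area", "CPTimeCourse", "cp_timecourse", "select_units",
           "population_cp", "CPCorrelationMatrix", "cp_correlation_matrix"]


def roc_area(counts_pref, counts_null) -> float:
    """Area under the ROC curve = Mann-Whitney statistic
    (#{pref > null} + 0.5 #{pref = null}) / (n_pref * n_null)."""
    x = np.asarray(counts_pref, float)
    y = np.asarray(counts_null, float)
    if len(x) == 0 or len(y) == 0:
        return np.nan
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[:len(x)].sum() - len(x) * (len(x) + 1) / 2
    return float(u / (len(x) * len(y)))


def _cp_from_counts(counts: np.ndarray, pref_mask: np.ndarray) -> np.ndarray:
    """Vectorized per-neuron, per-bin ROC area.

    counts: (K, L, B); pref_mask: (K, L) bool marking preferred-choice
    trials of each neuron.  Returns (K, B); rows with an empty class are nan.
    """
    K, L, B = counts.shape
    ranks = stats.rankdata(counts, axis=1)
    n_p = pref_mask.sum(axis=1).astype(float)  # (K,)
    n_n = L - n_p
    s = np.einsum("klb,kl->kb", ranks, pref_mask.astype(float))
    with np.errstate(invalid="ignore", divide="ignore"):
        cp = (s - (n_p * (n_p + 1) / 2)[:, None]) / (n_p * n_n)[:, None]
    cp[(n_p == 0) | (n_n == 0)] = np.nan
    return cp


@dataclass
class CPTimeCourse:
    neuron: int
    centres: np.ndarray  # ms from stimulus onset
    cp: np.ndarray  # (B,), nan where masked
    T: float
    mode: str
    n_pref: int
    n_null: int
    preferred_choice: int


def _zero_coherence_subset(ensemble: TrialEnsemble, zero_coherence_only):
    if not zero_coherence_only:
        return np.ones(ensemble.n_trials, bool)
    return ensemble.coherences == 0.0


def cp_timecourse(ensemble: TrialEnsemble, neuron: int, T: float = 100.0,
                  centres: np.ndarray | None = None, mode: str = "fixed",
                  zero_coherence_only: bool = True,
                  min_trials_per_class: int = 5) -> CPTimeCourse:
    """CP time-course of one neuron from choice-split spike counts.

    Analysis is restricted to zero-coherence trials unless overridden; bins
    are masked (nan) when either choice class has fewer than
    `min_trials_per_class` trials.
    """
    keep = _zero_coherence_subset(ensemble, zero_coherence_only)
    sub = _subset(ensemble, keep)
    if centres is None:
        centres = sliding_grid(ensemble.stim_duration, T)
    cm = spike_counts(sub, [neuron], T, centres=centres, mode=mode)
    pref = sub.preferred_choice(neuron)
    pref_mask = (sub.choices == pref)[None, :]
    cp = _cp_from_counts(cm.counts, pref_mask)[0]
    n_p = int(pref_mask.sum())
    n_n = sub.n_trials - n_p
    if min(n_p, n_n) < min_trials_per_class:
        cp[:] = np.nan
    return CPTimeCourse(neuron=neuron, centres=np.asarray(centres, float),
                        cp=cp, T=T, mode=mode, n_pref=n_p, n_null=n_n,
                        preferred_choice=pref)


def sliding_grid(stim_duration: float, T: float, step: float = 50.0):
    """Sliding bin centres every `step` ms (fully inside the stimulus)."""
    return np.arange(T / 2, stim_duration - T / 2 + 1e-9, step)


def _subset(ensemble: TrialEnsemble, mask: np.ndarray) -> TrialEnsemble:
    import dataclasses as dc
    trials = [t for t, m in zip(ensemble.trials, mask) if m]
    return dc.replace(ensemble, trials=trials)


# ---------------------------------------------------------------------------
# unit selection
# ---------------------------------------------------------------------------

def select_units(ensemble: TrialEnsemble, neurons=None,
                 min_trials: int = 20, min_per_choice: int = 5,
                 min_rate: float = 1.0, min_spikes: int = 100,
                 outlier_sd: float = 3.0):
    """Apply the unit-selection rules; returns (ids, per-rule exclusions).

    Per neuron, outlier trials (stimulus-epoch count deviating from the mean
    by more than `outlier_sd` s.d.) are removed first; then the neuron must
    have strictly more than `min_trials` zero-coherence trials, at least
    `min_per_choice` trials of each choice among them, a mean rate above
    `min_rate` sp/s and at least `min_spikes` spikes over all trials.
    """
    if neurons is None:
        e1, e2 = ensemble.population_slice("E1"), ensemble.population_slice("E2")
        neurons = np.r_[np.arange(e1.start, e1.stop),
                        np.arange(e2.start, e2.stop)]
    neurons = np.asarray(neurons, int)
    dur = ensemble.stim_duration
    cm = spike_counts(ensemble, neurons, dur, centres=np.array([dur / 2]))
    counts = cm.counts[:, :, 0]  # (K, L) stimulus-epoch counts
    zero = ensemble.coherences == 0.0
    choices = ensemble.choices
    excl = {"outlier_only": 0, "n_trials": 0, "per_choice": 0,
            "rate": 0, "total_spikes": 0}
    kept = []
    for a, k in enumerate(neurons):
        ck = counts[a]
        sd = ck.std(ddof=1) if len(ck) > 1 else 0.0
        good = np.abs(ck - ck.mean()) <= outlier_sd * sd if sd > 0 \
            else np.ones(len(ck), bool)
        z = zero & good
        if z.sum() <= min_trials:
            excl["n_trials"] += 1
            continue
        pref = ensemble.preferred_choice(int(k))
        n_p = np.sum(choices[z] == pref)
        n_n = z.sum() - n_p
        if min(n_p, n_n) < min_per_choice:
            excl["per_choice"] += 1
            continue
        if ck[good].mean() / (dur * 1e-3) <= min_rate:
            excl["rate"] += 1
            continue
        if ck.sum() < min_spikes:
            excl["total_spikes"] += 1
            continue
        kept.append(int(k))
    return np.array(kept, int), excl


# ---------------------------------------------------------------------------
# population CP
# ---------------------------------------------------------------------------

def population_cp(ensemble: TrialEnsemble, T: float = 100.0,
                  n_neurons: int = 100, min_rate: float = 1.0,
                  seed: int = 0, centres: np.ndarray | None = None,
                  mode: str = "fixed", zero_coherence_only: bool = True):
    """Mean CP trace +- s.e.m. over a seeded random sample of E1/E2 neurons
    with mean stimulus-epoch rate >= min_rate sp/s.

    Returns (centres, mean_cp, sem, neuron_ids).
    """
    keep = _zero_coherence_subset(ensemble, zero_coherence_only)
    sub = _subset(ensemble, keep)
    e1, e2 = sub.population_slice("E1"), sub.population_slice("E2")
    cands = np.r_[np.arange(e1.start, e1.stop), np.arange(e2.start, e2.stop)]
    dur = sub.stim_duration
    cm = spike_counts(sub, cands, dur, centres=np.array([dur / 2]))
    rates = cm.counts[:, :, 0].mean(axis=1) / (dur * 1e-3)
    eligible = cands[rates >= min_rate]
    rng = np.random.default_rng(seed)
    if len(eligible) > n_neurons:
        sample = rng.choice(eligible, size=n_neurons, replace=False)
    else:
        sample = eligible
    if centres is None:
        centres = sliding_grid(dur, T)
    cmx = spike_counts(sub, sample, T, centres=centres, mode=mode)
    pref_mask = np.stack([(sub.choices == sub.preferred_choice(int(k)))
                          for k in sample])
    cp = _cp_from_counts(cmx.counts, pref_mask)
    mean = np.nanmean(cp, axis=0)
    n_eff = np.sum(~np.isnan(cp), axis=0)
    sem = np.nanstd(cp, axis=0, ddof=1) / np.sqrt(np.maximum(n_eff, 1))
    return np.asarray(centres, float), mean, sem, np.asarray(sample, int)


# ---------------------------------------------------------------------------
# CP correlation (stability) matrix
# ---------------------------------------------------------------------------

@dataclass
class CPCorrelationMatrix:
    """Spearman rank correlation across neurons of CP at pairs of time bins,
    averaged over trial resamples."""

    matrix: np.ndarray  # (B, B) resample mean
    se: np.ndarray  # (B, B) resample s.e.
    centres: np.ndarray
    T: float
    n_trials_subsample: int
    n_resamples: int
    adjacent: np.ndarray  # C(t_i, t_{i+1}) series
    adjacent_times: np.ndarray  # s, midpoints of adjacent bins
    slope: float  # 1/s, least-squares slope of the adjacent series
    intercept: float
    p_slope: float  # permutation p-value (positive slope)


def cp_correlation_matrix(ensemble: TrialEnsemble, neurons, T: float = 250.0,
                          n_trials_subsample: int = 100,
                          n_resamples: int = 1000, seed: int = 0,
                          zero_coherence_only: bool = True,
                          n_permutations: int = 1000) -> CPCorrelationMatrix:
    """Resampled CP-stability matrix C(t_i, t_j).

    For each resample, `n_trials_subsample` trials are drawn without
    replacement, per-neuron CPs recomputed per bin, and the Spearman rank
    correlation across neurons taken for every bin pair; the mean and s.e.
    over resamples are reported together with the adjacent-bin series and
    its least-squares slope (permutation p-value for slope > 0).
    """
    keep = _zero_coherence_subset(ensemble, zero_coherence_only)
    sub = _subset(ensemble, keep)
    if n_trials_subsample > sub.n_trials:
        raise ValueError("n_trials_subsample exceeds available trials")
    neurons = np.asarray(neurons, int)
    centres = default_grid(sub.stim_duration, T)
    cm = spike_counts(sub, neurons, T, centres=centres)
    counts = cm.counts  # (K, L, B)
    pref_mask = np.stack([(sub.choices == sub.preferred_choice(int(k)))
                          for k in neurons])
    rng = np.random.default_rng(seed)
    B = len(centres)
    acc = np.zeros((n_resamples, B, B))
    L = sub.n_trials
    for r in range(n_resamples):
        idx = rng.choice(L, size=n_trials_subsample, replace=False)
        cp = _cp_from_counts(counts[:, idx, :], pref_mask[:, idx])
        ok = ~np.isnan(cp).any(axis=1)
        ranks = stats.rankdata(cp[ok], axis=0)
        acc[r] = np.corrcoef(ranks.T)
    mean = acc.mean(axis=0)
    se = acc.std(axis=0, ddof=1) / np.sqrt(n_resamples)
    adjacent = np.diagonal(mean, offset=1).copy()
    tmid = (centres[:-1] + centres[1:]) / 2 * 1e-3  # s
    slope, intercept = np.polyfit(tmid, adjacent, 1)
    perm = np.empty(n_permutations)
    prng = np.random.default_rng(seed + 1)
    for p in range(n_permutations):
        perm[p] = np.polyfit(tmid, prng.permutation(adjacent), 1)[0]
    p_slope = float((np.sum(perm >= slope) + 1) / (n_permutations + 1))
    return CPCorrelationMatrix(matrix=mean, se=se, centres=centres, T=T,
                               n_trials_subsample=n_trials_subsample,
                               n_resamples=n_resamples, adjacent=adjacent,
                               adjacent_times=tmid, slope=float(slope),
                               intercept=float(intercept), p_slope=p_slope)
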