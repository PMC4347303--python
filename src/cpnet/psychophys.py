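"""Psychophysics: reverse-correlation kernels, integration windows,
psychometric curves, Weibull threshold fits and the threshold-vs-window
trade-off.

The psychophysical kernel is the choice-conditioned difference of the
average stimulus evidence d(t) = s_E1(t) - s_E2(t); its shape measures when
during the trial stimulus fluctuations influence the decision.  The
integration window is the onset-anchored interval containing 85% of the
kernel's (positive-part) area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .protocol import TrialEnsemble, run_batch
from .config import StimulusConfig

__all__ = ["PsychKernel", "psych_kernel", "integration_window",
           "PsychometricCurve", "psychometric_curve", "PsychometricFit",
           "fit_weibull", "threshold_vs_window", "weibull"]


@dataclass
class PsychKernel:
    times: np.ndarray  # ms from stimulus onset
    kernel: np.ndarray  # units of stimulus-modulation s.d. difference
    sem: np.ndarray
    n_choice1: int
    n_choice2: int

    def window(self, fraction: float = 0.85) -> float:
        return integration_window(self, fraction)


def psych_kernel(ensemble: TrialEnsemble,
                 zero_coherence_only: bool = True) -> PsychKernel:
    """Kernel(t) = <d(t) | choice 1> - <d(t) | choice 2>.

    Uses the stored common stimulus terms; individual per-neuron modulations
    average out over the population and are not part of the evidence.
    """
    ds, choices = [], []
    for t in ensemble.trials:
        if zero_coherence_only and t.coherence != 0.0:
            continue
        if t.s_e1 is None or len(t.s_e1) == 0:
            raise ValueError(
                "trial lacks stored stimulus traces; reconstruct them from "
                "the stimulus seeds before computing kernels")
        ds.append(t.s_e1 - t.s_e2)
        choices.append(t.choice)
    d = np.asarray(ds)
    ch = np.asarray(choices)
    n1 = int(np.sum(ch == 1))
    n2 = int(np.sum(ch == 2))
    if n1 == 0 or n2 == 0:
        raise ValueError("need trials of both choices")
    m1 = d[ch == 1].mean(axis=0)
    m2 = d[ch == 2].mean(axis=0)
    v1 = d[ch == 1].var(axis=0, ddof=1) / n1 if n1 > 1 else np.zeros_like(m1)
    v2 = d[ch == 2].var(axis=0, ddof=1) / n2 if n2 > 1 else np.zeros_like(m2)
    dt = ensemble.trials[0].stim_dt
    times = (np.arange(len(m1)) + 0.5) * dt
    return PsychKernel(times=times, kernel=m1 - m2, sem=np.sqrt(v1 + v2),
                       n_choice1=n1, n_choice2=n2)


def integration_window(kernel: PsychKernel | np.ndarray,
                       fraction: float = 0.85,
                       times: np.ndarray | None = None) -> float:
    """Shortest onset-anchored interval containing `fraction` of the
    kernel's total (positive-part) area, in seconds.

    Negative excursions are clipped to zero before the area computation;
    the crossing point is located by linear interpolation of the cumulative
    area.
    """
    if isinstance(kernel, PsychKernel):
        k = kernel.kernel
        t = kernel.times
    else:
        k = np.asarray(kernel, float)
        t = np.asarray(times, float)
    pos = np.clip(k, 0.0, None)
    if len(pos) == 0:
        raise ValueError("empty kernel")
    dt = t[1] - t[0] if len(t) > 1 else 1.0
    cum = np.concatenate([[0.0], np.cumsum(pos) * dt])
    total = cum[-1]
    if total <= 0:
        raise ValueError("kernel has non-positive total area")
    target = fraction * total
    edges = np.concatenate([[t[0] - dt / 2], t + dt / 2])
    i = np.searchsorted(cum, target)
    # linear interpolation within sample i-1
    t_cross = edges[i - 1] + (target - cum[i - 1]) / (cum[i] - cum[i - 1]) * dt
    return float((t_cross - edges[0]) * 1e-3)


@dataclass
class PsychometricCurve:
    coherences: np.ndarray  # positive magnitudes
    n_trials: np.ndarray
    n_correct: np.ndarray

    @property
    def percent_correct(self) -> np.ndarray:
        return 100.0 * self.n_correct / self.n_trials

    def ci95(self) -> np.ndarray:
        p = self.n_correct / self.n_trials
        return 196.0 * np.sqrt(p * (1 - p) / self.n_trials)


def psychometric_curve(network, stimulus_config: StimulusConfig,
                       coherences, n_trials: int, master_seed: int = 0,
                       pre: float = 3000.0, progress: bool = False
                       ) -> PsychometricCurve:
    """Percent correct per coherence magnitude; a choice is correct when it
    matches the sign of the coherence (zero coherence is excluded from the
    accuracy accounting)."""
    import dataclasses as dc
    cs, nt, nc = [], [], []
    for ci, c in enumerate(coherences):
        if c == 0:
            continue
        cfg = dc.replace(stimulus_config, coherence=float(c))
        ens = run_batch(network, cfg, n_trials, mode="non-replicate",
                        master_seed=master_seed + 7919 * (ci + 1), pre=pre,
                        progress=progress)
        correct = np.sum(ens.choices == (1 if c > 0 else 2))
        cs.append(abs(float(c)))
        nt.append(n_trials)
        nc.append(int(correct))
    return PsychometricCurve(coherences=np.array(cs),
                             n_trials=np.array(nt), n_correct=np.array(nc))


def weibull(c, alpha, beta):
    """P(correct) = 1 - 0.5 exp(-(c/alpha)^beta); P(alpha) = 1 - 0.5/e."""
    with np.errstate(over="ignore"):  # (c/alpha)^beta -> inf maps to P = 1
        return 1.0 - 0.5 * np.exp(-np.power(c / alpha, beta))


@dataclass
class PsychometricFit:
    alpha: float
    beta: float
    threshold: float  # coherence at 82% correct (exact inversion)
    converged: bool
    nll: float

    def predict(self, c):
        return weibull(c, self.alpha, self.beta)


def fit_weibull(curve: PsychometricCurve, threshold_pc: float = 0.82
                ) -> PsychometricFit:
    """Maximum-likelihood 2-parameter Weibull fit on binomial counts.

    The discrimination threshold is the coherence where the fitted curve
    reaches `threshold_pc`, solved exactly:
    c = alpha * (ln(0.5 / (1 - p)))^(1/beta).
    """
    c = curve.coherences
    if len(c) < 2:
        raise ValueError("need >= 2 coherence levels")
    n = curve.n_trials
    k = curve.n_correct

    def nll(params):
        la, lb = params
        p = weibull(c, np.exp(la), np.exp(lb))
        p = np.clip(p, 1e-9, 1 - 1e-9)
        return -np.sum(k * np.log(p) + (n - k) * np.log(1 - p))

    # initial guess: alpha near the coherence closest to 82% correct
    pc = k / n
    a0 = c[np.argmin(np.abs(pc - threshold_pc))]
    best = None
    for b0 in (1.0, 1.5, 3.0):
        res = optimize.minimize(nll, [np.log(max(a0, 1e-4)), np.log(b0)],
                                method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-10,
                                         "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    alpha = float(np.exp(best.x[0]))
    beta = float(np.exp(best.x[1]))
    thr = alpha * np.log(0.5 / (1.0 - threshold_pc)) ** (1.0 / beta)
    return PsychometricFit(alpha=alpha, beta=beta, threshold=float(thr),
                           converged=bool(best.success), nll=float(best.fun))


def threshold_vs_window(thresholds, windows):
    """Log-log least-squares slope of discrimination threshold against
    integration-window length.  Returns (slope, intercept).

    Perfect evidence integration over a window of length W predicts
    threshold proportional to W^(-1/2).
    """
    thr = np.asarray(thresholds, float)
    win = np.asarray(windows, float)
    if len(thr) < 2:
        raise ValueError("need >= 2 (threshold, window) points")
    if np.any(thr <= 0) or np.any(win <= 0):
        raise ValueError("thresholds and windows must be positive")
    slope, intercept = np.polyfit(np.log10(win), np.log10(thr), 1)
    return float(slope), float(intercept)
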