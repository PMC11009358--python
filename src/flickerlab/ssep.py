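"""Steady-state evoked-potential quantification.

Per trial, spectral power is estimated with a multitaper PSD
(time-bandwidth product 3, 5 tapers).  The steady-state response of a
channel to a flicker condition is summarised as the normalised fold-change
in power at the stimulation frequency,

    FC_pow = mu_stim / mu_bl - 1,

where mu_stim and mu_bl are trial-averaged power at f_stim during
stimulation and baseline, tested with a one-sided trial-permutation test.
Phase locking between the stimulus (approximated as a sinusoid) and the
LFP is measured with the phase-locking value (PLV), the modulus of the
mean unit phasor of per-window phase differences, with significance from
the Rayleigh test.  Spiking modulation uses the formally identical vector
strength on spike phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
from scipy import signal, stats
from scipy.signal.windows import dpss

from .preprocess import TrialSet

logger = logging.getLogger("flickerlab")

ALPHA = 0.05
#: fold-change separating weak from strong flicker modulation
HIGH_MOD_FC = 1.5


# ---------------------------------------------------------------------------
# Multitaper PSD
# ---------------------------------------------------------------------------

@dataclass
class PSDSet:
    """Per-trial multitaper PSDs: ``power`` is (trials, channels, freqs)."""

    power: np.ndarray
    freqs: np.ndarray
    fs: float
    nw: float = 3.0
    n_tapers: int = 5

    def at(self, f: float) -> np.ndarray:
        """Power at the grid frequency nearest ``f`` -> (trials, channels)."""
        return self.power[:, :, int(np.argmin(np.abs(self.freqs - f)))]


def multitaper_psd_array(
    x: np.ndarray, fs: float, nw: float = 3.0, n_tapers: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Multitaper PSD of ``x`` along its last axis (one-sided density)."""
    n = x.shape[-1]
    tapers = dpss(n, nw, Kmax=n_tapers)  # (K, n), unit energy
    spec = np.fft.rfft(x[..., None, :] * tapers, axis=-1)
    psd = (np.abs(spec) ** 2).mean(axis=-2) * (2.0 / fs)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    return psd, freqs


def multitaper_psd(
    trialset: TrialSet,
    fmin: float = 2.0,
    fmax: float = 100.0,
    nw: float = 3.0,
    n_tapers: int = 5,
) -> PSDSet:
    """Per-trial PSD over the stimulus window of each trial.

    The half-bandwidth is ``nw / duration`` Hz (0.3 Hz for 10 s trials).
    """
    if fmax > trialset.fs / 2:
        raise ValueError(f"fmax {fmax} Hz exceeds Nyquist {trialset.fs / 2} Hz")
    if trialset.duration < 1.0:
        raise ValueError("trial duration must be >= 1 s for the multitaper PSD")
    x = trialset.data[:, :, trialset.stim_slice()]
    psd, freqs = multitaper_psd_array(x, trialset.fs, nw=nw, n_tapers=n_tapers)
    keep = (freqs >= fmin) & (freqs <= fmax)
    return PSDSet(psd[..., keep], freqs[keep], trialset.fs, nw, n_tapers)


# ---------------------------------------------------------------------------
# Fold-change and permutation significance
# ---------------------------------------------------------------------------

@dataclass
class FCResult:
    channel_id: str
    condition_id: str
    f_stim: float
    mu_stim: float
    mu_bl: float
    fc: float
    p_perm: float | None = None
    fc_diff: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_perm is not None and self.p_perm < ALPHA


def fold_change(
    psd_stim: PSDSet,
    psd_bl: PSDSet,
    f_stim: float,
    channel_ids: list[str] | None = None,
    condition_id: str = "",
    n_iter: int = 10_000,
    seed: int | None = None,
) -> list[FCResult]:
    """Eq.-style fold-change in power at ``f_stim``, one entry per channel.

    If ``seed`` is given the one-sided permutation p-value is filled in.
    Stimulation and baseline must carry equal, balanced trial counts.
    """
    if psd_stim.power.shape[0] != psd_bl.power.shape[0]:
        raise ValueError("unbalanced trial counts; run balance_trials first")
    p_stim = psd_stim.at(f_stim)  # (trials, channels)
    p_bl = psd_bl.at(f_stim)
    n_ch = p_stim.shape[1]
    if channel_ids is None:
        channel_ids = [f"ch{i}" for i in range(n_ch)]
    out = []
    for c in range(n_ch):
        mu_s = float(p_stim[:, c].mean())
        mu_b = float(p_bl[:, c].mean())
        if mu_b == 0:
            raise ZeroDivisionError("baseline power is zero")
        p = (
            permutation_significance(p_stim[:, c], p_bl[:, c], n_iter, seed)
            if seed is not None
            else None
        )
        out.append(
            FCResult(channel_ids[c], condition_id, f_stim, mu_s, mu_b,
                     mu_s / mu_b - 1.0, p)
        )
    return out


def permutation_significance(
    stim_values: np.ndarray,
    bl_values: np.ndarray,
    n_iter: int = 10_000,
    seed: int | None = None,
) -> float:
    """One-sided permutation p for mean(stim) > mean(baseline).

    p is the fraction of permuted mean-differences >= the observed
    difference; ties count as exceedances, so p is never 0.  When the number
    of distinct group assignments does not exceed ``n_iter`` the test
    enumerates all of them exactly instead of sampling.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    a = np.asarray(stim_values, float).ravel()
    b = np.asarray(bl_values, float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    n1, n = a.size, a.size + b.size
    observed = a.mean() - b.mean()
    total = pooled.sum()

    # tolerance keeps the identity assignment a tie despite float round-off
    tol = 1e-12 * max(1.0, float(np.abs(pooled).max()))
    if comb(n, n1) <= n_iter:
        sums = np.array(
            [pooled[list(ix)].sum() for ix in combinations(range(n), n1)]
        )
        diffs = sums / n1 - (total - sums) / (n - n1)
        return float(np.mean(diffs >= observed - tol))
    rng = np.random.default_rng(seed)
    picks = np.argsort(rng.random((n_iter, n)), axis=1)[:, :n1]
    sums = pooled[picks].sum(axis=1)
    diffs = sums / n1 - (total - sums) / (n - n1)
    # add-one (Phipson-Smyth) so a sampled p is never exactly 0
    return float((1 + np.sum(diffs >= observed - tol)) / (1 + n_iter))


def fc_specificity(fc_40: float, fc_30: float, fc_50: float) -> float:
    """Specificity of a 40 Hz response: FC at 40 Hz minus mean off-band FC."""
    return fc_40 - 0.5 * (fc_30 + fc_50)


def classify_modulation(
    fc_result: FCResult,
    fc_threshold: float = HIGH_MOD_FC,
    alpha: float = ALPHA,
) -> str:
    """Bucket a channel-condition as non_mod / low_mod / high_mod."""
    if fc_result.p_perm is None:
        raise ValueError("p_perm missing; run the permutation test first")
    if fc_result.p_perm >= alpha:
        return "non_mod"
    return "high_mod" if fc_result.fc > fc_threshold else "low_mod"


# ---------------------------------------------------------------------------
# Two-cycle evoked average
# ---------------------------------------------------------------------------

def evoked_two_cycle_average(
    trialset: TrialSet, f_stim: float, channel: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SEM of the LFP over two stimulus cycles.

    Each trial's stimulus window is re-segmented into two-cycle pieces with
    one overlapping cycle between consecutive segments; segment starts are
    snapped per segment so phase error never exceeds half a sample.
    Baseline trials are segmented identically by passing the stimulation
    frequency of the compared condition.
    """
    if f_stim <= 0:
        raise ValueError("f_stim must be positive")
    fs = trialset.fs
    seg_len = int(round(2.0 * fs / f_stim))
    i_start = int(round(trialset.pre * fs))
    n_stim = int(round(trialset.duration * fs))
    n_cycles = int(np.floor(trialset.duration * f_stim))
    segs = []
    for k in range(n_cycles - 1):
        off = int(round(k * fs / f_stim))
        if off + seg_len > n_stim:
            break
        segs.append(trialset.data[:, channel, i_start + off : i_start + off + seg_len])
    allsegs = np.concatenate(segs, axis=0)
    mean = allsegs.mean(axis=0)
    sem = allsegs.std(axis=0, ddof=1) / np.sqrt(allsegs.shape[0]) \
        if allsegs.shape[0] > 1 else np.zeros(seg_len)
    return mean, sem


# ---------------------------------------------------------------------------
# Phase-locking value
# ---------------------------------------------------------------------------

@dataclass
class PLVResult:
    channel_id: str
    condition_id: str
    f_stim: float
    plv: float
    rayleigh_p: float
    phases: np.ndarray = field(repr=False, default=None)


def rayleigh_test(phases: np.ndarray) -> tuple[float, float]:
    """Rayleigh z and p for non-uniformity of circular data."""
    from pingouin import circ_rayleigh  # deferred: heavy import chain

    phases = np.mod(np.asarray(phases, float), 2 * np.pi)
    z, p = circ_rayleigh(phases)
    return float(z), float(p)


def phase_locking_value(
    trialset: TrialSet,
    f_stim: float,
    channel: int = 0,
    condition_id: str = "",
) -> PLVResult:
    """PLV between the LFP and a stimulus-locked sinusoid at ``f_stim``.

    The cross-spectrum is evaluated per non-overlapping window of fs/2
    samples at the FFT bin nearest ``f_stim``; per-window phase differences
    are averaged as unit phasors across windows and trials and the modulus
    taken as the PLV.  Significance is a Rayleigh test on the per-window
    phases.
    """
    fs = trialset.fs
    win = int(fs // 2)
    n_stim = int(round(trialset.duration * fs))
    if win > n_stim:
        raise ValueError("PLV window longer than the stimulus window")
    i0 = int(round(trialset.pre * fs))
    n_win = n_stim // win
    freqs = np.fft.rfftfreq(win, 1.0 / fs)
    k = int(np.argmin(np.abs(freqs - f_stim)))
    t = np.arange(n_stim) / fs
    stim = np.cos(2 * np.pi * f_stim * t)
    phases = []
    for tr in range(trialset.n_trials):
        x = trialset.data[tr, channel, i0 : i0 + n_stim]
        for w in range(n_win):
            sl = slice(w * win, (w + 1) * win)
            cross = np.fft.rfft(x[sl])[k] * np.conj(np.fft.rfft(stim[sl])[k])
            phases.append(np.angle(cross))
    phases = np.asarray(phases)
    plv = float(np.abs(np.mean(np.exp(1j * phases))))
    _, p = rayleigh_test(phases)
    chan_id = (
        trialset.channels[channel].channel_id if trialset.channels else f"ch{channel}"
    )
    return PLVResult(chan_id, condition_id or trialset.condition_id, f_stim,
                     plv, p, phases)


# ---------------------------------------------------------------------------
# Neuronal unit vector strength
# ---------------------------------------------------------------------------

@dataclass
class UnitModulation:
    unit_id: str
    condition_id: str
    vector_strength: float
    rayleigh_p: float
    n_spikes: int
    phases: np.ndarray = field(repr=False, default=None)
    passes_sparsity: bool = True


def spike_phases_two_cycle(
    spike_times: np.ndarray, onsets: np.ndarray, duration: float, f_stim: float
) -> np.ndarray:
    """Spike phases (radians) relative to the two-cycle stimulus period."""
    period = 2.0 / f_stim
    phases = []
    for onset in onsets:
        t = np.asarray(spike_times, float)
        sel = t[(t >= onset) & (t < onset + duration)]
        phases.append(2 * np.pi * np.mod(sel - onset, period) / period)
    return np.concatenate(phases) if phases else np.array([])


def unit_vector_strength(
    spike_times: np.ndarray,
    schedule,
    f_stim: float,
    condition_id: str,
    unit_id: str = "unit",
    n_psth_bins: int = 40,
    max_empty_fraction: float = 0.2,
) -> UnitModulation:
    """Vector strength and Rayleigh p of a unit against the 2-cycle stimulus.

    Units whose peristimulus histogram has more than ``max_empty_fraction``
    empty bins are flagged as too sparse for a modulation call.
    """
    onsets = np.array(
        [t.onset for t in schedule.trials if t.condition_id == condition_id]
    )
    dur = next(
        t.duration for t in schedule.trials if t.condition_id == condition_id
    )
    phases = spike_phases_two_cycle(spike_times, onsets, dur, f_stim)
    if phases.size == 0:
        raise ValueError("no spikes in the analysis windows")
    hist, _ = np.histogram(phases, bins=n_psth_bins, range=(0, 2 * np.pi))
    sparse_ok = np.mean(hist == 0) <= max_empty_fraction
    vs = float(np.abs(np.mean(np.exp(1j * phases))))
    _, p = rayleigh_test(phases)
    return UnitModulation(unit_id, condition_id, vs, p, phases.size, phases,
                          sparse_ok)


# ---------------------------------------------------------------------------
# Persistence of the oscillatory response
# ---------------------------------------------------------------------------

def persistence_detection(
    trial_lfp: np.ndarray,
    fs: float,
    f_stim: float,
    stim_window: tuple[float, float],
    bandwidth: float = 2.0,
    threshold_factor: float = 3.0,
    min_cycles: int = 3,
) -> dict:
    """Classify a single trial as persistent / not_persistent / undetected.

    A symmetric (zero-phase) band-pass at ``f_stim`` +/- ``bandwidth`` Hz is
    applied and the Hilbert envelope taken.  A burst is first located where
    the envelope exceeds ``threshold_factor`` x the median pre-stimulus
    envelope for at least ``min_cycles`` stimulus cycles; its start and stop
    are then refined as the half-amplitude crossings of the burst envelope,
    so the symmetric filter smear shifts both edges equally and cancels in
    the persistence criterion.  With onset delay d = start - stim_start, the
    response is persistent iff the detected stop exceeds stim_end + d + one
    stimulus cycle.
    """
    t0, t1 = stim_window
    x = np.asarray(trial_lfp, float)
    sos = signal.butter(
        4, [max(f_stim - bandwidth, 0.5), f_stim + bandwidth],
        btype="bandpass", fs=fs, output="sos",
    )
    env = np.abs(signal.hilbert(signal.sosfiltfilt(sos, x)))
    i0 = int(round(t0 * fs))
    pre_env = env[:i0]
    if pre_env.size < 10:
        raise ValueError("trial must include a pre-stimulus window")
    thr = threshold_factor * np.median(pre_env)
    min_run = max(1, int(round(min_cycles * fs / f_stim)))
    runs = [(a, b) for a, b in _runs_of_true(env > thr) if b - a >= min_run]
    if not runs:
        return dict(status="undetected", start=None, stop=None, delay=None)
    a0 = runs[0][0]
    b0 = runs[-1][1]
    amp = np.median(env[a0:b0][env[a0:b0] > thr])
    refined = [
        (a, b) for a, b in _runs_of_true(env > 0.5 * amp)
        if b > a0 and a < b0 and b - a >= min_run
    ]
    if refined:
        a0, b0 = refined[0][0], refined[-1][1]
    start, stop = a0 / fs, b0 / fs
    delay = start - t0
    persistent = stop > t1 + delay + 1.0 / f_stim
    return dict(
        status="persistent" if persistent else "not_persistent",
        start=start, stop=stop, delay=delay,
    )


def _runs_of_true(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return list(zip(edges[::2], edges[1::2]))


# ---------------------------------------------------------------------------
# Proportion comparison
# ---------------------------------------------------------------------------

def compare_proportions(
    counts_modulated: np.ndarray, counts_total: np.ndarray
) -> tuple[float, int, float]:
    """Chi-square test of equality of k proportions (2 x k contingency)."""
    m = np.asarray(counts_modulated, int)
    n = np.asarray(counts_total, int)
    if m.size < 2:
        raise ValueError("need at least 2 groups")
    if np.any(n <= 0):
        raise ValueError("empty group")
    table = np.vstack([m, n - m])
    stat, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p)
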