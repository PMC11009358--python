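"""Single-pulse evoked-potential (EP) extraction and statistics.

Single 12.5 ms sensory pulses are delivered roughly once per second; the
evoked response of a channel is the trial-averaged LFP over [-0.25, 1] s
around pulse onset, its amplitude the absolute maximum of that mean in
[0, 1] s, and its significance a trial-permutation test of the RMS of the
mean waveform against the occluded (device-artifact) control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

from .preprocess import Recording, TrialSet, laplacian_rereference

logger = logging.getLogger("flickerlab")

HIGHPASS_HZ = 0.1
TRIAL_PRE = 0.25
TRIAL_DUR = 1.0
TRIAL_POST = 0.25
NORM_FLOOR = 0.001


@dataclass
class PulseEPResult:
    channel_id: str
    modality: str
    mean_waveform: np.ndarray
    sem: np.ndarray
    amplitude: float
    p_perm: float | None = None
    norm_log_amplitude: float | None = None

    @property
    def significant(self) -> bool:
        return self.p_perm is not None and self.p_perm < 0.05


def preprocess_pulses(
    recording: Recording,
    schedule,
    rereference: bool = True,
) -> dict[str, TrialSet]:
    """Re-reference, 0.1 Hz high-pass (4th-order Butterworth, zero-phase),
    segment into [-0.25, 1.25] s trials and baseline-correct each trial by
    its 0.25 s pre-onset mean.  Returns one TrialSet per pulse condition
    (including the occluded control)."""
    rec = laplacian_rereference(recording) if rereference else recording
    sos = signal.butter(4, HIGHPASS_HZ, btype="highpass", fs=rec.fs, output="sos")
    filt = Recording(
        signal.sosfiltfilt(sos, rec.data, axis=-1), rec.fs, rec.channels
    )
    fs = rec.fs
    n_samp = int(round((TRIAL_PRE + TRIAL_DUR + TRIAL_POST) * fs))
    n_pre = int(round(TRIAL_PRE * fs))
    out: dict[str, TrialSet] = {}
    by_cond: dict[str, list] = {}
    for tr in schedule.trials:
        if tr.pattern == "pulse":
            by_cond.setdefault(tr.condition_id, []).append(tr)
    if not by_cond:
        raise ValueError("schedule contains no pulse trials")
    for cond, trs in by_cond.items():
        segs = np.empty((len(trs), filt.n_channels, n_samp))
        onsets = np.empty(len(trs))
        for k, tr in enumerate(trs):
            i0 = int(np.floor((tr.onset - TRIAL_PRE) * fs))
            if i0 < 0 or i0 + n_samp > filt.data.shape[1]:
                raise ValueError("pulse trial window exceeds recording bounds")
            seg = filt.data[:, i0 : i0 + n_samp]
            base = seg[:, :n_pre].mean(axis=1, keepdims=True)
            segs[k] = seg - base
            onsets[k] = tr.onset
        out[cond] = TrialSet(cond, segs, fs, TRIAL_PRE, TRIAL_POST, TRIAL_DUR,
                             onsets, list(filt.channels))
    return out


def _rms_of_mean(trials: np.ndarray, i0: int, i1: int) -> float:
    m = trials.mean(axis=0)
    return float(np.sqrt(np.mean(m[i0:i1] ** 2)))


def pulse_ep_significance(
    stim_trials: np.ndarray,
    occluded_trials: np.ndarray,
    fs: float,
    pre: float = TRIAL_PRE,
    n_iter: int = 500,
    seed: int | None = None,
) -> float:
    """One-sided permutation p for an evoked response above the occluded
    control.

    The statistic is RMS(mean stimulation waveform over [0, 1] s) minus the
    same for the occluded condition; trial labels are permuted ``n_iter``
    times and p is the fraction of permuted statistics >= the observed one.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    a = np.asarray(stim_trials, float)
    b = np.asarray(occluded_trials, float)
    if a.ndim != 2 or b.ndim != 2 or a.shape[0] == 0 or b.shape[0] == 0:
        raise ValueError("need non-empty 2-D (trials x samples) arrays")
    i0 = int(round(pre * fs))
    i1 = i0 + int(round(TRIAL_DUR * fs))
    observed = _rms_of_mean(a, i0, i1) - _rms_of_mean(b, i0, i1)

    pooled = np.concatenate([a, b], axis=0)[:, i0:i1]
    n1, n = a.shape[0], a.shape[0] + b.shape[0]
    rng = np.random.default_rng(seed)
    # permuted group means via a 0/1 selection matrix (one BLAS call)
    sel = np.zeros((n_iter, n))
    for r in range(n_iter):
        sel[r, rng.choice(n, n1, replace=False)] = 1.0
    sum_all = pooled.sum(axis=0)
    sum_a = sel @ pooled
    mean_a = sum_a / n1
    mean_b = (sum_all[None, :] - sum_a) / (n - n1)
    stat = np.sqrt((mean_a**2).mean(axis=1)) - np.sqrt((mean_b**2).mean(axis=1))
    # tolerance absorbs float noise so exchangeable inputs count as ties
    tol = 1e-9 * (np.sqrt((pooled**2).mean()) + 1e-30)
    return float(np.mean(stat >= observed - tol))


def pulse_ep_amplitude(
    mean_waveform: np.ndarray, fs: float, pre: float = TRIAL_PRE
) -> float:
    """Absolute maximum of the mean response on [0, 1] s after onset."""
    i0 = int(round(pre * fs))
    i1 = i0 + int(round(TRIAL_DUR * fs))
    return float(np.max(np.abs(mean_waveform[i0:i1])))


def analyze_pulse_condition(
    trialsets: dict[str, TrialSet],
    condition: str,
    occluded: str = "occluded",
    n_iter: int = 500,
    seed: int | None = None,
) -> list[PulseEPResult]:
    """Mean waveform, amplitude and significance per channel for one
    pulse condition against the occluded control."""
    ts, occ = trialsets[condition], trialsets[occluded]
    out = []
    for c in range(ts.data.shape[1]):
        mean = ts.data[:, c].mean(axis=0)
        sem = ts.data[:, c].std(axis=0, ddof=1) / np.sqrt(ts.n_trials)
        amp = pulse_ep_amplitude(mean, ts.fs, ts.pre)
        p = pulse_ep_significance(ts.data[:, c], occ.data[:, c], ts.fs,
                                  ts.pre, n_iter, seed)
        cid = ts.channels[c].channel_id if ts.channels else f"ch{c}"
        out.append(PulseEPResult(cid, condition, mean, sem, amp, p))
    return out


def normalize_log_amplitudes(df: pd.DataFrame, value_col: str = "amplitude") -> pd.DataFrame:
    """Per subject x modality, map amplitudes linearly so the group minimum
    becomes 0.001 and the maximum 1, then take log10.

    Output column ``norm_log_amplitude`` lies in [-3, 0].
    """
    out = df.copy()
    vals = np.empty(len(df))
    for _, idx in df.groupby(["subject", "modality"]).groups.items():
        v = df.loc[idx, value_col].to_numpy(float)
        if v.size < 2 or np.ptp(v) == 0:
            raise ValueError("need >= 2 distinct values per subject x modality")
        scaled = NORM_FLOOR + (v - v.min()) / np.ptp(v) * (1.0 - NORM_FLOOR)
        vals[df.index.get_indexer(idx)] = np.log10(scaled)
    out["norm_log_amplitude"] = vals
    return out


def compare_flicker_vs_pulse(
    norm_flicker: np.ndarray, norm_pulse: np.ndarray
) -> tuple[float, float]:
    """Paired two-sided t-test of normalised log amplitudes -> (t, p)."""
    t, p = stats.ttest_rel(norm_flicker, norm_pulse)
    return float(t), float(p)
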