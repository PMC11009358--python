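"""Linear-superposition test of the steady-state response mechanism.

The null mechanism under test: a 40 Hz flicker response is nothing more
than single-pulse evoked potentials repeating every 25 ms and summing
linearly.  Simulated flicker trials are built by drawing recorded
single-pulse responses with replacement, one per 25 ms slot, shifting each
to its slot onset and summing (tails truncated at the trial end).  The
fold-change of simulated trials is then computed exactly as for real
trials and the two compared with a paired t-test: a real response
significantly above its superposed prediction rejects the mechanism.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .preprocess import TrialSet
from .ssep import FCResult, fold_change, multitaper_psd

logger = logging.getLogger("flickerlab")

N_SIM_TRIALS = 15
SIM_DURATION = 10.0
SIM_PERIOD = 0.025  # 40 Hz


@dataclass
class SimulatedFlickerSet:
    """Simulated 40 Hz flicker trials for one channel: (trials, samples)."""

    trials: np.ndarray
    fs: float
    source_indices: np.ndarray   # (n_trials, n_slots) drawn pulse-trial ids
    seed: int | None


def simulate_flicker_from_pulses(
    pulse_trials: np.ndarray,
    fs: float,
    pre: float = 0.25,
    n_trials: int = N_SIM_TRIALS,
    duration: float = SIM_DURATION,
    period: float = SIM_PERIOD,
    seed: int | None = None,
) -> SimulatedFlickerSet:
    """Sum randomly drawn single-pulse responses every ``period`` seconds.

    ``pulse_trials`` is (n_pulse_trials, n_samples) for one channel with
    pulse onset at ``pre`` s; the pre-onset portion of each drawn trial is
    discarded and the remainder aligned to its slot onset.
    """
    pulses = np.asarray(pulse_trials, float)
    if pulses.ndim != 2 or pulses.shape[0] == 0:
        raise ValueError("need >= 1 pulse trial (trials x samples)")
    i_on = int(round(pre * fs))
    kernels = pulses[:, i_on:]
    klen = kernels.shape[1]
    if klen == 0:
        raise ValueError("pulse trials shorter than their kernel support")
    n_out = int(round(duration * fs))
    n_slots = int(round(duration / period))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, pulses.shape[0], size=(n_trials, n_slots))
    out = np.zeros((n_trials, n_out))
    slot_starts = np.round(np.arange(n_slots) * period * fs).astype(int)
    for tr in range(n_trials):
        for s, start in enumerate(slot_starts):
            stop = min(start + klen, n_out)
            out[tr, start:stop] += kernels[idx[tr, s], : stop - start]
    return SimulatedFlickerSet(out, fs, idx, seed)


def simulated_fc(
    sim_stim: SimulatedFlickerSet,
    sim_baseline: SimulatedFlickerSet,
    f_stim: float = 40.0,
    n_iter: int = 10_000,
    seed: int | None = None,
    channel_id: str = "ch0",
    condition_id: str = "simulated",
) -> FCResult:
    """Fold-change of simulated flicker trials against a simulated baseline.

    The baseline set is built by the same summation from occluded /
    noise-only pulse trials, so the estimator matches the one used on real
    trials exactly.
    """
    def as_trialset(sim: SimulatedFlickerSet, cond: str) -> TrialSet:
        return TrialSet(cond, sim.trials[:, None, :], sim.fs, 0.0, 0.0,
                        sim.trials.shape[1] / sim.fs,
                        np.zeros(sim.trials.shape[0]))

    psd_s = multitaper_psd(as_trialset(sim_stim, condition_id))
    psd_b = multitaper_psd(as_trialset(sim_baseline, "sim_baseline"))
    return fold_change(psd_s, psd_b, f_stim, [channel_id], condition_id,
                       n_iter, seed)[0]


@dataclass
class SuperpositionComparison:
    mean_difference: float
    t_stat: float
    p_value: float
    n: int
    median_real: float
    median_sim: float
    frac_sim_significant: float | None = None


def compare_real_vs_simulated(
    fc_real: np.ndarray,
    fc_sim: np.ndarray,
    significant_real: np.ndarray | None = None,
    sim_p: np.ndarray | None = None,
) -> SuperpositionComparison:
    """Paired two-sided t-test of real vs simulated (uncapped) fold-changes.

    Only channels with a significant real 40 Hz response are included when
    ``significant_real`` is given.
    """
    real = np.asarray(fc_real, float)
    sim = np.asarray(fc_sim, float)
    if real.shape != sim.shape:
        raise ValueError("fc_real and fc_sim must be paired")
    if significant_real is not None:
        keep = np.asarray(significant_real, bool)
        real, sim = real[keep], sim[keep]
        if sim_p is not None:
            sim_p = np.asarray(sim_p, float)[keep]
    if real.size < 2:
        raise ValueError("need >= 2 paired observations")
    d = real - sim
    if np.std(d) == 0:
        t, p = (0.0, 1.0) if np.all(d == 0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(real, sim)
    frac = float(np.mean(sim_p < 0.05)) if sim_p is not None else None
    return SuperpositionComparison(
        float(np.mean(real - sim)), float(t), float(p), int(real.size),
        float(np.median(real)), float(np.median(sim)), frac,
    )
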