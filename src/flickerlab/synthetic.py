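"""Ground-truth generator for flicker-neurophysiology analyses.

Emulates the statistical structure the analysis pipeline assumes: stimulus
waveforms (50% duty-cycle square-wave flicker, random pulse trains, single
pulses), pseudo-randomised paradigm schedules, SEEG-like LFP with a 1/f^chi
aperiodic background plus endogenous spectral peaks and stimulus-locked
responses of controlled fold-change, Poisson interictal-discharge (IED)
event streams with condition-dependent rates, and a toy anatomical label
volume for localization tests.

Every random draw flows from a single session seed through named
substreams, so each stage regenerates identically on its own.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import h5py
import numpy as np
import pandas as pd

from .preprocess import ChannelMeta, Recording
from .ssep import multitaper_psd_array

logger = logging.getLogger("flickerlab")

MODALITIES = ("visual", "audiovisual", "auditory")
MODALITY_CODES = {"visual": "V", "audiovisual": "AV", "auditory": "A"}
#: the three-frequency paradigm's periodic frequencies (Hz)
FREQS_3 = (5.5, 40.0, 80.0)
#: the frequency-sweep paradigm's 26 periodic frequencies (Hz)
FREQS_RANGE = (
    5.5, 8.0, 11.0, 14.0, 17.0, 20.0, 23.0, 26.0, 29.0, 32.0, 35.0, 38.0,
    40.0, 42.0, 45.0, 48.0, 51.0, 54.0, 57.0, 63.0, 66.0, 69.0, 72.0, 75.0,
    78.0, 80.0,
)
PULSE_WIDTH = 0.0125       # s; matches one ON phase of 40 Hz flicker
RANDOM_GAP_MAX = 0.025     # s; random-pattern inter-pulse gap ~ U[0, 25] ms
AUDITORY_RAMP = 0.0016     # s; linear rise/fall of the auditory envelope
MAX_RUN = 3                # pseudo-randomisation: no condition >3 in a row

_SUB_SCHEDULE, _SUB_NOISE, _SUB_RESPONSE, _SUB_EVENTS, _SUB_VOLUME = range(5)


def _rng(seed, *stream) -> np.random.Generator:
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, *stream])


# ---------------------------------------------------------------------------
# Stimulus waveforms
# ---------------------------------------------------------------------------

@dataclass
class StimWaveform:
    samples: np.ndarray
    fs: float
    pulse_onsets: np.ndarray
    pulse_width: float
    modality: str
    pattern: str
    freq: float | None = None


def make_stimulus_waveform(
    modality: str,
    pattern: str,
    duration: float,
    fs: float,
    seed: int | None = None,
    freq: float | None = None,
) -> StimWaveform:
    """Build one trial's stimulus drive signal.

    ``pattern="periodic"`` is a 50% duty-cycle square wave at ``freq`` Hz
    (ON duration 0.5/freq); ``pattern="random"`` is a train of 12.5 ms
    pulses with gaps uniform on [0, 25] ms; ``pattern="pulse"`` is a single
    12.5 ms pulse at t=0.  Auditory envelopes get ~1.6 ms linear ramps.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if pattern == "periodic":
        if freq is None or freq <= 0:
            raise ValueError("periodic pattern requires a positive freq")
        if fs < 4 * freq:
            raise ValueError(f"fs={fs} too low for {freq} Hz flicker (need >= 4x)")
        onsets = np.arange(0.0, duration, 1.0 / freq)
        width = 0.5 / freq
    elif pattern == "random":
        rng = np.random.default_rng(seed)
        onsets, t = [], 0.0
        while t + PULSE_WIDTH <= duration:
            onsets.append(t)
            t += PULSE_WIDTH + rng.uniform(0.0, RANDOM_GAP_MAX)
        onsets = np.asarray(onsets)
        width = PULSE_WIDTH
    elif pattern == "pulse":
        onsets = np.array([0.0])
        width = PULSE_WIDTH
    else:
        raise ValueError(f"unsupported pattern {pattern!r}")

    n = int(round(duration * fs))
    t = np.arange(n) / fs
    samples = np.zeros(n)
    for on in onsets:
        samples[(t >= on) & (t < on + width)] = 1.0
    if modality == "auditory":
        ramp = max(int(round(AUDITORY_RAMP * fs)), 1)
        kernel = np.ones(ramp) / ramp
        samples = np.convolve(samples, kernel, mode="same")
    elif modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    return StimWaveform(samples, fs, onsets, width, modality, pattern, freq)


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

@dataclass
class Trial:
    condition_id: str
    modality: str
    pattern: str          # periodic | random | pulse | none
    freq: float | None
    onset: float
    duration: float
    is_baseline: bool = False


@dataclass
class StimSchedule:
    trials: list[Trial]
    paradigm: str
    seed: int

    @property
    def total_duration(self) -> float:
        last = self.trials[-1]
        return last.onset + last.duration

    def conditions(self) -> list[str]:
        seen = []
        for t in self.trials:
            if t.condition_id not in seen:
                seen.append(t.condition_id)
        return seen

    def stim_trials(self) -> list[Trial]:
        return [t for t in self.trials if not t.is_baseline]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                onset_s=[t.onset for t in self.trials],
                duration_s=[t.duration for t in self.trials],
                condition=[t.condition_id for t in self.trials],
                modality=[t.modality for t in self.trials],
                pattern=[t.pattern for t in self.trials],
                freq_hz=[t.freq if t.freq is not None else np.nan
                         for t in self.trials],
                is_baseline=[t.is_baseline for t in self.trials],
            )
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, paradigm: str = "custom", seed: int = 0):
        df = pd.read_csv(path, sep="\t")
        trials = [
            Trial(
                condition_id=str(r.condition),
                modality=str(r.modality),
                pattern=str(r.pattern),
                freq=None if np.isnan(r.freq_hz) else float(r.freq_hz),
                onset=float(r.onset_s),
                duration=float(r.duration_s),
                is_baseline=bool(r.is_baseline),
            )
            for r in df.itertuples()
        ]
        return cls(trials, paradigm, seed)


def _pseudo_random_order(
    items: list[tuple], counts: list[int], key_funcs, rng, max_restarts=2000
) -> list[tuple]:
    """Sequence with every attribute run length <= MAX_RUN (greedy + restart)."""
    for _ in range(max_restarts):
        remaining = list(counts)
        order: list[tuple] = []
        ok = True
        while sum(remaining) > 0:
            cand = []
            for i, item in enumerate(items):
                if remaining[i] == 0:
                    continue
                violates = False
                for kf in key_funcs:
                    k = kf(item)
                    run = 0
                    for prev in reversed(order):
                        if kf(prev) == k:
                            run += 1
                        else:
                            break
                    if run >= MAX_RUN:
                        violates = True
                        break
                if not violates:
                    cand.append(i)
            if not cand:
                ok = False
                break
            w = np.array([remaining[i] for i in cand], float)
            pick = cand[rng.choice(len(cand), p=w / w.sum())]
            order.append(items[pick])
            remaining[pick] -= 1
        if ok:
            return order
    raise RuntimeError("could not build a pseudo-randomised order")


def make_schedule(paradigm: str, seed: int, modality: str = "visual") -> StimSchedule:
    """Generate a pseudo-randomised trial schedule for one paradigm.

    ``flicker_3freq``: 12 stimulation conditions (3 modalities x {5.5, 40,
    80 Hz, random}) x 15 ten-second trials, each followed by a ten-second
    baseline trial (360 trials total).  ``single_pulse``: 200 single 12.5 ms
    pulses per modality plus 200 occluded control pulses, inter-pulse
    interval uniform on [987.5, 1487.5] ms.  ``flicker_range``: 26 periodic
    frequencies x 10 trials + 10 random + 10 baseline for one ``modality``,
    inter-trial interval uniform on [2, 2.5] s.
    """
    rng = _rng(seed, _SUB_SCHEDULE)
    trials: list[Trial] = []

    if paradigm == "flicker_3freq":
        items = []
        for mod in MODALITIES:
            for f in FREQS_3:
                items.append((mod, "periodic", f))
            items.append((mod, "random", None))
        order = _pseudo_random_order(
            items, [15] * len(items),
            key_funcs=[lambda it: it[0], lambda it: it[2]], rng=rng,
        )
        t = 0.0
        for mod, pattern, f in order:
            cid = _condition_id(mod, pattern, f)
            trials.append(Trial(cid, mod, pattern, f, t, 10.0))
            trials.append(Trial("baseline", "none", "none", None, t + 10.0,
                                10.0, is_baseline=True))
            t += 20.0
    elif paradigm == "single_pulse":
        items = [(m, "pulse", None) for m in MODALITIES] + [
            ("occluded", "pulse", None)
        ]
        order = _pseudo_random_order(
            items, [200] * len(items), key_funcs=[lambda it: it[0]], rng=rng
        )
        t = 1.0
        for mod, pattern, f in order:
            cid = "occluded" if mod == "occluded" else f"{MODALITY_CODES[mod]}-pulse"
            trials.append(Trial(cid, mod, pattern, f, t, PULSE_WIDTH))
            t += rng.uniform(0.9875, 1.4875)
    elif paradigm == "flicker_range":
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        items = [(modality, "periodic", f) for f in FREQS_RANGE]
        items.append((modality, "random", None))
        items.append(("none", "none", None))  # baseline
        order = _pseudo_random_order(
            items, [10] * len(items), key_funcs=[lambda it: it], rng=rng
        )
        t = 2.0
        for mod, pattern, f in order:
            if pattern == "none":
                trials.append(Trial("baseline", "none", "none", None, t, 10.0,
                                    is_baseline=True))
            else:
                trials.append(Trial(_condition_id(mod, pattern, f), mod,
                                    pattern, f, t, 10.0))
            t += 10.0 + rng.uniform(2.0, 2.5)
    else:
        raise ValueError(f"unknown paradigm {paradigm!r}")

    return StimSchedule(trials, paradigm, seed)


def _condition_id(modality: str, pattern: str, freq: float | None) -> str:
    code = MODALITY_CODES[modality]
    if pattern == "random":
        return f"{code}-random"
    f = f"{freq:g}"
    return f"{code}-{f}Hz"


# ---------------------------------------------------------------------------
# LFP simulation
# ---------------------------------------------------------------------------

@dataclass
class ResponseSpec:
    """Ground-truth condition response of one channel."""

    fold_change: float
    shape: str = "sinusoid"      # sinusoid | double_peak | broadband
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.fold_change < 0:
            raise ValueError("fold-change target must be >= 0")


@dataclass
class ChannelSpec:
    channel_id: str
    probe_id: str = "P0"
    contact_index: int = 0
    aperiodic_offset: float = 1.0
    aperiodic_exponent: float = 1.5
    peaks: list[tuple[float, float, float]] = field(default_factory=list)
    responses: dict[str, ResponseSpec] = field(default_factory=dict)
    pulse_kernel: np.ndarray | None = None
    group: str = "other"
    white_noise_psd: float = 0.0

    def __post_init__(self) -> None:
        if self.pulse_kernel is not None and len(self.pulse_kernel) == 0:
            raise ValueError("empty pulse kernel")

    def background_psd(self, freqs: np.ndarray) -> np.ndarray:
        """Model one-sided PSD of the channel background (units^2/Hz)."""
        f = np.maximum(np.asarray(freqs, float), 1e-6)
        logp = self.aperiodic_offset - self.aperiodic_exponent * np.log10(f)
        for center, height, width in self.peaks:
            sd = width / 2.0
            logp = logp + height * np.exp(-((f - center) ** 2) / (2 * sd**2))
        return 10.0**logp + self.white_noise_psd

    def meta(self) -> ChannelMeta:
        return ChannelMeta(self.channel_id, self.probe_id, self.contact_index,
                           group=self.group)


def _sine_psd_peak(f: float, n: int, fs: float) -> float:
    """Multitaper PSD at its peak bin for a unit-amplitude sinusoid."""
    t = np.arange(n) / fs
    psd, freqs = multitaper_psd_array(np.cos(2 * np.pi * f * t), fs)
    return float(psd[int(np.argmin(np.abs(freqs - f)))])


def _synth_background(spec: ChannelSpec, n: int, fs: float, rng) -> np.ndarray:
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    s = spec.background_psd(freqs)
    s[0] = 0.0
    amp = np.sqrt(s * fs * n / 4.0)
    x = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    return np.fft.irfft(x, n=n)


def _synth_band_noise(psd_band: np.ndarray, freqs: np.ndarray, n: int,
                      fs: float, rng) -> np.ndarray:
    amp = np.sqrt(psd_band * fs * n / 4.0)
    x = amp * (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size))
    return np.fft.irfft(x, n=n)


def simulate_lfp(
    schedule: StimSchedule,
    channel_specs: list[ChannelSpec],
    duration: float | None = None,
    fs: float = 1024.0,
    seed: int = 0,
) -> Recording:
    """Synthesize a seed-reproducible multichannel LFP recording.

    Per channel: aperiodic 1/f^chi background with endogenous spectral
    peaks, plus condition-locked responses calibrated so the downstream
    fold-change estimator recovers each ``ResponseSpec.fold_change`` in
    expectation (sinusoidal response for periodic conditions, band-limited
    power increase for random flicker, the channel's pulse kernel for
    single-pulse trials).
    """
    pad = 2.0
    if duration is None:
        duration = schedule.total_duration + pad
    if schedule.total_duration > duration + 1e-9:
        raise ValueError("schedule exceeds the requested recording duration")
    stim = sorted(schedule.stim_trials(), key=lambda t: t.onset)
    for a, b in zip(stim[:-1], stim[1:]):
        if b.onset < a.onset + a.duration - 1e-9:
            raise ValueError("overlapping stimulation trials")

    n = int(round(duration * fs))
    data = np.empty((len(channel_specs), n))
    sine_cache: dict[tuple[float, int], float] = {}

    for ci, spec in enumerate(channel_specs):
        noise_rng = _rng(seed, _SUB_NOISE, ci)
        x = _synth_background(spec, n, fs, noise_rng)
        resp_rng = _rng(seed, _SUB_RESPONSE, ci)
        for tr in schedule.trials:
            if tr.is_baseline:
                continue
            rs = spec.responses.get(tr.condition_id)
            if tr.pattern == "pulse":
                if spec.pulse_kernel is not None and tr.condition_id != "occluded":
                    k = spec.pulse_kernel
                    i0 = int(np.floor(tr.onset * fs))
                    m = min(len(k), n - i0)
                    x[i0 : i0 + m] += k[:m]
                continue
            if rs is None or rs.fold_change == 0:
                continue
            i0 = int(np.floor((tr.onset + rs.delay) * fs))
            n_dur = int(round(tr.duration * fs))
            i1 = min(i0 + n_dur, n)
            if tr.pattern == "periodic":
                f = tr.freq
                key = (f, n_dur)
                if key not in sine_cache:
                    sine_cache[key] = _sine_psd_peak(f, n_dur, fs)
                s_bg = float(spec.background_psd(np.array([f]))[0])
                a = np.sqrt(rs.fold_change * s_bg / sine_cache[key])
                t_rel = (np.arange(i0, i1) - i0) / fs
                wave = a * np.cos(2 * np.pi * f * t_rel)
                if rs.shape == "double_peak":
                    wave = wave + 0.5 * a * np.cos(2 * np.pi * 2 * f * t_rel)
                x[i0:i1] += wave
            elif tr.pattern == "random":
                freqs = np.fft.rfftfreq(n_dur, 1.0 / fs)
                band = (freqs >= 5.0) & (freqs <= 80.0)
                psd = np.where(band,
                               rs.fold_change * spec.background_psd(freqs), 0.0)
                burst = _synth_band_noise(psd, freqs, n_dur, fs, resp_rng)
                x[i0:i1] += burst[: i1 - i0]
        data[ci] = x

    return Recording(data, fs, [s.meta() for s in channel_specs])


def save_recording(recording: Recording, path) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("data", data=recording.data)
        h.attrs["fs"] = recording.fs
        tab = pd.DataFrame(
            [
                (c.channel_id, c.probe_id, c.contact_index, c.excluded,
                 c.exclusion_reason, c.anatomical_label, c.group)
                for c in recording.channels
            ]
        )
        h.create_dataset(
            "channels", data=tab.to_csv(index=False, header=False).encode()
        )


def load_recording(path) -> Recording:
    import io

    with h5py.File(path, "r") as h:
        data = h["data"][...]
        fs = float(h.attrs["fs"])
        tab = pd.read_csv(
            io.BytesIO(h["channels"][()]),
            names=["channel_id", "probe_id", "contact_index", "excluded",
                   "exclusion_reason", "anatomical_label", "group"],
            keep_default_na=False,
        )
    chans = [
        ChannelMeta(str(r.channel_id), str(r.probe_id), int(r.contact_index),
                    bool(r.excluded), str(r.exclusion_reason),
                    str(r.anatomical_label), str(r.group))
        for r in tab.itertuples()
    ]
    return Recording(data, fs, chans)


# ---------------------------------------------------------------------------
# IED event streams
# ---------------------------------------------------------------------------

@dataclass
class IEDRateModel:
    """Ground truth for event-rate analyses.

    ``base_rate`` maps channel -> baseline rate lambda (events/s);
    ``condition_effects`` maps (condition_id, group) -> log rate ratio mu
    applied multiplicatively during matching stimulation trials ("*"
    wildcards either key); ``drift`` is an optional rate multiplier over
    session time.
    """

    base_rate: dict[str, float]
    condition_effects: dict[tuple[str, str], float] = field(default_factory=dict)
    channel_group: dict[str, str] = field(default_factory=dict)
    drift: Callable[[np.ndarray], np.ndarray] | None = None

    def __post_init__(self) -> None:
        for ch, lam in self.base_rate.items():
            if not np.isfinite(lam) or lam < 0:
                raise ValueError(f"invalid baseline rate for {ch}: {lam}")

    def effect(self, condition_id: str, group: str) -> float:
        for key in ((condition_id, group), (condition_id, "*"),
                    ("*", group), ("*", "*")):
            if key in self.condition_effects:
                return self.condition_effects[key]
        return 0.0


def simulate_ied_events(
    schedule: StimSchedule,
    rate_model: IEDRateModel,
    seed: int = 0,
    duration: float | None = None,
) -> dict[str, np.ndarray]:
    """Inhomogeneous-Poisson IED timestamps per channel (thinning sampler)."""
    if duration is None:
        duration = schedule.total_duration
    stim = [t for t in schedule.trials if not t.is_baseline]
    starts = np.array([t.onset for t in stim])
    stops = np.array([t.onset + t.duration for t in stim])
    conds = [t.condition_id for t in stim]

    grid = np.linspace(0.0, duration, 2049)
    drift_vals = rate_model.drift(grid) if rate_model.drift else np.ones_like(grid)
    if np.any(drift_vals < 0):
        raise ValueError("drift multiplier must be non-negative")
    drift_max = float(drift_vals.max())

    out: dict[str, np.ndarray] = {}
    for k, (ch, lam) in enumerate(rate_model.base_rate.items()):
        rng = _rng(seed, _SUB_EVENTS, k)
        group = rate_model.channel_group.get(ch, "*")
        mults = np.array([np.exp(rate_model.effect(c, group)) for c in conds])
        lam_max = lam * drift_max * max(float(mults.max(initial=1.0)), 1.0)
        if lam_max == 0:
            out[ch] = np.array([])
            continue
        n_cand = rng.poisson(lam_max * duration)
        t_cand = np.sort(rng.uniform(0.0, duration, n_cand))
        rate = np.full(t_cand.size, lam)
        if rate_model.drift:
            rate *= rate_model.drift(t_cand)
        idx = np.searchsorted(starts, t_cand, side="right") - 1
        in_trial = (idx >= 0) & (t_cand < stops[np.maximum(idx, 0)])
        rate[in_trial] *= mults[idx[in_trial]]
        keep = rng.uniform(0.0, 1.0, t_cand.size) < rate / lam_max
        out[ch] = t_cand[keep]
    return out


def events_to_tsv(events: dict[str, np.ndarray], path) -> None:
    rows = [(t, ch) for ch, ts in events.items() for t in ts]
    pd.DataFrame(rows, columns=["onset_s", "channel"]).sort_values(
        "onset_s"
    ).to_csv(path, sep="\t", index=False)


def events_from_tsv(path) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        ch: np.sort(g["onset_s"].to_numpy())
        for ch, g in df.groupby("channel", sort=False)
    }


# ---------------------------------------------------------------------------
# Toy anatomical label volume
# ---------------------------------------------------------------------------

WHITE_MATTER = "cerebral-white-matter"


def make_label_volume(
    grid_shape: tuple[int, int, int],
    labels: list[str],
    electrode_xyz: np.ndarray,
    seed: int = 0,
    voxel_size_mm: float = 1.0,
):
    """Deterministic toy voxel label map plus validated electrode coords.

    The volume is white matter everywhere except seeded spherical regions,
    one per requested label.  Returns a ``localization.LabelVolume`` and the
    electrode coordinates in world mm.
    """
    from .localization import LabelVolume

    rng = _rng(seed, _SUB_VOLUME)
    shape = tuple(int(s) for s in grid_shape)
    vol = np.zeros(shape, dtype=int)  # 0 = white matter
    names = {0: WHITE_MATTER}
    centers = []
    for li, name in enumerate(labels, start=1):
        names[li] = name
        c = rng.uniform(0.25, 0.75, 3) * np.array(shape)
        r = rng.uniform(0.12, 0.25) * min(shape)
        centers.append((c, r))
        ii, jj, kk = np.indices(shape)
        d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        vol[d2 <= r**2] = li
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    volume = LabelVolume(vol, names, affine)

    xyz = np.atleast_2d(np.asarray(electrode_xyz, float))
    ijk = xyz / voxel_size_mm
    if np.any(ijk < -0.5) or np.any(ijk >= np.array(shape) - 0.5):
        raise ValueError("electrode outside the label grid")
    return volume, xyz
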