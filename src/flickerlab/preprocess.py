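"""Channel handling, re-referencing, segmentation, filtering, trial balancing.

Intracranial (SEEG) recordings are stored as a channels x samples array plus
per-contact metadata.  All downstream spectral statistics assume the
re-referenced, band-limited, trial-segmented representation produced here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

logger = logging.getLogger("flickerlab")

#: analysis band of the LFP pipeline (Hz)
BAND_LOW = 2.0
BAND_HIGH = 300.0
#: minimum sampling rate supporting the 2-300 Hz band
MIN_FS = 600.0


@dataclass
class ChannelMeta:
    """Metadata for one SEEG contact.

    ``contact_index`` counts from deep (0) to superficial along the probe.
    """

    channel_id: str
    probe_id: str
    contact_index: int
    excluded: bool = False
    exclusion_reason: str = ""
    anatomical_label: str = ""
    group: str = "other"


@dataclass
class Recording:
    """Multichannel LFP: ``data`` is (n_channels, n_samples) at ``fs`` Hz."""

    data: np.ndarray
    fs: float
    channels: list[ChannelMeta]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError("channel metadata does not match data rows")
        if self.fs <= MIN_FS:
            raise ValueError(
                f"fs={self.fs} Hz too low; need > {MIN_FS} Hz for the "
                f"{BAND_LOW}-{BAND_HIGH} Hz band"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_index(self, channel_id: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.channel_id == channel_id:
                return i
        raise KeyError(channel_id)


@dataclass
class TrialSet:
    """Per-condition trial segments: ``data`` is (trials, channels, samples).

    The segment spans ``pre`` s before stimulus onset to ``post`` s after
    stimulus offset; the stimulus itself occupies ``duration`` s.
    """

    condition_id: str
    data: np.ndarray
    fs: float
    pre: float
    post: float
    duration: float
    onsets: np.ndarray
    channels: list[ChannelMeta] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def stim_slice(self) -> slice:
        """Sample slice covering exactly the stimulus window."""
        i0 = int(round(self.pre * self.fs))
        i1 = i0 + int(round(self.duration * self.fs))
        return slice(i0, i1)


def channel_table(channels: list[ChannelMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            dict(
                channel_id=c.channel_id,
                probe_id=c.probe_id,
                contact_index=c.contact_index,
                excluded=c.excluded,
                exclusion_reason=c.exclusion_reason,
                anatomical_label=c.anatomical_label,
                group=c.group,
            )
            for c in channels
        ]
    )


def read_channel_table(path) -> list[ChannelMeta]:
    df = pd.read_csv(path, sep="\t")
    return [
        ChannelMeta(
            channel_id=str(r.channel_id),
            probe_id=str(r.probe_id),
            contact_index=int(r.contact_index),
            excluded=bool(r.excluded),
            exclusion_reason=str(getattr(r, "exclusion_reason", "") or ""),
            anatomical_label=str(getattr(r, "anatomical_label", "") or ""),
            group=str(getattr(r, "group", "other") or "other"),
        )
        for r in df.itertuples()
    ]


def write_channel_table(channels: list[ChannelMeta], path) -> None:
    channel_table(channels).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Laplacian / bipolar re-referencing
# ---------------------------------------------------------------------------

def laplacian_rereference(recording: Recording) -> Recording:
    """Re-reference every usable contact against its probe neighbours.

    Interior contacts get ``x_i - (x_below + x_above)/2`` (Laplacian); the
    contacts at either end of a probe get bipolar referencing against their
    single neighbour.  When an immediate neighbour is excluded the nearest
    non-excluded contact on that side is substituted.  Excluded channels are
    dropped from the output.
    """
    out_rows: list[np.ndarray] = []
    out_meta: list[ChannelMeta] = []
    probes: dict[str, list[int]] = {}
    for i, ch in enumerate(recording.channels):
        probes.setdefault(ch.probe_id, []).append(i)

    for probe_id, idxs in probes.items():
        idxs = sorted(idxs, key=lambda i: recording.channels[i].contact_index)
        usable = [i for i in idxs if not recording.channels[i].excluded]
        if len(usable) < 2:
            raise ValueError(
                f"probe {probe_id!r} has {len(usable)} usable contact(s); "
                "need at least 2 for re-referencing"
            )
        for pos, i in enumerate(usable):
            x = recording.data[i]
            below = usable[pos - 1] if pos > 0 else None
            above = usable[pos + 1] if pos < len(usable) - 1 else None
            if below is None:
                ref = recording.data[above]
            elif above is None:
                ref = recording.data[below]
            else:
                ref = 0.5 * (recording.data[below] + recording.data[above])
            out_rows.append(x - ref)
            out_meta.append(replace(recording.channels[i]))

    return Recording(np.array(out_rows), recording.fs, out_meta)


# ---------------------------------------------------------------------------
# Trial segmentation
# ---------------------------------------------------------------------------

def segment_trials(
    recording: Recording,
    schedule,
    pre: float = 1.0,
    post: float = 1.0,
    conditions: list[str] | None = None,
) -> dict[str, TrialSet]:
    """Cut the recording into per-condition trial segments.

    Each segment covers ``[onset - pre, onset + duration + post)`` and is
    demeaned over its full extent (baseline correction).  Trial onsets snap
    to the nearest-by-flooring sample.
    """
    fs = recording.fs
    by_cond: dict[str, list] = {}
    for tr in schedule.trials:
        if conditions is not None and tr.condition_id not in conditions:
            continue
        by_cond.setdefault(tr.condition_id, []).append(tr)

    out: dict[str, TrialSet] = {}
    for cond, trs in by_cond.items():
        dur = trs[0].duration
        n_samp = int(round((pre + dur + post) * fs))
        segs = np.empty((len(trs), recording.n_channels, n_samp))
        onsets = np.empty(len(trs))
        for k, tr in enumerate(trs):
            if abs(tr.duration - dur) > 1e-9:
                raise ValueError(f"unequal trial durations in condition {cond!r}")
            i0 = int(np.floor((tr.onset - pre) * fs))
            if i0 < 0 or i0 + n_samp > recording.data.shape[1]:
                raise ValueError(
                    f"trial at t={tr.onset:.3f}s exceeds recording bounds"
                )
            seg = recording.data[:, i0 : i0 + n_samp]
            segs[k] = seg - seg.mean(axis=1, keepdims=True)
            onsets[k] = tr.onset
        out[cond] = TrialSet(
            condition_id=cond,
            data=segs,
            fs=fs,
            pre=pre,
            post=post,
            duration=dur,
            onsets=onsets,
            channels=list(recording.channels),
        )
    return out


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def _bandpass_sos(fs: float, low: float, high: float, order: int = 4):
    nyq = fs / 2.0
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    return signal.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_trials(
    trialset: TrialSet, low: float = BAND_LOW, high: float = BAND_HIGH
) -> TrialSet:
    """Zero-phase 4th-order Butterworth band-pass applied per trial."""
    sos = _bandpass_sos(trialset.fs, low, high)
    data = signal.sosfiltfilt(sos, trialset.data, axis=-1)
    return replace(trialset, data=data)


def bandpass_recording(
    recording: Recording, low: float = BAND_LOW, high: float = BAND_HIGH
) -> Recording:
    sos = _bandpass_sos(recording.fs, low, high)
    return Recording(
        signal.sosfiltfilt(sos, recording.data, axis=-1),
        recording.fs,
        recording.channels,
    )


# ---------------------------------------------------------------------------
# Trial-count balancing
# ---------------------------------------------------------------------------

def balance_trials(
    trialsets: dict[str, TrialSet], seed: int | None = None
) -> dict[str, TrialSet]:
    """Randomly downsample every condition to the minimum trial count.

    Selection is without replacement, order-preserving, and reproducible
    from ``seed``.
    """
    counts = {c: ts.n_trials for c, ts in trialsets.items()}
    if any(n == 0 for n in counts.values()):
        empty = [c for c, n in counts.items() if n == 0]
        raise ValueError(f"empty condition(s): {empty}")
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    out = {}
    for cond, ts in trialsets.items():
        if ts.n_trials == n_min:
            out[cond] = ts
        else:
            keep = np.sort(rng.choice(ts.n_trials, size=n_min, replace=False))
            out[cond] = replace(ts, data=ts.data[keep], onsets=ts.onsets[keep])
    return out
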