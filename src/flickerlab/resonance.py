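"""Endogenous-oscillation detection and the resonance-vs-entrainment test.

The baseline power spectrum of each channel is parameterised as an
aperiodic power law plus up to five Gaussian peaks in log-power space
(iterative peak extraction; detection floor 0.6 log-units, peak widths
2-10 Hz, fit range 2-100 Hz).  A channel's response profile across the
26-frequency flicker sweep is summarised by its top stimulation frequency
(argmax significant fold-change) and compared against its nearest
endogenous peak: under entrainment the two coincide within 5 Hz, under
resonance they need not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import curve_fit

from .ssep import FCResult, PLVResult

logger = logging.getLogger("flickerlab")

MAX_PEAKS = 5
PEAK_WIDTH_LIMITS = (2.0, 10.0)   # Hz (full bandwidth = 2 sigma)
MIN_PEAK_HEIGHT = 0.6             # log10-power units above the aperiodic fit
FIT_RANGE = (2.0, 100.0)
ENTRAIN_WINDOW_HZ = 5.0
MIN_SIG_FREQS = 6                 # "more than 6" -> >= 7 significant freqs


# ---------------------------------------------------------------------------
# Spectral parameterization
# ---------------------------------------------------------------------------

@dataclass
class SpectralFit:
    channel_id: str
    offset: float
    exponent: float
    peaks: list[tuple[float, float, float]]   # (center Hz, height, width Hz)
    freqs: np.ndarray = field(repr=False, default=None)
    log_psd: np.ndarray = field(repr=False, default=None)

    def aperiodic(self, freqs: np.ndarray) -> np.ndarray:
        """Aperiodic component in log10-power."""
        return self.offset - self.exponent * np.log10(np.asarray(freqs, float))

    def peak_component(self, freqs: np.ndarray) -> np.ndarray:
        f = np.asarray(freqs, float)
        out = np.zeros_like(f)
        for c, h, w in self.peaks:
            out += h * np.exp(-((f - c) ** 2) / (2 * (w / 2.0) ** 2))
        return out

    def model(self, freqs: np.ndarray) -> np.ndarray:
        return self.aperiodic(freqs) + self.peak_component(freqs)


def _gauss(f, c, h, sd):
    return h * np.exp(-((f - c) ** 2) / (2 * sd**2))


def _multi_gauss(f, *params):
    out = np.zeros_like(f)
    for i in range(0, len(params), 3):
        out += _gauss(f, *params[i : i + 3])
    return out


def _robust_aperiodic(logf: np.ndarray, logp: np.ndarray) -> tuple[float, float]:
    """Power-law fit in log-log space, down-weighting oscillatory peaks."""
    A = np.vstack([np.ones_like(logf), -logf]).T
    coef, *_ = np.linalg.lstsq(A, logp, rcond=None)
    for _ in range(3):
        resid = logp - A @ coef
        # peaks only push residuals up; refit on the non-elevated portion
        mask = resid <= np.percentile(resid, 60)
        coef, *_ = np.linalg.lstsq(A[mask], logp[mask], rcond=None)
    return float(coef[0]), float(coef[1])


def fit_spectral_parameterization(
    freqs: np.ndarray,
    psd: np.ndarray,
    channel_id: str = "",
    max_peaks: int = MAX_PEAKS,
    width_limits: tuple[float, float] = PEAK_WIDTH_LIMITS,
    min_height: float = MIN_PEAK_HEIGHT,
    fit_range: tuple[float, float] = FIT_RANGE,
) -> SpectralFit:
    """Aperiodic power-law + iterative Gaussian peak fit of a baseline PSD.

    Peaks are extracted largest-first from the aperiodic-flattened log
    spectrum until the next candidate falls below ``min_height`` or
    ``max_peaks`` is reached, then refit jointly and the aperiodic
    component refit on the peak-subtracted spectrum.
    """
    freqs = np.asarray(freqs, float)
    psd = np.asarray(psd, float)
    if not np.all(np.isfinite(psd)):
        raise ValueError("PSD contains non-finite values")
    sel = (freqs >= fit_range[0]) & (freqs <= fit_range[1])
    f = freqs[sel]
    if np.any(psd[sel] <= 0):
        raise ValueError("PSD must be strictly positive on the fit range")
    logp = np.log10(psd[sel])
    logf = np.log10(f)

    offset, exponent = _robust_aperiodic(logf, logp)
    flat = logp - (offset - exponent * logf)
    sd_lim = (width_limits[0] / 2.0, width_limits[1] / 2.0)

    params: list[float] = []
    resid = flat.copy()
    for _ in range(max_peaks):
        i = int(np.argmax(resid))
        h0 = resid[i]
        if h0 < min_height:
            break
        # half-height width guess from the local crossing
        half = h0 / 2.0
        lo = i
        while lo > 0 and resid[lo] > half:
            lo -= 1
        hi = i
        while hi < resid.size - 1 and resid[hi] > half:
            hi += 1
        fwhm = max(f[hi] - f[lo], 1e-3)
        sd0 = np.clip(fwhm / 2.355, *sd_lim)
        try:
            popt, _ = curve_fit(
                _gauss, f, resid, p0=[f[i], h0, sd0],
                bounds=([fit_range[0], 0.0, sd_lim[0]],
                        [fit_range[1], 3 * h0 + 1, sd_lim[1]]),
                maxfev=2000,
            )
        except RuntimeError:
            popt = [f[i], h0, sd0]
        params.extend(popt)
        resid = resid - _gauss(f, *popt)

    if params:
        lo_b, hi_b = [], []
        for i in range(0, len(params), 3):
            lo_b += [fit_range[0], 0.0, sd_lim[0]]
            hi_b += [fit_range[1], np.inf, sd_lim[1]]
        try:
            params, _ = curve_fit(
                _multi_gauss, f, flat, p0=params, bounds=(lo_b, hi_b),
                maxfev=5000,
            )
            params = list(params)
        except RuntimeError:
            pass
        # refit the aperiodic component on the peak-subtracted spectrum
        A = np.vstack([np.ones_like(logf), -logf]).T
        coef, *_ = np.linalg.lstsq(A, logp - _multi_gauss(f, *params), rcond=None)
        offset, exponent = float(coef[0]), float(coef[1])

    peaks = []
    for i in range(0, len(params), 3):
        c, h, sd = params[i : i + 3]
        if h >= min_height and fit_range[0] <= c <= fit_range[1]:
            peaks.append((float(c), float(h), float(2 * sd)))
    peaks.sort(key=lambda p: -p[1])
    return SpectralFit(channel_id, offset, exponent, peaks, f, logp)


def endogenous_peak_foldchange(fit: SpectralFit) -> list[tuple[float, float]]:
    """(center Hz, fold-change) of each detected endogenous oscillation.

    Fold-change is modeled power over the aperiodic fit at the peak center
    minus one -- the same "-1" convention as the flicker fold-change.
    """
    if not fit.peaks:
        raise ValueError("no peaks in the spectral fit")
    out = []
    for c, _, _ in fit.peaks:
        fa = np.array([c])
        ratio = 10.0 ** (fit.model(fa) - fit.aperiodic(fa))
        out.append((c, float(ratio[0] - 1.0)))
    return out


# ---------------------------------------------------------------------------
# Frequency profiles across the stimulation sweep
# ---------------------------------------------------------------------------

@dataclass
class FrequencyProfile:
    channel_id: str
    freqs: np.ndarray
    fc: np.ndarray
    fc_significant: np.ndarray
    plv: np.ndarray | None
    plv_significant: np.ndarray | None
    top_freq: float | None
    n_sig_fc: int
    n_sig_plv: int
    nearest_endo_freq: float | None
    endo_distance: float | None
    within_5hz: bool | None

    @property
    def empty(self) -> bool:
        return self.top_freq is None


def build_frequency_profile(
    fc_results: list[FCResult],
    plv_results: list[PLVResult] | None = None,
    spectral_fit: SpectralFit | None = None,
    channel_id: str = "",
) -> FrequencyProfile:
    """Summarise one channel's response across the stimulation sweep.

    Top frequency is the argmax fold-change among significant frequencies
    (ties go to the lowest frequency); the nearest detected endogenous peak
    and the within-5-Hz entrainment flag are attached when a spectral fit
    is supplied.
    """
    fc_results = sorted(fc_results, key=lambda r: r.f_stim)
    freqs = np.array([r.f_stim for r in fc_results])
    fc = np.array([r.fc for r in fc_results])
    sig = np.array([r.significant for r in fc_results])
    if plv_results is not None:
        plv_results = sorted(plv_results, key=lambda r: r.f_stim)
        plv = np.array([r.plv for r in plv_results])
        plv_sig = np.array([r.rayleigh_p < 0.05 for r in plv_results])
        n_sig_plv = int(plv_sig.sum())
    else:
        plv = plv_sig = None
        n_sig_plv = 0

    if sig.any():
        masked = np.where(sig, fc, -np.inf)
        top = float(freqs[int(np.argmax(masked))])  # argmax ties -> lowest f
    else:
        top = None

    nearest = dist = within = None
    if spectral_fit is not None and spectral_fit.peaks and top is not None:
        centers = np.array([p[0] for p in spectral_fit.peaks])
        j = int(np.argmin(np.abs(centers - top)))
        nearest = float(centers[j])
        dist = float(abs(centers[j] - top))
        within = dist <= ENTRAIN_WINDOW_HZ

    return FrequencyProfile(
        channel_id or (fc_results[0].channel_id if fc_results else ""),
        freqs, fc, sig, plv, plv_sig, top, int(sig.sum()), n_sig_plv,
        nearest, dist, within,
    )


@dataclass
class EntrainmentTestResult:
    fraction_within_5hz: float
    t_stat: float
    p_value: float
    mean_difference: float
    n: int


def entrainment_test(
    profiles: list[FrequencyProfile],
    min_sig_freqs: int = MIN_SIG_FREQS,
) -> EntrainmentTestResult:
    """Fraction of qualifying channels whose top stimulation frequency lies
    within 5 Hz of an endogenous peak, plus a paired t-test of the two
    frequency lists.

    Qualifying channels have at least one detected endogenous oscillation
    and a significant fold-change at more than ``min_sig_freqs`` of the
    tested frequencies.
    """
    qual = [
        p for p in profiles
        if p.top_freq is not None and p.nearest_endo_freq is not None
        and p.n_sig_fc > min_sig_freqs
    ]
    if len(qual) < 2:
        raise ValueError("fewer than 2 qualifying channels")
    tops = np.array([p.top_freq for p in qual])
    endos = np.array([p.nearest_endo_freq for p in qual])
    frac = float(np.mean(np.abs(tops - endos) <= ENTRAIN_WINDOW_HZ))
    if np.allclose(tops - endos, (tops - endos)[0]):
        # degenerate paired differences (e.g. all zero): no variance to test
        t, p = (0.0, 1.0) if np.allclose(tops, endos) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_rel(tops, endos)
    return EntrainmentTestResult(frac, float(t), float(p),
                                 float(np.mean(tops - endos)), len(qual))
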