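"""Interictal epileptiform discharge (IED) event construction and
Poisson mixed-effects rate modeling.

Per-channel spike timestamps are merged into multichannel IED events: all
spikes within 100 ms of an event's first spike belong to that event, an
event spanning more than 11 distinct channels is flagged as noise and
removed, and each event is assigned to the first channel that detected its
first spike.  Event counts per 10 s stimulation trial and time-matched
baseline segment feed a Poisson generalized linear mixed model with a log
link, a stimulation indicator and trial start time as fixed effects, and
random intercepts absorbing between-subject/session baseline-rate
heterogeneity.  The fixed-effect log rate ratio mu is reported as a
percent change mu% = 100*(e^mu - 1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

logger = logging.getLogger("flickerlab")

MERGE_WINDOW = 0.100      # s
MAX_EVENT_CHANNELS = 11   # events on more channels are noise
OFF_PERIOD_S = 2.0        # matched-baseline segment length, sweep paradigm
N_OFF_PERIODS = 5         # segments per matched baseline


# ---------------------------------------------------------------------------
# Event merging
# ---------------------------------------------------------------------------

@dataclass
class IEDEvent:
    onset: float
    channels: tuple[str, ...]
    assigned_channel: str
    noise: bool = False

    @property
    def n_channels(self) -> int:
        return len(self.channels)


def merge_spikes_to_events(
    spikes: dict[str, np.ndarray],
    window: float = MERGE_WINDOW,
    max_channels: int = MAX_EVENT_CHANNELS,
    chain: bool = False,
) -> list[IEDEvent]:
    """Merge per-channel spike times into IED events.

    With the default non-chaining rule a spike joins the open event iff it
    falls within ``window`` of the event's *first* spike; ``chain=True``
    instead extends the window from the latest member spike.  Events
    spanning more than ``max_channels`` distinct channels are flagged noise
    (they are returned flagged; downstream counting skips them).
    """
    order = list(spikes.keys())
    rank = {ch: i for i, ch in enumerate(order)}
    flat = []
    for ch, ts in spikes.items():
        ts = np.asarray(ts, float)
        if np.any(ts < 0):
            raise ValueError("negative spike timestamps")
        flat.extend((float(t), ch) for t in ts)
    flat.sort(key=lambda x: (x[0], rank[x[1]]))

    events: list[IEDEvent] = []
    i = 0
    while i < len(flat):
        t0, ch0 = flat[i]
        members = [flat[i]]
        j = i + 1
        ref = t0
        while j < len(flat) and flat[j][0] - ref <= window:
            members.append(flat[j])
            if chain:
                ref = flat[j][0]
            j += 1
        chans = tuple(dict.fromkeys(ch for _, ch in members))
        events.append(
            IEDEvent(t0, chans, ch0, noise=len(chans) > max_channels)
        )
        i = j
    return events


def events_table(events: list[IEDEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        dict(
            onset_s=[e.onset for e in events],
            n_channels=[e.n_channels for e in events],
            assigned_channel=[e.assigned_channel for e in events],
            noise=[e.noise for e in events],
        )
    )


# ---------------------------------------------------------------------------
# Trial-level count table
# ---------------------------------------------------------------------------

def build_count_table(
    events: list[IEDEvent],
    schedule,
    channel_groups: dict[str, str],
    subject: str = "s01",
    session: str = "s01a",
    task: str | None = None,
    modulation_groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per (stimulation trial, channel group) and its time-matched
    baseline.

    For the three-frequency paradigm the matched baseline is the 10 s
    baseline trial that follows each stimulation trial; for the frequency
    sweep it is the 5 closest 2 s stimulation-OFF periods (baseline trials
    chopped into 2 s pieces plus inter-trial gaps >= 2 s).  Baseline rows
    inherit the stimulation trial's start-time covariate.
    """
    task = task or schedule.paradigm
    clean = [e for e in events if not e.noise]
    onsets = np.array([e.onset for e in clean])
    groups_of_events = np.array(
        [channel_groups.get(e.assigned_channel, "") for e in clean]
    )
    tracked = sorted(set(channel_groups.values()))

    def count(group: str, t0: float, t1: float) -> int:
        if onsets.size == 0:
            return 0
        m = (onsets >= t0) & (onsets < t1) & (groups_of_events == group)
        return int(m.sum())

    trials = schedule.trials
    rows = []
    if schedule.paradigm == "flicker_range":
        off_periods = _off_periods(schedule)

    for i, tr in enumerate(trials):
        if tr.is_baseline:
            continue
        if tr.pattern == "pulse":
            raise ValueError("count tables are defined for flicker paradigms")
        t0, t1 = tr.onset, tr.onset + tr.duration
        if schedule.paradigm == "flicker_range":
            centers = 0.5 * (off_periods[:, 0] + off_periods[:, 1])
            near = np.argsort(np.abs(centers - 0.5 * (t0 + t1)))[:N_OFF_PERIODS]
            if near.size < N_OFF_PERIODS:
                raise ValueError("not enough baseline OFF periods to match")
            bl_windows = off_periods[near]
        else:
            nxt = next(
                (t for t in trials[i + 1 :] if t.is_baseline), None
            )
            if nxt is None:
                raise ValueError(f"no baseline trial after t={t0:.1f}s")
            bl_windows = np.array([[nxt.onset, nxt.onset + nxt.duration]])

        for g in tracked:
            common = dict(
                condition=tr.condition_id, modality=tr.modality,
                subject=subject, session=session, task=task,
                trial_time=t0, group=g, trial_index=i,
                mod_group=(modulation_groups or {}).get(g, ""),
            )
            rows.append(dict(count=count(g, t0, t1), stimulation=1, **common))
            bl = sum(count(g, a, b) for a, b in bl_windows)
            rows.append(dict(count=bl, stimulation=0, **common))
    return pd.DataFrame(rows)


def _off_periods(schedule) -> np.ndarray:
    """2 s stimulation-OFF windows: baseline trials in 2 s pieces plus
    inter-trial gaps of at least 2 s."""
    out = []
    trials = sorted(schedule.trials, key=lambda t: t.onset)
    for tr in trials:
        if tr.is_baseline:
            k = int(tr.duration // OFF_PERIOD_S)
            for j in range(k):
                a = tr.onset + j * OFF_PERIOD_S
                out.append((a, a + OFF_PERIOD_S))
    for a, b in zip(trials[:-1], trials[1:]):
        gap0 = a.onset + a.duration
        if b.onset - gap0 >= OFF_PERIOD_S:
            out.append((gap0, gap0 + OFF_PERIOD_S))
    if not out:
        raise ValueError("schedule has no stimulation-OFF periods")
    return np.array(sorted(out))


# ---------------------------------------------------------------------------
# Poisson GLMM (maximum likelihood, adaptive Gauss-Hermite quadrature)
# ---------------------------------------------------------------------------

@dataclass
class GLMMResult:
    stratum: str
    mu: float
    se: float
    ci: tuple[float, float]
    p: float
    df: int
    mu_pct: float
    ci_pct: tuple[float, float]
    n_rows: int
    sigma_re: float | None = None
    method: str = "agq"
    term: str = "stimulation"

    def to_row(self) -> dict:
        return dict(
            stratum=self.stratum, term=self.term, mu=self.mu, se=self.se,
            mu_pct=self.mu_pct, ci_lo_pct=self.ci_pct[0],
            ci_hi_pct=self.ci_pct[1], p=self.p, df=self.df,
            n_rows=self.n_rows, method=self.method,
        )


def percent_change(mu: float, ci: tuple[float, float] | None = None):
    """Log rate ratio -> percent change, mu% = 100*(e^mu - 1)."""
    pct = 100.0 * (np.exp(mu) - 1.0)
    if ci is None:
        return float(pct)
    return float(pct), (float(100.0 * (np.exp(ci[0]) - 1.0)),
                        float(100.0 * (np.exp(ci[1]) - 1.0)))


def _agq_nll(params, y, X, groups, n_g, sum_y, n_quad=12):
    beta, log_sigma = params[:-1], params[-1]
    sigma2 = np.exp(2.0 * log_sigma)
    eta = X @ beta
    lam0 = np.exp(np.clip(eta, -30, 30))
    sum_lam0 = np.bincount(groups, weights=lam0, minlength=n_g)
    b = np.zeros(n_g)
    for _ in range(30):
        g = sum_y - sum_lam0 * np.exp(b) - b / sigma2
        h = -sum_lam0 * np.exp(b) - 1.0 / sigma2
        b -= np.clip(g / h, -4.0, 4.0)
    curv = sum_lam0 * np.exp(b) + 1.0 / sigma2
    s = 1.0 / np.sqrt(curv)
    z, w = np.polynomial.hermite_e.hermegauss(n_quad)
    B = b[:, None] + s[:, None] * z[None, :]
    f = (sum_y[:, None] * B - sum_lam0[:, None] * np.exp(B)
         - 0.5 * B**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2))
    log_int = logsumexp(f + 0.5 * z[None, :] ** 2 + np.log(w)[None, :],
                        axis=1) + np.log(s)
    const = float(np.sum(y * eta) - np.sum(gammaln(y + 1.0)))
    return -(const + float(np.sum(log_int)))


def _fit_agq(y, X, groups, n_quad=12):
    import statsmodels.api as sm
    from statsmodels.tools.numdiff import approx_hess

    n_g = int(groups.max()) + 1
    sum_y = np.bincount(groups, weights=y, minlength=n_g)
    start = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    x0 = np.r_[start.params, np.log(0.5)]
    nll = lambda p: _agq_nll(p, y, X, groups, n_g, sum_y, n_quad)
    res = minimize(nll, x0, method="BFGS",
                   options=dict(gtol=1e-5, maxiter=500))
    H = approx_hess(res.x, nll)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(res.x.size, np.nan)
    return res.x, se


def _design(table: pd.DataFrame, extra_terms: list[str]):
    cols = [np.ones(len(table)), table["stimulation"].to_numpy(float)]
    names = ["intercept", "stimulation"]
    if "trial_time" in table:
        t = table["trial_time"].to_numpy(float)
        span = np.ptp(t)
        cols.append((t - t.min()) / span if span > 0 else np.zeros_like(t))
        names.append("trial_time")
    if "task" in table and table["task"].nunique() > 1:
        for lev in sorted(table["task"].unique())[1:]:
            cols.append((table["task"] == lev).to_numpy(float))
            names.append(f"task[{lev}]")
    for term in extra_terms:
        cols.append(table[term].to_numpy(float))
        names.append(term)
    return np.column_stack(cols), names


def fit_poisson_glmm(
    table: pd.DataFrame,
    stratum: str = "overall",
    extra_terms: list[str] | None = None,
    term: str = "stimulation",
    n_quad: int = 12,
) -> GLMMResult:
    """Poisson GLMM of IED counts with a random intercept per
    subject-session cell.

    Fixed effects: stimulation indicator, trial start time (scaled to
    [0, 1]), task when several are present, plus any ``extra_terms``
    columns.  With fewer than two subjects the model falls back to a
    fixed-intercept Poisson regression (with a warning).  Wald CIs and
    two-sided p-values are reported for ``term`` along with the percent
    change transform.
    """
    if len(table) == 0 or table["count"].sum() == 0:
        raise ValueError(f"stratum {stratum!r} is empty or all-zero")
    y = table["count"].to_numpy(float)
    if np.any(y != np.round(y)) or np.any(y < 0):
        raise ValueError("counts must be non-negative integers")
    if table["stimulation"].nunique() < 2:
        raise ValueError("stratum needs both stimulation and baseline rows")
    X, names = _design(table, extra_terms or [])
    k = names.index(term)

    n_subjects = table["subject"].nunique()
    cells = (table["subject"].astype(str) + ":" + table["session"].astype(str))
    groups = pd.factorize(cells)[0]
    if n_subjects >= 2:
        params, se_all = _fit_agq(y, X, groups, n_quad)
        mu, se = float(params[k]), float(se_all[k])
        sigma_re = float(np.exp(params[-1]))
        method = "agq"
    else:
        import statsmodels.api as sm

        warnings.warn(
            "single subject: falling back to fixed-intercept Poisson "
            "regression", stacklevel=2
        )
        fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        mu, se = float(fit.params[k]), float(fit.bse[k])
        sigma_re = None
        method = "poisson_glm"

    ci = (mu - 1.96 * se, mu + 1.96 * se)
    zval = mu / se if se > 0 else np.inf
    p = float(2 * stats.norm.sf(abs(zval)))
    pct, ci_pct = percent_change(mu, ci)
    return GLMMResult(stratum, mu, se, ci, p, len(table) - X.shape[1],
                      pct, ci_pct, len(table), sigma_re, method, term)


def stratified_report(
    table: pd.DataFrame,
    by: list[str] | None = None,
    contrast: str | None = None,
    **fit_kwargs,
) -> list[GLMMResult]:
    """Separate flicker-vs-baseline models per stratum of ``by`` columns.

    Empty or all-zero strata are skipped with a log entry.  When
    ``contrast`` names a binary 0/1 column, a combined model with a
    stimulation x contrast interaction is appended, testing whether the
    flicker effect differs between the two groups.
    """
    results: list[GLMMResult] = []
    if by:
        for key, sub in table.groupby(by, sort=True):
            label = key if isinstance(key, str) else "/".join(map(str, key))
            try:
                results.append(fit_poisson_glmm(sub, stratum=label, **fit_kwargs))
            except ValueError as exc:
                logger.info("skipping stratum %s: %s", label, exc)
    else:
        results.append(fit_poisson_glmm(table, stratum="overall", **fit_kwargs))

    if contrast is not None:
        sub = table.copy()
        sub["stim_x_contrast"] = sub["stimulation"] * sub[contrast]
        sub[f"{contrast}_main"] = sub[contrast].astype(float)
        res = fit_poisson_glmm(
            sub, stratum=f"interaction:{contrast}",
            extra_terms=[f"{contrast}_main", "stim_x_contrast"],
            term="stim_x_contrast",
        )
        results.append(res)
    return results


def report_table(results: list[GLMMResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])
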