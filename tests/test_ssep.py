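"""Steady-state quantification: multitaper PSD, fold-change, permutation
test, two-cycle averages, PLV, vector strength, persistence and the
proportion comparison."""

from itertools import combinations

import numpy as np
import pytest
from scipy import special, stats

import flickerlab as fl
from flickerlab.preprocess import TrialSet
from flickerlab.ssep import multitaper_psd_array, rayleigh_test

FS = 1024.0


def trialset_from_array(data, fs=FS, pre=0.0, post=0.0, cond="V-40Hz"):
    dur = data.shape[-1] / fs - pre - post
    return TrialSet(cond, data, fs, pre, post, dur, np.zeros(data.shape[0]))


def sinusoid_trials(n_trials, dur, f, fs=FS, amp=1.0, phases=None):
    t = np.arange(int(round(dur * fs))) / fs
    if phases is None:
        phases = np.zeros(n_trials)
    return np.stack(
        [amp * np.cos(2 * np.pi * f * t + ph) for ph in phases]
    )[:, None, :]


class TestMultitaperPSD:
    def test_peak_at_stimulus_frequency(self):
        ts = trialset_from_array(sinusoid_trials(3, 10.0, 40.0))
        psd = fl.multitaper_psd(ts)
        assert psd.freqs[np.argmax(psd.power.mean(0)[0])] == pytest.approx(
            40.0, abs=0.11
        )

    def test_white_noise_flat(self, rng):
        x = rng.standard_normal((100, 1, int(2 * FS)))
        psd = fl.multitaper_psd(trialset_from_array(x))
        mean = psd.power.mean(axis=0)[0]
        bins = [(lo, lo + 10.0) for lo in np.arange(2, 92, 10)]
        band_means = [
            mean[(psd.freqs >= lo) & (psd.freqs < hi)].mean() for lo, hi in bins
        ]
        assert max(band_means) / min(band_means) < 1.5

    def test_power_scales_with_amplitude_squared(self):
        a = fl.multitaper_psd(trialset_from_array(sinusoid_trials(1, 4.0, 40.0)))
        b = fl.multitaper_psd(
            trialset_from_array(sinusoid_trials(1, 4.0, 40.0, amp=2.0))
        )
        ratio = b.at(40.0) / a.at(40.0)
        assert ratio[0, 0] == pytest.approx(4.0, rel=0.01)

    def test_fmax_beyond_nyquist(self):
        ts = trialset_from_array(sinusoid_trials(1, 2.0, 40.0, fs=1024.0))
        with pytest.raises(ValueError):
            fl.multitaper_psd(ts, fmax=600.0)


class TestFoldChange:
    def test_arithmetic_identities(self, rng):
        base = np.abs(rng.standard_normal((10, 1, 100))) + 1.0
        ts_b = trialset_from_array(base, pre=0, post=0)
        psd_b = fl.PSDSet(np.full((10, 1, 3), 2.0), np.array([30.0, 40, 50]), FS)
        psd_eq = fl.PSDSet(np.full((10, 1, 3), 2.0), psd_b.freqs, FS)
        psd_2x = fl.PSDSet(np.full((10, 1, 3), 4.0), psd_b.freqs, FS)
        assert fl.fold_change(psd_eq, psd_b, 40.0)[0].fc == pytest.approx(0.0)
        assert fl.fold_change(psd_2x, psd_b, 40.0)[0].fc == pytest.approx(1.0)

    def test_injected_power_ratio_recovered(self):
        # stim/baseline power ratio 6.1 at 40 Hz -> FC ~ 5.1
        fcs = []
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            noise = rng.standard_normal((15, 1, int(10 * FS)))
            noise_b = rng.standard_normal((15, 1, int(10 * FS)))
            psd_n, freqs = multitaper_psd_array(noise[:, 0], FS)
            k = int(np.argmin(np.abs(freqs - 40.0)))
            s_bg = psd_n[:, k].mean()
            tone, _ = multitaper_psd_array(
                np.cos(2 * np.pi * 40.0 * np.arange(int(10 * FS)) / FS), FS
            )
            amp = np.sqrt(5.1 * s_bg / tone[k])
            stim = noise + sinusoid_trials(15, 10.0, 40.0, amp=amp)
            ps = fl.multitaper_psd(trialset_from_array(stim))
            pb = fl.multitaper_psd(trialset_from_array(noise_b))
            fcs.append(fl.fold_change(ps, pb, 40.0)[0].fc)
        assert np.median(fcs) == pytest.approx(5.1, rel=0.30)

    def test_scale_invariance(self, rng):
        x = rng.standard_normal((8, 1, int(2 * FS)))
        y = rng.standard_normal((8, 1, int(2 * FS)))
        f1 = fl.fold_change(
            fl.multitaper_psd(trialset_from_array(x)),
            fl.multitaper_psd(trialset_from_array(y)), 40.0)[0].fc
        f2 = fl.fold_change(
            fl.multitaper_psd(trialset_from_array(3.7 * x)),
            fl.multitaper_psd(trialset_from_array(3.7 * y)), 40.0)[0].fc
        assert f1 == pytest.approx(f2, rel=1e-9)


class TestPermutationTest:
    def test_identical_groups_p_one(self):
        assert fl.permutation_significance(np.ones(5), np.ones(5), 200, 0) == 1.0

    def test_matches_full_enumeration(self):
        a = np.array([5.0, 7.0, 9.0])
        b = np.array([1.0, 2.0, 3.0])
        pooled = np.concatenate([a, b])
        obs = a.mean() - b.mean()
        count = 0
        for ix in combinations(range(6), 3):
            g1 = pooled[list(ix)]
            g2 = pooled[[i for i in range(6) if i not in ix]]
            if g1.mean() - g2.mean() >= obs:
                count += 1
        oracle = count / 20
        assert fl.permutation_significance(a, b, 10_000, 1) == oracle

    def test_sampled_agrees_with_exact(self, rng):
        a = rng.standard_normal(12) + 0.8
        b = rng.standard_normal(12)
        p1 = fl.permutation_significance(a, b, 50_000, 3)
        p2 = fl.permutation_significance(a, b, 50_000, 4)
        assert p1 == pytest.approx(p2, abs=0.01)

    def test_label_exchange_symmetry(self, rng):
        a, b = rng.standard_normal(4), rng.standard_normal(4)
        p_ab = fl.permutation_significance(a, b, 1_000, 0)
        p_ba = fl.permutation_significance(b, a, 1_000, 0)
        assert 1.0 <= p_ab + p_ba <= 1.0 + 2.0 / 70 + 1e-12

    def test_n_iter_floor(self):
        with pytest.raises(ValueError):
            fl.permutation_significance(np.ones(3), np.ones(3), 50)


class TestSpecificity:
    def test_rule_arithmetic(self):
        assert fl.fc_specificity(2.0, 2.0, 2.0) == 0.0
        assert fl.fc_specificity(4.0, 0.0, 0.0) == 4.0
        assert fl.fc_specificity(3.0, 1.0, 2.0) == pytest.approx(1.5)

    def test_broadband_response_nonspecific(self):
        # equal injected FC at 30/40/50 Hz -> FC_diff ~ 0
        from flickerlab.synthetic import ChannelSpec, ResponseSpec, simulate_lfp
        from tests.conftest import compact_flicker_schedule

        sched = compact_flicker_schedule(n_trials=12, condition="V-random")
        for tr in sched.trials:
            if not tr.is_baseline:
                tr.pattern, tr.freq = "random", None
        spec = ChannelSpec("c", responses={"V-random": ResponseSpec(1.0, "broadband")})
        rec = simulate_lfp(sched, [spec], fs=FS, seed=21)
        ts = fl.segment_trials(rec, sched)
        ps = fl.multitaper_psd(ts["V-random"])
        pb = fl.multitaper_psd(ts["baseline"])
        fcs = {f: fl.fold_change(ps, pb, f)[0].fc for f in (30.0, 40.0, 50.0)}
        diff = fl.fc_specificity(fcs[40.0], fcs[30.0], fcs[50.0])
        assert abs(diff) < 0.5 and fcs[40.0] == pytest.approx(1.0, abs=0.5)


class TestTwoCycleAverage:
    def test_locked_sinusoid_amplitude_preserved(self):
        data = sinusoid_trials(4, 10.0, 40.0, fs=FS)
        ts = trialset_from_array(data, pre=0.0)
        mean, sem = fl.evoked_two_cycle_average(ts, 40.0)
        assert mean.size == int(round(2 * FS / 40.0))
        assert np.max(np.abs(mean)) == pytest.approx(1.0, rel=0.01)
        assert np.max(sem) < 0.05

    def test_noise_mean_clt_scaling(self, rng):
        rms = []
        counts = [8, 32, 128]
        for n in counts:
            x = rng.standard_normal((n, 1, int(2 * FS)))
            mean, _ = fl.evoked_two_cycle_average(
                trialset_from_array(x, cond="x"), 40.0
            )
            rms.append(np.sqrt(np.mean(mean**2)))
        slope = np.polyfit(np.log(counts), np.log(rms), 1)[0]
        assert slope == pytest.approx(-0.5, abs=0.15)

    def test_zero_input(self):
        ts = trialset_from_array(np.zeros((3, 1, int(2 * FS))))
        mean, sem = fl.evoked_two_cycle_average(ts, 40.0)
        assert np.allclose(mean, 0) and np.allclose(sem, 0)

    def test_invalid_frequency(self):
        ts = trialset_from_array(np.zeros((1, 1, 1024)))
        with pytest.raises(ValueError):
            fl.evoked_two_cycle_average(ts, -1.0)


class TestPLV:
    def test_perfect_locking(self):
        ts = trialset_from_array(sinusoid_trials(5, 2.0, 40.0,
                                                 phases=np.full(5, 1.1)))
        res = fl.phase_locking_value(ts, 40.0)
        assert res.plv == pytest.approx(1.0, abs=1e-6)
        assert res.rayleigh_p < 1e-6

    def test_phase_offset_invariance(self):
        r1 = fl.phase_locking_value(
            trialset_from_array(sinusoid_trials(5, 2.0, 40.0,
                                                phases=np.full(5, 0.3))), 40.0)
        r2 = fl.phase_locking_value(
            trialset_from_array(sinusoid_trials(5, 2.0, 40.0,
                                                phases=np.full(5, 2.1))), 40.0)
        assert r1.plv == pytest.approx(r2.plv, abs=1e-9)

    def test_random_phase_rayleigh_walk(self, rng):
        # E[PLV] for N uniform phases ~ sqrt(pi/4)/sqrt(N)
        n_trials = 40
        plvs = []
        for _ in range(100):
            phases = rng.uniform(0, 2 * np.pi, n_trials)
            data = sinusoid_trials(n_trials, 0.5, 40.0, phases=phases)
            plvs.append(fl.phase_locking_value(trialset_from_array(data),
                                               40.0).plv)
        expect = np.sqrt(np.pi / 4) / np.sqrt(n_trials)
        assert expect / 1.5 < np.mean(plvs) < expect * 1.5

    def test_window_longer_than_trial(self):
        ts = trialset_from_array(sinusoid_trials(2, 0.25, 40.0))
        with pytest.raises(ValueError):
            fl.phase_locking_value(ts, 40.0)


class TestClassification:
    @pytest.mark.parametrize(
        "fc,p,expected",
        [(1.6, 0.01, "high_mod"), (1.4, 0.01, "low_mod"), (9.0, 0.2, "non_mod")],
    )
    def test_thresholds(self, fc, p, expected):
        r = fl.FCResult("c", "x", 40.0, 1.0, 1.0, fc, p)
        assert fl.classify_modulation(r) == expected


class TestVectorStrength:
    def _sched(self):
        from tests.conftest import compact_flicker_schedule
        return compact_flicker_schedule(n_trials=1, trial_s=100.0)

    def test_identical_phase_unity(self):
        sched = self._sched()
        onset = sched.trials[0].onset
        spikes = onset + 0.005 + np.arange(100) * (2 / 40.0)
        r = fl.unit_vector_strength(spikes, sched, 40.0, "V-40Hz")
        assert r.vector_strength == pytest.approx(1.0, abs=1e-9)

    def test_uniform_phases_low_vs(self, rng):
        sched = self._sched()
        onset = sched.trials[0].onset
        spikes = onset + np.sort(rng.uniform(0, 50.0, 1000))
        r = fl.unit_vector_strength(spikes, sched, 40.0, "V-40Hz")
        assert r.vector_strength < 0.06
        assert r.passes_sparsity

    def test_von_mises_concentration(self, rng):
        # VS of von Mises(kappa=2) -> I1(2)/I0(2) ~ 0.698
        sched = self._sched()
        onset = sched.trials[0].onset
        theta = stats.vonmises(2.0).rvs(2000, random_state=17) % (2 * np.pi)
        period = 2 / 40.0
        cycle = rng.integers(0, int(50.0 / period), 2000)
        spikes = onset + cycle * period + theta / (2 * np.pi) * period
        r = fl.unit_vector_strength(np.sort(spikes), sched, 40.0, "V-40Hz")
        expect = special.i1(2.0) / special.i0(2.0)
        assert r.vector_strength == pytest.approx(expect, abs=0.05)

    def test_no_spikes_error(self):
        sched = self._sched()
        with pytest.raises(ValueError):
            fl.unit_vector_strength(np.array([0.01]), sched, 40.0, "V-40Hz")


class TestPersistence:
    def _trial(self, rng, osc_start, osc_stop, amp=5.0, f=40.0, dur=13.0):
        t = np.arange(int(dur * FS)) / FS
        x = 0.1 * rng.standard_normal(t.size)
        m = (t >= osc_start) & (t < osc_stop)
        x[m] += amp * np.cos(2 * np.pi * f * (t[m] - osc_start))
        return x

    def test_exact_span_not_persistent(self, rng):
        d = 0.2
        x = self._trial(rng, 1.0 + d, 11.0 + d)
        r = fl.persistence_detection(x, FS, 40.0, (1.0, 11.0))
        assert r["status"] == "not_persistent"
        assert r["delay"] == pytest.approx(d, abs=0.05)

    def test_two_extra_cycles_persistent(self, rng):
        d = 0.2
        x = self._trial(rng, 1.0 + d, 11.0 + d + 2 / 40.0)
        r = fl.persistence_detection(x, FS, 40.0, (1.0, 11.0))
        assert r["status"] == "persistent"

    def test_baseline_only_mostly_undetected(self):
        # narrowband noise occasionally exceeds 3x the median envelope for a
        # few cycles, so assert the false-detection rate, not a single trial
        statuses = []
        for seed in range(10):
            x = 0.1 * np.random.default_rng(seed).standard_normal(int(13 * FS))
            r = fl.persistence_detection(x, FS, 40.0, (1.0, 11.0))
            statuses.append(r["status"])
        assert statuses.count("undetected") >= 7


class TestCompareProportions:
    def test_three_groups_df(self):
        stat, df, p = fl.compare_proportions([10, 40, 20], [100, 100, 100])
        assert df == 2

    def test_equal_proportions_near_zero(self):
        stat, _, p = fl.compare_proportions([50, 50, 50], [500, 500, 500])
        assert stat == pytest.approx(0.0, abs=1e-9) and p > 0.99

    def test_two_by_two_hand_formula(self):
        a, b, c, d = 10, 90, 30, 70  # modulated/not per group
        n = a + b + c + d
        oracle = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d)
        )
        stat, df, p = fl.compare_proportions([10, 30], [100, 100])
        assert stat == pytest.approx(oracle, rel=1e-12)
        assert oracle == pytest.approx(12.5)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            fl.compare_proportions([1, 2], [10, 0])


def test_rayleigh_against_circular_toolbox(rng):
    # concentrated phases significant, uniform phases not
    z, p = rayleigh_test(np.full(50, 0.5))
    assert p < 1e-10
    z2, p2 = rayleigh_test(rng.uniform(0, 2 * np.pi, 2000))
    assert p2 > 0.01
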