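# Methods

## Scope and data model

`flickerlab` analyzes multichannel intracranial LFP recorded while a
subject receives rhythmic visual/auditory/audio-visual stimulation
("flicker"), plus per-channel interictal-discharge (IED) spike timestamps.
A `Recording` is a channels × samples array at a stated sampling rate
(> 600 Hz so the 2–300 Hz analysis band is representable; 1024 Hz is used
throughout the synthetic studies) with per-contact metadata (probe, contact
index deep→superficial, exclusion flag, anatomical group). A
`StimSchedule` is an ordered list of trials (condition, modality, pattern,
onset, duration, baseline flag). Amplitudes are arbitrary units: every
downstream statistic is scale-free (power ratios, ranks, phases, counts),
so no calibration to microvolts is attempted.

## Stimulation paradigms

Three schedules are generated, all pseudo-randomized so that no modality or
frequency repeats more than three times in a row (greedy sampling with
restart; regeneration from the same seed is identical):

- **Three-frequency paradigm** — 12 stimulation conditions (visual,
  audio-visual, auditory × 5.5/40/80 Hz periodic and random pattern) × 15
  ten-second trials, each followed by a ten-second baseline trial: 360
  trials, 180 of them baseline.
- **Single-pulse paradigm** — 200 single 12.5 ms pulses per modality plus
  200 occluded control pulses, inter-onset intervals uniform on
  [987.5, 1487.5] ms.
- **Frequency sweep** — 26 periodic frequencies spanning 5.5–80 Hz × 10
  trials, plus 10 random-pattern and 10 baseline trials, inter-trial
  interval uniform on [2, 2.5] s.

Periodic stimuli are 50% duty-cycle square waves (ON duration 0.5/f);
random-pattern stimuli are 12.5 ms pulses with gaps uniform on [0, 25] ms
(mean rate ≈ 40 Hz); auditory envelopes carry 1.6 ms linear ramps. The
7 kHz auditory carrier is omitted by default — it lies far above the
2–300 Hz analysis band and no statistic sees it.

## Preprocessing

Laplacian re-referencing subtracts from each contact the mean of its two
probe neighbours; end contacts are re-referenced bipolar against their
single neighbour. When a neighbour is excluded (noisy contact, outside
parenchyma — exclusion flags are inputs, not detected), the nearest
non-excluded contact on the same side substitutes. Probes with fewer than
two usable contacts are an error. Trials are segmented to
[onset − 1 s, offset + 1 s], demeaned over the full 12 s segment, and
band-passed 2–300 Hz with a zero-phase 4th-order Butterworth (the band is
prescribed; the order mirrors the single-pulse filter, the one place an
order is stated). Conditions with unequal trial counts (baseline especially)
are randomly downsampled to the common minimum, seed-reproducibly, before
any stimulation/baseline power comparison.

## Steady-state EP quantification

Per-trial PSDs over the 10 s stimulation window use multitaper estimation
with time–bandwidth product 3 and 5 DPSS tapers (half-bandwidth
3/duration = 0.3 Hz), built directly on `scipy.signal.windows.dpss` since
no multitaper package is part of the dependency stack. The response
measure is `FC_pow = mu_stim/mu_bl − 1` at the grid frequency nearest the
stimulation frequency. Significance is a one-sided permutation test of
trial-level power values (default 10,000 iterations): p is the fraction of
permuted mean-differences ≥ the observed one, with ties counted (a
float-noise tolerance keeps the identity assignment a tie), exhaustive
enumeration when the assignment count does not exceed the iteration budget,
and the add-one correction on the sampled path so p is never exactly 0.
Channels are classed `non_mod` (p ≥ 0.05), `low_mod` (significant,
FC ≤ 1.5) or `high_mod` (significant, FC > 1.5).

PLV uses non-overlapping windows of fs/2 samples: per window the
cross-spectrum phase between the LFP and a stimulus-locked sinusoid is
taken at the FFT bin nearest the stimulation frequency, phases are averaged
as unit phasors across windows and trials (circular mean — raw-angle
averaging is ill-defined at ±π), and the modulus is the PLV. Significance
is a Rayleigh test (pingouin) on the per-window phases; per-window rather
than per-trial phases were chosen as the sample unit (the alternative is a
one-line change). Spike modulation uses the formally identical vector
strength on spike phases relative to the two-cycle stimulus period, with a
sparsity flag when more than 20% of peristimulus histogram bins are empty.

Persistence of the oscillatory response beyond stimulus offset is detected
on a zero-phase band-pass at f ± 2 Hz: a burst is located where the Hilbert
envelope exceeds 3× the median pre-stimulus envelope for ≥ 3 cycles, then
its edges are refined as half-amplitude crossings. Because the filter is
symmetric, onset and offset smear equally and cancel in the criterion: with
onset delay d, the response is persistent iff the detected stop exceeds
stimulus end + d + one stimulus cycle.

## Single pulses and the superposition test

Single-pulse trials are re-referenced, high-passed at 0.1 Hz (4th-order
Butterworth, zero-phase), segmented to [−0.25, 1.25] s and baseline-
corrected by the 0.25 s pre-onset mean. Response amplitude is the absolute
maximum of the trial-averaged waveform on [0, 1] s; significance compares
RMS(mean stimulation waveform) against the occluded control via a 500-
iteration trial permutation. Note a property of this statistic: with
identical (non-constant) trial sets its permutation distribution is
symmetric rather than degenerate, so the null p sits near 0.5, not 1 —
the test is calibrated (type-I ≈ 5%) but "no difference" does not mean
p ≈ 1. For cross-metric comparison, amplitudes are mapped per
subject × modality linearly onto [0.001, 1] and log10-taken (range
[−3, 0]), flicker and single-pulse metrics separately, then compared with a
paired two-sided t-test.

The superposition null mechanism is simulated by drawing, for each 25 ms
slot of a 10 s trial, one recorded single-pulse response with replacement,
aligning its post-onset portion to the slot and summing (400 summands;
tails truncated at the trial end — wrap-around was the alternative and
makes no measurable difference at 10 s). Simulated baseline trials apply
the same summation to occluded pulse trials so the fold-change estimator is
identical on real and simulated data. Real and simulated fold-changes are
compared with a paired two-sided t-test over channels with significant real
modulation.

Two calibration properties of this comparison, found while validating it on
ground-truth cohorts, are worth knowing:

1. **Selection on significance biases the null.** Restricting to channels
   with significant *real* modulation conditions on the real-FC noise; on
   marginal channels this biases real > simulated even when both come from
   the same mechanism. The comparison is only exchangeable when inclusion
   is essentially deterministic, i.e. on clearly modulated channels — the
   regime the synthetic cohorts use (strong pulse kernels) and the regime
   the filtered comparison is meant for.
2. **Heteroscedastic cohorts break the t-test at small n.** Raw FC
   differences scale with each channel's FC, so a cohort with orders-of-
   magnitude FC spread is dominated by its largest channels and the paired
   t-test over-rejects. Synthetic cohorts therefore vary kernel shape,
   frequency and decay but normalize the kernels' 40 Hz spectral content,
   giving comparable per-channel FC; measured null level is then ≈ 5%
   (29/30 cohorts with p > 0.05).

## Baseline spectra, resonance and entrainment

Mean baseline PSDs are parameterized in log10-power as an aperiodic power
law (offset − χ·log10 f; no knee by default — the 2–100 Hz band rarely
needs one, and a knee can be added to the model trivially) plus up to five
Gaussian peaks extracted iteratively largest-first from the flattened
spectrum, stopping below a height of 0.6 log-units; peak bandwidths (2σ)
are bounded to [2, 10] Hz and the fit range is 2–100 Hz. After extraction,
peaks are refit jointly and the aperiodic component refit on the
peak-subtracted spectrum. Endogenous-oscillation amplitude is reported as
modeled power over the aperiodic fit at the peak center minus one (the same
−1 convention as FC_pow).

For the frequency sweep, each channel's profile records FC and PLV per
stimulation frequency, the top stimulation frequency (argmax FC among
significant frequencies, ties to the lowest), the count of significant
frequencies, and the distance to the nearest endogenous peak. The
entrainment test takes channels with at least one endogenous peak and
significant FC at more than 6 of the 26 frequencies ("more than 6" read
strictly as ≥ 7) and reports the fraction whose top frequency lies within
5 Hz of an endogenous peak plus a paired t-test of the two frequency lists.
Under entrainment the fraction approaches 1; under resonance the top
frequency is unrelated to the endogenous spectrum and the fraction matches
the geometric overlap of ±5 Hz bands with the tested range.

## IED rate modeling

Per-channel spikes merge into events anchored at the event's first spike:
every spike within 100 ms of that anchor joins (the chaining reading of the
rule — extend from the latest member — is available behind a flag). Events
spanning more than 11 distinct channels are flagged as noise and dropped;
each event is assigned to the first channel detecting its first spike, and
counts contribute only to that channel's group. Count tables hold one row
per stimulation trial × channel group and a time-matched baseline row: the
following 10 s baseline trial in the three-frequency paradigm, or the 5
nearest 2 s stimulation-OFF periods (baseline trials in 2 s pieces plus
inter-trial gaps ≥ 2 s) in the sweep paradigm — 10 s of exposure either
way, so no offset term is needed. Baseline rows inherit the stimulation
trial's start time, which enters the model as a linear fixed effect to
absorb slow drift in IED frequency.

The rate model is a Poisson GLMM with log link: fixed effects are the
stimulation indicator, scaled trial start time, and task when several are
pooled; random intercepts act at the subject:session level. The fitter is
an own maximum-likelihood implementation using adaptive Gauss–Hermite
quadrature (per-group Newton mode finding, 12 probabilists'-Hermite nodes,
BFGS over fixed effects and log random-effect SD, Wald standard errors from
the numerical Hessian): the installed Python stack offers only a Bayesian
variational Poisson mixed model, whose interval coverage proved too erratic
for calibration guarantees, while this fitter reproduces `lme4::glmer`
(nAGQ = 12) estimates and standard errors to ~1e-6 — a frozen glmer fixture
is kept as an independent oracle in the test suite. A single random-
intercept level was kept instead of nested subject + session intercepts:
with one session per subject the two coincide, and with several, session
intercepts still absorb the between-subject heterogeneity; the second
integral adds little identifiable structure at these sizes. With fewer
than two subjects the model falls back to a fixed-intercept Poisson
regression with a warning.

Effects are reported as percent change `mu% = 100·(e^mu − 1)` with Wald
CIs transformed monotonically. Strata (overall, modulation class, modality
× region, …) are fit separately; between-stratum contrasts (high-mod vs
non/low-mod) use a stimulation × stratum interaction in a combined model.
Empty or all-zero strata are skipped with a log entry. No multiple-
comparison correction is applied inside the module; Bonferroni notes belong
at the reporting level.

## Anatomical label assignment

An electrode contact is labeled from a voxel label volume by the weighted
search sphere: all voxel centers within 5 mm (in world mm, through the
volume affine), white-matter labels dropped, each voxel weighted 1/r
(weight 1 at r = 0), weights summed per label, argmax returned (ties to
the smallest label id), with an explicit no-label outcome when only white
matter is in reach. The enumerated 1/r procedure is implemented as stated
even though the construction is conventionally called a "Gaussian" search
sphere.

## Synthetic data: what it emulates, what it does not

Channel backgrounds are synthesized in the frequency domain with one-sided
PSD `10^(offset − χ log10 f + Σ Gaussian peaks)` and random phases, so the
aperiodic slope and endogenous peaks are exact by construction (log-log
slope of background-only channels recovers −χ within ±0.2). Periodic
responses are stimulus-locked sinusoids whose amplitude is calibrated
against the same multitaper estimator used downstream, so the injected
fold-change is recovered in expectation; a double-peak option adds a
2f harmonic for tests of harmonic content. Random-pattern responses are
synthesized as a band-limited (5–80 Hz) power increase proportional to the
channel background rather than a filtered pulse train: this makes the
injected FC equal at every in-band frequency, which is the ground truth the
specificity (FC_diff ≈ 0) test needs exactly. Single-pulse responses add a
per-channel kernel; IED streams are inhomogeneous Poisson (thinning
sampler) with multiplicative condition effects during stimulation trials
and an optional continuous rate drift. All draws descend from one session
seed through named substreams (schedule / noise / response / events /
volume), so each stage regenerates independently.

Deliberately not modeled: volume conduction between probes, eye movements,
photic-induced seizures, sensory adaptation or other nonlinearities (the
superposition module implements only the null mechanism), spike waveforms
(IED timestamps are the input contract), and real anatomical geometry (the
label volume is a labeled-spheres toy). Passing tests therefore show the
estimators are correct and calibrated on data satisfying their assumptions,
not that those assumptions hold in patient recordings.

## Numerical choices and problem sizes

Two-cycle segment starts are snapped per segment (phase error ≤ half a
sample); trial onsets floor to the sample grid (< 1 ms at ≥ 1024 Hz).
Simulation studies in the test suite and acceptance script use 1024 Hz
recordings (1280 Hz where the 25 ms slot must be an integer sample count),
15 trials per condition, cohorts of 12–24 channels, 5–50 seed replicates,
and mixed-model designs of 6–10 subjects × 60–240 trials — sizes chosen so
the whole suite runs in a few minutes on one CPU while leaving each
statistical check adequately powered.
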