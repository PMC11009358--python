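# flickerlab

Analysis of rhythmic audio-visual ("flicker") stimulation neurophysiology on
SEEG-like local field potential (LFP) recordings, with a ground-truth
synthetic-data generator for validating every stage.

Rhythmic sensory stimulation at a frequency *f* evokes a steady-state evoked
potential (steady-state EP): a narrow-band oscillation of the LFP at *f*.
`flickerlab` implements, end to end:

- **Steady-state EP quantification.** Per-trial multitaper power spectra
  (time–bandwidth 3, 5 tapers) and the normalized fold-change in power at
  the stimulation frequency,

  ```
  FC_pow = mu_stim / mu_bl - 1
  ```

  with one-sided trial-permutation significance (10,000 iterations,
  exhaustive enumeration when feasible), the specificity contrast
  `FC_diff = FC_40 - mean(FC_30, FC_50)`, two-cycle evoked averages,
  stimulus–LFP phase-locking values (PLV) with Rayleigh tests, and spike
  vector strength for single units.
- **Mechanism tests.** A linear-superposition simulator that builds
  simulated flicker trials by summing randomly drawn single-pulse evoked
  potentials every 25 ms (the null mechanism), paired real-vs-simulated
  comparisons, persistence detection of oscillations beyond stimulus
  offset, aperiodic (1/f) + Gaussian-peak spectral parameterization of
  baseline spectra, and the resonance-vs-entrainment comparison of each
  channel's best stimulation frequency against its endogenous oscillations.
- **Interictal epileptiform discharge (IED) rate analysis.** Merging of
  per-channel spikes into multichannel IED events (100 ms window, >11
  channels = noise), trial-level count tables with time-matched baselines,
  and a maximum-likelihood Poisson generalized linear mixed model (adaptive
  Gauss–Hermite quadrature, random intercepts per subject/session) whose
  flicker effect is reported as `mu% = 100*(e^mu - 1)`.
- **Support.** Laplacian/bipolar re-referencing with excluded-contact
  handling, trial segmentation and balancing, stimulus waveform and
  paradigm-schedule generation, weighted search-sphere anatomical label
  assignment, and a synthetic LFP/IED generator with controllable
  ground-truth fold-changes, spectral peaks, and event-rate effects.

## Worked example

Simulate a 15-trial 40 Hz visual flicker session with a channel whose true
fold-change is 5, and quantify it:

```python
import numpy as np
import flickerlab as fl
from flickerlab.synthetic import ChannelSpec, ResponseSpec, StimSchedule, Trial

trials, t = [], 1.0
for _ in range(15):
    trials.append(Trial("V-40Hz", "visual", "periodic", 40.0, t, 10.0))
    trials.append(Trial("baseline", "none", "none", None, t + 10.5, 10.0,
                        is_baseline=True))
    t += 21.0
sched = StimSchedule(trials, "custom", seed=0)

spec = ChannelSpec("hpc-3", peaks=[(10.0, 1.0, 3.0)],
                   responses={"V-40Hz": ResponseSpec(fold_change=5.0)})
rec = fl.simulate_lfp(sched, [spec], fs=1024.0, seed=11)

ts = fl.balance_trials(fl.segment_trials(rec, sched), seed=1)
psd_stim = fl.multitaper_psd(ts["V-40Hz"])
psd_bl = fl.multitaper_psd(ts["baseline"])
r = fl.fold_change(psd_stim, psd_bl, 40.0, n_iter=10_000, seed=2)[0]
print(f"FC_pow = {r.fc:.2f}  p = {r.p_perm:.4f}  "
      f"class = {fl.classify_modulation(r)}")
```

This prints

```
FC_pow = 4.84  p = 0.0001  class = high_mod
```

a fold-change of 4.84 at 40 Hz (true value 5, recovered within estimator
noise), significant under the trial permutation test, and classified as
strongly modulated (significant and FC > 1.5 — the stratum in which flicker
suppresses IED rates most).

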