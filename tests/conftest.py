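import numpy as np
import pytest

from flickerlab.synthetic import ChannelSpec, ResponseSpec, StimSchedule, Trial


def compact_flicker_schedule(
    n_trials: int = 15,
    freq: float = 40.0,
    condition: str = "V-40Hz",
    trial_s: float = 10.0,
    gap_s: float = 0.5,
) -> StimSchedule:
    """Alternating stimulation/baseline schedule for fast simulations."""
    trials, t = [], 1.0
    for _ in range(n_trials):
        trials.append(Trial(condition, "visual", "periodic", freq, t, trial_s))
        t += trial_s + gap_s
        trials.append(
            Trial("baseline", "none", "none", None, t, trial_s, is_baseline=True)
        )
        t += trial_s + gap_s
    return StimSchedule(trials, "custom", 0)


def responsive_channel(fc: float, cid: str = "ch0", **kw) -> ChannelSpec:
    return ChannelSpec(
        cid, responses={"V-40Hz": ResponseSpec(fc)}, **kw
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def small_schedule():
    return compact_flicker_schedule(n_trials=8)
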