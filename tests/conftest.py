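import numpy as np
import pytest

from connectogrip.grip import DigitForceTrial


def make_target_trial(
    fs=500.0,
    duration=5.5,
    cue_grip=1.0,
    cue_rest=3.0,
    reaction=0.3,
    relaxation=0.35,
    hold=4.0,
    theta_deg=0.0,
    noise_sd=0.0,
    rise=0.15,
    fall=0.02,
    hand="paretic",
    seed=0,
):
    """Piecewise-linear synthetic target-grip trial with known latencies."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    t_on = cue_grip + reaction
    t_fall = cue_rest + relaxation - fall
    env = np.interp(t, [t_on, t_on + rise, t_fall, t_fall + fall], [0.0, hold, hold, 0.0])
    env[t < t_on] = 0.0
    env[t > t_fall + fall] = 0.0
    plateau = (t >= t_on + rise) & (t <= t_fall)
    tan = np.tan(np.radians(theta_deg))
    forces = {}
    for digit in ("thumb", "index"):
        fn = env + (rng.normal(0, noise_sd, n) if noise_sd > 0 else 0.0)
        shear = np.where(plateau, fn * tan, 0.0)
        forces[digit] = np.column_stack([fn, shear, np.zeros(n)])
    return DigitForceTrial(
        sampling_rate=fs,
        time=t,
        forces=forces,
        cue_grip=cue_grip,
        cue_rest=cue_rest,
        trial_kind="target_grip",
        hand=hand,
    )


@pytest.fixture
def target_trial():
    return make_target_trial()
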