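import numpy as np
import pytest

from miniscape import synth


@pytest.fixture(scope="session")
def short_params():
    """A 10-minute, 30-neuron session used by several suites."""
    return synth.SynthParams(seed=101, duration_s=600.0, n_neurons=30,
                             frac_responsive=0.3, gain_pos=4.0)


@pytest.fixture(scope="session")
def free_movement_session():
    """Kinematics + traces + ground truth for one synthetic free-movement session."""
    p = synth.SynthParams(seed=202, duration_s=600.0, n_neurons=20,
                          frac_responsive=0.4, gain_pos=4.0, base_rate_hz=0.1)
    rec, bouts = p_rec = synth.generate_kinematics(p)
    gt = synth.draw_recruitment(p, event_type="movement_onset")
    gt.bouts = bouts
    traces, gt = synth.generate_traces(p, bouts[:, 0], gt,
                                       event_type="movement_onset")
    return {"params": p, "accel": rec, "bouts": bouts, "traces": traces, "gt": gt}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
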