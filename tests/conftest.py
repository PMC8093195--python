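import numpy as np
import pytest

from ephyskit.io import SweepSet
from ephyskit.protocols import make_current_steps
from ephyskit.sim import ModelParams, simulate

FS = 10_000.0


@pytest.fixture(scope="session")
def fs():
    return FS


def simulate_step_family(params: ModelParams, fs: float = FS,
                         start: float = -400.0, stop: float = 400.0,
                         increment: float = 50.0) -> SweepSet:
    """Current-clamp step family (600 ms) for one simulated cell."""
    cmds = make_current_steps(start, stop, increment, fs=fs, cell_id="cell")
    sweeps, amps = [], []
    for cmd, amp in zip(cmds.sweeps, cmds.amplitudes):
        res = simulate(params, cmd.current, fs, cell_id="cell",
                       stim_onset=cmd.stim_onset, stim_offset=cmd.stim_offset,
                       seed=params.seed + int(amp))
        sweeps.append(res.sweep)
        amps.append(amp)
    return SweepSet(sweeps, amps)


@pytest.fixture(scope="session")
def l5_step_family():
    """Step family of an L5-like cell with prominent Ih (shared across tests)."""
    return simulate_step_family(ModelParams(gh=5.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
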