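import numpy as np
import pytest

from cereb import synthdata


@pytest.fixture(scope="session")
def noisy_trace():
    """Standard TTX->GBZ trace: 8 + 6 pA shifts, 2-Hz sIPSCs, 2-pA noise."""
    rng = np.random.default_rng(11)
    times = np.sort(rng.uniform(1.0, 139.0, 280))
    times = times[np.diff(times, prepend=-1.0) > 2e-2]
    truth = synthdata.TraceGroundTruth(
        component_shifts={"base->TTX": 8.0, "TTX->GBZ": 6.0},
        ipsc_times=times,
        ipsc_amplitudes=np.full(len(times), 30.0),
        noise_sd=2.0,
    )
    trace, truth = synthdata.gen_tonic_trace(("TTX", "GBZ"), truth, seed=11)
    return trace, truth


@pytest.fixture(scope="session")
def walking_skeleton():
    """Two minutes of mixed-turning antiphase walking."""
    truth = synthdata.GaitGroundTruth(
        lr_phase_mix=0.0, turning_profile=(20.0, -20.0, 0.0, 40.0)
    )
    skel, truth = synthdata.gen_skeleton(truth, duration=120.0, seed=7)
    return skel, truth
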