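import numpy as np
import pytest

import whiskephys as wp


@pytest.fixture(scope="session")
def config():
    return wp.AnalysisConfig()


@pytest.fixture(scope="session")
def single_bout():
    """10 s sweep, one noiseless 10 Hz bout at 2-6 s (amp 10, mid 15)."""
    params = wp.WhiskGenParams(
        sweep_duration=10.0, bout_schedule=[(2.0, 6.0, 10.0, 10.0, 15.0)],
        quiet_noise_sd=0.0, baseline_deg=5.0, seed=0)
    return wp.generate_whisker_trace(params)


@pytest.fixture(scope="session")
def rich_session():
    """40 s sweep with three bouts and mild quiet jitter, plus pipeline outputs."""
    params = wp.WhiskGenParams(
        sweep_duration=40.0,
        bout_schedule=[(5.0, 10.0, 8.0, 12.0, 15.0), (15.0, 21.0, 12.0, 8.0, 12.0),
                       (26.0, 32.0, 10.0, 10.0, 14.0)],
        quiet_noise_sd=0.1, baseline_deg=5.0, seed=1)
    synth = wp.generate_whisker_trace(params)
    return {
        "params": params,
        "synth": synth,
        "decomp": wp.decompose(synth.trace),
        "epochs": wp.segment_epochs(synth.trace),
        "truth_decomp": wp.truth_decomposition(synth),
        "truth_epochs": wp.truth_epochs(params),
    }


@pytest.fixture(scope="session")
def whisking300():
    """300 s of realistic whisking kinematics shared by tuning tests.

    25 bouts with varying frequency and amplitude; decomposition and
    epochs come from the analysis pipeline itself, as they would for real
    recordings.
    """
    sched = []
    for k in range(25):
        s = 12.0 * k + 2.0
        sched.append((s, s + 7.0, [8, 10, 12, 15, 9][k % 5],
                      [8, 12, 10, 15, 6][k % 5], 15.0))
    params = wp.WhiskGenParams(sweep_duration=300.0, bout_schedule=sched,
                               quiet_noise_sd=0.3, baseline_deg=5.0, seed=7)
    synth = wp.generate_whisker_trace(params)
    decomp = wp.decompose(synth.trace)
    epochs = wp.segment_epochs(synth.trace)
    mask = epochs.sample_mask("whisking", decomp.phase.size, params.sample_rate)
    return {"params": params, "synth": synth, "decomp": decomp, "epochs": epochs,
            "whisk_mask": mask, "truth_decomp": wp.truth_decomposition(synth),
            "truth_epochs": wp.truth_epochs(params)}


@pytest.fixture(scope="session")
def continuous_whisk300():
    """300 s of continuous 10 Hz whisking, for phase-tuning power checks."""
    params = wp.WhiskGenParams(sweep_duration=300.0,
                               bout_schedule=[(0.5, 299.5, 10.0, 10.0, 15.0)],
                               quiet_noise_sd=0.0, seed=3)
    synth = wp.generate_whisker_trace(params)
    decomp = wp.truth_decomposition(synth)
    epochs = wp.truth_epochs(params)
    mask = epochs.sample_mask("whisking", decomp.phase.size, params.sample_rate)
    return {"params": params, "synth": synth, "decomp": decomp, "epochs": epochs,
            "whisk_mask": mask}
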