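import dataclasses

import numpy as np
import pytest

import mitoscreen as ms


@pytest.fixture(scope="session")
def lps_params():
    return ms.make_default_parameters("lps", "microglia")


@pytest.fixture(scope="session")
def lps_params_noise_free(lps_params):
    return dataclasses.replace(lps_params, noise_sd=0.0)


@pytest.fixture(scope="session")
def canonical_pct(lps_params_noise_free):
    """Noise-free canonical whole-cell percent-change trace (1 s sampling)."""
    tr = ms.simulate_trace(lps_params_noise_free)
    return ms.percent_change(tr)


@pytest.fixture(scope="session")
def canonical_segmentation(canonical_pct):
    return ms.detect_states(canonical_pct)


@pytest.fixture(scope="session")
def small_scene():
    """Desk-scale rendered scene: 5 min baseline + 5 min post-treatment."""
    return ms.SceneConfig(seed=0, duration=600.0, treatment_time=300.0)


@pytest.fixture(scope="session")
def rendered(small_scene):
    params = [ms.make_default_parameters("lps", "microglia")] * small_scene.n_microglia + [
        ms.make_default_parameters("lps", "neuron")
    ] * small_scene.n_neurons
    return ms.render_stack(small_scene, params)


def make_ramp_trace(
    onsets, durations, amplitudes, duration=2100.0, treatment_time=300.0, dt=1.0
):
    """Noise-free piecewise-linear percent-change trace built independently of
    the simulator (explicit per-sample loop over ramp segments)."""
    n = int(round(duration / dt))
    t = np.arange(n) * dt - treatment_time
    pct = np.zeros(n)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        for i, ti in enumerate(t):
            if ti >= onset + dur:
                pct[i] += amp
            elif ti > onset:
                pct[i] += amp * (ti - onset) / dur
    return ms.PercentChangeTrace(
        time=t, pct=pct, baseline_window=(-300.0, 0.0), baseline_mean=100.0
    )
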