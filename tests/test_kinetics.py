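import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mitoscreen as ms
from mitoscreen.kinetics import DetectorConfig, rate_of_change, state_metrics

from conftest import make_ramp_trace


class TestPercentChange:
    def test_constant_trace_zero(self):
        tr = ms.FluorescenceTrace(
            time=np.arange(-300, 900, 1.0), intensity=np.full(1200, 80.0)
        )
        pct = ms.percent_change(tr)
        assert np.all(pct.pct == 0)
        assert pct.baseline_mean == 80.0

    def test_doubling_is_100_percent(self):
        t = np.arange(-300, 900, 1.0)
        y = np.where(t < 0, 100.0, 200.0)
        pct = ms.percent_change(ms.FluorescenceTrace(time=t, intensity=y))
        assert pct.value_at(500.0) == pytest.approx(100.0)

    def test_baseline_mean_is_zero_mean_window(self, canonical_pct):
        sel = (canonical_pct.time >= -300) & (canonical_pct.time < 0)
        assert canonical_pct.pct[sel].mean() == pytest.approx(0.0, abs=1e-9)

    @given(scale=st.floats(min_value=0.1, max_value=1000))
    @settings(max_examples=25, deadline=None)
    def test_invariant_to_intensity_rescaling(self, scale):
        rng = np.random.default_rng(42)
        t = np.arange(-300, 900, 2.0)
        y = 100 + 20 * rng.random(t.size)
        a = ms.percent_change(ms.FluorescenceTrace(time=t, intensity=y))
        b = ms.percent_change(ms.FluorescenceTrace(time=t, intensity=scale * y))
        assert np.allclose(a.pct, b.pct, atol=1e-8)

    def test_errors(self):
        t = np.arange(-300, 900, 1.0)
        with pytest.raises(ValueError, match="baseline mean"):
            ms.percent_change(
                ms.FluorescenceTrace(time=t, intensity=np.zeros(t.size))
            )
        with pytest.raises(ValueError, match="samples"):
            ms.percent_change(
                ms.FluorescenceTrace(time=t, intensity=np.ones(t.size)),
                baseline_window=(-900.0, -800.0),
            )


class TestRateOfChange:
    def test_linear_ramp_exact_rate(self):
        """A 60%-in-60 s linear segment has rate exactly 1 %/s inside it."""
        pct = make_ramp_trace([300.0], [60.0], [60.0], duration=1200.0)
        rate = rate_of_change(pct)
        sel = (pct.time > 320) & (pct.time < 340)  # interior, clear of edges
        assert np.allclose(rate[sel], 1.0, atol=1e-9)

    def test_flat_trace_zero_rate(self):
        pct = make_ramp_trace([], [], [], duration=900.0)
        assert np.allclose(rate_of_change(pct), 0.0)

    def test_canonical_s1_interior_rate(self, canonical_pct):
        """S1 ramps 120% over 121.2 s -> interior rate = 0.990 %/s."""
        rate = rate_of_change(canonical_pct)
        sel = (canonical_pct.time > 400) & (canonical_pct.time < 450)
        assert np.allclose(rate[sel], 120.0 / 121.2, atol=1e-6)

    def test_too_short_trace_raises(self):
        t = np.arange(0, 20, 1.0)
        pct = ms.PercentChangeTrace(t, np.zeros(t.size), (-5, 0), 100.0)
        with pytest.raises(ValueError, match="smoothing window"):
            rate_of_change(pct, smooth_window=30.0)


class TestSlopeAngle:
    def test_one_percent_per_minute_is_45_degrees(self):
        t = np.arange(0, 600, 1.0)
        pct = ms.PercentChangeTrace(t, t / 60.0, (0, 1), 100.0)
        assert ms.slope_angle(pct, (0, 599)) == pytest.approx(45.0, abs=1e-9)

    def test_flat_segment_zero_degrees(self):
        t = np.arange(0, 600, 1.0)
        pct = ms.PercentChangeTrace(t, np.full(t.size, 5.0), (0, 1), 100.0)
        assert ms.slope_angle(pct, (100, 200)) == pytest.approx(0.0)

    def test_canonical_s1_steeper_than_s3(self, canonical_pct, lps_params_noise_free):
        p = lps_params_noise_free
        windows = [
            (p.state_onsets[i], p.state_onsets[i] + p.state_durations[i])
            for i in range(3)
        ]
        angles = [ms.slope_angle(canonical_pct, w) for w in windows]
        assert angles[0] > angles[1] > angles[2]

    def test_errors(self, canonical_pct):
        with pytest.raises(ValueError):
            ms.slope_angle(canonical_pct, (5000.0, 6000.0))


class TestDetectStates:
    def test_flat_trace_no_states(self):
        pct = make_ramp_trace([], [], [])
        assert ms.detect_states(pct).n_states == 0

    def test_single_ramp_recovered(self):
        pct = make_ramp_trace([400.0], [100.0], [80.0])
        seg = ms.detect_states(pct)
        assert seg.n_states == 1
        assert seg.states[0].onset == pytest.approx(400.0, abs=30.0)
        assert seg.states[0].duration == pytest.approx(100.0, abs=30.0)

    def test_canonical_three_states(self, canonical_segmentation):
        """Noise-free canonical trace yields the three reported states."""
        seg = canonical_segmentation
        assert seg.n_states == 3
        assert np.allclose(seg.onsets(), [363.6, 843.6, 1410.0], atol=30.0)
        assert np.allclose(seg.durations(), [121.2, 124.2, 180.0], atol=30.0)

    def test_detector_brute_force_grid(self):
        """Detector matches construction over a grid of noise-free
        piecewise-linear traces satisfying the config minima."""
        grid = itertools.product(
            [120.0, 420.0],          # first onset
            [80.0, 150.0],           # durations
            [0.5, 1.2],              # ramp rates (%/s), all above threshold
            [2, 3],                  # number of states
        )
        for onset0, dur, rate, k in grid:
            onsets = [onset0 + i * (dur + 120.0) for i in range(k)]
            durations = [dur] * k
            amplitudes = [rate * dur] * k
            pct = make_ramp_trace(onsets, durations, amplitudes)
            seg = ms.detect_states(pct)
            assert seg.n_states == k, (onset0, dur, rate, k)
            assert np.allclose(seg.onsets(), onsets, atol=30.0)
            assert np.allclose(seg.durations(), durations, atol=30.0)

    def test_subthreshold_rise_ignored(self):
        # 20% over 400 s = 0.05 %/s, far below the 0.25 %/s threshold
        pct = make_ramp_trace([300.0], [400.0], [20.0])
        assert ms.detect_states(pct).n_states == 0

    def test_max_states_keeps_largest_gains(self):
        onsets = [100.0, 400.0, 700.0, 1000.0]
        amps = [40.0, 90.0, 100.0, 80.0]
        pct = make_ramp_trace(onsets, [80.0] * 4, amps)
        seg = ms.detect_states(pct, DetectorConfig(max_states=3))
        assert seg.n_states == 3
        # smallest-gain state (the first) dropped; order preserved
        assert np.allclose(seg.onsets(), onsets[1:], atol=30.0)

    def test_noisy_parameter_recovery(self, lps_params):
        """Across 10 seeded noisy traces (noise 2% of baseline), mean onsets
        recover the generative values within 30 s."""
        onsets, n_three = [], 0
        for seed in range(1, 11):
            tr = ms.simulate_trace(lps_params, seed=seed)
            seg = ms.detect_states(ms.percent_change(tr))
            if seg.n_states == 3:
                n_three += 1
                onsets.append(seg.onsets())
        assert n_three >= 9
        mean_onsets = np.mean(onsets, axis=0)
        assert np.all(np.abs(mean_onsets - np.array([363.6, 843.6, 1410.0])) <= 30.0)

    def test_short_trace_rejected(self):
        pct = make_ramp_trace([100.0], [60.0], [40.0], duration=700.0)
        with pytest.raises(ValueError, match="600 s"):
            ms.detect_states(pct)

    def test_state_gains_bounded_by_total(self, canonical_segmentation, canonical_pct):
        total = canonical_pct.value_at(1800.0)
        gains = sum(s.pct_change for s in canonical_segmentation.states)
        assert gains <= total + 1e-6


@pytest.fixture(scope="module")
def cohort_metrics(lps_params_noise_free, canonical_segmentation):
    by_comp = {
        c: ms.percent_change(ms.simulate_trace(lps_params_noise_free, compartment=c))
        for c in ms.COMPARTMENTS
    }
    return state_metrics(by_comp, canonical_segmentation)


class TestStateMetricsAndSummary:
    def test_subcellular_pattern(self, cohort_metrics):
        """Largest soma gain in S1, largest endfoot gain in S3, steepest
        branch slope in S2 (within whole-cell state windows)."""
        m = cohort_metrics
        soma = m[m.compartment == "soma"].set_index("state")["pct_change"]
        endfeet = m[m.compartment == "endfeet"].set_index("state")["pct_change"]
        branch = m[m.compartment == "branches"].set_index("state")["max_slope_angle"]
        assert soma.idxmax() == 1
        assert endfeet.idxmax() == 3
        assert branch.idxmax() == 2

    def test_identical_cells_zero_sem(self, cohort_metrics):
        reps = []
        for i in range(10):
            df = cohort_metrics.copy()
            df["roi_id"] = f"cell_{i}"
            reps.append(df)
        summary = ms.summarize_states(pd.concat(reps, ignore_index=True))
        assert np.allclose(summary["sem"], 0.0)
        assert np.all(summary["n"] == 10)

    def test_missing_states_absent_not_zero(self, cohort_metrics):
        partial = cohort_metrics[cohort_metrics.state < 3].copy()
        partial["roi_id"] = "partial"
        full = cohort_metrics.copy()
        full["roi_id"] = "full"
        summary = ms.summarize_states(pd.concat([partial, full], ignore_index=True))
        s3 = summary[(summary.state == 3) & (summary.metric == "pct_change")]
        assert np.all(s3["n"] == 1)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            ms.summarize_states(pd.DataFrame())
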