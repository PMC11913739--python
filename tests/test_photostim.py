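import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from penumbra.photostim import (
    decay_constant,
    extract_target_traces,
    prestim_level,
    response_cv,
    response_magnitude,
    response_matrix,
    select_nontargets,
    widefield_response,
    zscore_to_baseline,
)
from penumbra.traces import RoiTable


class TestResponseMagnitude:
    def test_flat_trace_zero(self):
        t = np.arange(100) / 10.0
        assert response_magnitude(np.full(100, 2.0), t, 3.0, 3.3) == pytest.approx(0.0)

    def test_zero_pre_one_post(self):
        t = np.arange(100) / 10.0
        f = np.where(t > 3.3, 1.0, 0.0)
        assert response_magnitude(f, t, 3.0, 3.3) == pytest.approx(1.0)

    def test_hand_arithmetic_symmetric_windows(self):
        # pre [1,2,3,4,5] and post [5,4,3,2,1] -> equal means, response 0
        t = np.arange(12) / 10.0
        f = np.array([0, 0, 1, 2, 3, 4, 5, 5, 4, 3, 2, 1], dtype=float)
        # pre window [0.15, 0.65) covers frames 2-6, post (0.65, 1.15] frames 7-11
        out = response_magnitude(f, t, 0.65, 0.65, pre=0.5, post=0.5)
        assert out == pytest.approx(0.0, abs=1e-15)

    def test_window_conventions(self):
        # onset frame belongs to neither window; offset frame excluded, offset+post included
        t = np.arange(10) / 10.0
        f = np.arange(10, dtype=float)
        out = response_magnitude(f, t, 0.3, 0.5, pre=0.2, post=0.2)
        assert out == pytest.approx(np.mean([6, 7]) - np.mean([1, 2]))

    def test_excluded_frames_dropped(self):
        t = np.arange(10) / 10.0
        f = np.arange(10, dtype=float)
        ex = np.zeros(10, bool)
        ex[6] = True
        out = response_magnitude(f, t, 0.3, 0.5, pre=0.2, post=0.2, excluded=ex)
        assert out == pytest.approx(7 - np.mean([1, 2]))

    def test_empty_window_nan(self):
        t = np.arange(10) / 10.0
        ex = np.ones(10, bool)
        assert np.isnan(response_magnitude(np.ones(10), t, 0.3, 0.5, excluded=ex))

    @given(st.floats(min_value=-10, max_value=10))
    def test_shift_invariance(self, c):
        t = np.arange(100) / 10.0
        f = np.sin(t)
        a = response_magnitude(f, t, 3.0, 3.3)
        b = response_magnitude(f + c, t, 3.0, 3.3)
        assert a == pytest.approx(b, abs=1e-9)


class TestDecayConstant:
    def test_hand_enumeration(self):
        # post samples [1.0, 0.8, 0.7, 0.5] at 10 Hz -> first strictly below
        # 0.63 is the 4th sample, 0.3 s after stimulation end
        t = np.arange(4) / 10.0
        f = np.array([1.0, 0.8, 0.7, 0.5])
        assert decay_constant(f, t, stim_end=0.0) == pytest.approx(0.3)

    def test_exponential_closed_form(self):
        fr = 100.0
        t = np.arange(0, 10 * fr) / fr
        f = 2.0 * np.exp(-t / 1.0)
        out = decay_constant(f, t, stim_end=0.0)
        assert out == pytest.approx(-np.log(0.63), abs=1.0 / fr)

    def test_never_crossing_nan(self):
        t = np.arange(50) / 10.0
        assert np.isnan(decay_constant(np.ones(50), t, stim_end=0.0))

    def test_monotone_increasing_nan(self):
        # the signal never *decreases* below threshold
        t = np.arange(50) / 10.0
        assert np.isnan(decay_constant(np.arange(50.0), t, stim_end=0.0))

    def test_horizon_limits_segment(self):
        t = np.arange(50) / 10.0
        f = np.ones(50)
        f[-1] = 0.0  # only crossing is outside the horizon
        assert np.isnan(decay_constant(f, t, stim_end=0.0, horizon=2.0))


class TestZscore:
    def test_baseline_mean_maps_to_zero(self):
        assert zscore_to_baseline(2.0, [1.0, 2.0, 3.0]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert zscore_to_baseline(3.0, [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_self_normalization(self):
        base = np.array([0.3, 1.1, -0.4, 2.0, 0.7])
        z = zscore_to_baseline(base, base)
        assert np.mean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.std(z, ddof=1) == pytest.approx(1.0)

    def test_too_few_baseline_nan(self):
        assert np.isnan(zscore_to_baseline(1.0, [2.0]))

    def test_zero_sd_nan(self):
        assert np.isnan(zscore_to_baseline(1.0, [2.0, 2.0, 2.0]))


class TestResponseCv:
    def test_identical_responses_zero(self):
        assert response_cv([2.0, 2.0, 2.0]) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        assert response_cv([1.0, 3.0]) == pytest.approx(np.sqrt(2.0) / 2.0)

    def test_scale_invariance(self):
        r = np.array([1.0, 2.0, 4.0])
        assert response_cv(3.7 * r) == pytest.approx(response_cv(r))

    def test_degenerate_nan(self):
        assert np.isnan(response_cv([5.0]))
        assert np.isnan(response_cv([-1.0, 1.0]))


class TestSelectNontargets:
    def _rois(self):
        rows = [
            (0, 100.0, 100.0, True, False),
            (1, 115.0, 100.0, False, False),  # 15 um
            (2, 120.0, 100.0, False, False),  # exactly 20 um
            (3, 125.0, 100.0, False, False),  # 25 um
        ]
        return RoiTable(pd.DataFrame(rows, columns=["roi_id", "x", "y", "is_target", "is_inhibitory"]))

    def test_exclusion_rules(self):
        out = select_nontargets(self._rois(), [(100.0, 100.0)])
        assert out["roi_id"].tolist() == [3]

    def test_targets_never_returned(self):
        out = select_nontargets(self._rois(), [(400.0, 400.0)])
        assert 0 not in out["roi_id"].tolist()


class TestPrestimLevel:
    def test_flat(self):
        t = np.arange(100) / 10.0
        assert prestim_level(np.full(100, 4.0), t, 5.0) == pytest.approx(4.0)

    def test_ramp_midpoint(self):
        fr = 1000.0
        t = np.arange(10 * fr) / fr
        f = np.clip((t - 4.5) / 0.5, 0.0, 1.0)  # 0 -> 1 over the pre-window
        # half-open window [4.5, 5.0) misses the ramp's endpoint sample
        assert prestim_level(f, t, 5.0) == pytest.approx(0.5, abs=2e-3)

    def test_neuropil_variant_window(self):
        t = np.arange(100) / 10.0
        f = np.where(t >= 4.75, 1.0, 0.0)
        assert prestim_level(f, t, 5.0, window=0.25) == pytest.approx(1.0)

    def test_fully_excluded_nan(self):
        t = np.arange(100) / 10.0
        assert np.isnan(prestim_level(np.ones(100), t, 5.0, excluded=np.ones(100, bool)))


class TestWidefieldResponse:
    def test_flat_zero(self):
        t = np.arange(100) / 10.0
        assert widefield_response(np.full(100, 1.0), t, 3.0, 3.4) == pytest.approx(0.0)

    def test_hand_arithmetic(self):
        t = np.arange(100) / 10.0
        f = np.where(t > 3.4, 5.0, 3.0)
        assert widefield_response(f, t, 3.0, 3.4) == pytest.approx(2.0)

    def test_shutter_order_enforced(self):
        t = np.arange(100) / 10.0
        with pytest.raises(ValueError):
            widefield_response(np.ones(100), t, 3.4, 3.0)


class TestResponseMatrix:
    def test_matches_scalar_op(self, rng):
        t = np.arange(600) / 10.0
        f = rng.normal(size=(7, 600))
        trials = pd.DataFrame({"trial_id": [0, 1], "onset": [10.0, 30.0], "offset": [10.25, 30.25]})
        ex = np.zeros(600, bool)
        ex[100:104] = True
        out = response_matrix(f, t, trials, excluded=ex)
        for i, (on, off) in enumerate(zip(trials["onset"], trials["offset"])):
            for j in range(7):
                assert out[i, j] == pytest.approx(
                    response_magnitude(f[j], t, on, off, excluded=ex), abs=1e-12
                )

    def test_empty_window_gives_nan_row(self):
        t = np.arange(600) / 10.0
        trials = pd.DataFrame({"trial_id": [0], "onset": [10.0], "offset": [10.25]})
        ex = np.zeros(600, bool)
        ex[95:100] = True  # entire pre window
        out = response_matrix(np.ones((2, 600)), t, trials, excluded=ex)
        assert np.isnan(out).all()


class TestExtractTargetTraces:
    def test_uniform_stack(self):
        stack = np.full((5, 32, 32), 7.0)
        ts = extract_target_traces(stack, [(64.0, 64.0)], px_size=4.0, frame_rate=10.0)
        assert np.allclose(ts.fluorescence, 7.0)
        assert ts.frame_rate == 10.0

    def test_disjoint_targets_independent(self):
        stack = np.zeros((3, 32, 32))
        stack[:, :, :16] = 2.0  # left half bright (x < 64 um at 4 um pixels)
        ts = extract_target_traces(stack, [(30.0, 64.0), (100.0, 64.0)], px_size=4.0, frame_rate=10.0)
        assert np.allclose(ts.fluorescence[0], 2.0)
        assert np.allclose(ts.fluorescence[1], 0.0)

    def test_disk_outside_rejected(self):
        stack = np.zeros((1, 8, 8))
        with pytest.raises(ValueError):
            extract_target_traces(stack, [(500.0, 500.0)], px_size=4.0, frame_rate=10.0)
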