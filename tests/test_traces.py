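import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from penumbra.traces import (
    RoiTable,
    TraceSet,
    activity_rate,
    align_to_seizure,
    annulus_neuropil,
    dff_normalize,
    nearest_excitatory,
    overlap_filter,
    recruitment_delay,
    xcorr_lag,
)


def _rois(rows, masks=None, px_size=1.0):
    table = pd.DataFrame(rows, columns=["roi_id", "x", "y", "is_target", "is_inhibitory"])
    return RoiTable(table, masks or {}, px_size=px_size, fov_size=(512.0, 512.0))


class TestDffNormalize:
    def test_constant_trace_is_zero(self):
        assert np.allclose(dff_normalize([5.0, 5.0, 5.0, 5.0]), 0.0)

    def test_hand_arithmetic(self):
        assert np.allclose(dff_normalize([1.0, 3.0]), [-0.5, 0.5], atol=1e-15)

    def test_excluded_frame_still_transformed(self):
        out = dff_normalize([1.0, 3.0, 100.0], excluded_frames=[False, False, True])
        assert np.allclose(out, [-0.5, 0.5, 49.0], atol=1e-13)

    def test_matrix_rows_independent(self):
        out = dff_normalize(np.array([[1.0, 3.0], [2.0, 6.0]]))
        assert np.allclose(out, [[-0.5, 0.5], [-0.5, 0.5]])

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            dff_normalize([1.0, -3.0])

    def test_all_excluded_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            dff_normalize([1.0, 2.0], excluded_frames=[True, True])

    @given(st.floats(min_value=0.01, max_value=1e4))
    def test_scale_invariance(self, c):
        f = np.array([1.0, 2.0, 5.0, 0.5])
        assert np.allclose(dff_normalize(c * f), dff_normalize(f), rtol=1e-9)


class TestActivityRate:
    def test_zeros(self):
        assert activity_rate(np.zeros(100), 30.0) == 0.0

    def test_constant_one(self):
        assert activity_rate(np.ones(37), 12.5) == pytest.approx(1.0)

    def test_hand_arithmetic(self):
        assert activity_rate([0.0, 2.0, 0.0], 10.0) == pytest.approx(2.0 / 3.0)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            activity_rate([1.0, -1.0], 10.0)

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            activity_rate([], 10.0)


class TestAlignToSeizure:
    def test_constant_trace_zeros(self):
        t = np.arange(100) / 10.0
        out = align_to_seizure(np.full(100, 3.0), t, seizure_onset=5.0)
        assert np.allclose(out, 0.0)

    def test_step_at_onset(self):
        t = np.arange(100) / 10.0
        f = np.where(t >= 5.0, 2.0, 0.0)
        out = align_to_seizure(f, t, seizure_onset=5.0)
        assert np.allclose(out[t >= 5.0], 2.0)

    def test_shift_invariance(self):
        t = np.arange(100) / 10.0
        f = np.sin(t)
        assert np.allclose(
            align_to_seizure(f + 7.3, t, 5.0), align_to_seizure(f, t, 5.0)
        )

    def test_empty_window_rejected(self):
        t = np.arange(100) / 10.0
        with pytest.raises(ValueError):
            align_to_seizure(np.ones(100), t, seizure_onset=0.5)


class TestRecruitmentDelay:
    def test_step_delay(self):
        t = np.arange(200) / 10.0
        f = np.where(t >= 7.0, 1.0, 0.0)
        assert recruitment_delay(f, t, 5.0, 15.0, 0.65) == pytest.approx(2.0)

    def test_linear_ramp_closed_form(self):
        # ramp from onset to offset over D seconds: crossing at frac * D
        fr = 1000.0
        t = np.arange(0, 20 * fr) / fr
        d = 10.0
        f = np.clip((t - 5.0) / d, 0.0, 1.0)
        delay = recruitment_delay(f, t, 5.0, 15.0, 0.65)
        assert delay == pytest.approx(0.65 * d, abs=1.5 / fr)

    def test_max_at_onset_gives_zero(self):
        t = np.arange(100) / 10.0
        f = np.where(t >= 0, 1.0, 0.0)
        assert recruitment_delay(f, t, 2.0, 8.0, 0.85) == 0.0

    def test_no_positive_excursion_nan(self):
        t = np.arange(100) / 10.0
        assert np.isnan(recruitment_delay(np.zeros(100), t, 2.0, 8.0, 0.65))
        assert np.isnan(recruitment_delay(-np.ones(100), t, 2.0, 8.0, 0.65))

    def test_monotone_in_frac(self):
        t = np.arange(300) / 10.0
        f = np.clip((t - 5.0) / 10.0, 0.0, 1.0)
        d65 = recruitment_delay(f, t, 5.0, 20.0, 0.65)
        d85 = recruitment_delay(f, t, 5.0, 20.0, 0.85)
        assert d65 <= d85


class TestXcorrLag:
    def test_identical_traces_zero_lag(self, rng):
        a = rng.normal(size=500)
        assert xcorr_lag(a, a, 10.0) == 0.0

    def test_recovers_constructed_shift(self, rng):
        a = rng.normal(size=500)
        k = 7
        b = np.roll(a, k)
        assert xcorr_lag(a, b, 10.0) == pytest.approx(k / 10.0)

    def test_antisymmetry(self, rng):
        a = rng.normal(size=500)
        b = np.roll(a, 5)
        assert xcorr_lag(a, b, 10.0) == pytest.approx(-xcorr_lag(b, a, 10.0))

    def test_zero_variance_nan(self):
        assert np.isnan(xcorr_lag(np.ones(200), np.arange(200.0), 10.0))

    def test_window_too_short_rejected(self):
        with pytest.raises(ValueError):
            xcorr_lag(np.ones(10), np.ones(10), 10.0, max_lag=2.0)


class TestAnnulusNeuropil:
    def test_uniform_image(self):
        stack = np.full((4, 60, 60), 3.5)
        out = annulus_neuropil(stack, (120.0, 120.0), px_size=4.0)
        assert np.allclose(out, 3.5)

    def test_inner_disk_excluded_by_geometry(self):
        # intensity 1 only inside r < 20 um -> annulus [20, 100) reads 0
        h = w = 60
        px = 4.0
        xs = (np.arange(w) + 0.5) * px
        ys = (np.arange(h) + 0.5) * px
        rr = np.hypot(xs[None, :] - 120.0, ys[:, None] - 120.0)
        img = (rr < 20.0).astype(float)
        out = annulus_neuropil(img[None], (120.0, 120.0), px_size=px)
        assert np.allclose(out, 0.0)

    def test_exclusion_masks_removed(self):
        stack = np.full((2, 60, 60), 9.0)
        # poison half the annulus, then exclude exactly those pixels
        xs = (np.arange(60) + 0.5) * 4.0
        ys = (np.arange(60) + 0.5) * 4.0
        rr = np.hypot(xs[None, :] - 120.0, ys[:, None] - 120.0)
        poison = (rr >= 20.0) & (rr < 100.0) & (xs[None, :] > 120.0)
        stack[:, poison] = 1e6
        out = annulus_neuropil(stack, (120.0, 120.0), px_size=4.0, exclusion_masks=[poison])
        assert np.allclose(out, 9.0)

    def test_empty_annulus_rejected(self):
        stack = np.ones((1, 5, 5))
        with pytest.raises(ValueError):
            annulus_neuropil(stack, (2.5, 2.5), px_size=1.0, r_in=20.0, r_out=100.0)


class TestNearestExcitatory:
    def test_single_candidate(self):
        rois = _rois([(0, 100.0, 100.0, False, True), (1, 150.0, 100.0, False, False)])
        assert nearest_excitatory(0, rois) == 1

    def test_picks_closer(self):
        rois = _rois(
            [
                (0, 100.0, 100.0, False, True),
                (1, 160.0, 100.0, False, False),
                (2, 130.0, 100.0, False, False),
            ]
        )
        assert nearest_excitatory(0, rois) == 2

    def test_none_within_radius(self):
        rois = _rois([(0, 100.0, 100.0, False, True), (1, 250.0, 100.0, False, False)])
        assert nearest_excitatory(0, rois) is None

    def test_unknown_roi(self):
        rois = _rois([(0, 100.0, 100.0, False, True)])
        with pytest.raises(KeyError):
            nearest_excitatory(99, rois)


class TestOverlapFilter:
    def _build(self, shared):
        inh_mask = (np.arange(10), np.zeros(10, dtype=int))
        exc_rows = np.concatenate([np.arange(shared), 20 + np.arange(100 - shared)])
        exc_cols = np.concatenate([np.zeros(shared, dtype=int), np.ones(100 - shared, dtype=int)])
        return _rois(
            [(0, 10.0, 10.0, False, True), (1, 30.0, 30.0, False, False)],
            masks={0: inh_mask, 1: (exc_rows, exc_cols)},
        )

    def test_ten_percent_overlap_excluded(self):
        out = overlap_filter(self._build(shared=10))
        assert out.table["roi_id"].tolist() == [0]

    def test_four_percent_overlap_kept(self):
        out = overlap_filter(self._build(shared=4))
        assert sorted(out.table["roi_id"].tolist()) == [0, 1]

    def test_no_masks_rejected(self):
        rois = _rois([(0, 10.0, 10.0, False, True)])
        with pytest.raises(ValueError):
            overlap_filter(rois)


class TestContainers:
    def test_roi_outside_fov_rejected(self):
        with pytest.raises(ValueError, match="field of view"):
            _rois([(0, 600.0, 10.0, False, False)])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            _rois([(0, 10.0, 10.0, False, False)], masks={0: (np.array([]), np.array([]))})

    def test_traceset_shapes(self):
        ts = TraceSet(np.zeros((3, 50)), frame_rate=10.0)
        assert ts.n_neurons == 3 and ts.n_frames == 50
        assert np.allclose(ts.frame_times, np.arange(50) / 10.0)
        with pytest.raises(ValueError):
            TraceSet(np.zeros((3, 50)), frame_rate=10.0, deconvolved=np.zeros((3, 49)))
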