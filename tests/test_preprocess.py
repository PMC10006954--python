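"""Filtering, normalization, imputation, rate conversion and windowing."""

import numpy as np
import pytest
from scipy.signal import freqz

from cowfeed import (
    TagRecording,
    align_labels,
    BoutLabel,
    design_highpass,
    highpass_filter,
    impute_missing,
    normalize_amplitude,
    resample_to_rate,
    segment_windows,
    windows_from_recording,
)
from cowfeed.preprocess import preprocess_recording


def make_rec(values, rate=25.0, mask=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = np.stack([values] * 3, axis=1)
    if mask is None:
        mask = np.zeros(len(values), bool)
    return TagRecording("c", 0, rate, values, mask)


class TestHighpass:
    def test_filter_has_512_taps(self):
        assert len(design_highpass()) == 512  # order 511

    def test_dc_gain_is_null(self):
        h = design_highpass()
        _, H = freqz(h, worN=[0.0])
        assert abs(H[0]) <= 1e-6

    def test_unit_gain_at_1hz(self):
        h = design_highpass()
        _, H = freqz(h, worN=[2 * np.pi * 1.0 / 25.0])
        assert abs(abs(H[0]) - 1.0) < 0.01

    def test_constant_input_rejected(self):
        rec = make_rec(np.full(4000, 0.98))  # pure gravity
        out = highpass_filter(rec)
        interior = out.values[300:-300]
        assert np.max(np.abs(interior)) <= 1e-3

    def test_sine_at_1hz_passes(self):
        t = np.arange(6000) / 25.0
        rec = make_rec(np.sin(2 * np.pi * 1.0 * t))
        out = highpass_filter(rec)
        amp = np.max(np.abs(out.values[1000:-1000, 0]))
        assert abs(amp - 1.0) < 0.01

    def test_linearity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=(2, 1500, 3))
        fa = highpass_filter(make_rec(a)).values
        fb = highpass_filter(make_rec(b)).values
        fab = highpass_filter(make_rec(a + b)).values
        np.testing.assert_allclose(fab, fa + fb, atol=1e-9)

    def test_too_short_recording_errors(self):
        with pytest.raises(ValueError, match="shorter than filter"):
            highpass_filter(make_rec(np.zeros(100)))

    def test_length_preserved(self):
        out = highpass_filter(make_rec(np.random.default_rng(1).normal(size=700)))
        assert out.n_samples == 700


class TestNormalize:
    def test_scales_to_unit_peak(self):
        v = np.array([[-2.0, 1.0, 0.5], [2.0, -1.0, 0.25]])
        out = normalize_amplitude(v)
        assert np.max(np.abs(out)) == 1.0
        np.testing.assert_allclose(out, v / 2.0)

    def test_all_zero_unchanged(self):
        v = np.zeros((10, 3))
        np.testing.assert_array_equal(normalize_amplitude(v), v)

    def test_scaling_factor_is_inverse_peak(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(100, 3)) * 3.7
        out = normalize_amplitude(v)
        np.testing.assert_allclose(out * np.max(np.abs(v)), v)


class TestImpute:
    def test_no_missing_is_identity(self):
        rec = make_rec(np.ones(50))
        np.testing.assert_array_equal(impute_missing(rec).values, rec.values)

    def test_masked_slots_become_zero_and_mask_kept(self):
        mask = np.zeros(50, bool)
        mask[10:20] = True
        mask[30:50] = True
        v = np.ones((50, 3))
        v[mask] = np.nan
        rec = make_rec(v, mask=mask)
        out = impute_missing(rec)
        assert np.all(out.values[mask] == 0.0)
        assert np.all(out.values[~mask] == 1.0)
        np.testing.assert_array_equal(out.missing_mask, mask)


class TestResample:
    def test_10_to_25_hz_counts(self):
        rec = make_rec(np.arange(100, dtype=float), rate=10.0)
        out = resample_to_rate(rec, 25.0)
        assert out.n_samples == 250
        assert (~out.missing_mask).sum() == 100
        assert out.missing_mask.sum() == 150

    def test_occupied_values_exact(self):
        src = np.arange(40, dtype=float)
        rec = make_rec(src, rate=10.0)
        out = resample_to_rate(rec, 25.0)
        idx = np.floor(np.arange(40) * 2.5 + 0.5).astype(int)
        np.testing.assert_array_equal(out.values[idx, 0], src)
        assert not out.missing_mask[idx].any()

    def test_identity_at_same_rate(self):
        rec = make_rec(np.arange(30, dtype=float), rate=25.0)
        out = resample_to_rate(rec, 25.0)
        np.testing.assert_array_equal(out.values, rec.values)

    def test_downsampling_refused(self):
        with pytest.raises(ValueError, match="downsampling"):
            resample_to_rate(make_rec(np.zeros(10), rate=25.0), 10.0)


class TestSegmentation:
    def single_bout_rec(self, seconds=300):
        n = int(seconds * 25)
        rng = np.random.default_rng(0)
        rec = make_rec(rng.normal(size=n))
        labels = align_labels(rec, [BoutLabel(0, seconds, "feeding")])
        return rec, labels

    def test_window_counts_with_overlap(self):
        rec, labels = self.single_bout_rec(300)
        assert len(segment_windows(rec, labels, 60, overlap=0.5)) == 9
        assert len(segment_windows(rec, labels, 60, overlap=0.0)) == 5

    def test_60s_window_holds_1500_samples(self):
        rec, labels = self.single_bout_rec(60)
        store = segment_windows(rec, labels, 60)
        assert len(store) == 1
        assert store.window_len == 1500  # 60 s x 25 Hz

    def test_windows_straddling_class_change_excluded(self):
        n = 300 * 25
        rec = make_rec(np.zeros(n))
        labels = align_labels(
            rec, [BoutLabel(0, 150, "feeding"), BoutLabel(150, 300, "other")]
        )
        store = segment_windows(rec, labels, 60, overlap=0.0)
        # starts 0,60,120,180,240 -> the one at 120 s straddles 150 s
        assert len(store) == 4
        assert sorted(store.start_s) == [0, 60, 180, 240]
        assert list(store.y[np.argsort(store.start_s)]) == [0, 0, 2, 2]

    def test_unlabeled_slots_excluded(self):
        n = 120 * 25
        rec = make_rec(np.zeros(n))
        labels = align_labels(rec, [BoutLabel(30, 90, "ruminating")])
        store = segment_windows(rec, labels, 60, overlap=0.5)
        assert len(store) == 1 and store.start_s[0] == 30.0

    def test_window_longer_than_recording_is_empty(self):
        rec, labels = self.single_bout_rec(30)
        assert len(segment_windows(rec, labels, 60)) == 0

    def test_overlap_at_most_doubles_windows(self):
        rec, labels = self.single_bout_rec(300)
        n0 = len(segment_windows(rec, labels, 30, overlap=0.0))
        n5 = len(segment_windows(rec, labels, 30, overlap=0.5))
        assert n5 <= 2 * n0 - 1


class TestPipeline:
    def test_pipeline_order_impute_filter_normalize(self):
        from cowfeed.preprocess import (
            highpass_filter,
            impute_missing,
            normalize_recording,
        )

        rng = np.random.default_rng(4)
        mask = np.zeros(2000, bool)
        mask[100:200] = True
        v = rng.normal(0, 0.3, size=(2000, 3)) + 1.0
        v[mask] = np.nan
        rec = make_rec(v, mask=mask)
        manual = normalize_recording(highpass_filter(impute_missing(rec)))
        auto = preprocess_recording(rec)
        np.testing.assert_allclose(auto.values, manual.values)

    def test_source_profile_resampled_before_chain(self):
        rng = np.random.default_rng(5)
        rec = make_rec(rng.normal(size=3000), rate=10.0)
        out = preprocess_recording(rec)
        assert out.sampling_rate == 25.0
        assert out.n_samples == 7500

    def test_windows_from_recording_matches_manual_chain(self):
        rng = np.random.default_rng(6)
        n = 25 * 240
        rec = make_rec(rng.normal(size=n) + 0.8)
        bouts = [BoutLabel(0, 240, "other")]
        auto = windows_from_recording(rec, bouts, 30, 0.5)
        processed = preprocess_recording(rec)
        manual = segment_windows(processed, align_labels(processed, bouts), 30, 0.5)
        np.testing.assert_array_equal(auto.X, manual.X)
        np.testing.assert_array_equal(auto.y, manual.y)
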