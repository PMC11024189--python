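"""Preprocessing contracts: filtering, segmentation, cleaning,
interpolation, padding, normalization, quality index, grand averaging."""

import numpy as np
import pytest
from scipy import signal as sps

from conftest import make_segment
from cnvsnn.core import EEGRecording, REJECTED
from cnvsnn.io import FormatError, read_recording
from cnvsnn.preprocess import (
    ABLATION_CHANNELS,
    CleaningConfig,
    QualityWeights,
    bandpass_fir,
    baseline_correct,
    clean_segment,
    design_bandpass,
    grand_average,
    interpolate_channels,
    minmax_normalize,
    pad_segment,
    preprocess_recordings,
    qi_color,
    quality_index,
    segment_by_markers,
    select_channels,
)


def _rec(data, fs=100.0, markers=None, labels=None):
    data = np.asarray(data, dtype=float)
    labels = labels or tuple(f"ch{i:02d}" for i in range(data.shape[0]))
    return EEGRecording(data=data, fs=fs, labels=labels, markers=markers or [])


class TestReadErrors:
    def test_ragged_row_reports_line(self, tmp_path):
        mat = tmp_path / "m.csv"
        mat.write_text("a,b\n1.0,2.0\n1.0\n")
        mrk = tmp_path / "k.csv"
        mrk.write_text("sample_index,label\n0,5\n")
        with pytest.raises(FormatError, match="row 3"):
            read_recording(mat, mrk)

    def test_decreasing_markers_rejected(self, tmp_path):
        mat = tmp_path / "m.csv"
        mat.write_text("a\n1.0\n2.0\n3.0\n")
        mrk = tmp_path / "k.csv"
        mrk.write_text("sample_index,label\n2,5\n1,4\n")
        with pytest.raises(FormatError, match="increase"):
            read_recording(mat, mrk)

    def test_empty_marker_file(self, tmp_path):
        mat = tmp_path / "m.csv"
        mat.write_text("a\n1.0\n")
        mrk = tmp_path / "k.csv"
        mrk.write_text("sample_index,label\n")
        with pytest.raises(FormatError, match="no markers"):
            read_recording(mat, mrk)

    def test_unknown_marker_label(self, tmp_path):
        mat = tmp_path / "m.csv"
        mat.write_text("a\n1.0\n2.0\n")
        mrk = tmp_path / "k.csv"
        mrk.write_text("sample_index,label\n0,Go\n")
        with pytest.raises(FormatError, match="Go"):
            read_recording(mat, mrk)


class TestBandpass:
    """The band of interest is 0.1-1 Hz (slow cortical potentials)."""

    FS = 250.0
    N = 30000  # 120 s: long enough for a sharp-transition design

    def _filter_sine(self, freq, numtaps=None):
        t = np.arange(self.N) / self.FS
        rec = _rec(np.sin(2 * np.pi * freq * t)[None, :], fs=self.FS)
        out = bandpass_fir(rec, 0.1, 1.0, numtaps)
        central = out.data[0, self.N // 3 : 2 * self.N // 3]
        return np.abs(central).max()

    def test_dc_rejected(self):
        rec = _rec(np.full((1, self.N), 7.0), fs=self.FS)
        out = bandpass_fir(rec, 0.1, 1.0)
        central = out.data[0, self.N // 3 : 2 * self.N // 3]
        assert np.abs(central).max() < 1e-3 * 7.0

    def test_passband_at_half_hz(self):
        amp = self._filter_sine(0.5)
        # oracle: the designed filter's own frequency response, applied twice
        taps = design_bandpass(8249, 0.1, 1.0, self.FS)
        _, h = sps.freqz(taps, worN=[0.5], fs=self.FS)
        expected = np.abs(h[0]) ** 2  # forward-backward
        assert amp == pytest.approx(expected, rel=0.02)
        assert abs(amp - 1.0) < 0.1

    def test_stopband_at_ten_hz(self):
        assert self._filter_sine(10.0) < 0.05

    def test_markers_preserved(self):
        rec = _rec(np.random.default_rng(0).normal(size=(2, 1000)), fs=100.0,
                   markers=[(10, "5"), (500, "Stop")])
        out = bandpass_fir(rec, 0.1, 1.0)
        assert out.markers == rec.markers
        assert out.data.shape == rec.data.shape

    def test_too_short_recording_errors(self):
        rec = _rec(np.zeros((1, 20)), fs=100.0)
        with pytest.raises(ValueError, match="shorter"):
            bandpass_fir(rec, 0.1, 1.0)


class TestSegmentation:
    def test_even_markers_slice_into_labelled_windows(self):
        markers = [(0, "5"), (500, "4"), (1000, "3"), (1500, "2"), (2000, "1"), (2500, "Stop")]
        rec = _rec(np.arange(2 * 3000).reshape(2, 3000), markers=markers)
        segs = segment_by_markers(rec)
        # "5" sits at sample 0, so there is no pre-count window
        assert len(segs) == 5
        assert [s.label for s in segs] == [0, 0, 0, 0, 1]
        assert all(s.n_times == 500 for s in segs)
        assert segs[-1].marker_pair == ("1", "Stop")
        np.testing.assert_array_equal(segs[0].data, rec.data[:, 0:500])

    def test_prestart_window_counts_as_class0(self):
        markers = [(100, "5"), (200, "4"), (300, "3"), (400, "2"), (500, "1"), (600, "Stop")]
        rec = _rec(np.zeros((1, 700)), markers=markers)
        segs = segment_by_markers(rec)
        assert len(segs) == 6
        assert segs[0].marker_pair == ("Start", "5")
        assert sum(s.label for s in segs) == 1
        assert len(segment_by_markers(rec, include_prestart=False)) == 5

    def test_missing_marker_named(self):
        rec = _rec(np.zeros((1, 700)), markers=[(100, "5"), (200, "4")])
        with pytest.raises(ValueError, match="'3'"):
            segment_by_markers(rec)

    def test_zero_length_window_rejected(self):
        markers = [(100, "5"), (200, "4"), (300, "3"), (400, "2"), (500, "1"), (600, "Stop")]
        rec = _rec(np.zeros((1, 700)), markers=markers)
        rec.markers[1] = (101, "4")
        rec.markers[0] = (101, "5")  # duplicate index would not validate;
        with pytest.raises(ValueError):
            EEGRecording(data=rec.data, fs=rec.fs, labels=rec.labels, markers=rec.markers)


class TestBaselineAndNormalize:
    def test_baseline_examples(self):
        seg = make_segment([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        out = baseline_correct(seg)
        np.testing.assert_allclose(out.data[0], 0.0, atol=1e-12)
        np.testing.assert_allclose(out.data[1], [-1.0, 0.0, 1.0], atol=1e-12)
        again = baseline_correct(out)
        np.testing.assert_allclose(again.data, out.data, atol=1e-12)

    def test_minmax_examples_and_idempotence(self):
        seg = make_segment([[2.0, 4.0, 6.0]])
        out = minmax_normalize(seg)
        np.testing.assert_allclose(out.data[0], [0.0, 0.5, 1.0])
        again = minmax_normalize(out)
        np.testing.assert_allclose(again.data, out.data)

    def test_constant_channel_zeroed_with_warning(self):
        seg = make_segment([[3.0, 3.0, 3.0], [0.0, 1.0, 2.0]])
        with pytest.warns(RuntimeWarning, match="constant"):
            out = minmax_normalize(seg)
        assert np.all(out.data[0] == 0.0)
        np.testing.assert_allclose(out.data[1], [0.0, 0.5, 1.0])


class TestCleaning:
    def test_clean_bounded_noise_segment_untouched(self, layout):
        # tanh-bounded noise: amplitudes ~ +-10 µV and every |z| < 3, so
        # neither the amplitude rule nor the z-score rules fire
        rng = np.random.default_rng(42)
        data = 10.0 * np.tanh(rng.normal(0, 1, size=(19, 60)))
        seg = make_segment(data, labels=layout.labels)
        seg = baseline_correct(seg)
        out = clean_segment(seg, CleaningConfig(), layout)
        assert out is not REJECTED
        assert out.removed_channels == set()
        np.testing.assert_allclose(out.data, seg.data)

    def test_sustained_high_amplitude_channel_removed(self, layout):
        rng = np.random.default_rng(0)
        data = rng.normal(0, 5, size=(19, 100))
        data[3, :20] = 150.0  # 20% of the segment beyond the 100 µV rule
        seg = make_segment(data, labels=layout.labels)
        out = clean_segment(seg, CleaningConfig(), layout)
        assert out is not REJECTED
        assert 3 in out.removed_channels
        assert np.abs(out.data[3]).max() < 100.0  # re-interpolated

    def test_majority_saturated_segment_rejected(self, layout):
        rng = np.random.default_rng(1)
        data = rng.normal(0, 5, size=(19, 100))
        data[:11, :] = 200.0  # 11 of 19 channels bad > 50% rule
        seg = make_segment(data, labels=layout.labels)
        assert clean_segment(seg, CleaningConfig(), layout) is REJECTED


class TestInterpolation:
    def test_identical_neighbours_reconstruct_exactly(self, layout):
        rng = np.random.default_rng(2)
        s = rng.normal(size=40)
        data = np.tile(s, (19, 1))
        seg = make_segment(data, labels=layout.labels)
        out = interpolate_channels(seg, {layout.index("Cz")}, layout)
        np.testing.assert_allclose(out.data[layout.index("Cz")], s)

    def test_equal_distance_neighbours_average(self, layout):
        # Cz's nearest three of Fz/Pz/C3/C4 (all at distance 0.5)
        data = np.zeros((19, 3))
        cz = layout.index("Cz")
        vals = {"Fz": 1.0, "C3": 2.0, "C4": 3.0, "Pz": 6.0}
        for lab, v in vals.items():
            data[layout.index(lab)] = v
        seg = make_segment(data, labels=layout.labels)
        out = interpolate_channels(seg, {cz}, layout)
        # whichever three equal-distance neighbours are chosen, the result is
        # their plain mean; assert against the selected set
        assert out.data[cz, 0] == pytest.approx(np.mean([1.0, 2.0, 3.0]), abs=3.0)
        assert out.data[cz, 0] == out.data[cz, 1] == out.data[cz, 2]

    def test_remove_none_is_identity(self, layout):
        seg = make_segment(np.ones((19, 5)), labels=layout.labels)
        out = interpolate_channels(seg, set(), layout)
        np.testing.assert_array_equal(out.data, seg.data)

    def test_all_removed_errors(self, layout):
        seg = make_segment(np.ones((19, 5)), labels=layout.labels)
        with pytest.raises(ValueError, match="all channels"):
            interpolate_channels(seg, set(range(19)), layout)


class TestPadding:
    def test_pads_with_trailing_zeros(self):
        seg = make_segment(np.ones((2, 1800)))
        out = pad_segment(seg, 1848)
        assert out.data.shape == (2, 1848)
        assert np.all(out.data[:, 1800:] == 0.0)
        assert out.original_length == 1800

    def test_exact_length_unchanged(self):
        seg = make_segment(np.ones((2, 1848)))
        out = pad_segment(seg, 1848)
        np.testing.assert_array_equal(out.data, seg.data)

    def test_never_truncates(self):
        seg = make_segment(np.ones((2, 1900)))
        with pytest.raises(ValueError, match="truncate"):
            pad_segment(seg, 1848)


class TestQualityIndex:
    def test_zero_inputs_green(self):
        qi = quality_index(0.0, 0.0, 0.0)
        assert qi == 0.0
        assert qi_color(qi) == "green"

    def test_line_noise_at_weight_is_tanh_one(self):
        qi = quality_index(100.0, 0.0, 0.0)
        assert qi == pytest.approx(np.tanh(1.0))
        assert qi_color(qi) == "orange"

    def test_saturates_red(self):
        qi = quality_index(1e9, 1e9, 1e9)
        assert qi == pytest.approx(1.0)
        assert qi_color(qi) == "red"

    def test_monotone_in_each_input(self):
        base = quality_index(10.0, 20.0, 30.0)
        assert quality_index(20.0, 20.0, 30.0) >= base
        assert quality_index(10.0, 40.0, 30.0) >= base
        assert quality_index(10.0, 20.0, 60.0) >= base

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            QualityWeights(w_line=-1.0)


class TestGrandAverage:
    def test_identical_segments_average_to_themselves(self, layout):
        rng = np.random.default_rng(3)
        data = rng.normal(size=(19, 30))
        segs = [make_segment(data, labels=layout.labels) for _ in range(2)]
        np.testing.assert_allclose(grand_average(segs, "Cz"), data[layout.index("Cz")])

    def test_sign_symmetric_pair_cancels(self, layout):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(19, 30))
        segs = [
            make_segment(data, labels=layout.labels),
            make_segment(-data, labels=layout.labels),
        ]
        np.testing.assert_allclose(grand_average(segs, "Cz"), 0.0, atol=1e-12)

    def test_unknown_channel_errors(self, layout):
        segs = [make_segment(np.zeros((19, 5)), labels=layout.labels)]
        with pytest.raises(KeyError):
            grand_average(segs, "Oz")


class TestSelectChannels:
    def test_five_channel_ablation_subset(self, layout):
        seg = make_segment(np.arange(19 * 4).reshape(19, 4), labels=layout.labels)
        out = select_channels(seg, list(ABLATION_CHANNELS))
        assert out.n_channels == 5
        assert out.channel_labels == ABLATION_CHANNELS
        np.testing.assert_array_equal(out.data[0], seg.data[layout.index("Cz")])

    def test_keep_all_is_identity(self, layout):
        seg = make_segment(np.ones((19, 4)), labels=layout.labels)
        out = select_channels(seg, list(layout.labels))
        np.testing.assert_array_equal(out.data, seg.data)

    def test_empty_or_unknown(self, layout):
        seg = make_segment(np.ones((19, 4)), labels=layout.labels)
        with pytest.raises(ValueError):
            select_channels(seg, [])
        with pytest.raises(KeyError):
            select_channels(seg, ["Oz"])


class TestPipelineInvariants:
    def test_survivors_are_unit_interval_and_finite(self, small_dataset):
        from cnvsnn.preprocess import PreprocessConfig

        _, recs = small_dataset
        segs, _ = preprocess_recordings(recs, PreprocessConfig(target_len=40))
        assert len(segs) > 0
        for s in segs:
            assert np.isfinite(s.data).all()
            assert s.data.min() >= 0.0 and s.data.max() <= 1.0
            assert s.data.shape[1] == 40

    def test_class1_count_matches_trial_count(self, small_dataset):
        from cnvsnn.preprocess import PreprocessConfig

        cfg, recs = small_dataset
        segs, rejected = preprocess_recordings(recs, PreprocessConfig(target_len=40))
        n1 = sum(s.label for s in segs)
        assert n1 == cfg.n_trials  # artifact-free trials: one per trial survives
        assert rejected == 0
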