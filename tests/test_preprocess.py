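"""Preprocessing chain: segmentation, filtering, baseline, rejection,
re-referencing, averaging and resampling."""

import numpy as np
import pytest

from itdeeg import StimulusSpec, simulate_recording
from itdeeg.preprocess import (Epochs, average, bandpass, baseline_correct,
                               reject_artifacts, rereference, resample,
                               segment, VIRTUAL_CZ)
from itdeeg.synth_eeg import ArtifactModel, EEGRecording
from conftest import SIM_FS, noiseless_config


def butter2_bandpass_mag(f, lo, hi, fs):
    """Closed-form magnitude of the 2nd-order digital Butterworth band-pass.

    Band-pass transform of the order-2 prototype, |H|^2 = 1 / (1 + q^4)
    with q = (w^2 - lo*hi) / ((hi - lo) * w), evaluated at the bilinear-
    prewarped frequencies of the digital design.
    """
    warp = lambda x: fs / np.pi * np.tan(np.pi * x / fs)
    fw, low, hiw = warp(f), warp(lo), warp(hi)
    q = (fw ** 2 - low * hiw) / ((hiw - low) * fw)
    return 1.0 / np.sqrt(1 + q ** 4)


def tone_amplitude(y, fs, f, window):
    """Amplitude of the f-Hz component by complex demodulation."""
    seg = y[window]
    n_cycles = int(np.floor(len(seg) * f / fs))
    n = int(round(n_cycles * fs / f))
    t = np.arange(n) / fs
    return 2 * np.abs(np.sum(seg[:n] * np.exp(-2j * np.pi * f * t))) / n


def make_epochs(data, fs=SIM_FS, labels=("a", "b", "c", "d")):
    return Epochs(data=np.asarray(data, dtype=float), fs=fs,
                  channel_labels=tuple(labels))


class TestSegment:
    def test_epoch_counts_and_length(self):
        rec = simulate_recording(noiseless_config(n_trials=5))
        ep = segment(rec)
        assert ep.data.shape == (5, 4, int(8.2 * SIM_FS))
        assert ep.t0_offset_s == -0.2

    def test_sample_count_at_20khz(self):
        assert int(round(8.2 * 20000)) == 164000

    def test_event_near_edge_dropped(self):
        rec = simulate_recording(noiseless_config(n_trials=3))
        clipped = EEGRecording(
            data=rec.data[:, : int((rec.events[-1][0] + 1.0) * rec.fs)],
            fs=rec.fs, channel_labels=rec.channel_labels, events=rec.events,
            ground_truth=rec.ground_truth)
        ep = segment(clipped)
        assert ep.n_trials == 2


class TestBandpass:
    def test_dc_rejected(self):
        x = np.full(int(20 * SIM_FS), 5.0)
        y = bandpass(x, SIM_FS, 0.1, 30.0)
        assert np.max(np.abs(y[int(5 * SIM_FS):-int(5 * SIM_FS)])) < 1e-3

    def test_passband_sinusoid_preserved(self):
        fs = 20000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 40 * t)
        y = bandpass(x, fs, 0.1, 1000.0)
        mid = slice(int(fs), int(3 * fs))
        assert tone_amplitude(y, fs, 40.0, mid) == pytest.approx(1.0, rel=0.01)

    def test_stopband_matches_closed_form(self):
        # 2-kHz tone against the analytic response; zero-phase application
        # squares the magnitude
        fs = 20000.0
        t = np.arange(int(4 * fs)) / fs
        x = np.sin(2 * np.pi * 2000 * t)
        y = bandpass(x, fs, 0.1, 1000.0)
        expected = butter2_bandpass_mag(2000.0, 0.1, 1000.0, fs) ** 2
        mid = slice(int(fs), int(3 * fs))
        assert tone_amplitude(y, fs, 2000.0, mid) == pytest.approx(expected,
                                                                   rel=0.01)

    def test_invalid_corners_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros(100), SIM_FS, 30.0, 0.1)


class TestBaseline:
    def test_constant_epoch_zeroed(self):
        ep = make_epochs(np.full((2, 4, int(3 * SIM_FS)), 7.0))
        out = baseline_correct(ep)
        assert np.allclose(out.data, 0.0)

    def test_final_second_mean_is_zero(self):
        rng = np.random.default_rng(0)
        ep = make_epochs(rng.normal(size=(3, 4, int(4 * SIM_FS))))
        out = baseline_correct(ep)
        tail = out.data[:, :, -int(SIM_FS):]
        assert np.allclose(tail.mean(axis=2), 0.0, atol=1e-12)

    def test_linear_ramp_oracle(self):
        n = int(2 * SIM_FS)
        ramp = np.arange(n, dtype=float)
        ep = make_epochs(np.broadcast_to(ramp, (1, 4, n)).copy())
        out = baseline_correct(ep)
        expected = ramp - ramp[-int(SIM_FS):].mean()
        assert np.allclose(out.data[0, 0], expected)

    def test_epoch_shorter_than_window_rejected(self):
        ep = make_epochs(np.zeros((1, 4, 100)))
        with pytest.raises(ValueError):
            baseline_correct(ep)


class TestReject:
    def test_single_201uV_sample_rejected(self):
        data = np.zeros((3, 4, 1000))
        data[1, 2, 500] = 201.0
        out = reject_artifacts(make_epochs(data))
        assert list(out.keep_mask) == [True, False, True]

    def test_all_zero_no_rejections(self):
        out = reject_artifacts(make_epochs(np.zeros((4, 4, 100))))
        assert out.n_kept == 4

    def test_ground_truth_artifacts_exactly_rejected(self):
        cfg = noiseless_config(n_trials=12,
                               artifact=ArtifactModel(n_epochs=5), seed=9)
        rec = simulate_recording(cfg)
        ep = reject_artifacts(segment(rec))
        assert ep.n_kept == 7
        assert tuple(np.nonzero(~ep.keep_mask)[0]) == rec.artifact_trials


class TestRereference:
    def test_hand_arithmetic(self):
        data = np.zeros((1, 4, 1))
        data[0, :, 0] = [1.0, 2.0, 3.0, 6.0]
        out = rereference(make_epochs(data))
        assert np.allclose(out.data[0, :4, 0], [-2.0, -1.0, 0.0, 3.0])
        assert out.data[0, 4, 0] == pytest.approx(-3.0)  # virtual Cz
        assert out.channel_labels[-1] == VIRTUAL_CZ

    def test_identical_channels_vanish(self):
        out = rereference(make_epochs(np.full((2, 4, 10), 3.3)))
        assert np.allclose(out.data[:, :4, :], 0.0)

    def test_mean_of_rereferenced_channels_is_zero(self):
        rng = np.random.default_rng(1)
        out = rereference(make_epochs(rng.normal(size=(2, 4, 50))))
        assert np.allclose(out.data[:, :4, :].mean(axis=1), 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        once = rereference(make_epochs(rng.normal(size=(1, 4, 20))))
        twice = rereference(once)
        assert np.allclose(once.data, twice.data)
        assert once.channel_labels == twice.channel_labels


class TestAverageResample:
    def test_identical_trials_average_is_any_trial(self):
        one = np.random.default_rng(3).normal(size=(1, 4, 100))
        ep = make_epochs(np.repeat(one, 5, axis=0))
        assert np.allclose(average(ep).data, one[0])

    def test_zero_surviving_trials_errors(self):
        ep = make_epochs(np.zeros((2, 4, 10)))
        ep.keep_mask[:] = False
        with pytest.raises(ValueError):
            average(ep)

    def test_white_noise_average_sd(self):
        rng = np.random.default_rng(4)
        ep = make_epochs(rng.normal(0, 5.0, size=(60, 4, 2000)))
        ev = average(ep)
        assert ev.data.std() == pytest.approx(5.0 / np.sqrt(60), rel=0.15)

    def test_downsampled_peaks_agree(self):
        # peak latency from a 1-kHz downsampled clean template within 2 ms
        # of the full-rate result
        from itdeeg.synth_eeg import CaepTemplateParams, caep_template
        fs_hi = 20000.0
        tpl = caep_template(CaepTemplateParams(), "onset", fs_hi)
        lo = resample(tpl, fs_hi, 1000.0)
        lat_hi = np.argmax(tpl) / fs_hi * 1e3
        lat_lo = np.argmax(lo) / 1000.0 * 1e3
        assert abs(lat_hi - lat_lo) <= 2.0
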