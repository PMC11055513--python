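"""Stimulus synthesis: waveform properties and measurement round-trips."""

import numpy as np
import pytest
from scipy.signal import hilbert

from itdeeg import (Experiment, SequenceLayout, StimulusSpec,
                    make_filtered_clicks, make_masking_noise, make_sam_itdenv,
                    make_sam_itdfs, make_stimulus, measure_broadband_itd,
                    measure_carrier_ipd, measure_envelope_itd,
                    measure_modulation_rate)
from itdeeg.stimuli import (UnreliableEstimateError, passband_edges, read_wav,
                            spectral_slope_db_per_octave, write_wav)

FS = 20000.0
US_PER_SAMPLE = 1e6 / FS


class TestLayout:
    def test_sam_defaults_total_8s(self):
        lay = SequenceLayout.for_experiment(Experiment.ITDFS_SAM)
        assert lay.total_s == 8.0
        assert [a[0] for a in lay.annotations()] == ["T1", "T2", "T3", "T4"]

    def test_click_defaults_total_6s_no_t3(self):
        lay = SequenceLayout.for_experiment(Experiment.IPTD_CLICKS)
        assert lay.total_s == 6.0
        assert [a[0] for a in lay.annotations()] == ["T1", "T2", "T4"]

    def test_annotations_tile_without_overlap(self):
        lay = SequenceLayout()
        ann = lay.annotations()
        assert ann[0][1] == 0.0 and ann[-1][2] == lay.total_s
        for (_, _, e0), (_, s1, _) in zip(ann, ann[1:]):
            assert e0 == s1


class TestSamItdfs:
    def test_duration_and_diotic_t1(self, itdfs_signal):
        assert itdfs_signal.duration_s == pytest.approx(8.0)
        l, r = itdfs_signal.slice("T1")
        assert np.array_equal(l, r)  # bit-identical before the IPD switch

    def test_t3_diotic_again(self, itdfs_signal):
        l, r = itdfs_signal.slice("T3")
        assert np.array_equal(l, r)

    def test_zero_ipd_is_fully_diotic(self):
        sig = make_sam_itdfs(StimulusSpec(ipd=0.0))
        assert np.array_equal(sig.left, sig.right)

    def test_t2_carrier_phase_is_ipd(self, itdfs_signal):
        # independent cross-spectral phase oracle at the carrier
        ipd = measure_carrier_ipd(itdfs_signal, 400.0, "T2")
        assert ipd == pytest.approx(np.pi / 2, abs=1e-3)

    def test_envelope_identical_across_ears(self, itdfs_signal):
        l, r = itdfs_signal.slice((0.5, 7.5))
        env_l = np.abs(hilbert(l))
        env_r = np.abs(hilbert(r))
        assert np.max(np.abs(env_l - env_r)) < 1e-3 * env_l.max()

    def test_switch_at_envelope_trough(self, itdfs_signal):
        # at both nominal boundaries the envelope is at a trough (< 1% peak)
        env = np.abs(hilbert(itdfs_signal.left[: int(6 * FS)]))
        for t in (2.0, 4.0):
            i = int(round(t * FS))
            assert env[i] < 0.01 * env.max()

    def test_rejects_out_of_range_ipd(self):
        with pytest.raises(ValueError):
            StimulusSpec(ipd=3.5)

    def test_rejects_undersampled_carrier(self):
        with pytest.raises(ValueError):
            StimulusSpec(f_c=1600.0, fs=3000.0)

    def test_modulation_rate_recovered(self, itdfs_signal):
        assert measure_modulation_rate(itdfs_signal, "T1") == pytest.approx(40.0)


class TestSamItdenv:
    def test_envelope_lag_is_500us(self, itdenv_signal):
        itd = measure_envelope_itd(itdenv_signal, "T2")
        assert itd == pytest.approx(500.0, abs=US_PER_SAMPLE)

    def test_zero_itd_identity(self):
        sig = make_sam_itdenv(
            StimulusSpec(experiment="itdenv_sam", f_c=4000.0, itd_env_us=0.0))
        assert np.array_equal(sig.left, sig.right)

    def test_carrier_stays_in_phase(self, itdenv_signal):
        # envelope carries the ITD but the 4-kHz carrier must not
        ipd = measure_carrier_ipd(itdenv_signal, 4000.0, "T2")
        assert abs(ipd) < 1e-2

    def test_diotic_segments_report_zero(self, itdenv_signal):
        assert measure_envelope_itd(itdenv_signal, "T1") == pytest.approx(
            0.0, abs=US_PER_SAMPLE)
        assert measure_carrier_ipd(itdenv_signal, 4000.0, "T1") == pytest.approx(
            0.0, abs=1e-3)

    def test_ambiguous_itd_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(experiment="itdenv_sam", f_c=4000.0, f_m=320.0,
                         itd_env_us=2000.0)

    def test_short_window_unreliable(self, itdenv_signal):
        with pytest.raises(UnreliableEstimateError):
            measure_envelope_itd(itdenv_signal, (2.0, 2.05), f_m=40.0)


class TestFilteredClicks:
    def test_broadband_lag_is_500us(self, clicks_signal):
        itd = measure_broadband_itd(clicks_signal, "T2")
        assert itd == pytest.approx(500.0, abs=US_PER_SAMPLE)

    def test_impulse_count_before_filtering(self):
        # 40 pps over a 2-s diotic segment -> exactly 80 pulses
        rate, t1 = 40.0, 2.0
        n = sum(1 for k in range(1000) if k / rate < t1)
        assert n == 80

    def test_stopband_rejection(self, clicks_signal):
        l, _ = clicks_signal.slice("T1")
        mag = np.abs(np.fft.rfft(l))
        freqs = np.fft.rfftfreq(len(l), 1 / FS)
        peak_db = 20 * np.log10(mag[(freqs > 3000) & (freqs < 5000)].max())
        low_db = 20 * np.log10(mag[(freqs > 100) & (freqs < 2000)].max())
        high_db = 20 * np.log10(mag[freqs > 6000].max())
        assert peak_db - low_db >= 30
        assert peak_db - high_db >= 30

    def test_passband_centered_at_4khz(self, clicks_signal):
        l, _ = clicks_signal.slice("T1")
        lo, hi = passband_edges(l, FS)
        assert (lo + hi) / 2 == pytest.approx(4000.0, abs=100.0)

    def test_iptd_beyond_interpulse_interval_rejected(self):
        with pytest.raises(ValueError):
            StimulusSpec(experiment="iptd_clicks", f_c=4000.0, f_m=320.0,
                         iptd_us=4000.0)

    def test_t4_is_silent(self, clicks_signal):
        l, r = clicks_signal.slice("T4")
        assert np.max(np.abs(l)) == 0.0 and np.max(np.abs(r)) == 0.0


class TestMaskingNoise:
    def test_slope_above_200hz_is_minus_3db_per_octave(self):
        slopes = [spectral_slope_db_per_octave(
            make_masking_noise(6.0, seed=s).left, FS) for s in range(1, 21)]
        assert np.mean(slopes) == pytest.approx(-3.0, abs=0.5)

    def test_flat_below_200hz(self):
        slopes = [spectral_slope_db_per_octave(
            make_masking_noise(6.0, seed=s).left, FS, f_lo=20.0, f_hi=200.0)
            for s in range(1, 11)]
        assert abs(np.mean(slopes)) < 0.5

    def test_ears_uncorrelated(self):
        n = make_masking_noise(2.0, seed=7)
        r = np.corrcoef(n.left, n.right)[0, 1]
        assert abs(r) < 0.1

    def test_level_35db_below_reference(self):
        n = make_masking_noise(6.0, seed=1, ref_level_dbfs=-20.0)
        rms_db = 20 * np.log10(np.sqrt(np.mean(n.left**2)))
        assert rms_db == pytest.approx(-55.0, abs=0.5)


class TestDeterminismAndRoundTrip:
    @pytest.mark.parametrize("spec", [
        StimulusSpec(),
        StimulusSpec(experiment="itdenv_sam", f_c=4000.0),
        StimulusSpec(experiment="iptd_clicks", f_c=4000.0, f_m=160.0),
    ], ids=["itdfs", "itdenv", "clicks"])
    def test_same_spec_bit_identical(self, spec):
        a = make_stimulus(spec)
        b = make_stimulus(spec)
        assert np.array_equal(a.left, b.left)
        assert np.array_equal(a.right, b.right)

    def test_noise_seeded(self):
        a = make_masking_noise(1.0, seed=3)
        b = make_masking_noise(1.0, seed=3)
        c = make_masking_noise(1.0, seed=4)
        assert np.array_equal(a.left, b.left)
        assert not np.array_equal(a.left, c.left)

    def test_lead_ear_flips_sign(self):
        left_leads = make_sam_itdenv(StimulusSpec(
            experiment="itdenv_sam", f_c=4000.0, lead_ear="left"))
        itd = measure_envelope_itd(left_leads, "T2")
        assert itd == pytest.approx(-500.0, abs=US_PER_SAMPLE)

    def test_wav_sidecar_round_trip(self, tmp_path, itdenv_signal):
        spec = StimulusSpec(experiment="itdenv_sam", f_c=4000.0)
        path = tmp_path / "stim.wav"
        write_wav(path, itdenv_signal, spec)
        sig, spec2 = read_wav(path)
        assert sig.fs == itdenv_signal.fs
        assert spec2.f_c == 4000.0
        assert np.allclose(sig.left, itdenv_signal.left, atol=1e-6)
        assert sig.annotations == itdenv_signal.annotations
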