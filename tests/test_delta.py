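"""Delta-wave segmentation, morphology formulas, band power, ERP, ROIs."""

import numpy as np
import pandas as pd
import pytest

from clasdelta import (DeltaWaveEvent, Recording, band_power, density,
                       erp_difference, roi_aggregate, segment_delta_waves,
                       wave_metrics)


class TestSegmentation:
    def test_sinusoid_yields_one_event_per_period(self, sine, fs):
        events = segment_delta_waves(sine(0.5, 100.0, 60.0), fs)
        assert len(events) in (29, 30)
        for ev in events[1:-1]:
            assert ev.d_s == pytest.approx(2.0, rel=0.01)

    def test_duration_gate_excludes_long_waves(self, fs):
        # an 11 s wave (5.5 s half-sines) embedded in silence is dropped
        def wave(total_s):
            half = int(round(total_s * fs / 2))
            t = np.arange(half) / fs
            h = np.sin(np.pi * t / (total_s / 2))
            return np.concatenate([-100 * h, 100 * h])

        pad = np.zeros(int(5 * fs))
        sig = np.concatenate([pad, wave(11.0), pad, wave(9.0), pad])
        events = segment_delta_waves(sig, fs, band=None)
        assert [round(e.d_s, 3) for e in events] == [9.0]

    def test_offset_signal_without_crossings_is_empty(self, fs):
        sig = 50.0 + 10.0 * np.sin(2 * np.pi * 0.5 *
                                   np.arange(int(30 * fs)) / fs)
        assert segment_delta_waves(sig, fs, band=None) == []

    def test_constant_signal_is_empty(self, fs):
        assert segment_delta_waves(np.zeros(10000), fs) == []
        assert segment_delta_waves(np.full(10000, 7.0), fs) == []

    def test_amplitude_gate_optional(self, sine, fs):
        sig = sine(0.5, 30.0, 60.0)
        assert segment_delta_waves(sig, fs, band=None) != []
        assert segment_delta_waves(sig, fs, band=None,
                                   min_amplitude_uv=75.0) == []

    def test_events_are_ordered_and_non_overlapping(
            self, clean_delta_recording):
        rec = clean_delta_recording
        events = segment_delta_waves(rec.data[0], rec.fs, band=None)
        for a, b in zip(events, events[1:]):
            assert a.t_zc3_s <= b.t_zc1_s + 1e-9


class TestWaveMetrics:
    def test_amplitude_is_absolute_extremum_difference(self):
        ev = DeltaWaveEvent(0.0, 0.3, 0.8, 1.2, -60.0, 50.0)
        assert wave_metrics(ev).amplitude_uv == pytest.approx(110.0)

    def test_frequency_is_inverse_duration(self):
        ev = DeltaWaveEvent(0.0, 0.3, 0.9, 1.25, -80.0, 70.0)
        assert wave_metrics(ev).frequency_hz == pytest.approx(0.8)

    def test_closed_form_sine_identities(self):
        """For a 1 Hz +-100 uV sine wave: A=200, F=1, slopes=400, Ftrans=1."""
        ev = DeltaWaveEvent(0.0, 0.25, 0.75, 1.0, -100.0, 100.0)
        m = wave_metrics(ev)
        assert m.amplitude_uv == pytest.approx(200.0)
        assert m.frequency_hz == pytest.approx(1.0)
        assert m.slope_zc_e1 == pytest.approx(400.0)
        assert m.slope_e1_e2 == pytest.approx(400.0)
        assert m.slope_e2_zc == pytest.approx(400.0)
        assert m.f_trans_hz == pytest.approx(1.0)

    def test_segmented_sine_matches_closed_form(self, sine, fs):
        """End-to-end: segment a pure sinusoid, check all identities <1%."""
        freq, amp = 0.5, 100.0
        events = segment_delta_waves(sine(freq, amp, 120.0), fs)
        for ev in events[2:-2]:  # exclude filter edge effects
            m = wave_metrics(ev)
            assert m.amplitude_uv == pytest.approx(2 * amp, rel=0.01)
            assert m.frequency_hz == pytest.approx(freq, rel=0.01)
            assert m.f_trans_hz == pytest.approx(freq, rel=0.01)
            for slope in (m.slope_zc_e1, m.slope_e1_e2, m.slope_e2_zc):
                assert slope == pytest.approx(4 * amp * freq, rel=0.01)

    def test_degenerate_event_rejected(self):
        with pytest.raises(ValueError, match="ordered"):
            DeltaWaveEvent(0.0, 0.5, 0.5, 1.0, -50.0, 50.0)


class TestDensity:
    def test_event_rate(self):
        assert density(list(range(120)), 180.0) == pytest.approx(2.0 / 3.0,
                                                                 abs=1e-4)
        assert density([], 180.0) == 0.0

    def test_density_conserves_count(self):
        events = list(range(37))
        assert density(events, 100.0) * 100.0 == len(events)

    def test_matches_generator_truth(self, clean_delta_recording):
        rec = clean_delta_recording
        events = segment_delta_waves(rec.data[0], rec.fs, band=None)
        truth_density = len(rec.ground_truth) / rec.duration_s
        assert density(events, rec.duration_s) == pytest.approx(
            truth_density, rel=0.02)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            density([], 0.0)


class TestBandPower:
    def test_pure_tone_concentrates_in_its_band(self, sine, fs):
        rec = Recording(sine(2.0, 50.0, 60.0)[None], fs, ["a"])
        bp = band_power(rec)
        total = bp.loc["a"].sum()
        assert bp.loc["a", "delta"] / total > 0.95

    def test_white_noise_power_proportional_to_bandwidth(self, fs):
        rng = np.random.default_rng(0)
        rec = Recording(rng.standard_normal((1, int(120 * fs))), fs, ["a"])
        bp = band_power(rec)
        for name, (lo, hi) in [("theta", (4, 8)), ("alpha", (8, 13)),
                               ("beta", (13, 30))]:
            ratio = bp.loc["a", name] / bp.loc["a", "theta"]
            assert ratio == pytest.approx((hi - lo) / 4.0, rel=0.1)

    def test_zero_signal_zero_power(self, fs):
        rec = Recording(np.zeros((2, int(30 * fs))), fs, ["a", "b"])
        assert (band_power(rec).to_numpy() == 0).all()

    def test_short_segment_drops_unresolvable_band(self, fs):
        rec = Recording(np.random.default_rng(1).standard_normal(
            (1, int(5 * fs))), fs, ["a"])
        with pytest.warns(UserWarning, match="delta"):
            bp = band_power(rec)
        assert "delta" not in bp.columns


class TestErpDifference:
    def test_null_case_difference_is_small(self, fs):
        rng = np.random.default_rng(7)
        rec = Recording(rng.standard_normal((2, int(600 * fs) // 2)), fs,
                        ["a", "b"])
        starts = rng.integers(int(fs), rec.n_samples - int(fs), 400)
        diff, info = erp_difference(rec, list(starts[:200]),
                                    list(starts[200:]))
        sem = np.sqrt(2.0 / 200)  # unit-variance white noise epochs
        assert np.abs(diff).max() < 5 * sem

    def test_injected_evoked_bump_recovered(self, fs):
        rng = np.random.default_rng(8)
        n = int(300 * fs)
        data = rng.standard_normal((1, n))
        bump = 5.0 * np.hanning(int(0.2 * fs))
        stim = rng.choice(np.arange(int(fs), n - int(2 * fs), int(1.5 * fs)),
                          size=150, replace=False)
        sham = stim + int(0.7 * fs)
        for s in stim:
            data[0, s:s + bump.size] += bump
        rec = Recording(data, fs, ["a"])
        diff, info = erp_difference(rec, list(stim), list(sham))
        onset = int(0.5 * fs)
        assert diff[0, onset:onset + bump.size].max() == pytest.approx(
            5.0, rel=0.1)

    def test_single_epoch_each_is_exact_difference(self, fs):
        rng = np.random.default_rng(9)
        rec = Recording(rng.standard_normal((1, int(10 * fs))), fs, ["a"])
        diff, _ = erp_difference(rec, [int(2 * fs)], [int(6 * fs)])
        w0, w1 = int(-0.5 * fs), int(1.0 * fs)
        expected = (rec.data[:, int(2 * fs) + w0:int(2 * fs) + w1]
                    - rec.data[:, int(6 * fs) + w0:int(6 * fs) + w1])
        assert np.allclose(diff, expected)

    def test_out_of_bounds_epochs_dropped_and_counted(self, fs):
        rec = Recording(np.zeros((1, int(10 * fs))), fs, ["a"])
        diff, info = erp_difference(rec, [5, int(5 * fs)], [int(6 * fs)])
        assert info["n_stim"] == 1 and info["n_dropped_stim"] == 1

    def test_no_usable_epochs_rejected(self, fs):
        rec = Recording(np.zeros((1, int(2 * fs))), fs, ["a"])
        with pytest.raises(ValueError, match="no usable epochs"):
            erp_difference(rec, [0], [0])


class TestRoiAggregate:
    def test_single_roi_equals_grand_mean(self):
        tab = pd.DataFrame({"delta": [1.0, 2.0, 3.0]},
                           index=["a", "b", "c"])
        out = roi_aggregate(tab, {"a": "all", "b": "all", "c": "all"})
        assert out.loc["all", "delta"] == pytest.approx(2.0)

    def test_disjoint_rois_recombine_to_grand_mean(self):
        tab = pd.DataFrame({"p": [1.0, 3.0, 5.0, 7.0]},
                           index=list("abcd"))
        out = roi_aggregate(tab, {"a": "front", "b": "front", "c": "back",
                                  "d": "back"})
        grand = (2 * out.loc["front", "p"] + 2 * out.loc["back", "p"]) / 4
        assert grand == pytest.approx(tab["p"].mean())

    def test_frontal_gradient_orders_roi_power(self):
        from clasdelta import SynthConfig, make_delta_eeg

        rec = make_delta_eeg(SynthConfig(
            n_channels=4, duration_s=60.0, seed=6,
            frontal_gradient=(1.0, 0.9, 0.3, 0.2)))
        bp = band_power(rec)
        roi = roi_aggregate(bp, {"ch000": "frontal", "ch001": "frontal",
                                 "ch002": "occipital", "ch003": "occipital"})
        assert roi.loc["frontal", "delta"] > roi.loc["occipital", "delta"]

    def test_unmapped_channels_counted(self):
        tab = pd.DataFrame({"x": [1.0, 2.0]}, index=["a", "b"])
        out = roi_aggregate(tab, {"a": "roi"})
        assert out.attrs["n_unmapped"] == 1

    def test_empty_roi_warns_and_is_absent(self):
        tab = pd.DataFrame({"x": [1.0]}, index=["a"])
        with pytest.warns(UserWarning, match="no member"):
            out = roi_aggregate(tab, {"a": "roi", "zz": "ghost"})
        assert "ghost" not in out.index
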