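"""Synthetic waveform generation and CSV round-tripping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coroflow import (Waveform, WaveformSpec, cycle_mean, read_waveform_csv,
                      synth_waveform, write_waveform_csv)
from coroflow.waveforms import WaveformError


class TestSynthesis:
    def test_flat_spec_gives_constant_series(self):
        w = synth_waveform(WaveformSpec(mean=100.0, pulse_amplitude=0.0,
                                        noise_sd=0.0))
        assert np.allclose(w.values, 100.0)

    def test_default_grid_has_17_samples(self):
        # 0.8 s cycle at 0.05 s steps: 16 intervals, both endpoints
        w = synth_waveform(WaveformSpec(period=0.8), dt=0.05)
        assert len(w.times) == 17

    def test_cycle_mean_preserved(self):
        w = synth_waveform(WaveformSpec(mean=100.0, pulse_amplitude=20.0,
                                        noise_sd=0.0))
        assert cycle_mean(w) == pytest.approx(100.0, rel=1e-3)

    def test_single_dominant_systolic_peak(self):
        w = synth_waveform(WaveformSpec(mean=100.0, pulse_amplitude=40.0),
                           dt=0.01)
        v = w.values[:-1]
        peaks = [i for i in range(len(v))
                 if v[i] > v[i - 1] and v[i] > v[(i + 1) % len(v)]
                 and v[i] > np.mean(v) + 0.25 * np.ptp(v)]
        assert len(peaks) == 1

    def test_determinism_for_fixed_seed(self):
        spec = WaveformSpec(noise_sd=2.0, seed=42)
        assert np.array_equal(synth_waveform(spec).values,
                              synth_waveform(spec).values)
        other = WaveformSpec(noise_sd=2.0, seed=43)
        assert not np.array_equal(synth_waveform(spec).values,
                                  synth_waveform(other).values)

    def test_velocity_is_clipped_nonnegative(self):
        spec = WaveformSpec(kind="velocity", mean=0.05, pulse_amplitude=0.3,
                            noise_sd=0.0)
        w = synth_waveform(spec)
        assert np.all(w.values >= 0)

    def test_dt_not_dividing_period_rejected(self):
        with pytest.raises(WaveformError, match="divide"):
            synth_waveform(WaveformSpec(period=0.8), dt=0.07)

    def test_dt_at_least_period_rejected(self):
        with pytest.raises(WaveformError):
            synth_waveform(WaveformSpec(period=0.8), dt=0.8)

    @given(mean=st.floats(50.0, 150.0), amp=st.floats(0.0, 60.0),
           period=st.sampled_from([0.6, 0.8, 1.0]))
    @settings(max_examples=30, deadline=None)
    def test_mean_preservation_property(self, mean, amp, period):
        spec = WaveformSpec(mean=mean, pulse_amplitude=amp, period=period,
                            noise_sd=0.0)
        w = synth_waveform(spec, dt=period / 20)
        assert cycle_mean(w) == pytest.approx(mean, rel=1e-3)

    def test_resampling_stability_of_cycle_mean(self):
        spec = WaveformSpec(mean=100.0, pulse_amplitude=40.0, noise_sd=0.0)
        coarse = synth_waveform(spec, dt=0.05)
        fine = synth_waveform(spec, dt=0.025)
        assert cycle_mean(fine) == pytest.approx(cycle_mean(coarse),
                                                 rel=5e-3)


class TestCycleMean:
    def test_constant(self):
        w = Waveform(np.array([0.0, 0.4, 0.8]), np.array([100.0] * 3), 0.8)
        assert cycle_mean(w) == pytest.approx(100.0)

    def test_sawtooth_symmetry(self):
        w = Waveform(np.array([0.0, 0.4, 0.8]),
                     np.array([90.0, 110.0, 90.0]), 0.8)
        assert cycle_mean(w) == pytest.approx(100.0)


class TestCsvIO:
    def test_round_trip_is_lossless(self, tmp_path):
        w = synth_waveform(WaveformSpec(mean=100.0, pulse_amplitude=40.0,
                                        noise_sd=1.0, seed=7))
        path = tmp_path / "w.csv"
        write_waveform_csv(w, path)
        back = read_waveform_csv(path)
        assert np.allclose(back.values, w.values, rtol=1e-12)
        assert back.period == pytest.approx(w.period, rel=1e-12)

    def test_period_inferred_from_grid(self, tmp_path):
        path = tmp_path / "w.csv"
        lines = ["time_s,value"] + [
            f"{0.05 * i:.2f},{100 + i}" for i in range(17)]
        path.write_text("\n".join(lines) + "\n")
        assert read_waveform_csv(path).period == pytest.approx(0.8)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0.0,100\n0.05,101\n")
        with pytest.raises(WaveformError, match="header"):
            read_waveform_csv(path)

    def test_negative_velocity_rejected(self, tmp_path):
        path = tmp_path / "v.csv"
        path.write_text("time_s,value\n0.0,0.1\n0.05,-0.1\n0.1,0.1\n")
        with pytest.raises(WaveformError, match="negative"):
            read_waveform_csv(path, kind="velocity")

    def test_non_monotone_times_rejected(self, tmp_path):
        path = tmp_path / "t.csv"
        path.write_text("time_s,value\n0.0,1\n0.1,2\n0.05,3\n")
        with pytest.raises(WaveformError, match="increasing"):
            read_waveform_csv(path)
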