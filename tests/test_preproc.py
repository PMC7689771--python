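"""Referencing, broadband filtering, epoching, interpolation and the
alpha filter-Hilbert transform."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mwdecode.dipole import potential_at_electrodes
from mwdecode.preproc import (ContinuousRecording, EpochSet, alpha_power,
                              broadband_filter_and_resample, design_alpha_fir,
                              epoch_and_baseline, interpolate_bad_channel,
                              rereference)


def _recording(data, labels=None, rate=512.0, events=None):
    labels = labels or tuple(f"ch{i}" for i in range(data.shape[0]))
    return ContinuousRecording(rate=rate, data=np.asarray(data, float),
                               labels=labels,
                               events=events if events is not None
                               else pd.DataFrame())


class TestRereference:
    def test_zero_data_unchanged_and_mastoids_dropped(self):
        rec = _recording(np.zeros((4, 100)), ("a", "b", "M1", "M2"))
        out = rereference(rec)
        assert out.labels == ("a", "b")
        assert np.all(out.data == 0)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(st.floats(-1e3, 1e3, allow_nan=False))
    def test_common_mode_rejected(self, c):
        rng = np.random.default_rng(0)
        base = rng.normal(size=(4, 50))
        rec = _recording(base, ("a", "b", "M1", "M2"))
        out = rereference(rec)
        out_shift = rereference(_recording(base + c, ("a", "b", "M1", "M2")))
        assert np.allclose(out.data, out_shift.data, atol=1e-9)

    def test_hand_computed_subtraction(self):
        data = np.array([[4.0], [8.0], [2.0], [6.0]])
        rec = _recording(data, ("a", "b", "M1", "M2"))
        out = rereference(rec)
        # mastoid mean = 4 -> a: 0, b: 4
        assert np.allclose(out.data[:, 0], [0.0, 4.0])

    def test_missing_reference_raises(self):
        rec = _recording(np.zeros((2, 10)), ("a", "M1"))
        with pytest.raises(ValueError):
            rereference(rec)


class TestBroadbandFilter:
    def _sine(self, f, rate=512.0, dur=8.0, n_ch=2):
        t = np.arange(int(dur * rate)) / rate
        return _recording(np.tile(np.sin(2 * np.pi * f * t), (n_ch, 1)),
                          rate=rate)

    def test_50hz_attenuated(self):
        rec = self._sine(50.0)
        out = broadband_filter_and_resample(rec)
        mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
        assert np.sqrt((out.data[0, mid] ** 2).mean()) < 0.1 * np.sqrt(0.5)

    def test_10hz_passes_unit_gain(self):
        rec = self._sine(10.0)
        out = broadband_filter_and_resample(rec)
        mid = slice(out.n_samples // 4, 3 * out.n_samples // 4)
        amp = np.sqrt(2.0 * (out.data[0, mid] ** 2).mean())
        assert 0.95 <= amp <= 1.05

    def test_decimation_by_two(self):
        rec = self._sine(10.0)
        out = broadband_filter_and_resample(rec)
        assert out.rate == 256.0
        assert out.n_samples == rec.n_samples // 2

    def test_event_samples_rescaled(self):
        rec = self._sine(10.0)
        rec.events = pd.DataFrame({"onset_sample": [1000, 2000]})
        out = broadband_filter_and_resample(rec)
        assert out.events["onset_sample"].tolist() == [500, 1000]

    def test_wrong_rate_rejected(self):
        rec = self._sine(10.0, rate=256.0)
        with pytest.raises(ValueError):
            broadband_filter_and_resample(rec)


class TestEpoching:
    def _rec_with_events(self, onsets, n=6000, rate=256.0):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(3, n))
        ev = pd.DataFrame({"onset_sample": onsets})
        return _recording(data, rate=rate, events=ev)

    def test_index_arithmetic(self):
        rec = self._rec_with_events([1500])
        ep = epoch_and_baseline(rec)
        raw = rec.data[:, 1500 - 256:1500 + 768]
        bl = raw[:, 205:256].mean(axis=1, keepdims=True)
        assert ep.data.shape == (1, 3, 1024)
        assert np.allclose(ep.data[0], raw - bl, atol=1e-9)
        assert np.isclose(ep.times[0], -1.0)
        assert ep.times[-1] < 3.0

    def test_baseline_mean_zero_and_idempotent(self):
        rec = self._rec_with_events([1000, 2500, 4000])
        ep = epoch_and_baseline(rec)
        mask = (ep.times >= -0.2) & (ep.times < 0.0)
        assert np.allclose(ep.data[:, :, mask].mean(axis=2), 0.0, atol=1e-9)
        # re-applying the baseline subtraction changes nothing
        again = ep.data - ep.data[:, :, mask].mean(axis=2, keepdims=True)
        assert np.allclose(again, ep.data, atol=1e-12)

    def test_constant_signal_gives_zero_epochs(self):
        rec = _recording(np.full((2, 4000), 7.7), rate=256.0,
                         events=pd.DataFrame({"onset_sample": [2000]}))
        ep = epoch_and_baseline(rec)
        assert np.allclose(ep.data, 0.0, atol=1e-9)

    def test_edge_trials_dropped(self):
        rec = self._rec_with_events([100, 3000, 5900])
        ep = epoch_and_baseline(rec)
        assert ep.n_trials == 1
        assert ep.metadata["onset_sample"].tolist() == [3000]

    def test_empty_events_rejected(self):
        rec = self._rec_with_events([])
        with pytest.raises(ValueError):
            epoch_and_baseline(rec)


class TestBadChannelInterpolation:
    def _epochs(self, data, labels, rate=256.0):
        t = np.arange(data.shape[2]) / rate - 1.0
        meta = pd.DataFrame({"trial": range(data.shape[0])})
        return EpochSet(data=data, times=t, labels=labels, metadata=meta,
                        rate=rate)

    def test_constant_field_reproduced(self, montage):
        labels = montage.analysis_labels
        data = np.full((2, 32, 64), 3.5)
        ep = self._epochs(data, labels)
        out = interpolate_bad_channel(ep, "Cz", montage)
        assert np.allclose(out.data[:, labels.index("Cz"), :], 3.5, atol=1e-6)

    def test_smooth_dipolar_field_reconstructed(self, montage, head_model):
        labels = montage.analysis_labels
        topo = potential_at_electrodes([0.02, -0.03, 0.035],
                                       [1e-8, 1e-8, 2e-8], head_model,
                                       montage.analysis_positions)
        topo = 1e6 * topo  # to uV-ish scale
        data = np.tile(topo[None, :, None], (1, 1, 16))
        ep = self._epochs(data.copy(), labels)
        bad = "P3"
        corrupted = ep.data.copy()
        corrupted[:, labels.index(bad), :] = 999.0
        out = interpolate_bad_channel(self._epochs(corrupted, labels), bad,
                                      montage)
        err = np.abs(out.data[0, labels.index(bad), 0] - topo[labels.index(bad)])
        assert err < 0.15 * np.sqrt((topo ** 2).mean())

    def test_clean_channel_barely_changes(self, montage, head_model):
        labels = montage.analysis_labels
        topo = 1e6 * potential_at_electrodes([0.0, -0.02, 0.015],
                                             [0, 1e-8, 2e-8], head_model,
                                             montage.analysis_positions)
        data = np.tile(topo[None, :, None], (1, 1, 8))
        ep = self._epochs(data.copy(), labels)
        out = interpolate_bad_channel(ep, "Pz", montage)
        err = np.abs(out.data[0, labels.index("Pz"), 0] - topo[labels.index("Pz")])
        assert err < 0.15 * np.sqrt((topo ** 2).mean())

    def test_too_few_channels_rejected(self, montage):
        ep = self._epochs(np.zeros((1, 3, 8)), ("Cz", "Pz", "Fz"))
        with pytest.raises(ValueError):
            interpolate_bad_channel(ep, "Cz", montage)


class TestAlphaKernel:
    def test_symmetric_linear_phase(self):
        k = design_alpha_fir(256.0)
        assert len(k) % 2 == 1
        assert np.allclose(k.coefficients, k.coefficients[::-1], atol=1e-15)

    def test_length_covers_three_cycles_of_lowest_frequency(self):
        k = design_alpha_fir(256.0)
        assert len(k) >= 3 * 256.0 / 8.5
        assert len(k) == 91

    def test_design_sse_matches_printed_value(self):
        k = design_alpha_fir(256.0)
        # one significant figure
        assert float(f"{k.design_sse:.1g}") == 0.1

    def test_realized_gains(self):
        k = design_alpha_fir(256.0)
        g10 = k.frequency_response(10.0)[0]
        g2 = k.frequency_response(2.0)[0]
        assert 0.95 <= g10 <= 1.05
        assert g2 <= 0.05


class TestAlphaPower:
    def _epochs(self, signals, rate=256.0):
        # signals: (trials, channels, samples)
        t = np.arange(signals.shape[2]) / rate - 1.0
        meta = pd.DataFrame({"trial": range(signals.shape[0])})
        return EpochSet(data=signals, times=t,
                        labels=tuple(f"c{i}" for i in range(signals.shape[1])),
                        metadata=meta, rate=rate)

    def test_zero_input_zero_power(self):
        ep = self._epochs(np.zeros((1, 2, 1024)))
        k = design_alpha_fir(256.0)
        _, power = alpha_power(ep, k)
        assert np.allclose(power.data, 0.0)

    def test_unit_alpha_sinusoid_power_one(self):
        t = np.arange(1024) / 256.0
        sig = np.sin(2 * np.pi * 10.0 * t)[None, None, :]
        ep = self._epochs(sig)
        k = design_alpha_fir(256.0)
        _, power = alpha_power(ep, k)
        mid = slice(256, 768)  # middle 50%
        assert np.all(np.abs(power.data[0, 0, mid] - 1.0) < 0.05)

    @pytest.mark.parametrize("freq", [4.0, 20.0])
    def test_out_of_band_suppressed(self, freq):
        t = np.arange(1024) / 256.0
        sig = np.sin(2 * np.pi * freq * t)[None, None, :]
        ep = self._epochs(sig)
        k = design_alpha_fir(256.0)
        _, power = alpha_power(ep, k)
        mid = slice(256, 768)
        assert np.all(power.data[0, 0, mid] < 0.01)

    def test_amplitude_ramp_squares_to_power(self):
        t = np.arange(1024) / 256.0
        amp = 1.0 + t / t[-1]  # 1 -> 2
        sig = (amp * np.sin(2 * np.pi * 10.0 * t))[None, None, :]
        ep = self._epochs(sig)
        k = design_alpha_fir(256.0)
        _, power = alpha_power(ep, k)
        mid = slice(256, 768)
        expected = amp[mid] ** 2
        assert np.all(np.abs(power.data[0, 0, mid] / expected - 1.0) < 0.10)

    def test_oscillation_is_band_passed_real_part(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=(2, 3, 1024))
        ep = self._epochs(sig)
        k = design_alpha_fir(256.0)
        osc, power = alpha_power(ep, k)
        assert np.all(power.data >= 0)
        # power is the squared envelope: it upper-bounds the oscillation
        assert np.all(power.data - osc.data ** 2 >= -1e-9)

    def test_kernel_longer_than_epoch_rejected(self):
        ep = self._epochs(np.zeros((1, 1, 64)))
        k = design_alpha_fir(256.0)
        with pytest.raises(ValueError):
            alpha_power(ep, k)
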