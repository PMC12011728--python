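"""Filtering, epoching, baseline, channel QC and artifact-rejection contracts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import signal

from minf import (
    ChannelQCConfig,
    EpochSet,
    FilterSpec,
    artifact_mask,
    baseline_correct,
    detect_bad_channels,
    epoch_data,
    fir_filter,
    prepare_reference,
)
from minf.preprocessing import (
    NF_BANDPASS,
    OFFLINE_HIGHPASS,
    OFFLINE_LOWPASS,
    QCError,
    filter_array,
    frequency_response,
    moving_std,
)
from minf.simulate import ContinuousRecording, equidistant_layout

FS = 500.0


def make_recording(data, events=None):
    n = data.shape[0]
    labels, pos = equidistant_layout(n)
    if events is None:
        events = pd.DataFrame(
            columns=["onset_sample", "hand", "run", "block", "trial_index"])
    return ContinuousRecording(data=data, fs=FS, channel_labels=labels,
                               channel_positions=pos, events=events)


def make_epochs(data, labels=None, t0=-7.0, fs=FS):
    n_tr, n_ch, n_s = data.shape
    ch_labels, pos = equidistant_layout(n_ch)
    if labels is None:
        labels = np.array(["left", "right"] * (n_tr // 2 + 1))[:n_tr]
    return EpochSet(
        data=data, times=t0 + np.arange(n_s) / fs,
        labels=np.asarray(labels, dtype=object),
        runs=np.array(["T"] * n_tr, dtype=object),
        blocks=np.ones(n_tr, int), trial_index=np.arange(n_tr),
        fs=fs, channel_labels=ch_labels, channel_positions=pos,
    )


class TestFilters:
    def test_highpass_rejects_dc(self):
        x = np.ones((1, 10_000))
        y = filter_array(x, OFFLINE_HIGHPASS, FS)
        assert np.abs(y[0, 2000:-2000]).max() < 0.01

    def test_10hz_passband_unity_gain(self):
        t = np.arange(30_000) / FS
        x = np.sin(2 * np.pi * 10 * t)[None, :]
        y = filter_array(filter_array(x, OFFLINE_HIGHPASS, FS),
                         OFFLINE_LOWPASS, FS)
        steady = y[0, 5000:-5000]
        assert steady.max() == pytest.approx(1.0, abs=0.05)
        # design-level oracle: response of the chain evaluated at 10 Hz
        h = (frequency_response(OFFLINE_HIGHPASS, FS, np.array([10.0]))
             * frequency_response(OFFLINE_LOWPASS, FS, np.array([10.0])))
        assert h[0] == pytest.approx(1.0, abs=0.05)

    def test_band_edges_at_8_and_30(self):
        # -6 dB points of the zero-phase FIR chain within +-1 Hz of 8 / 30
        freqs = np.linspace(0.5, 60, 2000)
        h = (frequency_response(OFFLINE_HIGHPASS, FS, freqs)
             * frequency_response(OFFLINE_LOWPASS, FS, freqs))
        half = h >= 0.25  # zero-phase doubles dB: amplitude^2 >= -6 dB
        lo, hi = freqs[half][0], freqs[half][-1]
        assert lo == pytest.approx(8.0, abs=1.0)
        assert hi == pytest.approx(30.0, abs=1.0)

    def test_butterworth_bandpass_passes_midband(self):
        t = np.arange(20_000) / FS
        x = np.sin(2 * np.pi * 15 * t)[None, :]
        y = filter_array(x, NF_BANDPASS, FS)
        assert y[0, 5000:].max() == pytest.approx(1.0, abs=0.05)

    def test_linearity(self, rng):
        x = rng.standard_normal((2, 4000))
        y = rng.standard_normal((2, 4000))
        lhs = filter_array(3.0 * x + 0.5 * y, OFFLINE_LOWPASS, FS)
        rhs = 3.0 * filter_array(x, OFFLINE_LOWPASS, FS) \
            + 0.5 * filter_array(y, OFFLINE_LOWPASS, FS)
        assert np.allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_zero_phase_has_no_group_delay(self):
        t = np.arange(20_000) / FS
        x = np.sin(2 * np.pi * 12 * t)[None, :]
        y = filter_array(x, OFFLINE_LOWPASS, FS)
        xc = signal.correlate(y[0, 5000:15000], x[0, 5000:15000], mode="full")
        lag = np.argmax(xc) - (10000 - 1)
        assert lag == 0

    def test_causal_mode_documents_group_delay(self, rng):
        spec = dataclasses.replace(OFFLINE_LOWPASS, mode="causal")
        assert spec.group_delay_samples == 110.0
        x = rng.standard_normal((1, 20_000))  # broadband probe
        y = filter_array(x, spec, FS)
        xc = signal.correlate(y[0, 5000:15000], x[0, 5000:15000], mode="full")
        lag = np.argmax(xc) - (10000 - 1)
        assert lag == pytest.approx(spec.group_delay_samples, abs=1)

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            filter_array(np.zeros((1, 100)), FilterSpec("fir-lowpass", 300.0, 10), FS)


class TestEpoching:
    def test_window_sample_count(self, small_recording):
        ep = epoch_data(small_recording, small_recording.events, (-7.0, 9.0))
        assert ep.data.shape[2] == 8000  # 16 s at 500 Hz

    def test_no_events_gives_empty_set(self, small_recording):
        empty = small_recording.events.iloc[0:0]
        ep = epoch_data(small_recording, empty, (-7.0, 9.0))
        assert ep.n_trials == 0 and ep.n_dropped == 0

    def test_out_of_bounds_event_dropped_and_counted(self):
        data = np.zeros((4, 5000))
        events = pd.DataFrame(dict(onset_sample=[3600, 4500],
                                   hand=["left", "right"], run=["T", "T"],
                                   block=[1, 1], trial_index=[0, 1]))
        rec = make_recording(data, events)
        ep = epoch_data(rec, events, (-7.0, 9.0))  # needs 4500 samples after
        assert ep.n_trials == 0 and ep.n_dropped == 2
        ep2 = epoch_data(rec, events, (-1.0, 1.0))
        assert ep2.n_trials == 2

    def test_bookkeeping_conserves_trials(self, band_epochs, small_config):
        scheduled = small_config.n_trials_per_run
        assert band_epochs.n_trials + band_epochs.n_dropped == scheduled

    def test_non_grid_window_rejected(self, small_recording):
        with pytest.raises(ValueError):
            epoch_data(small_recording, small_recording.events, (-7.0001, 9.0))


class TestBaseline:
    def test_mean_over_interval_is_zero(self, band_epochs):
        out = baseline_correct(band_epochs, (-6.0, -4.0))
        sl = out.sample_slice((-6.0, -4.0))
        means = out.data[:, :, sl].mean(axis=2)
        assert np.abs(means).max() < 1e-9 * np.abs(out.data).max()

    def test_idempotent(self, band_epochs):
        once = baseline_correct(band_epochs, (-6.0, -4.0))
        twice = baseline_correct(once, (-6.0, -4.0))
        assert np.allclose(once.data, twice.data)

    def test_constant_offset_removed_exactly(self):
        ep = make_epochs(np.full((2, 3, 1000), 5.0), t0=-1.0)
        out = baseline_correct(ep, (-0.5, 0.0))
        assert np.allclose(out.data, 0.0)

    def test_interval_outside_window_rejected(self, band_epochs):
        with pytest.raises(ValueError):
            baseline_correct(band_epochs, (-20.0, -10.0))


class TestChannelQC:
    def test_identical_noise_level_passes(self, rng):
        row = rng.standard_normal(5000)
        signs = (-1.0) ** np.arange(8)
        rec = make_recording(np.outer(signs, row))  # equal SD on every channel
        assert detect_bad_channels(rec) == []

    def test_outlier_channel_flagged(self, rng):
        data = rng.standard_normal((8, 5000))
        data[5] *= 10.0
        rec = make_recording(data)
        bad = detect_bad_channels(rec)
        assert bad == [rec.channel_labels[5]]
        # SD oracle
        sds = data.std(axis=1)
        assert sds[5] > sds.mean() + 2 * sds.std()

    def test_typical_simulated_session_flags_few(self, small_recording):
        bad = detect_bad_channels(small_recording)
        assert 0 <= len(bad) <= 3

    def test_car_zero_mean_and_idempotent(self, band_epochs):
        out = prepare_reference(band_epochs, [])
        sums = out.data.mean(axis=1)
        assert np.abs(sums).max() < 1e-9 * np.abs(out.data).max()
        again = prepare_reference(out, [])
        assert np.allclose(out.data, again.data)

    def test_interpolation_matches_hand_computed_weights(self):
        # 4-channel toy: interpolate channel 0 from its neighbors
        data = np.zeros((1, 4, 100))
        data[0, 1], data[0, 2], data[0, 3] = 1.0, 2.0, 4.0
        ep = make_epochs(data, labels=["left"], t0=0.0)
        pos = ep.channel_positions
        out = prepare_reference(ep, [ep.channel_labels[0]])
        d = np.linalg.norm(pos[1:] - pos[0], axis=1)
        w = (1 / d) / (1 / d).sum()
        expected_interp = w @ np.array([1.0, 2.0, 4.0])
        # CAR afterwards subtracts the common average of all 4 channels
        car = (expected_interp + 1 + 2 + 4) / 4
        assert out.data[0, 0, 0] == pytest.approx(expected_interp - car, rel=1e-9)

    def test_too_many_bad_channels_aborts(self, band_epochs):
        bad = band_epochs.channel_labels[:8]  # 8/16 = 50% > 25%
        with pytest.raises(QCError):
            prepare_reference(band_epochs, bad)


class TestArtifactMask:
    def test_constant_signal_not_rejected(self):
        ep = make_epochs(np.ones((3, 2, 2000)), t0=0.0)
        flagged = artifact_mask(ep, method="msd")
        assert not flagged.any()

    def test_burst_flagged_by_msd(self, rng):
        # trial 1 carries a 1-s burst of 5x variance
        data = rng.standard_normal((3, 2, 4000))
        data[1, 0, 1000:1500] *= 5.0
        ep = make_epochs(data, t0=0.0)
        flagged = artifact_mask(ep, ChannelQCConfig(), method="msd")
        assert flagged[1] and not flagged[0] and not flagged[2]
        # moving-SD oracle on the constructed trace
        msd = moving_std(data[1, 0][None, :], 250)[0]
        assert msd.max() > 2.5 * data[1, 0].std()

    def test_named_preset_matches_rule(self):
        qc = ChannelQCConfig()
        assert qc.msd_window == 250 and qc.msd_factor == 2.5

    def test_amplitude_mode(self, rng):
        data = rng.standard_normal((2, 2, 1000))
        data[0, 1, 500] = 500.0
        ep = make_epochs(data, t0=0.0)
        flagged = artifact_mask(ep, ChannelQCConfig(amp_threshold=100.0),
                                method="amplitude")
        assert flagged[0] and not flagged[1]
        assert ep.rejected[0] and ep.reject_reason[0] == "amplitude"

    def test_rejected_trials_tracked_with_reason(self, rng):
        data = rng.standard_normal((2, 1, 3000))
        data[0, 0, 100:350] *= 6.0
        ep = make_epochs(data, t0=0.0)
        artifact_mask(ep, method="msd")
        assert ep.rejected[0] and "msd" in ep.reject_reason[0]
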