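"""EMG preprocessing: filtering, epoching, rejection, envelopes,
z-normalization, window means, difference scores."""

import numpy as np
import pandas as pd
import pytest

from vocalsmile import emg
from vocalsmile.behavior import SMILE_C, SMILING_F, UNSMILE_C, UNSMILING_F
from vocalsmile.emg import (AnalysisWindows, EMGRecording, Envelope, Epochs,
                            PipelineConfig, bandpass, bandpass_array,
                            detect_artifacts, difference_scores, envelope,
                            envelope_array, epoch, epoch_times,
                            process_epochs, window_mask, window_means,
                            znormalize, znormalize_array)

FS = 1024.0


def _recording(n_events=10, spacing_ms=6000.0, length_extra_s=8.0,
               seed=0, onset0_ms=1500.0):
    rng = np.random.default_rng(seed)
    onsets = onset0_ms + np.arange(n_events) * spacing_ms
    n = int((onsets[-1] / 1000.0 + length_extra_s) * FS)
    events = pd.DataFrame({
        "onset_ms": onsets,
        "sentence_id": np.arange(n_events),
        "filter": [SMILING_F, UNSMILING_F] * (n_events // 2),
        "choice": [SMILE_C, UNSMILE_C] * (n_events // 2),
    })
    channels = {m: rng.normal(size=n) for m in emg.MUSCLES}
    return EMGRecording(FS, channels, events)


class TestBandpass:
    def test_dc_is_removed(self):
        rec = _recording(2)
        rec.channels = {m: np.full_like(v, 7.5)
                        for m, v in rec.channels.items()}
        out = bandpass(rec)
        assert np.max(np.abs(out.channels["zm"])) < 1e-6 * 7.5

    def test_passband_tone_preserved(self):
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 150.0 * t)
        y = bandpass_array(x, FS)
        mid = slice(2000, -2000)
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_tone_attenuated(self):
        t = np.arange(int(8 * FS)) / FS
        x = np.sin(2 * np.pi * 10.0 * t)
        y = bandpass_array(x, FS)
        atten_db = 20 * np.log10(np.abs(y[2000:-2000]).max())
        assert atten_db <= -20.0

    def test_sampling_rate_guard(self):
        with pytest.raises(ValueError):
            bandpass_array(np.zeros(1000), fs=400.0)


class TestEpoching:
    def test_one_epoch_per_event_and_sample_count(self):
        rec = _recording(10)
        ep = epoch(rec)
        assert ep.data.shape == (10, 2, 4915)  # 4.8 s at 1024 Hz
        assert list(ep.labels["sentence_id"]) == list(range(10))

    def test_event_without_baseline_is_dropped(self, caplog):
        rec = _recording(4, onset0_ms=100.0)  # first baseline would start < 0
        ep = epoch(rec)
        assert ep.data.shape[0] == 3

    def test_timebase_spans_baseline_to_4000(self):
        times = epoch_times(FS, -800, 4000)
        assert times[0] == pytest.approx(-800.0)
        assert times[-1] < 4000.0
        assert times.size == 4915


class TestArtifactDetection:
    def test_clean_identical_epochs_keep_everything(self):
        data = np.ones((20, 2, 100))
        ep = Epochs(FS, epoch_times(FS, -800, -702), data,
                    pd.DataFrame({"sentence_id": range(20)}))
        assert detect_artifacts(ep).sum() == 0

    def test_single_large_transient_is_isolated(self, rng):
        data = rng.normal(size=(100, 2, 500))
        data[17, 0, 250] = 50.0 * np.abs(data).max()
        ep = Epochs(FS, epoch_times(FS, -800, -312), data,
                    pd.DataFrame({"sentence_id": range(100)}))
        mask = detect_artifacts(ep)
        assert mask[17] and mask.sum() == 1

    def test_mask_is_invariant_to_epoch_order(self, rng):
        data = rng.normal(size=(50, 2, 300))
        data[5] *= 30
        labels = pd.DataFrame({"sentence_id": range(50)})
        ep = Epochs(FS, epoch_times(FS, -800, -507), data, labels)
        perm = rng.permutation(50)
        ep_p = Epochs(FS, ep.times_ms, data[perm], labels)
        np.testing.assert_array_equal(detect_artifacts(ep)[perm],
                                      detect_artifacts(ep_p))

    def test_rejection_fraction_plausible_at_default_rate(self, small_cohort):
        """With the default 20% artifact rate the automated rejection lands
        in a plausible range around the generator rate."""
        from vocalsmile.pipeline import cohort_amplitudes
        _, rejection = cohort_amplitudes(small_cohort)
        assert 0.10 <= rejection["rejected_fraction"].mean() <= 0.35


class TestEnvelope:
    def test_constant_signal_has_flat_envelope(self):
        x = np.full(2048, 5.0)
        env = envelope_array(x, FS)
        np.testing.assert_allclose(env, 5.0, rtol=1e-12)

    def test_fast_square_wave_envelope_is_amplitude(self):
        x = 5.0 * np.where(np.arange(4096) % 2 == 0, 1.0, -1.0)
        env = envelope_array(x, FS)
        np.testing.assert_allclose(env, 5.0, rtol=1e-12)

    def test_impulse_smears_into_300ms_rectangle(self):
        """A single boxcar pass spreads an impulse uniformly over the
        307-sample (300 ms) window."""
        x = np.zeros(4096)
        x[2048] = 1.0
        env = envelope_array(x, FS)
        support = np.nonzero(env > 0)[0]
        assert support.size == 307
        np.testing.assert_allclose(env[support], 1.0 / 307, rtol=1e-9)

    def test_envelope_is_nonnegative(self, rng):
        env = envelope_array(rng.normal(size=(4, 2, 2000)), FS)
        assert np.all(env >= 0)


class TestZNormalize:
    times = epoch_times(FS, -800, 4000)

    def test_baseline_mean_zero_sd_one(self, rng):
        env = envelope_array(np.abs(rng.normal(size=self.times.size)), FS)
        z, degenerate = znormalize_array(env, self.times)
        base = z[(self.times >= -800) & (self.times < 0)]
        assert not degenerate
        assert abs(base.mean()) < 1e-10
        assert abs(base.std(ddof=1) - 1.0) < 1e-10

    def test_constant_envelope_is_degenerate(self):
        env = np.ones(self.times.size)
        _, degenerate = znormalize_array(env, self.times)
        assert degenerate
        e = Envelope(FS, self.times, env, "zm")
        assert znormalize(e).rejected

    def test_scale_invariance_of_z(self, rng):
        env = envelope_array(np.abs(rng.normal(size=self.times.size)) + 0.5, FS)
        z1, _ = znormalize_array(env, self.times)
        z2, _ = znormalize_array(3.7 * env, self.times)
        np.testing.assert_allclose(z1, z2, atol=1e-9)


class TestWindowMeans:
    times = epoch_times(FS, -800, 4000)
    windows = AnalysisWindows()

    def test_unit_signal_means_are_one(self):
        e = Envelope(FS, self.times, np.ones(self.times.size), "zm", is_z=True)
        means = window_means(e, self.windows)
        assert all(v == pytest.approx(1.0) for v in means.values())

    def test_linear_ramp_window_integrals(self):
        values = np.clip(self.times / 4000.0, 0.0, 1.0)
        e = Envelope(FS, self.times, values, "zm", is_z=True)
        means = window_means(e, self.windows)
        assert means["listening"] == pytest.approx(0.2375, abs=1e-3)
        assert means["processing"] == pytest.approx(0.7375, abs=1e-3)

    def test_target_window_uses_exactly_512_samples(self):
        assert window_mask(self.times, self.windows.target).sum() == 512

    def test_listening_processing_partition_zero_to_4000(self):
        m_listen = window_mask(self.times, self.windows.listening)
        m_process = window_mask(self.times, self.windows.processing)
        assert not np.any(m_listen & m_process)
        full = window_mask(self.times, (0.0, 4000.0))
        np.testing.assert_array_equal(m_listen | m_process, full)

    def test_rejected_trial_has_no_means(self):
        e = Envelope(FS, self.times, np.ones(self.times.size), "zm",
                     rejected=True)
        with pytest.raises(ValueError):
            window_means(e, self.windows)

    def test_invalid_windows_rejected(self):
        with pytest.raises(ValueError):
            AnalysisWindows(listening=(100.0, 50.0))
        with pytest.raises(ValueError):
            AnalysisWindows(target=(100.0, 500.0))


class TestPipelineScaleInvariance:
    def test_amplitudes_invariant_to_raw_gain(self, rng):
        data = np.abs(rng.normal(size=(12, 2, 4915))) + 0.1
        labels = pd.DataFrame({
            "sentence_id": range(12),
            "filter": [SMILING_F, UNSMILING_F] * 6,
            "choice": [SMILE_C, UNSMILE_C] * 6})
        times = epoch_times(FS, -800, 4000)
        a1, _ = process_epochs(Epochs(FS, times, data, labels))
        a2, _ = process_epochs(Epochs(FS, times, 37.0 * data, labels))
        for col in ("mean_listening", "mean_processing", "mean_target"):
            np.testing.assert_allclose(a1[col], a2[col], atol=1e-9)


class TestDifferenceScores:
    def _amplitudes(self, zm_sf, zm_uf, cs_uc, cs_sc):
        rows = []
        for muscle, filt, choice, val in [
                ("zm", SMILING_F, SMILE_C, zm_sf),
                ("zm", UNSMILING_F, UNSMILE_C, zm_uf),
                ("cs", SMILING_F, UNSMILE_C, cs_uc),
                ("cs", UNSMILING_F, SMILE_C, cs_sc)]:
            for _ in range(3):
                rows.append({"participant": "p0", "muscle": muscle,
                             "filter": filt, "choice": choice,
                             "mean_target": val})
        return pd.DataFrame(rows)

    def test_identical_condition_means_give_zero(self):
        out = difference_scores(self._amplitudes(0.3, 0.3, 0.1, 0.1))
        assert out.loc[0, "zm_filter"] == pytest.approx(0.0)
        assert out.loc[0, "cs_choice"] == pytest.approx(0.0)

    def test_hand_computed_difference(self):
        out = difference_scores(self._amplitudes(0.6, 0.2, 0.5, 0.1))
        assert out.loc[0, "zm_filter"] == pytest.approx(0.4)
        assert out.loc[0, "cs_choice"] == pytest.approx(0.4)

    def test_label_permutation_flips_sign(self):
        df = self._amplitudes(0.6, 0.2, 0.5, 0.1)
        flipped = df.copy()
        flipped["filter"] = flipped["filter"].map(
            {SMILING_F: UNSMILING_F, UNSMILING_F: SMILING_F})
        a = difference_scores(df).loc[0, "zm_filter"]
        b = difference_scores(flipped).loc[0, "zm_filter"]
        assert a == pytest.approx(-b)

    def test_empty_cell_excludes_participant(self):
        df = self._amplitudes(0.6, 0.2, 0.5, 0.1)
        df = df[~((df["muscle"] == "cs") & (df["choice"] == UNSMILE_C))]
        out = difference_scores(df)
        assert out.empty
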