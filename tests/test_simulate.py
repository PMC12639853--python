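"""Synthetic observers, behavioral sessions, EMG generator, cohorts."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as ssig
from scipy import stats as sps

from vocalsmile import emg, simulate
from vocalsmile.behavior import SMILE_C, SMILING_F, UNSMILE_C, UNSMILING_F
from vocalsmile.simulate import (ASD, NT, EmgGenParams, ObserverModel,
                                 SessionDesign, band_limited_noise,
                                 canonical_template, choice_consistency,
                                 noise_for_consistency, simulate_cohort,
                                 simulate_emg_epochs, simulate_emg_trial,
                                 simulate_main_task, simulate_revcorr_session)


class TestRevcorrObserver:
    def test_noise_free_single_band_template_tracks_gain_sign(self, eq_params):
        template = np.zeros(25)
        template[5] = 1.0
        obs = ObserverModel(template, 0.0)
        sess = simulate_revcorr_session(obs, eq_params, 500,
                                        np.random.default_rng(0))
        expected = np.where(sess.gains[:, 5] > 0, "smile", "unsmile")
        assert np.array_equal(sess.choices, expected)

    def test_null_template_choice_rate_matches_closed_form(self, eq_params):
        """With a zero template, P(smile) = Phi(-bias/noise)."""
        obs = ObserverModel(np.zeros(25), decision_noise=2.0, bias=1.0)
        sess = simulate_revcorr_session(obs, eq_params, 10_000,
                                        np.random.default_rng(1))
        expected = sps.norm.cdf(-1.0 / 2.0)
        assert np.mean(sess.choices == "smile") == pytest.approx(
            expected, abs=0.02)

    def test_consistency_solver_inverts_forward_model(self, eq_params):
        template = canonical_template(eq_params.grid)
        for target in (0.65, 0.75, 0.9):
            noise = noise_for_consistency(template, eq_params, target)
            c = params_consistency = choice_consistency(
                _signal_sd(template, eq_params), noise)
            assert c == pytest.approx(target, abs=1e-6)


def _signal_sd(template, params):
    c = params.clip_sd
    var_factor = (1 - 2 * c * sps.norm.pdf(c) - 2 * sps.norm.sf(c)
                  + 2 * c**2 * sps.norm.sf(c))
    return params.sd_db * np.sqrt(var_factor) * np.linalg.norm(template)


class TestMainTask:
    def test_noise_free_observer_is_perfect(self, eq_params):
        obs = ObserverModel(np.zeros(25), 0.0)
        df = simulate_main_task(obs, SessionDesign(), 1.0,
                                np.random.default_rng(2))
        assert df["correct"].all()
        assert (df["filter"] == SMILING_F).sum() == 40

    def test_zero_filter_strength_is_guessing(self, eq_params):
        obs = ObserverModel(np.zeros(25), 1.0)
        rng = np.random.default_rng(3)
        acc = np.mean([simulate_main_task(obs, SessionDesign(), 0.0, rng)
                       ["correct"].mean() for _ in range(200)])
        assert acc == pytest.approx(0.5, abs=0.02)

    def test_unit_effect_accuracy_matches_phi(self):
        """noise = 1, strength = 1 -> accuracy ~ Phi(1) = 0.841."""
        obs = ObserverModel(np.zeros(25), 1.0)
        design = SessionDesign(n_sentences=10_000)
        df = simulate_main_task(obs, design, 1.0, np.random.default_rng(4))
        assert df["correct"].mean() == pytest.approx(
            sps.norm.cdf(1.0), abs=0.02)

    def test_rating_and_choice_are_consistent(self):
        obs = ObserverModel(np.zeros(25), 1.0)
        df = simulate_main_task(obs, SessionDesign(), 0.7,
                                np.random.default_rng(5))
        assert set(df["rating"]) <= {1, 2, 3, 4}
        assert ((df["rating"] >= 3) == (df["choice"] == SMILE_C)).all()


class TestEmgGenerator:
    def test_carrier_is_unit_variance_and_band_limited(self, rng):
        x = band_limited_noise(4915, 1024.0, (50.0, 250.0), rng, (300,))
        assert x.var() == pytest.approx(1.0, rel=0.05)
        f, p = ssig.welch(x.ravel(), fs=1024.0, nperseg=2048)
        in_band = p[(f >= 50) & (f <= 250)].mean()
        out_band = p[(f < 40) | (f > 280)].mean()
        assert 10 * np.log10(in_band / out_band) >= 30.0

    def test_stationary_null_trials_are_condition_free(self):
        """No condition effects + no artifacts: window means carry only the
        small positive bias of per-trial z-normalization (E[1/s_hat] >
        1/E[s_hat] with an ~3-independent-sample baseline); the bias is
        identical across windows and vanishes as the baseline lengthens."""
        behav = pd.DataFrame({
            "sentence_id": range(100),
            "filter": [SMILING_F, UNSMILING_F] * 50,
            "choice": [SMILE_C, UNSMILE_C] * 50})
        se = {"effect_amps_uv": [], "relaxation_fraction": 0.0}

        def window_bias(baseline_ms):
            params = EmgGenParams(effects=[], artifact_rate=0.0,
                                  asd_relaxation=(0.0, 0.0),
                                  epoch_span_ms=(baseline_ms, 4000.0))
            data, _ = simulate_emg_epochs(params, behav, NT,
                                          np.random.default_rng(6), se)
            cfg = emg.PipelineConfig(baseline_ms=(baseline_ms, 0.0),
                                     epoch_span_ms=(baseline_ms, 4000.0))
            epochs = emg.Epochs(params.fs,
                                emg.epoch_times(params.fs, baseline_ms, 4000),
                                data, behav)
            amps, _ = emg.process_epochs(epochs, cfg)
            return amps[["mean_listening", "mean_processing",
                         "mean_target"]].mean()

        short = window_bias(-800.0)
        # the bias is shared by all windows: no spurious timing contrast
        assert abs(short["mean_processing"] - short["mean_listening"]) < 0.1
        assert abs(short.mean()) < 0.5
        long = window_bias(-8000.0)
        assert abs(long.mean()) < 0.1
        assert abs(long.mean()) < abs(short.mean())

    def test_nt_zm_smiling_increment_raises_target_window(self):
        params = EmgGenParams(artifact_rate=0.0)
        rng = np.random.default_rng(7)
        behav = pd.DataFrame({
            "sentence_id": range(200),
            "filter": [SMILING_F, UNSMILING_F] * 100,
            "choice": [SMILE_C, UNSMILE_C] * 100})
        se = simulate.draw_subject_effects(params, NT,
                                          np.random.default_rng(100))
        data, _ = simulate_emg_epochs(params, behav, NT, rng, se)
        epochs = emg.Epochs(params.fs,
                            emg.epoch_times(params.fs, -800, 4000),
                            data, behav)
        amps, _ = emg.process_epochs(epochs, emg.PipelineConfig())
        zm = amps[amps["muscle"] == "zm"]
        by_filter = zm.groupby("filter")["mean_target"].mean()
        assert by_filter[SMILING_F] > by_filter[UNSMILING_F]

    def test_contaminated_trials_all_detected(self):
        """At 25% contamination every artifact trial (known from the
        generator's ground truth) is flagged and clean trials mostly
        survive."""
        params = EmgGenParams(artifact_rate=0.25)
        rng = np.random.default_rng(8)
        behav = pd.DataFrame({"sentence_id": range(120),
                              "filter": [SMILING_F, UNSMILING_F] * 60,
                              "choice": [SMILE_C, UNSMILE_C] * 60})
        se = simulate.draw_subject_effects(params, NT, rng)
        data, hit = simulate_emg_epochs(params, behav, NT, rng, se)
        filt = emg.bandpass_array(data, params.fs)
        epochs = emg.Epochs(params.fs,
                            emg.epoch_times(params.fs, -800, 4000),
                            filt, behav)
        mask = emg.detect_artifacts(epochs)
        assert mask[hit].all()
        assert mask[~hit].mean() < 0.1

    def test_single_trial_generator_matches_epoch_shape(self):
        params = EmgGenParams()
        tr = simulate_emg_trial(params, ASD, "cs", SMILING_F, UNSMILE_C,
                                np.random.default_rng(10))
        assert tr.shape == (4915,)


class TestCohort:
    def test_study_sized_cohort_has_41_participants(self):
        cohort = simulate_cohort(seed=20, n_nt=21, n_asd=20,
                                 include_emg=False, include_revcorr=False)
        assert len(cohort.participants) == 41
        assert (cohort.participants["group"] == NT).sum() == 21

    def test_small_cohort_is_schema_complete(self, small_cohort):
        assert set(small_cohort.participants.columns) == {
            "participant_id", "group", "aq", "eq"}
        for pdata in small_cohort.data.values():
            assert pdata.revcorr is not None
            assert len(pdata.behavior) == 80
            assert pdata.emg.shape == (80, 2, 4915)
            assert "template" in pdata.ground_truth

    def test_same_seed_is_bit_identical(self):
        a = simulate_cohort(seed=21, n_nt=2, n_asd=2, n_revcorr_trials=40)
        b = simulate_cohort(seed=21, n_nt=2, n_asd=2, n_revcorr_trials=40)
        for pid in a.data:
            np.testing.assert_array_equal(a.data[pid].emg, b.data[pid].emg)
            pd.testing.assert_frame_equal(a.data[pid].behavior,
                                          b.data[pid].behavior)
            np.testing.assert_array_equal(a.data[pid].revcorr.gains,
                                          b.data[pid].revcorr.gains)

    def test_enlarging_cohort_keeps_early_participants(self):
        """Per-participant substreams: participant k is identical whether
        the cohort has 4 or 6 members."""
        small = simulate_cohort(seed=22, n_nt=2, n_asd=2,
                                n_revcorr_trials=40, include_emg=False)
        large = simulate_cohort(seed=22, n_nt=2, n_asd=4,
                                n_revcorr_trials=40, include_emg=False)
        for pid in ("nt00", "nt01"):
            np.testing.assert_array_equal(small.data[pid].revcorr.gains,
                                          large.data[pid].revcorr.gains)

    def test_group_covariates_match_configured_means(self):
        cohort = simulate_cohort(seed=23, n_nt=100, n_asd=100,
                                 include_emg=False, include_revcorr=False)
        p = cohort.participants
        for group, (mean, sd) in simulate.AQ_DIST.items():
            sample = p.loc[p["group"] == group, "aq"]
            assert abs(sample.mean() - mean) < 2 * sd / np.sqrt(100)

    def test_null_cohort_drops_condition_effects(self):
        cohort = simulate_cohort(seed=24, n_nt=2, n_asd=2,
                                 include_revcorr=False, null_effects=True)
        assert all(e.factor is None for e in cohort.emg_params.effects)
        assert cohort.emg_params.asd_relaxation == (0.0, 0.0)

    def test_minimum_group_size_enforced(self):
        with pytest.raises(ValueError):
            simulate_cohort(seed=25, n_nt=1, n_asd=5)
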