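import numpy as np
import pytest
from dataclasses import replace

from hepflow.cardiac import rmssd
from hepflow.synthetic import (
    EvokedEffect,
    HepEffect,
    SyntheticStudyConfig,
    generate_rr_series,
    generate_study,
    generate_subject_recording,
    simulate_evoked_dataset,
)

SMALL = SyntheticStudyConfig(n_subjects_per_group=2, duration_s=30.0, seed=7)


class TestConfigValidation:
    def test_effect_window_outside_epoch_rejected(self):
        with pytest.raises(ValueError, match="window"):
            SyntheticStudyConfig(
                hep_effect=HepEffect(window_ms=(650.0, 750.0))
            )

    def test_unknown_effect_channel_rejected(self):
        with pytest.raises(ValueError, match="montage"):
            SyntheticStudyConfig(hep_effect=HepEffect(channels=("Xx9",)))

    def test_rr_mean_must_exceed_twice_sd(self):
        with pytest.raises(ValueError, match="2 \\* rr_sd"):
            SyntheticStudyConfig(mean_rr_ms=100.0, rr_sd_ms=60.0)


class TestRrSeries:
    def test_zero_sd_gives_constant_series(self):
        config = replace(SMALL, rr_sd_ms=0.0, resp_amplitude_ms=0.0)
        rr = generate_rr_series(config, "pre", np.random.default_rng(0))
        np.testing.assert_allclose(rr, config.mean_rr_ms)
        assert rmssd(rr) == 0.0

    def test_same_seed_identical_series(self):
        a = generate_rr_series(SMALL, "pre", np.random.default_rng(42))
        b = generate_rr_series(SMALL, "pre", np.random.default_rng(42))
        np.testing.assert_array_equal(a, b)

    def test_sample_mean_within_3se_of_configured_mean(self):
        config = SyntheticStudyConfig(
            mean_rr_ms=800.0, rr_sd_ms=40.0, duration_s=3600.0,
            resp_amplitude_ms=0.0,
        )
        rr = generate_rr_series(config, "pre", np.random.default_rng(5))
        phi = config.ar_coefficient
        se = 40.0 / np.sqrt(len(rr)) * np.sqrt((1 + phi) / (1 - phi))
        assert abs(rr.mean() - 800.0) < 3 * se

    def test_post_condition_less_variable(self):
        rng = np.random.default_rng(1)
        config = replace(SMALL, duration_s=600.0)
        pre = generate_rr_series(config, "pre", np.random.default_rng(1))
        post = generate_rr_series(config, "post", np.random.default_rng(1))
        assert post.std() < pre.std()

    def test_series_covers_duration(self):
        rr = generate_rr_series(SMALL, "pre", np.random.default_rng(3))
        assert rr.sum() >= SMALL.duration_s * 1000.0


class TestSubjectRecording:
    def _rr(self, seed=0):
        return generate_rr_series(SMALL, "pre", np.random.default_rng(seed))

    def test_ground_truth_peaks_spaced_by_rr(self):
        rr = self._rr()
        rec = generate_subject_recording(
            SMALL, rr, np.random.default_rng(1), condition="pre"
        )
        gaps_ms = np.diff(rec.true_r_peaks) * 1000.0 / rec.sample_rate
        # positions are rounded to the sample grid (5 ms at 200 Hz)
        offsets = np.cumsum(rr)[: len(gaps_ms)]
        expected = np.diff(np.round((500.0 + np.concatenate([[0], offsets]))
                                    * 0.2)) * 5.0
        np.testing.assert_allclose(gaps_ms, expected[: len(gaps_ms)])

    def test_zero_amplitude_conditions_differ_only_in_noise(self):
        rr = self._rr()
        rec_a = generate_subject_recording(
            SMALL, rr, np.random.default_rng(2), condition="pre",
            hep_amplitude_uv=0.0,
        )
        rec_b = generate_subject_recording(
            SMALL, rr, np.random.default_rng(2), condition="post",
            hep_amplitude_uv=0.0,
        )
        np.testing.assert_array_equal(rec_a.eeg, rec_b.eeg)

    def test_zero_cfa_gain_decorrelates_eeg_from_ecg(self):
        rr = self._rr()
        rng = np.random.default_rng(3)
        rec = generate_subject_recording(SMALL, rr, rng, condition="pre")
        corrs = [
            abs(np.corrcoef(rec.eeg[c], rec.ecg)[0, 1])
            for c in range(rec.n_channels)
        ]
        # noise floor: pink noise over 30 s has limited effective samples
        assert max(corrs) < 0.15

    def test_nonzero_cfa_gain_couples_eeg_to_ecg(self):
        rr = self._rr()
        gain = np.full(23, 0.05)
        rec = generate_subject_recording(
            SMALL, rr, np.random.default_rng(3), condition="pre",
            cfa_gain=gain,
        )
        corr = np.corrcoef(rec.eeg[0], rec.ecg)[0, 1]
        assert corr > 0.3

    def test_injected_bump_raises_effect_channel_amplitude(self, montage):
        rr = self._rr()
        big = replace(SMALL, noise_sd_uv=0.01)
        rec = generate_subject_recording(
            big, rr, np.random.default_rng(4), condition="pre",
            hep_amplitude_uv=5.0,
        )
        peak = rec.true_r_peaks[3]
        center = peak + int(round(545.0 * 0.2))  # bump center sample
        i_eff = montage.index("Fz")
        i_far = montage.index("O2")
        assert rec.eeg[i_eff, center] > 2.0
        assert abs(rec.eeg[i_far, center]) < 1.0

    def test_duration_too_short_rejected(self):
        config = replace(SMALL, duration_s=0.8)
        with pytest.raises(ValueError, match="short"):
            generate_subject_recording(
                config, np.array([850.0] * 3), np.random.default_rng(0),
                condition="pre",
            )


class TestStudyGeneration:
    def test_counts_balanced(self):
        study = generate_study(SMALL)
        assert len(study.subjects) == 4
        assert sum(s.group_age == "young" for s in study.subjects) == 2
        recordings = [
            rec for s in study.subjects for rec in s.recordings.values()
        ]
        assert len(recordings) == 8
        sexes = [s.sex for s in study.subjects if s.group_age == "young"]
        assert sorted(sexes) == ["F", "M"]

    def test_seed_determinism_byte_identical(self):
        a = generate_study(SMALL)
        b = generate_study(SMALL)
        for sa, sb in zip(a.subjects, b.subjects):
            for cond in ("pre", "post"):
                np.testing.assert_array_equal(
                    sa.recordings[cond].eeg, sb.recordings[cond].eeg
                )
                np.testing.assert_array_equal(
                    sa.recordings[cond].ecg, sb.recordings[cond].ecg
                )

    def test_seed_change_new_noise_same_layout(self):
        a = generate_study(SMALL)
        b = generate_study(replace(SMALL, seed=8))
        assert [s.subject_id for s in a.subjects] == [
            s.subject_id for s in b.subjects
        ]
        assert [s.sex for s in a.subjects] == [s.sex for s in b.subjects]
        assert not np.array_equal(
            a.subjects[0].recordings["pre"].eeg,
            b.subjects[0].recordings["pre"].eeg,
        )

    def test_effect_restricted_to_configured_group(self):
        study = generate_study(SMALL)
        for s in study.subjects:
            if s.group_age == "young":
                assert s.hep_amplitude_uv == 0.0

    def test_manifest_shape(self):
        study = generate_study(SMALL)
        manifest = study.manifest
        assert len(manifest) == 8
        assert set(manifest["condition"]) == {"pre", "post"}


class TestInjectedEffectConservation:
    def test_mean_pre_post_difference_matches_amplitude(self, montage):
        """Averaged over epochs/noise, pre - post at the bump center
        equals the injected amplitude (within Monte-Carlo error)."""
        from hepflow.epoching import average_evoked, epoch_around_rpeaks
        from hepflow.cardiac import RPeakSeries

        config = replace(
            SMALL, duration_s=120.0,
            hep_effect=replace(SMALL.hep_effect, subject_sd_uv=0.0),
        )
        rr = generate_rr_series(config, "pre", np.random.default_rng(0))
        amp = 2.0
        diffs = []
        i_fz = montage.index("Fz")
        for seed in range(4):
            rngs = [np.random.default_rng([seed, k]) for k in (0, 1)]
            rec_pre = generate_subject_recording(
                config, rr, rngs[0], condition="pre", hep_amplitude_uv=amp
            )
            rec_post = generate_subject_recording(
                config, rr, rngs[1], condition="post", hep_amplitude_uv=0.0
            )
            peaks = RPeakSeries(rec_pre.true_r_peaks, config.sample_rate)
            ev_pre = average_evoked(
                epoch_around_rpeaks(rec_pre, peaks), "HEP"
            )
            ev_post = average_evoked(
                epoch_around_rpeaks(rec_post, peaks), "HEP"
            )
            center = np.argmin(np.abs(ev_pre.times_ms - 545.0))
            diffs.append(ev_pre.data[i_fz, center] - ev_post.data[i_fz, center])
        # raised cosine at 545 ms (window 530-560) = 1.0 at center
        assert np.mean(diffs) == pytest.approx(amp, abs=0.5)


class TestEvokedSimulator:
    def test_shapes_and_default_toi_grid(self):
        data, times = simulate_evoked_dataset(5, rng=0)
        assert data.shape == (5, 23, 91)
        assert times[0] == 200.0 and times[-1] == 650.0

    def test_determinism(self):
        a, _ = simulate_evoked_dataset(4, rng=np.random.default_rng(9))
        b, _ = simulate_evoked_dataset(4, rng=np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_unit_marginal_sd(self):
        data, _ = simulate_evoked_dataset(300, rng=1)
        sds = data.std(axis=0)
        assert abs(np.median(sds) - 1.0) < 0.1

    def test_effect_adds_mean_at_bump_center(self, montage):
        eff = EvokedEffect(amplitude_uv=2.0)
        data, times = simulate_evoked_dataset(500, effect=eff, rng=2)
        center = np.argmin(np.abs(times - 545.0))
        i = montage.index("C3")
        assert data[:, i, center].mean() == pytest.approx(2.0, abs=0.2)
        far = montage.index("O2")
        assert abs(data[:, far, center].mean()) < 0.2
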