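"""Synthetic-study generator: determinism, design counts, effect scaling."""

import numpy as np
import pytest

import graspid as g
from graspid.errors import ConfigurationError
from graspid.synthetic import _rng


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_subjects": 0},
            {"subject_effect_scale": -1.0},
            {"force_rate": 1000.0},  # not an integer multiple of 120
            {"spring_constant": 0.0},
            {"phase_duration_ranges": ((0.5, 0.2), (1, 2), (1, 2))},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            g.SyntheticConfig(**kwargs)

    def test_rate_ratio_default_is_eight(self):
        assert g.SyntheticConfig().rate_ratio == 8


class TestSubjectProfiles:
    def test_deterministic_given_seed_and_index(self):
        cfg = g.SyntheticConfig(seed=5)
        p1 = g.generate_subject_profile(cfg, 3)
        p2 = g.generate_subject_profile(cfg, 3)
        t = np.linspace(0, 1, 100)
        np.testing.assert_array_equal(p1.angle_templates(t), p2.angle_templates(t))
        assert p1.hand_size == p2.hand_size

    def test_zero_effect_gives_identical_templates(self):
        cfg = g.SyntheticConfig(subject_effect_scale=0.0, seed=2)
        t = np.linspace(0, 1, 50)
        base = g.generate_subject_profile(cfg, 0).angle_templates(t)
        for i in (1, 7, 30):
            np.testing.assert_allclose(
                g.generate_subject_profile(cfg, i).angle_templates(t), base, atol=1e-12
            )

    def test_between_subject_std_matches_effect_scale(self):
        """Monte-Carlo: pointwise std of templates across many subjects is
        the configured effect scale within 20%."""
        cfg = g.SyntheticConfig(n_subjects=400, subject_effect_scale=1.0, seed=8)
        t = np.linspace(0.05, 0.95, 40)
        values = np.stack([
            g.generate_subject_profile(cfg, i).angle_curves(t) for i in range(400)
        ])  # (n, 10, T) - raw curves, no clipping
        std = values.std(axis=0)
        assert np.all(std > 0.8) and np.all(std < 1.2)

    def test_template_bounds(self):
        cfg = g.SyntheticConfig(subject_effect_scale=5.0, seed=1)
        t = np.linspace(0, 1, 200)
        for i in range(5):
            tpl = g.generate_subject_profile(cfg, i).angle_templates(t)
            assert tpl.min() >= 0.0 and tpl.max() <= 180.0

    def test_force_templates_nonnegative_zero_at_endpoints(self):
        cfg = g.SyntheticConfig(seed=4)
        p = g.generate_subject_profile(cfg, 2)
        gamma = np.linspace(0, 1, 101)
        f = p.force_templates(gamma)
        assert f.min() >= 0.0
        np.testing.assert_allclose(f[:, [0, -1]], 0.0, atol=1e-9)


class TestTrials:
    def test_rate_ratio_between_blocks(self, small_study):
        _, dataset, _ = small_study
        for trial in dataset.trials[:5]:
            assert trial.force_block.shape[1] == 8 * trial.marker_block.shape[1]
            assert np.isfinite(trial.marker_block).all()
            assert trial.marker_block.shape[0] == 20

    def test_noise_free_trials_identical(self, noise_free_config):
        profile = g.generate_subject_profile(noise_free_config, 1)
        rng = lambda: np.random.default_rng(99)
        t1 = g.generate_trial(profile, "tennis_ball", 0, noise_free_config,
                              rng=rng(), object_index=0)
        t2 = g.generate_trial(profile, "tennis_ball", 1, noise_free_config,
                              rng=rng(), object_index=0)
        np.testing.assert_array_equal(t1.marker_block, t2.marker_block)
        np.testing.assert_array_equal(t1.force_block, t2.force_block)

    def test_reach_phase_forces_are_sensor_noise(self):
        cfg = g.SyntheticConfig(n_subjects=1, n_objects=1, n_trials_per_object=1,
                                mains_noise_amplitude=0.0, seed=6)
        profile = g.generate_subject_profile(cfg, 0)
        trial = g.generate_trial(profile, "tennis_ball", 0, cfg, object_index=0)
        onset, contact, _, _ = trial.true_phase_bounds
        reach = trial.force_block[:, 8 * onset: 8 * (contact - 2)]
        assert abs(reach.mean()) < 0.01
        assert reach.std() == pytest.approx(cfg.sensor_noise_std, rel=0.2)

    def test_mains_component_present_at_50hz(self):
        cfg = g.SyntheticConfig(n_subjects=1, n_objects=1, n_trials_per_object=1,
                                sensor_noise_std=0.0, trial_noise_scale=0.0,
                                marker_noise_std_mm=0.0, seed=6)
        profile = g.generate_subject_profile(cfg, 0)
        trial = g.generate_trial(profile, "tennis_ball", 0, cfg, object_index=0)
        onset = trial.true_phase_bounds[0]
        rest = trial.force_block[0, : 8 * onset]
        freqs = np.fft.rfftfreq(rest.size, 1 / 960.0)
        spectrum = np.abs(np.fft.rfft(rest))
        assert freqs[np.argmax(spectrum[1:]) + 1] == pytest.approx(50.0, abs=1.5)


class TestDataset:
    def test_design_counts(self):
        cfg = g.SyntheticConfig(n_subjects=2, n_objects=3, n_trials_per_object=4, seed=0)
        ds = g.generate_dataset(cfg)
        assert len(ds.trials) == 24
        cfg1 = g.SyntheticConfig(n_subjects=1, n_objects=1, n_trials_per_object=1, seed=0)
        assert len(g.generate_dataset(cfg1).trials) == 1

    def test_full_dataset_deterministic(self):
        cfg = g.SyntheticConfig(n_subjects=2, n_objects=2, n_trials_per_object=2, seed=77)
        d1, d2 = g.generate_dataset(cfg), g.generate_dataset(cfg)
        for t1, t2 in zip(d1.trials, d2.trials):
            np.testing.assert_array_equal(t1.marker_block, t2.marker_block)
            np.testing.assert_array_equal(t1.force_block, t2.force_block)

    def test_disjoint_rng_streams(self):
        s1 = _rng(0, 13, 0, 0, 0).standard_normal(8)
        s2 = _rng(0, 13, 0, 0, 1).standard_normal(8)
        assert not np.allclose(s1, s2)

    def test_calibrations_per_subject_and_finger(self, small_study):
        _, dataset, _ = small_study
        assert set(dataset.calibrations) == {p.subject_id for p in dataset.profiles}
        for cal in dataset.calibrations.values():
            assert set(cal) == {"thumb", "index", "middle", "ring", "pinky"}
            for rec in cal.values():
                assert len(rec.repetitions) == 3

    def test_between_subject_feature_variance_scales_with_effect(self):
        """Extracted-feature spread across subjects grows with the
        between-subject effect scale (three settings, fixed seeds)."""
        spreads = []
        for effect in (0.0, 1.0, 3.0):
            cfg = g.SyntheticConfig(n_subjects=6, n_objects=1, n_trials_per_object=2,
                                    subject_effect_scale=effect, seed=21)
            dm = g.build_dataset_matrix(g.generate_dataset(cfg), seed=21)
            centroids = np.stack([
                dm.vectors[dm.subjects == s].mean(axis=0) for s in np.unique(dm.subjects)
            ])
            spreads.append(float(centroids.std(axis=0).mean()))
        assert spreads[0] < spreads[1] < spreads[2]


class TestPlantedFeatureDataset:
    def test_shapes_and_normalization(self):
        ds = g.generate_feature_dataset(n_subjects=4, n_trials_per_subject=3,
                                        informative=(0, 1), n_features=6,
                                        n_samples=80, seed=0)
        assert ds.values.shape == (12, 6, 80)
        assert abs(ds.values.mean()) < 1e-9 and abs(ds.values.std() - 1.0) < 1e-9

    def test_coded_structure_needs_enough_bits(self):
        with pytest.raises(ConfigurationError):
            g.generate_feature_dataset(n_subjects=9, informative=(0, 1, 2),
                                       structure="coded")

    def test_deterministic(self):
        a = g.generate_feature_dataset(n_subjects=3, n_trials_per_subject=2, seed=5)
        b = g.generate_feature_dataset(n_subjects=3, n_trials_per_subject=2, seed=5)
        np.testing.assert_array_equal(a.values, b.values)
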