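"""Phase segmentation, time normalization, feature matrices, normalization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import graspid as g
from graspid.errors import (
    ConfigurationError,
    DegenerateDataError,
    InputTooShortError,
    SegmentationError,
)
from graspid.features import ANGLE_ROWS, FEATURE_NAMES, FORCE_ROWS
from graspid.kinematics import AngleSeriesSet, wrist_speed
from graspid.pipeline import extract_trial, forces_in_newtons


@pytest.fixture(scope="module")
def extracted(noise_free_config, noise_free_trial):
    profile, trial = noise_free_trial
    cal = g.generate_calibration(profile, noise_free_config)
    curves = {f: g.fit_calibration(rec) for f, rec in cal.items()}
    angles = g.extract_joint_angles(trial)
    forces = forces_in_newtons(trial, curves)
    T = min(angles.values.shape[1], forces.shape[1])
    angles.values = angles.values[:, :T]
    speed = wrist_speed(trial)[:T]
    return profile, trial, curves, angles, forces[:, :T], speed


class TestSegmentation:
    def test_detected_bounds_match_ground_truth(self, extracted):
        _, trial, _, angles, forces, speed = extracted
        seg = g.segment_phases(angles, forces, speed)
        for detected, true in zip(
            (seg.movement_onset, seg.contact_onset, seg.release_onset, seg.movement_end),
            trial.true_phase_bounds,
        ):
            assert abs(detected - true) <= 5

    def test_detected_bounds_with_default_noise(self, small_study):
        _, dataset, _ = small_study
        cal = dataset.calibrations
        for trial in dataset.trials[:4]:
            curves = {f: g.fit_calibration(r) for f, r in cal[trial.subject_id].items()}
            angles = g.extract_joint_angles(trial)
            forces = forces_in_newtons(trial, curves)
            T = min(angles.values.shape[1], forces.shape[1])
            angles.values = angles.values[:, :T]
            seg = g.segment_phases(angles, forces[:, :T], wrist_speed(trial)[:T])
            for detected, true in zip(
                (seg.movement_onset, seg.contact_onset, seg.release_onset, seg.movement_end),
                trial.true_phase_bounds,
            ):
                assert abs(detected - true) <= 5

    def test_zero_forces_rejected(self, extracted):
        _, _, _, angles, forces, speed = extracted
        with pytest.raises(SegmentationError):
            g.segment_phases(angles, np.zeros_like(forces), speed)

    def test_clean_step_signals_recovered_exactly(self):
        T = 400
        speed = np.zeros(T)
        speed[100:300] = 200.0
        force = np.zeros((5, T))
        force[:, 150:250] = 1.0
        angles = AngleSeriesSet(np.full((10, T), 90.0))
        seg = g.segment_phases(angles, force, speed)
        assert (seg.movement_onset, seg.movement_end) == (99, 300)
        assert (seg.contact_onset, seg.release_onset) == (149, 250)

    def test_bounds_must_increase(self):
        with pytest.raises(SegmentationError):
            g.PhaseSegmentation(10, 5, 20, 30)


class TestTimeNormalize:
    def test_ramp_preserved(self):
        ramp = np.linspace(0.0, 1.0, 800)
        out = g.time_normalize(ramp, 500)
        assert out.shape == (500,)
        assert out[0] == 0.0 and out[-1] == 1.0
        assert np.abs(out - np.linspace(0, 1, 500)).max() < 1e-9

    def test_identity_when_already_target_length(self):
        x = np.random.default_rng(0).normal(size=(3, 500))
        np.testing.assert_allclose(g.time_normalize(x, 500), x, atol=1e-12)

    def test_constant_series(self):
        out = g.time_normalize(np.full(73, 4.2), 500)
        np.testing.assert_allclose(out, 4.2)

    def test_too_short(self):
        with pytest.raises(InputTooShortError):
            g.time_normalize(np.array([1.0]), 500)


class TestAssemble:
    @pytest.mark.parametrize("mode", ["full", "no_release", "phase_equalized"])
    def test_matrix_shape_15x500(self, extracted, mode):
        _, trial, _, angles, forces, speed = extracted
        seg = g.segment_phases(angles, forces, speed)
        fm = g.assemble_feature_matrix(angles, forces, seg, mode=mode,
                                       rng=np.random.default_rng(0))
        assert fm.values.shape == (15, 500)

    def test_unknown_mode(self, extracted):
        _, _, _, angles, forces, speed = extracted
        seg = g.segment_phases(angles, forces, speed)
        with pytest.raises(ConfigurationError):
            g.assemble_feature_matrix(angles, forces, seg, mode="bogus")

    def test_phase_equalized_halves(self, extracted):
        """Columns 1-250 come from the reach, 251-500 from the grasp."""
        _, trial, _, angles, forces, speed = extracted
        seg = g.segment_phases(angles, forces, speed)
        fm = g.assemble_feature_matrix(angles, forces, seg, mode="phase_equalized",
                                       rng=np.random.default_rng(0))
        row = fm.values[0]  # thumb theta1
        reach = g.time_normalize(angles.values[0, seg.movement_onset:seg.contact_onset + 1], 250)
        grasp = g.time_normalize(angles.values[0, seg.contact_onset:seg.release_onset + 1], 250)
        np.testing.assert_allclose(row[:250], reach, atol=1e-9)
        np.testing.assert_allclose(row[250:], grasp, atol=1e-9)

    def test_noncontact_forces_are_noise(self, extracted):
        _, _, _, angles, forces, speed = extracted
        seg = g.segment_phases(angles, forces, speed)
        fm = g.assemble_feature_matrix(angles, forces, seg, mode="phase_equalized",
                                       rng=np.random.default_rng(5))
        reach_forces = fm.values[np.asarray(FORCE_ROWS)][:, :250]
        assert abs(reach_forces.mean()) < 0.1 and abs(reach_forces.std() - 1.0) < 0.1

    def test_full_mode_roundtrip_under_1deg(self, noise_free_config, extracted):
        """The resampled angle rows of a noise-free trial match the
        generating templates after identical resampling."""
        from graspid.synthetic import _object_effects

        profile, trial, curves, _, _, _ = extracted
        fm = extract_trial(trial, curves, mode="full", use_true_bounds=True)
        tau = np.linspace(0.0, 1.0, 500)
        offset, _ = _object_effects(noise_free_config, 0)
        expected = np.clip((profile.angle_curves + offset)(tau), 1, 179)
        for i, row in enumerate(ANGLE_ROWS):
            finger, angle = FEATURE_NAMES[row].rsplit("_", 1)
            template_idx = 2 * (row // 3) + (0 if angle == "theta1" else 1)
            assert np.abs(fm.values[row] - expected[template_idx]).max() < 1.0

    def test_duration_invariance(self):
        """Uniform time stretching only changes the matrix via resampling."""
        t_short = np.linspace(0.0, 1.0, 300)
        t_long = np.linspace(0.0, 1.0, 900)
        curve = lambda t: 90 + 30 * np.sin(2 * np.pi * t) + 10 * np.cos(4 * np.pi * t)
        short = g.time_normalize(curve(t_short), 500)
        long = g.time_normalize(curve(t_long), 500)
        assert np.abs(short - long).max() / np.ptp(short) < 0.01


class TestNormalizeDataset:
    def test_pooled_blocks_standardized(self, small_study):
        _, _, dm = small_study
        angle = dm.values[:, list(ANGLE_ROWS), :]
        force = dm.values[:, list(FORCE_ROWS), :]
        assert abs(angle.mean()) < 1e-9 and abs(angle.std() - 1.0) < 1e-9
        assert abs(force.mean()) < 1e-9 and abs(force.std() - 1.0) < 1e-9

    def test_flattened_lengths(self, small_study):
        _, _, dm = small_study
        assert dm.vectors.shape[1] == 7500
        assert dm.angles_only().vectors.shape[1] == 5000

    def test_angles_only_is_row_subset(self, small_study):
        _, _, dm = small_study
        sub = dm.angles_only()
        np.testing.assert_array_equal(sub.values, dm.values[:, list(ANGLE_ROWS), :])

    def test_zero_variance_rejected(self):
        mats = [g.FeatureMatrix("S0", "o", i, np.ones((15, 500))) for i in range(3)]
        with pytest.raises(DegenerateDataError):
            g.normalize_dataset(mats)


class TestSubstitute:
    def test_keep_all_is_identity(self, small_study):
        _, _, dm = small_study
        out = g.substitute_features(dm, range(15), np.random.default_rng(0))
        np.testing.assert_array_equal(out.values, dm.values)

    def test_empty_keep_rejected(self, small_study):
        _, _, dm = small_study
        with pytest.raises(ConfigurationError):
            g.substitute_features(dm, [], np.random.default_rng(0))

    def test_replaced_rows_standard_normal(self, small_study):
        _, _, dm = small_study
        keep = [0, 3, 5, 7, 9, 11]
        out = g.substitute_features(dm, keep, np.random.default_rng(12))
        drop = [i for i in range(15) if i not in keep]
        block = out.values[:, drop, :]
        assert block.size > 1e4
        assert abs(block.mean()) < 0.05 and abs(block.std() - 1.0) < 0.05
        np.testing.assert_array_equal(out.values[:, keep, :], dm.values[:, keep, :])

    def test_noncontact_force_rows_carry_no_subject_signal(self):
        """Classifying on reach-phase force rows (noise-substituted) is at
        chance level."""
        from graspid.analysis import cross_validate_features

        cfg = g.SyntheticConfig(n_subjects=5, n_objects=1, n_trials_per_object=6, seed=9)
        dm = g.build_dataset_matrix(g.generate_dataset(cfg), mode="phase_equalized", seed=9)
        reach_force = dm.values[:, list(FORCE_ROWS), :250].reshape(dm.n_trials, -1)
        rep = cross_validate_features(reach_force, dm.subjects, n_folds=3, seed=0)
        assert rep.mean_accuracy < 0.2 + 0.25  # chance 0.2 within MC slack


@given(st.integers(min_value=2, max_value=40), st.integers(min_value=2, max_value=600))
def test_time_normalize_preserves_endpoints(n_in, n_out):
    x = np.linspace(-3.0, 7.0, n_in) ** 2
    out = g.time_normalize(x, n_out)
    assert out.shape == (n_out,)
    assert out[0] == pytest.approx(x[0]) and out[-1] == pytest.approx(x[-1])
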