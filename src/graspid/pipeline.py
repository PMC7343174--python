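"""End-to-end extraction: raw trial recordings to a classifiable dataset.

This ties the stage modules together in the order the measurement chain
dictates: marker trajectories are low-pass filtered (15 Hz) and reduced to
ten joint angles; force voltages are mains-notched (50 Hz), decimated
960 -> 120 Hz and mapped to newtons through the subject's calibration
curves; phases are segmented; and each trial becomes a time-normalised
15 x 500 feature matrix. The trial collection is then z-normalised into a
:class:`~graspid.features.DatasetMatrix`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import GraspidError
from .features import (
    DatasetMatrix,
    FeatureMatrix,
    PhaseSegmentation,
    assemble_feature_matrix,
    normalize_dataset,
    segment_phases,
)
from .kinematics import FINGERS, extract_joint_angles, wrist_speed
from .kinetics import (
    CalibrationCurve,
    bandstop_mains,
    downsample_to_kinematic_rate,
    fit_calibration,
    voltage_to_force,
)
from .synthetic import SyntheticDataset, TrialRecording

logger = logging.getLogger(__name__)


def forces_in_newtons(
    trial: TrialRecording,
    curves: dict[str, CalibrationCurve],
    notch_mains: bool = True,
) -> np.ndarray:
    """(5, T_k) calibrated force block at the kinematic rate."""
    volts = np.asarray(trial.force_block, dtype=float)
    if notch_mains:
        volts = bandstop_mains(volts, rate_hz=trial.force_rate)
    factor = int(round(trial.force_rate / trial.kinematic_rate))
    volts = downsample_to_kinematic_rate(volts, factor=factor)
    out = np.empty_like(volts)
    for i, finger in enumerate(FINGERS):
        out[i] = voltage_to_force(curves[finger], volts[i])
    return out


def extract_trial(
    trial: TrialRecording,
    curves: dict[str, CalibrationCurve],
    mode: str = "full",
    rng: np.random.Generator | None = None,
    target_length: int = 500,
    use_true_bounds: bool = False,
) -> FeatureMatrix:
    """One trial -> 15 x ``target_length`` feature matrix.

    ``use_true_bounds`` bypasses phase detection with the generator's ground
    truth (diagnostics / round-trip tests only).
    """
    angles = extract_joint_angles(trial)
    forces = forces_in_newtons(trial, curves)
    T = min(angles.values.shape[1], forces.shape[1])
    angles.values = angles.values[:, :T]
    forces = forces[:, :T]
    if use_true_bounds and trial.true_phase_bounds is not None:
        b = trial.true_phase_bounds
        seg = PhaseSegmentation(*(min(int(x), T - 1) for x in b))
    else:
        speed = wrist_speed(trial)[:T]
        seg = segment_phases(angles, forces, speed)
    return assemble_feature_matrix(
        angles, forces, seg, mode=mode,
        subject_id=trial.subject_id, object_id=trial.object_id,
        trial_index=trial.trial_index, target_length=target_length, rng=rng,
    )


def build_dataset_matrix(
    dataset: SyntheticDataset,
    mode: str = "full",
    angles_only: bool = False,
    target_length: int = 500,
    seed: int = 0,
    skip_failures: bool = True,
    use_true_bounds: bool = False,
) -> DatasetMatrix:
    """Extract and z-normalise every trial of a synthetic study.

    Trials whose phase segmentation fails are rejected and logged (mirroring
    the rejection of recordings with missing data); set
    ``skip_failures=False`` to raise instead.
    """
    curves = {
        sid: {f: fit_calibration(rec) for f, rec in cal.items()}
        for sid, cal in dataset.calibrations.items()
    }
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 23)))
    matrices, rejected = [], []
    for trial in dataset.trials:
        try:
            matrices.append(extract_trial(
                trial, curves[trial.subject_id], mode=mode, rng=rng,
                target_length=target_length, use_true_bounds=use_true_bounds,
            ))
        except GraspidError as e:
            if not skip_failures:
                raise
            rejected.append((trial.subject_id, trial.object_id, trial.trial_index, str(e)))
            logger.warning("rejected trial %s/%s/%d: %s", trial.subject_id,
                           trial.object_id, trial.trial_index, e)
    if rejected:
        logger.info("rejected %d of %d trials", len(rejected), len(dataset.trials))
    ds = normalize_dataset(matrices, hand_sizes=dataset.hand_sizes)
    return ds.angles_only() if angles_only else ds
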