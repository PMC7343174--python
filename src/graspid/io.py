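"""Plain-text persistence of trials, calibrations, datasets and reports.

One directory per trial: ``markers.csv`` (frame, marker, x, y, z in mm),
``forces.csv`` (sample, f1..f5 in volts) and ``meta.json`` (identity, rates,
handedness, ground-truth phase bounds when known). A dataset manifest JSON
lists every trial directory. Calibration recordings are CSVs with columns
sample, voltage, displacement_mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .features import DatasetMatrix
from .kinematics import FINGERS, MARKER_NAMES
from .kinetics import CalibrationRecording
from .synthetic import SyntheticDataset, TrialRecording


def trial_dirname(trial: TrialRecording) -> str:
    return f"{trial.subject_id}_{trial.object_id}_t{trial.trial_index:02d}"


def write_trial(trial: TrialRecording, out_dir: Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_markers, T, _ = trial.marker_block.shape
    frames = np.repeat(np.arange(T), n_markers)
    labels = np.tile(np.array(MARKER_NAMES[:n_markers]), T)
    xyz = trial.marker_block.transpose(1, 0, 2).reshape(-1, 3)
    pd.DataFrame({
        "frame": frames, "marker": labels,
        "x": xyz[:, 0], "y": xyz[:, 1], "z": xyz[:, 2],
    }).to_csv(out / "markers.csv", index=False, float_format="%.4f")
    fdf = pd.DataFrame(trial.force_block.T, columns=[f"f{i + 1}" for i in range(5)])
    fdf.insert(0, "sample", np.arange(trial.force_block.shape[1]))
    fdf.to_csv(out / "forces.csv", index=False, float_format="%.6f")
    meta = {
        "subject_id": trial.subject_id,
        "object_id": trial.object_id,
        "trial_index": trial.trial_index,
        "kinematic_rate": trial.kinematic_rate,
        "force_rate": trial.force_rate,
        "handedness": trial.handedness,
        "true_phase_bounds": list(trial.true_phase_bounds)
        if trial.true_phase_bounds is not None else None,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def read_trial(trial_dir: Path) -> TrialRecording:
    trial_dir = Path(trial_dir)
    meta = json.loads((trial_dir / "meta.json").read_text())
    mdf = pd.read_csv(trial_dir / "markers.csv")
    T = int(mdf["frame"].max()) + 1
    markers = np.full((len(MARKER_NAMES), T, 3), np.nan)
    name_to_idx = {n: i for i, n in enumerate(MARKER_NAMES)}
    idx = mdf["marker"].map(name_to_idx).to_numpy()
    markers[idx, mdf["frame"].to_numpy()] = mdf[["x", "y", "z"]].to_numpy()
    fdf = pd.read_csv(trial_dir / "forces.csv")
    forces = fdf[[f"f{i + 1}" for i in range(5)]].to_numpy().T
    bounds = meta.get("true_phase_bounds")
    return TrialRecording(
        subject_id=meta["subject_id"],
        object_id=meta["object_id"],
        trial_index=int(meta["trial_index"]),
        marker_block=markers,
        force_block=forces,
        kinematic_rate=float(meta["kinematic_rate"]),
        force_rate=float(meta["force_rate"]),
        handedness=meta.get("handedness", "right"),
        true_phase_bounds=tuple(bounds) if bounds else None,
    )


def write_calibration(cal: dict, out_dir: Path) -> Path:
    """Write {finger: CalibrationRecording} as one CSV per finger/repetition."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for finger, rec in cal.items():
        for r, (volts, disp) in enumerate(rec.repetitions):
            pd.DataFrame({
                "sample": np.arange(len(volts)),
                "voltage": volts,
                "displacement_mm": disp,
            }).to_csv(out / f"{finger}_rep{r}.csv", index=False, float_format="%.6f")
    (out / "spring.json").write_text(json.dumps(
        {"spring_constant": next(iter(cal.values())).spring_constant}
    ))
    return out


def read_calibration(cal_dir: Path) -> dict:
    cal_dir = Path(cal_dir)
    k = json.loads((cal_dir / "spring.json").read_text())["spring_constant"]
    out = {}
    for finger in FINGERS:
        reps = []
        for path in sorted(cal_dir.glob(f"{finger}_rep*.csv")):
            df = pd.read_csv(path)
            reps.append((df["voltage"].to_numpy(), df["displacement_mm"].to_numpy()))
        if reps:
            out[finger] = CalibrationRecording(finger, reps, spring_constant=k)
    return out


def write_dataset(dataset: SyntheticDataset, out_dir: Path) -> Path:
    """Write every trial and calibration session plus a manifest JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for trial in dataset.trials:
        d = write_trial(trial, out / "trials" / trial_dirname(trial))
        entries.append(str(d.relative_to(out)))
    for sid, cal in dataset.calibrations.items():
        write_calibration(cal, out / "calibration" / sid)
    manifest = {
        "n_subjects": dataset.config.n_subjects,
        "n_objects": dataset.config.n_objects,
        "n_trials_per_object": dataset.config.n_trials_per_object,
        "hand_sizes": dataset.hand_sizes,
        "trials": entries,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out


@dataclass
class TrialValidation:
    path: str
    passed: bool
    reasons: list = field(default_factory=list)


def validate_trial_files(paths) -> list[TrialValidation]:
    """Structural validation of trial directories.

    Checks: readable files, exactly 20 markers, no missing marker frames,
    force block length = rate ratio x marker block length. Failing trials
    are reported with reasons so no exclusion is silent.
    """
    reports = []
    for p in paths:
        p = Path(p)
        reasons = []
        try:
            trial = read_trial(p)
        except (OSError, KeyError, ValueError) as e:
            reports.append(TrialValidation(str(p), False, [f"unreadable: {e}"]))
            continue
        mdf = pd.read_csv(p / "markers.csv")
        n_markers = mdf["marker"].nunique()
        if n_markers != len(MARKER_NAMES):
            reasons.append(f"marker count: expected {len(MARKER_NAMES)}, got {n_markers}")
        if not np.isfinite(trial.marker_block[:n_markers]).all():
            reasons.append("missing frames: non-finite marker coordinates")
        ratio = trial.force_rate / trial.kinematic_rate
        expected_T_f = int(round(ratio)) * trial.marker_block.shape[1]
        if trial.force_block.shape[1] != expected_T_f:
            reasons.append(
                f"rate ratio: force block has {trial.force_block.shape[1]} samples, "
                f"expected {expected_T_f}"
            )
        reports.append(TrialValidation(str(p), not reasons, reasons))
    return reports


def load_dataset(root: Path) -> tuple:
    """Load a written dataset back, excluding (and reporting) invalid trials."""
    root = Path(root)
    manifest = json.loads((root / "manifest.json").read_text())
    paths = [root / rel for rel in manifest["trials"]]
    validations = validate_trial_files(paths)
    trials = [read_trial(p) for p, v in zip(paths, validations) if v.passed]
    calibrations = {
        d.name: read_calibration(d) for d in sorted((root / "calibration").iterdir())
        if d.is_dir()
    }
    return trials, manifest, validations, calibrations


@dataclass
class LoadedDataset:
    """Duck-typed stand-in for a generated study, backed by files on disk;
    accepted anywhere a :class:`~graspid.synthetic.SyntheticDataset` is."""

    trials: list
    calibrations: dict
    hand_sizes: dict


def open_dataset(root: Path) -> LoadedDataset:
    trials, manifest, _, calibrations = load_dataset(root)
    return LoadedDataset(trials=trials, calibrations=calibrations,
                         hand_sizes=manifest.get("hand_sizes", {}))


def write_dataset_matrix_csv(ds: DatasetMatrix, path: Path) -> Path:
    """One row per trial: subject, object, trial, then the flattened vector."""
    path = Path(path)
    vec = ds.vectors
    cols = [f"{name}_{j:03d}" for name in ds.feature_names for j in range(ds.n_samples)]
    df = pd.DataFrame(vec, columns=cols)
    df.insert(0, "trial", ds.trial_indices)
    df.insert(0, "object", ds.objects)
    df.insert(0, "subject", ds.subjects)
    df.to_csv(path, index=False, float_format="%.5f")
    return path


def write_report_json(report, path: Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(report.to_dict(), indent=1))
    return path


def write_confusion_csv(report, path: Path) -> Path:
    path = Path(path)
    labels = [str(c) for c in report.class_order]
    pd.DataFrame(report.confusion, index=labels, columns=labels).to_csv(path)
    return path
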