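"""Per-trial feature assembly and dataset normalization.

Each trial is reduced to a 15 x 500 matrix: ten joint-angle rows (deg) and
five fingertip-force rows (N), time-normalised to 500 samples so trials of
different duration are comparable. Rows are ordered per finger as
(theta1, theta2, force) for thumb, index, middle, ring, pinky.

Three croppings are supported:

* ``full`` — the whole movement (reach + grasp + release) resampled to 500;
* ``no_release`` — the release phase discarded, the remainder to 500;
* ``phase_equalized`` — reach and grasp each resampled to 250 samples and
  concatenated, removing the between-subject variance in the reach/grasp
  duration proportion.

In the latter two modes force samples outside the contact interval carry no
signal and are replaced by standard-normal noise (matching the scale of the
z-normalised data), so classification cannot exploit sensor idiosyncrasies
during non-contact motion.

Dataset normalization pools one (mean, std) pair over all angle entries of
all trials and a separate pair over all force entries, producing
dimensionless vectors of length 7500 (or 5000 angles-only).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateDataError,
    InputTooShortError,
    SegmentationError,
)
from .kinematics import ANGLE_NAMES, FINGERS, AngleSeriesSet

#: Fixed feature order: per finger theta1, theta2, force.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{finger}_{feat}" for finger in FINGERS for feat in ("theta1", "theta2", "force")
)
ANGLE_ROWS: tuple[int, ...] = tuple(
    i for i, n in enumerate(FEATURE_NAMES) if not n.endswith("force")
)
FORCE_ROWS: tuple[int, ...] = tuple(
    i for i, n in enumerate(FEATURE_NAMES) if n.endswith("force")
)

MODES = ("full", "no_release", "phase_equalized")


@dataclass(frozen=True)
class PhaseSegmentation:
    """Frame indices (120 Hz) of the phase transitions of one trial."""

    movement_onset: int
    contact_onset: int
    release_onset: int
    movement_end: int

    def __post_init__(self) -> None:
        b = (self.movement_onset, self.contact_onset, self.release_onset, self.movement_end)
        if any(x < 0 for x in b) or not all(b[i] < b[i + 1] for i in range(3)):
            raise SegmentationError(f"phase bounds must be strictly increasing, got {b}")


def segment_phases(
    angles: AngleSeriesSet,
    forces_newtons: np.ndarray,
    wrist_marker_speed: np.ndarray,
    speed_threshold: float = 50.0,   # mm/s
    speed_floor: float = 10.0,       # mm/s, onset backtrack level
    force_threshold: float = 0.5,    # N summed over fingers
    force_floor: float = 0.05,       # N, contact backtrack level
    min_duration_frames: int = 6,
) -> PhaseSegmentation:
    """Detect reach/grasp/release boundaries of a trial.

    Movement onset/end come from the wrist speed crossing ``speed_threshold``
    (sustained for ``min_duration_frames``), backtracked to where the speed
    last fell below ``speed_floor`` — thresholds alone lag a smooth movement
    onset by several frames. Contact and release come from the total
    fingertip force crossing ``force_threshold`` with the same debouncing and
    a backtrack to ``force_floor``.
    """
    speed = np.asarray(wrist_marker_speed, dtype=float)
    forces = np.atleast_2d(np.asarray(forces_newtons, dtype=float))
    total_force = forces.sum(axis=0)
    T = speed.shape[0]
    if total_force.shape[0] != T or angles.values.shape[1] != T:
        raise ValueError("angles, forces and wrist speed must share one time base")

    onset = _sustained_crossing(speed, speed_threshold, min_duration_frames, "first")
    end = _sustained_crossing(speed, speed_threshold, min_duration_frames, "last")
    if onset is None or end is None:
        raise SegmentationError("no wrist movement detected")
    # floors adapt to the measured rest-phase noise level so the backtrack
    # cannot walk through a noise floor that sits above the nominal value
    speed_floor = _adaptive_floor(speed, onset - 6, speed_floor)
    onset = _backtrack(speed, onset, speed_floor, direction=-1)
    end = _backtrack(speed, end, speed_floor, direction=+1)

    contact = _sustained_crossing(total_force, force_threshold, min_duration_frames, "first")
    release = _sustained_crossing(total_force, force_threshold, min_duration_frames, "last")
    if contact is None or release is None:
        raise SegmentationError("no object contact detected (total force never "
                                f"exceeded {force_threshold} N); trial rejected")
    force_floor = _adaptive_floor(total_force, contact - 12, force_floor)
    contact = _backtrack(total_force, contact, force_floor, direction=-1)
    release = _backtrack(total_force, release, force_floor, direction=+1)

    onset = min(onset, contact - 1)
    end = max(end, release + 1)
    return PhaseSegmentation(int(onset), int(contact), int(release), int(end))


def _adaptive_floor(x: np.ndarray, upto: int, floor: float) -> float:
    """Raise a backtrack floor above the contact-free noise level observed
    in the first ``upto`` samples (kept unchanged for clean signals)."""
    if upto > 8:
        floor = max(floor, 1.1 * float(np.quantile(x[:upto], 0.99)))
    return floor


def _sustained_crossing(x: np.ndarray, threshold: float, min_frames: int, which: str):
    above = x > threshold
    if min_frames > 1:
        kernel = np.ones(min_frames)
        sustained = np.convolve(above.astype(float), kernel, mode="valid") == min_frames
        idx = np.nonzero(sustained)[0]
        if idx.size == 0:
            return None
        return int(idx[0]) if which == "first" else int(idx[-1] + min_frames - 1)
    idx = np.nonzero(above)[0]
    if idx.size == 0:
        return None
    return int(idx[0]) if which == "first" else int(idx[-1])


def _backtrack(x: np.ndarray, start: int, floor: float, direction: int) -> int:
    """Walk from a threshold crossing towards the true edge of the event:
    first to where the signal drops below ``floor``, then down any remaining
    monotone slope (a smooth onset keeps decreasing towards the true edge,
    while in stationary noise the walk stops immediately)."""
    i = start
    n = x.shape[0]
    while 0 <= i + direction < n and x[i] > floor:
        i += direction
    while 0 <= i + direction < n and x[i + direction] < x[i]:
        i += direction
    return i


def time_normalize(series_block: np.ndarray, target_length: int = 500) -> np.ndarray:
    """Resample each row to ``target_length`` samples by linear interpolation
    over a normalized [0, 1] time axis; endpoints are preserved exactly."""
    block = np.atleast_2d(np.asarray(series_block, dtype=float))
    T = block.shape[-1]
    if T < 2:
        raise InputTooShortError("need at least 2 samples to time-normalize")
    if target_length < 2:
        raise ConfigurationError("target length must be >= 2")
    src = np.linspace(0.0, 1.0, T)
    dst = np.linspace(0.0, 1.0, target_length)
    out = np.empty(block.shape[:-1] + (target_length,))
    for idx in np.ndindex(block.shape[:-1]):
        out[idx] = np.interp(dst, src, block[idx])
    return out if series_block.ndim > 1 else out[0]


@dataclass
class FeatureMatrix:
    """One trial's 15 x 500 feature matrix (10 angle rows in deg, 5 force
    rows in N) plus identity metadata."""

    subject_id: str
    object_id: str
    trial_index: int
    values: np.ndarray
    mode: str = "full"
    feature_names: tuple[str, ...] = FEATURE_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape[0] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} feature rows, got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("feature matrix contains non-finite values")


def assemble_feature_matrix(
    angles: AngleSeriesSet,
    forces_newtons: np.ndarray,
    segmentation: PhaseSegmentation,
    mode: str = "full",
    subject_id: str = "",
    object_id: str = "",
    trial_index: int = 0,
    target_length: int = 500,
    rng: np.random.Generator | None = None,
) -> FeatureMatrix:
    """Crop, time-normalize and interleave angles and forces into one matrix.

    ``rng`` seeds the standard-normal substitution of non-contact force
    samples in the ``no_release`` and ``phase_equalized`` modes (fresh draws
    per call, so sensitivity repeats see new noise).
    """
    if mode not in MODES:
        raise ConfigurationError(f"unknown mode {mode!r}; expected one of {MODES}")
    forces = np.atleast_2d(np.asarray(forces_newtons, dtype=float))
    if forces.shape[0] != len(FINGERS):
        raise ValueError(f"expected {len(FINGERS)} force rows, got {forces.shape[0]}")
    rng = rng if rng is not None else np.random.default_rng(0)

    # interleave rows per finger: theta1, theta2, force
    T = angles.values.shape[1]
    stacked = np.empty((len(FEATURE_NAMES), T))
    for i in range(len(FINGERS)):
        stacked[3 * i] = angles.values[2 * i]
        stacked[3 * i + 1] = angles.values[2 * i + 1]
        stacked[3 * i + 2] = forces[i]

    s = segmentation
    force_rows = np.asarray(FORCE_ROWS)
    if mode == "full":
        out = time_normalize(stacked[:, s.movement_onset:s.movement_end + 1], target_length)
    elif mode == "no_release":
        out = time_normalize(stacked[:, s.movement_onset:s.release_onset + 1], target_length)
        contact_frac = (s.contact_onset - s.movement_onset) / (s.release_onset - s.movement_onset)
        cols = np.linspace(0.0, 1.0, target_length) < contact_frac
        out[np.ix_(force_rows, np.nonzero(cols)[0])] = rng.standard_normal(
            (force_rows.size, int(cols.sum()))
        )
    else:  # phase_equalized
        half = target_length // 2
        reach = time_normalize(stacked[:, s.movement_onset:s.contact_onset + 1], half)
        grasp = time_normalize(stacked[:, s.contact_onset:s.release_onset + 1], target_length - half)
        reach[force_rows] = rng.standard_normal((force_rows.size, half))
        out = np.concatenate([reach, grasp], axis=1)

    return FeatureMatrix(subject_id, object_id, trial_index, out, mode=mode)


@dataclass
class DatasetMatrix:
    """Z-normalised trial collection ready for embedding and classification.

    ``values`` is (n_trials, n_features, n_samples); ``vectors`` flattens
    each trial row-major (feature-major), giving 7500-long vectors for the
    full 15 x 500 matrices and 5000-long for the angles-only view.
    """

    values: np.ndarray
    subjects: np.ndarray
    objects: np.ndarray
    trial_indices: np.ndarray
    feature_names: tuple[str, ...]
    mode: str = "full"
    hand_sizes: dict | None = None
    angle_stats: tuple[float, float] | None = None
    force_stats: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subjects = np.asarray(self.subjects)
        self.objects = np.asarray(self.objects)
        self.trial_indices = np.asarray(self.trial_indices)
        n = self.values.shape[0]
        if not (len(self.subjects) == len(self.objects) == len(self.trial_indices) == n):
            raise ValueError("label arrays must match the number of trials")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match the feature axis")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    @property
    def vectors(self) -> np.ndarray:
        return self.values.reshape(self.n_trials, -1)

    def angles_only(self) -> "DatasetMatrix":
        """Exact row-subset of the matrix keeping only the angle features."""
        rows = [i for i, name in enumerate(self.feature_names) if not name.endswith("force")]
        return replace(
            self,
            values=self.values[:, rows, :],
            feature_names=tuple(self.feature_names[i] for i in rows),
            force_stats=None,
        )

    def select_objects(self, object_ids) -> "DatasetMatrix":
        keep = np.isin(self.objects, np.asarray(list(object_ids)))
        return replace(
            self,
            values=self.values[keep],
            subjects=self.subjects[keep],
            objects=self.objects[keep],
            trial_indices=self.trial_indices[keep],
        )


def normalize_dataset(
    matrices: list[FeatureMatrix],
    hand_sizes: dict | None = None,
) -> DatasetMatrix:
    """Pool all trials and z-normalise angle and force blocks separately.

    One (mean, std) pair is computed over every angle entry of every trial,
    and another over every force entry, so the output is dimensionless and
    the two blocks are on a common scale.
    """
    if len(matrices) < 2:
        raise ConfigurationError("need at least 2 trials to normalize a dataset")
    names = matrices[0].feature_names
    if any(m.feature_names != names for m in matrices):
        raise ConfigurationError("all trials must share one feature ordering")
    values = np.stack([m.values for m in matrices])  # (n, 15, L)
    angle_rows = [i for i, n in enumerate(names) if not n.endswith("force")]
    force_rows = [i for i, n in enumerate(names) if n.endswith("force")]

    stats = {}
    for key, rows in (("angle", angle_rows), ("force", force_rows)):
        if not rows:
            continue
        block = values[:, rows, :]
        mu, sd = float(block.mean()), float(block.std())
        if sd <= 0:
            raise DegenerateDataError(f"pooled {key} block has zero variance")
        values[:, rows, :] = (block - mu) / sd
        stats[key] = (mu, sd)

    return DatasetMatrix(
        values=values,
        subjects=np.array([m.subject_id for m in matrices]),
        objects=np.array([m.object_id for m in matrices]),
        trial_indices=np.array([m.trial_index for m in matrices]),
        feature_names=names,
        mode=matrices[0].mode,
        hand_sizes=hand_sizes,
        angle_stats=stats.get("angle"),
        force_stats=stats.get("force"),
    )


def substitute_features(
    dataset: DatasetMatrix,
    keep,
    rng: np.random.Generator,
) -> DatasetMatrix:
    """Replace every feature row not in ``keep`` by standard-normal noise.

    This is the sensitivity-analysis substitution: the input dimensionality
    and the (z-normalised) distribution are unchanged, so the downstream
    pipeline runs with identical parameters while the excluded features
    carry no information.
    """
    keep = sorted(set(int(i) for i in keep))
    if not keep:
        raise ConfigurationError("keep set must be non-empty")
    if keep[0] < 0 or keep[-1] >= dataset.n_features:
        raise ConfigurationError(f"feature indices out of range 0..{dataset.n_features - 1}")
    drop = [i for i in range(dataset.n_features) if i not in keep]
    values = dataset.values.copy()
    if drop:
        values[:, drop, :] = rng.standard_normal((dataset.n_trials, len(drop), dataset.n_samples))
    return replace(dataset, values=values)


def substitute_time_window(
    dataset: DatasetMatrix,
    start: int,
    width: int,
    rng: np.random.Generator,
) -> DatasetMatrix:
    """Keep only the columns [start, start+width) of every feature row and
    replace everything outside the window by standard-normal noise."""
    if width < 1 or start < 0 or start + width > dataset.n_samples:
        raise ConfigurationError("time window outside the sample range")
    values = rng.standard_normal(dataset.values.shape)
    values[:, :, start:start + width] = dataset.values[:, :, start:start + width]
    if width == dataset.n_samples:
        values = dataset.values.copy()
    return replace(dataset, values=values)
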