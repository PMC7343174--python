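"""Synthetic multi-subject grasp recordings.

The generator emulates the study design the analysis pipeline assumes:
31 subjects x 5 objects x 7 trials of a reach-grasp-release prehension task,
recorded as 20 hand-marker trajectories (mm, 120 Hz) and 5 fingertip force
voltages (V, 960 Hz), plus a per-subject spring-platform calibration session.

Each subject owns smooth angle and force templates — a population-mean curve
plus a random band-limited perturbation — so grasping patterns are stable
within a subject and differ between subjects, which is exactly the structure
the classification stage tries to detect. Marker positions are synthesised
with a planar-per-finger forward kinematic chain built so that the two
angles per finger fully determine the marker geometry: angle extraction
applied to a noise-free trial recovers the generating templates.

Templates are low-order harmonic expansions. Perturbation coefficients are
scaled so the pointwise standard deviation across subjects equals
``subject_effect_scale`` at every time point (the harmonic pairs satisfy
cos^2 + sin^2 = 1), which makes effect sizes directly interpretable.

Force channels are zero-mean sensor noise plus a 50 Hz mains sinusoid with
random phase outside contact, and the template force mapped through the
subject's (mildly nonlinear) sensor response during the grasp phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .kinematics import FINGERS, MARKER_NAMES
from .kinetics import CalibrationRecording

N_HARMONICS = 4
OBJECT_NAMES = ("tennis_ball", "bottle_full", "bottle_half",
                "ellipsoid_soft", "ellipsoid_stiff")
#: Geometrically distinct objects (the two bottles share one shape, as do
#: the two ellipsoids), used for grip-type classification.
GEOMETRIC_OBJECTS = ("tennis_ball", "bottle_full", "ellipsoid_soft")

_MARKER_ROLES = tuple(
    ("finger", name.split("_")[0], name.split("_")[1]) if i < 15
    else (("palm", "", name) if i < 18 else ("wrist", "", name))
    for i, name in enumerate(MARKER_NAMES)
)


@dataclass
class SyntheticConfig:
    """Study-design parameters of the synthetic dataset.

    Defaults reproduce the experimental design: 31 subjects, 5 objects,
    7 trials per object (35 grasps per subject), kinematics at 120 Hz,
    forces at 960 Hz, spring constant 0.45 N/mm.
    """

    n_subjects: int = 31
    n_objects: int = 5
    n_trials_per_object: int = 7
    subject_effect_scale: float = 1.0   # deg / N, between-subject template std
    trial_noise_scale: float = 0.25     # deg / N, within-subject trial std
    object_effect_scale: float = 1.0    # deg, between-object template std
    mains_noise_amplitude: float = 0.05  # V, 50 Hz hum amplitude
    sensor_noise_std: float = 0.02      # V, white sensor noise
    marker_noise_std_mm: float = 0.1    # mm, optical marker noise
    kinematic_rate: float = 120.0       # Hz
    force_rate: float = 960.0           # Hz
    # (min, max) seconds for reach, grasp, release subject means
    phase_duration_ranges: tuple = ((0.7, 1.3), (1.2, 2.2), (0.7, 1.3))
    rest_duration: float = 0.4          # s of stillness before/after movement
    duration_jitter_frac: float = 0.15  # per-trial duration jitter (off at zero trial noise)
    spring_constant: float = 0.45       # N/mm
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_objects", "n_trials_per_object"):
            if int(getattr(self, name)) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("subject_effect_scale", "trial_noise_scale",
                     "object_effect_scale", "mains_noise_amplitude",
                     "sensor_noise_std", "marker_noise_std_mm"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.kinematic_rate <= 0 or self.force_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        ratio = self.force_rate / self.kinematic_rate
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ConfigurationError(
                "force_rate must be an integer multiple of kinematic_rate"
            )
        if self.spring_constant <= 0:
            raise ConfigurationError("spring_constant must be positive")
        if len(self.phase_duration_ranges) != 3:
            raise ConfigurationError("need (reach, grasp, release) duration ranges")
        for lo, hi in self.phase_duration_ranges:
            if not 0 < lo <= hi:
                raise ConfigurationError("phase duration ranges must be positive")

    @property
    def rate_ratio(self) -> int:
        return int(round(self.force_rate / self.kinematic_rate))

    def object_names(self) -> list[str]:
        if self.n_objects <= len(OBJECT_NAMES):
            return list(OBJECT_NAMES[: self.n_objects])
        return [f"object_{i:02d}" for i in range(self.n_objects)]


@dataclass
class HarmonicSet:
    """Band-limited curves c0 + sum_j a_j cos(2 pi j t) + b_j sin(2 pi j t),
    one per row, evaluated on normalized time in [0, 1]."""

    c0: np.ndarray        # (n,)
    cos_coeffs: np.ndarray  # (n, m)
    sin_coeffs: np.ndarray  # (n, m)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        j = np.arange(1, self.cos_coeffs.shape[1] + 1)
        arg = 2.0 * np.pi * j[:, None] * t[None, :]       # (m, T)
        out = self.c0[:, None] + self.cos_coeffs @ np.cos(arg) + self.sin_coeffs @ np.sin(arg)
        return out

    def __add__(self, other: "HarmonicSet") -> "HarmonicSet":
        return HarmonicSet(self.c0 + other.c0,
                           self.cos_coeffs + other.cos_coeffs,
                           self.sin_coeffs + other.sin_coeffs)


def _perturbation(rng: np.random.Generator, n_rows: int, scale: float,
                  m: int = N_HARMONICS) -> HarmonicSet:
    """Random harmonic curves whose pointwise std across draws is ``scale``."""
    s = scale / np.sqrt(m)
    return HarmonicSet(
        c0=np.zeros(n_rows),
        cos_coeffs=rng.standard_normal((n_rows, m)) * s,
        sin_coeffs=rng.standard_normal((n_rows, m)) * s,
    )


def _sine_basis_curve(coeffs: np.ndarray, t: np.ndarray) -> np.ndarray:
    """sum_j coeffs[:, j-1] sin(pi j t): vanishes at t = 0 and t = 1."""
    j = np.arange(1, coeffs.shape[1] + 1)
    return coeffs @ np.sin(np.pi * j[:, None] * np.asarray(t)[None, :])


def _population_angle_means() -> HarmonicSet:
    """Fixed population-mean angle templates (deg) on normalized movement
    time: theta1 dips and theta2 rises towards mid-movement (peak flexion
    around the grasp), with small per-finger offsets."""
    c0 = np.empty(10)
    cos = np.zeros((10, N_HARMONICS))
    sin = np.zeros((10, N_HARMONICS))
    for i in range(5):
        # theta1 = (95 + 2i) - 18 * bump(t), bump = (1 - cos 2 pi t) / 2
        c0[2 * i] = 95.0 + 2.0 * i - 9.0
        cos[2 * i, 0] = 9.0
        # theta2 = (18 + 3i) + 44 * bump(t)
        c0[2 * i + 1] = 18.0 + 3.0 * i + 22.0
        cos[2 * i + 1, 0] = -22.0
    return HarmonicSet(c0, cos, sin)


_POPULATION_FORCE_PEAKS = np.array([6.0, 5.0, 4.5, 3.5, 2.5])  # N per finger


@dataclass
class SubjectProfile:
    """Stable per-subject grasping pattern: hand size, angle and force
    templates, sensor response and preferred phase durations."""

    subject_id: str
    subject_index: int
    hand_size: float                    # mm, wrist to middle fingertip
    handedness: str                     # "right" | "left"
    angle_curves: HarmonicSet           # 10 rows, deg, on movement time
    force_peaks: np.ndarray             # (5,) N
    force_shape_coeffs: np.ndarray      # (5, m) sine-basis, grasp time
    phase_duration_means: np.ndarray    # (3,) s: reach, grasp, release
    sensor_gain: np.ndarray             # (5,) V/N
    sensor_quad: np.ndarray             # (5,) V/N^2

    def angle_templates(self, t: np.ndarray) -> np.ndarray:
        """(10, len(t)) angle templates in deg, clipped to (0, 180)."""
        return np.clip(self.angle_curves(t), 1.0, 179.0)

    def force_templates(self, gamma: np.ndarray) -> np.ndarray:
        """(5, len(gamma)) force templates in N on grasp-phase time;
        non-negative and zero at both endpoints."""
        gamma = np.asarray(gamma, dtype=float)
        base = self.force_peaks[:, None] * np.sin(np.pi * gamma)[None, :]
        return np.maximum(base + _sine_basis_curve(self.force_shape_coeffs, gamma), 0.0)

    def sensor_response(self, force_n: np.ndarray) -> np.ndarray:
        """Voltage produced by each finger's sensor for a (5, T) force block."""
        f = np.asarray(force_n, dtype=float)
        return self.sensor_gain[:, None] * f + self.sensor_quad[:, None] * f**2


@dataclass
class TrialRecording:
    """One synthetic grasp trial."""

    subject_id: str
    object_id: str
    trial_index: int
    marker_block: np.ndarray            # (20, T_k, 3) mm
    force_block: np.ndarray             # (5, T_f) V
    kinematic_rate: float = 120.0
    force_rate: float = 960.0
    handedness: str = "right"
    marker_roles: tuple = _MARKER_ROLES
    true_phase_bounds: tuple[int, int, int, int] | None = None

    def __post_init__(self) -> None:
        self.marker_block = np.asarray(self.marker_block, dtype=float)
        self.force_block = np.asarray(self.force_block, dtype=float)


@dataclass
class SyntheticDataset:
    """Full synthetic study: profiles, trials and calibration sessions."""

    config: SyntheticConfig
    profiles: list[SubjectProfile]
    trials: list[TrialRecording]
    calibrations: dict  # subject_id -> {finger: CalibrationRecording}

    @property
    def hand_sizes(self) -> dict:
        return {p.subject_id: p.hand_size for p in self.profiles}


def _rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(tuple(int(k) for k in keys)))


def _rotation_matrix(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation from a normalised quaternion."""
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * u * (u * (6.0 * u - 15.0) + 10.0)


def generate_subject_profile(
    config: SyntheticConfig, subject_index: int,
    rng: np.random.Generator | None = None,
) -> SubjectProfile:
    """Draw one subject's stable grasping pattern.

    Deterministic given (config.seed, subject_index): templates are the
    population mean plus a smooth perturbation with pointwise std
    ``subject_effect_scale``.
    """
    if not 0 <= subject_index < config.n_subjects:
        raise ConfigurationError("subject_index out of range")
    rng = rng if rng is not None else _rng(config.seed, 11, subject_index)
    angle_curves = _population_angle_means() + _perturbation(
        rng, 10, config.subject_effect_scale
    )
    force_peaks = np.maximum(
        _POPULATION_FORCE_PEAKS + config.subject_effect_scale * 0.5 * rng.standard_normal(5),
        0.5,
    )
    m = N_HARMONICS
    force_shape = rng.standard_normal((5, m)) * (config.subject_effect_scale / np.sqrt(m))
    # preferred phase durations are part of the subject-specific pattern:
    # the deviation from the population mean scales with the effect size
    factor = min(config.subject_effect_scale, 1.0)
    durations = np.array([
        0.5 * (lo + hi) + factor * (rng.uniform(lo, hi) - 0.5 * (lo + hi))
        for lo, hi in config.phase_duration_ranges
    ])
    return SubjectProfile(
        subject_id=f"S{subject_index:02d}",
        subject_index=subject_index,
        hand_size=float(max(rng.normal(180.0, 12.0), 120.0)),
        handedness="left" if rng.random() < 4 / 31 else "right",
        angle_curves=angle_curves,
        force_peaks=force_peaks,
        force_shape_coeffs=force_shape,
        phase_duration_means=durations,
        sensor_gain=rng.uniform(0.35, 0.55, size=5),
        sensor_quad=rng.uniform(0.0, 0.01, size=5),
    )


def _object_effects(config: SyntheticConfig, object_index: int):
    """Object-dependent grasp-shape offset (shared by all subjects) and a
    weight/stiffness factor scaling the grip forces."""
    rng = _rng(config.seed, 19, object_index)
    angle_offset = _perturbation(rng, 10, config.object_effect_scale)
    force_factor = float(np.clip(
        1.0 + 0.25 * config.object_effect_scale * rng.standard_normal(), 0.2, 2.5
    ))
    return angle_offset, force_factor


# palm-plane geometry (unscaled, mm, palm normal = +z before rigid motion)
_PALM_OFFSETS = np.array([[15.0, 10.0, 0.0], [-15.0, 10.0, 0.0], [0.0, -20.0, 0.0]])
_WRIST_OFFSETS = np.array([[10.0, -45.0, 0.0], [-10.0, -45.0, 0.0]])
_FINGER_AZIMUTHS_DEG = np.array([-50.0, -15.0, 5.0, 25.0, 45.0]) + 90.0
_SEGMENT_LENGTHS = np.array([70.0, 30.0, 25.0])  # base, mid, tip segment, mm
_REFERENCE_HAND_SIZE = 180.0


def generate_trial(
    profile: SubjectProfile,
    object_id: str,
    trial_index: int,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    object_index: int | None = None,
) -> TrialRecording:
    """Synthesise one trial's marker block and force voltages.

    Marker positions come from a planar-per-finger forward chain inverted
    from the (object- and trial-perturbed) angle templates, rigidly moved
    along a smooth reach/transport/return hand path and finally rotated by a
    random rigid transform. Force voltages are the subject's sensor response
    to the template force during grasp, plus white sensor noise and a 50 Hz
    mains sinusoid with random phase throughout.
    """
    if object_index is None:
        names = config.object_names()
        object_index = names.index(object_id) if object_id in names else 0
    rng = rng if rng is not None else _rng(
        config.seed, 13, profile.subject_index, object_index, trial_index
    )
    angle_offset, force_factor = _object_effects(config, object_index)

    # phase durations: subject means, jittered per trial; the jitter
    # amplitude scales with the trial-noise level so a noise-free subject
    # repeats trials exactly
    durations = profile.phase_duration_means.copy()
    jitter = config.duration_jitter_frac * min(config.trial_noise_scale, 1.0)
    if jitter > 0:
        durations = durations * rng.uniform(1.0 - jitter, 1.0 + jitter, size=3)
    rate = config.kinematic_rate
    rest_f = int(round(config.rest_duration * rate))
    reach_f, grasp_f, release_f = (max(int(round(d * rate)), 8) for d in durations)
    onset = rest_f
    contact = onset + reach_f
    release = contact + grasp_f
    end = release + release_f
    T_k = end + rest_f
    T_f = config.rate_ratio * T_k

    # --- angles on normalized movement time ---
    frames = np.arange(T_k)
    tau = np.clip((frames - onset) / (end - onset), 0.0, 1.0)
    trial_angle_pert = _perturbation(rng, 10, config.trial_noise_scale)
    angles = np.clip(
        (profile.angle_curves + angle_offset + trial_angle_pert)(tau), 1.0, 179.0
    )  # (10, T_k), deg

    # --- forward kinematics ---
    scale = profile.hand_size / _REFERENCE_HAND_SIZE
    path = _hand_path(frames, onset, contact, release, end)  # (T_k, 3) mm
    markers = np.empty((20, T_k, 3))
    normal = np.array([0.0, 0.0, 1.0])
    L1, L2, L3 = _SEGMENT_LENGTHS * scale
    for i in range(5):
        phi = np.radians(_FINGER_AZIMUTHS_DEG[i])
        u = np.array([np.cos(phi), np.sin(phi), 0.0])
        th1 = np.radians(angles[2 * i])
        th2 = np.radians(angles[2 * i + 1])
        d1 = np.cos(th1)[:, None] * normal + np.sin(th1)[:, None] * u  # (T,3)
        w = -np.sin(th1)[:, None] * normal + np.cos(th1)[:, None] * u
        m1 = path + L1 * d1
        m2 = m1 + L2 * d1
        m3 = m2 + L3 * (np.cos(th2)[:, None] * d1 + np.sin(th2)[:, None] * w)
        markers[3 * i], markers[3 * i + 1], markers[3 * i + 2] = m1, m2, m3
    markers[15:18] = path[None, :, :] + scale * _PALM_OFFSETS[:, None, :]
    markers[18:20] = path[None, :, :] + scale * _WRIST_OFFSETS[:, None, :]

    # random rigid placement of the whole recording volume
    R = _rotation_matrix(rng)
    offset = rng.uniform(-100.0, 100.0, size=3)
    markers = markers @ R.T + offset
    if profile.handedness == "left":
        markers = markers.copy()
        markers[:, :, 0] *= -1.0
    if config.marker_noise_std_mm > 0:
        markers = markers + rng.normal(0.0, config.marker_noise_std_mm, markers.shape)

    # --- forces at the force rate ---
    t_f = np.arange(T_f) / config.force_rate
    t_contact, t_release = contact / rate, release / rate
    gamma = (t_f - t_contact) / (t_release - t_contact)
    in_grasp = (gamma >= 0.0) & (gamma <= 1.0)
    force_n = np.zeros((5, T_f))
    force_n[:, in_grasp] = force_factor * profile.force_templates(gamma[in_grasp])
    if config.trial_noise_scale > 0:
        trial_force_pert = rng.standard_normal((5, N_HARMONICS)) * (
            config.trial_noise_scale / np.sqrt(N_HARMONICS)
        )
        force_n[:, in_grasp] = np.maximum(
            force_n[:, in_grasp] + _sine_basis_curve(trial_force_pert, gamma[in_grasp]), 0.0
        )
    volts = profile.sensor_response(force_n)
    if config.sensor_noise_std > 0:
        volts = volts + rng.normal(0.0, config.sensor_noise_std, volts.shape)
    if config.mains_noise_amplitude > 0:
        phase = rng.uniform(0.0, 2.0 * np.pi, size=(5, 1))
        volts = volts + config.mains_noise_amplitude * np.sin(
            2.0 * np.pi * 50.0 * t_f[None, :] + phase
        )

    return TrialRecording(
        subject_id=profile.subject_id,
        object_id=object_id,
        trial_index=trial_index,
        marker_block=markers,
        force_block=volts,
        kinematic_rate=config.kinematic_rate,
        force_rate=config.force_rate,
        handedness=profile.handedness,
        true_phase_bounds=(onset, contact, release, end),
    )


def _hand_path(frames, onset, contact, release, end) -> np.ndarray:
    """Smooth rest -> object -> symmetric target -> rest hand trajectory."""
    p_rest = np.array([0.0, -250.0, 0.0])
    p_obj = np.array([150.0, 50.0, 30.0])
    p_target = np.array([-150.0, 50.0, 30.0])
    path = np.empty((len(frames), 3))
    seg = [(onset, contact, p_rest, p_obj),
           (contact, release, p_obj, p_target),
           (release, end, p_target, p_rest)]
    path[:onset] = p_rest
    for a, b, p0, p1 in seg:
        u = _smoothstep((np.arange(a, b) - a) / max(b - a, 1))
        path[a:b] = p0 + u[:, None] * (p1 - p0)
    path[end:] = p_rest
    return path


def generate_calibration(
    profile: SubjectProfile,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
    max_displacement_mm: float = 25.0,
    n_repetitions: int = 3,
) -> dict:
    """Simulate the spring-platform calibration session for one subject.

    Each repetition presses the platform from rest to the rail end
    (0 -> ``max_displacement_mm``); the applied force is k * dx and the
    recorded voltage is the subject's sensor response plus noise.
    Returns {finger: CalibrationRecording}.
    """
    rng = rng if rng is not None else _rng(config.seed, 17, profile.subject_index)
    n = int(round(2.0 * config.kinematic_rate))  # ~2 s press
    out = {}
    for i, finger in enumerate(FINGERS):
        reps = []
        for _ in range(n_repetitions):
            disp = max_displacement_mm * _smoothstep(np.linspace(0.0, 1.0, n))
            force = config.spring_constant * disp
            volts = (profile.sensor_gain[i] * force + profile.sensor_quad[i] * force**2)
            if config.sensor_noise_std > 0:
                volts = volts + rng.normal(0.0, config.sensor_noise_std, n)
            reps.append((volts, disp))
        out[finger] = CalibrationRecording(
            finger=finger, repetitions=reps, spring_constant=config.spring_constant
        )
    return out


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the full study: every subject x object x trial combination
    plus per-subject calibration sessions. With the default design each
    subject contributes 5 x 7 = 35 grasps (1085 trials for 31 subjects)."""
    objects = config.object_names()
    profiles = [generate_subject_profile(config, i) for i in range(config.n_subjects)]
    trials = []
    for profile in profiles:
        for obj_idx, obj in enumerate(objects):
            for t in range(config.n_trials_per_object):
                trials.append(generate_trial(
                    profile, obj, t, config, object_index=obj_idx
                ))
    calibrations = {p.subject_id: generate_calibration(p, config) for p in profiles}
    return SyntheticDataset(config, profiles, trials, calibrations)


def generate_feature_dataset(
    n_subjects: int = 8,
    n_trials_per_subject: int = 6,
    informative=(0, 1, 2, 3),
    n_features: int = 15,
    n_samples: int = 500,
    effect_scale: float = 1.0,
    noise_scale: float = 0.3,
    structure: str = "independent",
    object_id: str = "obj",
    seed: int = 0,
) -> "DatasetMatrix":
    """Directly synthesise a z-normalised DatasetMatrix with planted
    informative features.

    Rows listed in ``informative`` carry subject-specific signal plus white
    trial noise of std ``noise_scale``; all other rows are pure
    standard-normal noise. This bypasses the kinematic/kinetic synthesis and
    is the workhorse for sensitivity-analysis studies, where only the
    feature-level information structure matters.

    Two signal structures are available:

    * ``independent`` — each informative row carries its own smooth
      subject-specific template (pointwise between-subject std
      ``effect_scale``); features contribute additively to separability.
    * ``coded`` — subject identity is binary-coded across the informative
      rows: row j carries ``+effect_scale * curve_j`` or ``-effect_scale *
      curve_j`` according to bit j of the subject index (requires
      n_subjects <= 2 ** n_informative). The planted features are then
      jointly necessary and sufficient: dropping any one of them merges
      subject pairs and caps the attainable accuracy, which makes the set
      sharply recoverable by a subset scan.
    """
    from .features import FeatureMatrix, normalize_dataset

    informative = tuple(sorted(int(i) for i in informative))
    if informative and (informative[0] < 0 or informative[-1] >= n_features):
        raise ConfigurationError("informative indices out of range")
    if structure not in ("independent", "coded"):
        raise ConfigurationError("structure must be 'independent' or 'coded'")
    if structure == "coded" and n_subjects > 2 ** len(informative):
        raise ConfigurationError(
            f"coded structure needs n_subjects <= 2^{len(informative)}"
        )
    names = tuple(f"f{i:02d}" for i in range(n_features))
    t = np.linspace(0.0, 1.0, n_samples)
    code_curves = _perturbation(_rng(seed, 43), len(informative), 1.0)(t)
    matrices = []
    for s in range(n_subjects):
        rng_s = _rng(seed, 31, s)
        if structure == "coded":
            bits = np.array([(s >> j) & 1 for j in range(len(informative))])
            templates = effect_scale * (2.0 * bits[:, None] - 1.0) * code_curves
        else:
            templates = _perturbation(rng_s, len(informative), effect_scale)(t)
        for trial in range(n_trials_per_subject):
            rng_t = _rng(seed, 37, s, trial)
            values = rng_t.standard_normal((n_features, n_samples))
            for row, idx in enumerate(informative):
                values[idx] = templates[row] + noise_scale * rng_t.standard_normal(n_samples)
            matrices.append(FeatureMatrix(
                subject_id=f"S{s:02d}", object_id=object_id, trial_index=trial,
                values=values, feature_names=names,
            ))
    return normalize_dataset(matrices)
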