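"""Study-level evaluation experiments.

Self-contained experiments that measure what the pipeline delivers under
controlled synthetic conditions: classification accuracy as a function of
the between-subject effect size, recovery of planted informative feature
sets by the sensitivity scan, round-trip fidelity of the kinematic and
kinetic extraction, and the frequency responses of the two filters. The
acceptance script and parts of the test suite drive these functions; every
number they return is computed at call time.
"""

from __future__ import annotations

import numpy as np

from .analysis import PipelineSettings, cross_validate, embed, weighted_knn_predict
from .features import time_normalize
from .kinematics import extract_joint_angles, lowpass_trajectories
from .kinetics import bandstop_mains, fit_calibration
from .pipeline import build_dataset_matrix, forces_in_newtons
from .sensitivity import best_subset, enumerate_subsets, sensitivity_scan, size_profile
from .synthetic import (
    SyntheticConfig,
    TrialRecording,
    _object_effects,
    generate_calibration,
    generate_dataset,
    generate_feature_dataset,
    generate_subject_profile,
    generate_trial,
)

#: Pipeline settings for the reduced-scale experiments: perplexity within
#: the 10-15 range used for subject clustering, shortened optimisation.
FAST_SETTINGS = PipelineSettings(perplexity=10, tsne_max_iter=300)


def subject_accuracy(
    subject_effect: float,
    trial_noise: float,
    seed: int,
    n_subjects: int = 10,
    n_objects: int = 2,
    n_trials: int = 5,
    settings: PipelineSettings | None = None,
    n_repeats: int = 3,
) -> float:
    """Mean per-object cross-validated subject accuracy of the full pipeline
    (generation -> extraction -> embedding -> weighted kNN -> CV).

    The embedding is stochastic, so each object is scored as the average
    over ``n_repeats`` embedding seeds — the same repeat-averaging the
    sensitivity scan uses for robustness.
    """
    settings = settings or PipelineSettings(perplexity=10)
    cfg = SyntheticConfig(
        n_subjects=n_subjects, n_objects=n_objects, n_trials_per_object=n_trials,
        subject_effect_scale=subject_effect, trial_noise_scale=trial_noise,
        seed=int(seed) % (2**31),
    )
    dm = build_dataset_matrix(generate_dataset(cfg), seed=cfg.seed)
    accs = []
    for obj in np.unique(dm.objects):
        sub = dm.select_objects([obj])
        for repeat in range(n_repeats):
            emb = embed(sub, dims=settings.dims, perplexity=settings.perplexity,
                        seed=cfg.seed + 1000 * repeat, max_iter=settings.tsne_max_iter)
            rep = cross_validate(emb, sub.subjects, k_neighbors=settings.k_neighbors,
                                 n_folds=settings.n_folds, seed=cfg.seed)
            accs.append(rep.mean_accuracy)
    return float(np.mean(accs))


def effect_size_sweep(
    seed: int,
    effects=(0.0, 0.3, 1.0, 3.0),
    trial_noise: float = 0.25,
) -> list[float]:
    """Accuracy across a fixed-seed sweep of the between-subject effect."""
    return [subject_accuracy(e, trial_noise, seed) for e in effects]


#: Planted-code study design used by the recovery experiments: subject
#: identity binary-coded over 3 of 8 features, 8 subjects x 7 trials.
PLANTED_INFORMATIVE = (0, 2, 5)
_PLANTED_KWARGS = dict(
    n_subjects=8, n_trials_per_subject=7, informative=PLANTED_INFORMATIVE,
    n_features=8, n_samples=150, effect_scale=2.0, noise_scale=0.4,
    structure="coded",
)


def planted_recovery_rate(seed: int, n_runs: int = 10) -> float:
    """Fraction of seeded runs in which the exhaustive size-3 subset scan
    ranks the planted feature set first."""
    hits = 0
    subsets = enumerate_subsets(8, 3, 3)
    for run in range(n_runs):
        run_seed = (int(seed) + run) % (2**31)
        ds = generate_feature_dataset(seed=run_seed, **_PLANTED_KWARGS)
        scan = sensitivity_scan({"obj": ds}, subsets=subsets, settings=FAST_SETTINGS,
                                n_repeats=1, master_seed=run_seed)
        best, _ = best_subset(scan, size=3)
        hits += best == PLANTED_INFORMATIVE
    return hits / n_runs


def planted_size_profile(seed: int, n_repeats: int = 2):
    """Max/mean/min quality against subset size on a planted-code dataset
    (full enumeration, sizes 2-7 of 8 features)."""
    ds = generate_feature_dataset(seed=int(seed) % (2**31), **_PLANTED_KWARGS)
    scan = sensitivity_scan({"obj": ds}, settings=FAST_SETTINGS, n_repeats=n_repeats,
                            master_seed=int(seed) % (2**31), min_size=2, max_size=7)
    return size_profile(scan)


def _noise_free_config(seed: int) -> SyntheticConfig:
    return SyntheticConfig(
        n_subjects=1, n_objects=1, n_trials_per_object=1,
        trial_noise_scale=0.0, mains_noise_amplitude=0.0,
        sensor_noise_std=0.0, marker_noise_std_mm=0.0, seed=int(seed) % (2**31),
    )


def angle_roundtrip_error(seed: int) -> float:
    """Max |extracted - generating| angle (deg) on a noise-free trial."""
    cfg = _noise_free_config(seed)
    profile = generate_subject_profile(cfg, 0)
    trial = generate_trial(profile, "tennis_ball", 0, cfg, object_index=0)
    angles = extract_joint_angles(trial)
    onset, _, _, end = trial.true_phase_bounds
    tau = np.clip((np.arange(trial.marker_block.shape[1]) - onset) / (end - onset), 0, 1)
    offset, _ = _object_effects(cfg, 0)
    expected = np.clip((profile.angle_curves + offset)(tau), 1, 179)
    return float(np.abs(angles.values - expected).max())


def calibration_roundtrip_error(seed: int) -> float:
    """Max relative force error (fraction of peak) after the spring
    calibration + voltage conversion round trip on a noise-free trial."""
    cfg = _noise_free_config(seed)
    profile = generate_subject_profile(cfg, 0)
    trial = generate_trial(profile, "tennis_ball", 0, cfg, object_index=0)
    curves = {f: fit_calibration(r) for f, r in generate_calibration(profile, cfg).items()}
    recovered = forces_in_newtons(trial, curves)
    _, contact, release, _ = trial.true_phase_bounds
    frames = np.arange(recovered.shape[1])
    gamma = (frames - contact) / (release - contact)
    inside = (gamma > 0.02) & (gamma < 0.98)
    _, force_factor = _object_effects(cfg, 0)
    expected = force_factor * profile.force_templates(gamma[inside])
    return float(np.abs(recovered[:, inside] - expected).max() / expected.max())


def rigid_and_scale_invariance_error(seed: int) -> float:
    """Max angle change (deg) under a random rigid motion and a uniform
    scaling of all marker coordinates."""
    cfg = _noise_free_config(seed)
    profile = generate_subject_profile(cfg, 0)
    trial = generate_trial(profile, "tennis_ball", 0, cfg, object_index=0)
    rng = np.random.default_rng(int(seed) % (2**31))
    q = rng.standard_normal(4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    base = extract_joint_angles(trial, lowpass=False).values
    worst = 0.0
    for block in (trial.marker_block @ R.T + rng.uniform(-200, 200, 3),
                  trial.marker_block * 1.6):
        moved = TrialRecording(
            subject_id="S00", object_id="x", trial_index=0,
            marker_block=block, force_block=trial.force_block,
        )
        worst = max(worst, float(np.abs(
            extract_joint_angles(moved, lowpass=False).values - base
        ).max()))
    return worst


def knn_oracle_agreement(seed: int, n_instances: int = 200) -> float:
    """Fraction of random instances on which the weighted kNN matches an
    independent exhaustive-vote reference (should be 1.0)."""
    rng = np.random.default_rng(int(seed) % (2**31))
    agree = 0
    for _ in range(n_instances):
        n = int(rng.integers(5, 51))
        dims = int(rng.integers(1, 4))
        k = int(rng.integers(1, min(n, 10) + 1))
        train = rng.normal(size=(n, dims))
        labels = np.array([f"c{i}" for i in rng.integers(0, 5, n)])
        query = rng.normal(size=(4, dims))
        expected = []
        for qpt in query:
            d = np.sqrt(((train - qpt) ** 2).sum(axis=1))
            order = np.argsort(d, kind="stable")[:k]
            votes: dict = {}
            for i in order:
                votes[labels[i]] = votes.get(labels[i], 0.0) + 1.0 / max(d[i], 1e-12) ** 2
            expected.append(max(sorted(votes), key=lambda c: votes[c]))
        got = weighted_knn_predict(train, labels, query, k=k)
        agree += list(got) == expected
    return agree / n_instances


def filter_responses() -> dict:
    """Measured (not analytic) responses of the two measurement filters."""
    t_k = np.arange(1200) / 120.0
    block = np.zeros((1, t_k.size, 3))
    block[0, :, 0] = np.sin(2 * np.pi * 50 * t_k)
    lp50 = float(np.abs(lowpass_trajectories(block)[0, 200:-200, 0]).max())
    block[0, :, 0] = np.sin(2 * np.pi * 2 * t_k)
    lp2 = float(np.abs(lowpass_trajectories(block)[0, 200:-200, 0]).max())
    # the narrow notch has a ~1 s edge transient under zero-phase filtering;
    # measure the steady state on a long tone with 2 s trimmed at each end
    t_f = np.arange(960 * 12) / 960.0
    trim = 960 * 2
    bs50 = float(np.abs(bandstop_mains(np.sin(2 * np.pi * 50 * t_f))[trim:-trim]).max())
    bs_dc = float(np.abs(bandstop_mains(np.full(t_f.size, 1.0))[trim:-trim]).mean())
    return {
        "lowpass_50hz_attenuation_db": float(-20 * np.log10(max(lp50, 1e-12))),
        "lowpass_2hz_gain": lp2,
        "bandstop_50hz_residual": bs50,
        "bandstop_dc_gain": bs_dc,
    }
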