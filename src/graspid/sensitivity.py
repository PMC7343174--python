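"""Exhaustive feature-subset sensitivity analysis.

Which of the 15 features (ten joint angles, five fingertip forces) carry the
subject-specific signal? The scan evaluates every feature subset of sizes
2..14 (32,751 subsets for 15 features): the excluded rows are replaced by
standard-normal noise — matching the distribution of the z-normalised data,
so the pipeline's input dimensionality and scale are unchanged — and the
unchanged t-SNE + weighted kNN + cross-validation pipeline is re-run. Since
the embedding is stochastic, each subset is evaluated ``n_repeats`` times
(default 3) with fresh noise and averaged. Per-object tables are averaged
(unweighted) into a cross-object table.

Every (subset, repeat) pair derives its seed from a stable hash of the
master seed, the subset and the repeat index, so the scan is reproducible
and its result is independent of evaluation order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .analysis import PipelineSettings, cross_validate, embed
from .errors import ConfigurationError
from .features import DatasetMatrix, substitute_features, substitute_time_window


def enumerate_subsets(
    n_features: int = 15, min_size: int = 2, max_size: int = 14
) -> list[tuple[int, ...]]:
    """All feature subsets of sizes min_size..max_size, each exactly once,
    in deterministic order (by size, then lexicographic)."""
    if not 1 <= min_size <= max_size <= n_features:
        raise ConfigurationError(
            f"need 1 <= min_size <= max_size <= n_features, got "
            f"({min_size}, {max_size}, {n_features})"
        )
    out: list[tuple[int, ...]] = []
    for size in range(min_size, max_size + 1):
        out.extend(combinations(range(n_features), size))
    return out


def subset_count(n_features: int, min_size: int, max_size: int) -> int:
    """Closed form sum_{s=min}^{max} C(n, s)."""
    return sum(math.comb(n_features, s) for s in range(min_size, max_size + 1))


def derive_seed(master_seed: int, subset, repeat: int) -> int:
    """Stable per-(subset, repeat) seed below 2^31."""
    ss = np.random.SeedSequence((int(master_seed), int(repeat)) + tuple(int(i) for i in subset))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def subset_quality(
    dataset: DatasetMatrix,
    subset,
    settings: PipelineSettings | None = None,
    n_repeats: int = 3,
    master_seed: int = 0,
) -> float:
    """Pipeline quality (mean cross-validated accuracy) of one feature subset.

    The non-chosen features are replaced by N(0, 1) noise and the unchanged
    embedding + kNN + CV pipeline is run; repeats use fresh noise and fresh
    embedding seeds and are averaged.
    """
    subset = tuple(sorted(int(i) for i in subset))
    if not subset:
        raise ConfigurationError("subset must be non-empty")
    settings = settings or PipelineSettings()
    accs = []
    for repeat in range(int(n_repeats)):
        seed = derive_seed(master_seed, subset, repeat)
        rng = np.random.default_rng(seed)
        try:
            sub = (substitute_features(dataset, subset, rng)
                   if len(subset) < dataset.n_features else dataset)
            emb = embed(sub, dims=settings.dims, perplexity=settings.perplexity,
                        seed=seed, max_iter=settings.tsne_max_iter)
            rep = cross_validate(emb, dataset.subjects, k_neighbors=settings.k_neighbors,
                                 n_folds=settings.n_folds, seed=seed)
        except Exception as e:
            raise type(e)(f"subset {subset}, repeat {repeat}: {e}") from e
        accs.append(rep.mean_accuracy)
    return float(np.mean(accs))


@dataclass
class SubsetSensitivityResult:
    """Quality score for every scanned subset, per object and aggregated.

    ``per_object`` maps object id -> {subset: quality}; ``aggregate`` is the
    unweighted cross-object mean.
    """

    per_object: dict
    aggregate: dict
    n_repeats: int
    objects_included: tuple

    @property
    def subsets(self) -> list[tuple[int, ...]]:
        return list(self.aggregate.keys())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subset, q in self.aggregate.items():
            row = {
                "subset": "+".join(map(str, subset)),
                "bitmask": sum(1 << i for i in subset),
                "size": len(subset),
                "mean_quality": q,
            }
            for obj in self.objects_included:
                row[f"quality_{obj}"] = self.per_object[obj][subset]
            rows.append(row)
        return pd.DataFrame(rows)


def sensitivity_scan(
    datasets: dict,
    subsets: list | None = None,
    settings: PipelineSettings | None = None,
    n_repeats: int = 3,
    master_seed: int = 0,
    min_size: int = 2,
    max_size: int | None = None,
    progress: bool = False,
) -> SubsetSensitivityResult:
    """Run the exhaustive subset scan over per-object datasets.

    ``datasets`` maps object id -> DatasetMatrix (consistent feature
    ordering). Each subset's quality is computed per object, then averaged
    (unweighted) across objects. Seeds depend only on (master_seed, subset,
    repeat), so results are independent of evaluation order.
    """
    if not datasets:
        raise ConfigurationError("no object datasets given")
    objects = tuple(datasets.keys())
    n_feat = {obj: ds.n_features for obj, ds in datasets.items()}
    if len(set(n_feat.values())) != 1:
        raise ConfigurationError(f"object datasets disagree on feature count: {n_feat}")
    n_features = next(iter(n_feat.values()))
    names = {tuple(ds.feature_names) for ds in datasets.values()}
    if len(names) != 1:
        raise ConfigurationError("object datasets disagree on feature ordering")
    if subsets is None:
        subsets = enumerate_subsets(
            n_features, min_size, max_size if max_size is not None else n_features - 1
        )
    subsets = [tuple(sorted(int(i) for i in s)) for s in subsets]

    iterator = subsets
    if progress:
        from tqdm import tqdm  # pragma: no cover - cosmetic
        iterator = tqdm(subsets, desc="subset scan")

    per_object: dict = {obj: {} for obj in objects}
    aggregate: dict = {}
    for subset in iterator:
        qualities = []
        for obj in objects:
            q = subset_quality(datasets[obj], subset, settings=settings,
                               n_repeats=n_repeats, master_seed=master_seed)
            per_object[obj][subset] = q
            qualities.append(q)
        aggregate[subset] = float(np.mean(qualities))
    return SubsetSensitivityResult(
        per_object=per_object, aggregate=aggregate,
        n_repeats=int(n_repeats), objects_included=objects,
    )


@dataclass
class SizeProfile:
    """Max / mean / min subset quality for each subset size."""

    table: pd.DataFrame  # columns: size, max, mean, min

    def __post_init__(self) -> None:
        bad = self.table[(self.table["min"] > self.table["mean"] + 1e-12)
                         | (self.table["mean"] > self.table["max"] + 1e-12)]
        if len(bad):
            raise ValueError("size profile violates min <= mean <= max")


def size_profile(result: SubsetSensitivityResult) -> SizeProfile:
    """Per-size extrema and mean of the aggregated subset qualities."""
    if not result.aggregate:
        raise ConfigurationError("empty sensitivity result")
    by_size: dict[int, list[float]] = {}
    for subset, q in result.aggregate.items():
        by_size.setdefault(len(subset), []).append(q)
    rows = [
        {"size": s, "max": max(v), "mean": float(np.mean(v)), "min": min(v)}
        for s, v in sorted(by_size.items())
    ]
    return SizeProfile(pd.DataFrame(rows))


def best_subset(result: SubsetSensitivityResult, size: int = 6):
    """Highest-quality subset of the given size in the aggregated table.

    Ties break towards the first subset in the deterministic scan order.
    Returns (subset, quality).
    """
    candidates = [(s, q) for s, q in result.aggregate.items() if len(s) == size]
    if not candidates:
        raise ConfigurationError(f"no subsets of size {size} were scanned")
    best = max(candidates, key=lambda item: item[1])
    return best[0], float(best[1])


def time_window_scan(
    dataset: DatasetMatrix,
    window_width: int = 50,
    stride: int | None = None,
    settings: PipelineSettings | None = None,
    n_repeats: int = 3,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Clustering quality as a function of the retained time window.

    For each window position (non-overlapping by default) every sample
    outside the window — across all features — is replaced by N(0, 1) noise
    and the unchanged pipeline is re-run. With 50-sample windows on
    500-sample trials this gives 10 positions spanning the movement.
    Returns a DataFrame with columns start, stop, quality.
    """
    if not 1 <= window_width <= dataset.n_samples:
        raise ConfigurationError("window width must be in 1..n_samples")
    stride = int(stride) if stride is not None else int(window_width)
    if stride < 1:
        raise ConfigurationError("stride must be >= 1")
    settings = settings or PipelineSettings()
    rows = []
    for start in range(0, dataset.n_samples - window_width + 1, stride):
        accs = []
        for repeat in range(int(n_repeats)):
            seed = derive_seed(master_seed, (start, window_width), repeat)
            rng = np.random.default_rng(seed)
            sub = substitute_time_window(dataset, start, window_width, rng)
            emb = embed(sub, dims=settings.dims, perplexity=settings.perplexity,
                        seed=seed, max_iter=settings.tsne_max_iter)
            rep = cross_validate(emb, dataset.subjects, k_neighbors=settings.k_neighbors,
                                 n_folds=settings.n_folds, seed=seed)
            accs.append(rep.mean_accuracy)
        rows.append({"start": start, "stop": start + window_width,
                     "quality": float(np.mean(accs))})
    return pd.DataFrame(rows)
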