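"""Subject/object classification: t-SNE embedding + weighted kNN + k-fold CV.

The pipeline mirrors standard practice for visual cluster analysis of
high-dimensional movement data: trials (7500-dimensional z-normalised
feature vectors) are embedded into 2-3 dimensions with t-SNE (perplexity
10-15 for per-object subject clustering; 50 for the coarser grip-type
clustering), then a k-nearest-neighbour classifier with inverse-square
distance weights (w_i = d_i^-2, k = 10) is scored by stratified 5-fold
cross-validation. The mean fold accuracy is the "quality of clustering".

Note the embedding is fitted on all trials before the folds are split, so
test points participate in the embedding; that is the faithful rendition of
the original pipeline and slightly optimistic as a generalization estimate.
``GraspPatternModel(holdout="feature_space")`` gives a leakage-free variant
that classifies in the original feature space instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.manifold import TSNE
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, MetadataError
from .features import DatasetMatrix

EPS_DISTANCE = 1e-12  # floor for d^-2 weights; duplicates dominate, as the limit dictates


@dataclass
class PipelineSettings:
    """Parameters of the embedding + kNN + CV pipeline."""

    dims: int = 3
    perplexity: float = 13.0
    k_neighbors: int = 10
    n_folds: int = 5
    tsne_max_iter: int = 1000

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ConfigurationError("embedding dims must be 2 or 3")
        if self.perplexity <= 0 or self.k_neighbors < 1 or self.n_folds < 2:
            raise ConfigurationError("invalid pipeline settings")


@dataclass
class EmbeddingResult:
    """Low-dimensional t-SNE coordinates of the trials (rows align with the
    dataset's trial order)."""

    coords: np.ndarray
    perplexity: float
    seed: int
    n_input_dims: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.isfinite(self.coords).all():
            raise ValueError("embedding produced non-finite coordinates")


@dataclass
class ClassificationReport:
    """Cross-validated weighted-kNN classification outcome.

    ``mean_accuracy`` is the pooled (trace-of-confusion) accuracy over all
    folds; ``per_fold_accuracy`` are the individual fold accuracies.
    """

    per_fold_accuracy: np.ndarray
    mean_accuracy: float
    confusion: np.ndarray
    class_order: np.ndarray
    k_neighbors: int
    n_folds: int

    @property
    def subject_order(self) -> np.ndarray:  # alias when classes are subjects
        return self.class_order

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": [float(a) for a in self.per_fold_accuracy],
            "mean_accuracy": float(self.mean_accuracy),
            "confusion": self.confusion.tolist(),
            "class_order": [str(c) for c in self.class_order],
            "k_neighbors": self.k_neighbors,
            "n_folds": self.n_folds,
        }


def embed(
    dataset: DatasetMatrix | np.ndarray,
    dims: int = 3,
    perplexity: float = 13.0,
    seed: int = 0,
    max_iter: int = 1000,
) -> EmbeddingResult:
    """t-SNE embedding of the flattened trial vectors into 2 or 3 dimensions.

    Deterministic given ``seed``. Requires n_trials > 3 * perplexity (the
    usual validity constraint on the effective neighbourhood size).
    """
    X = dataset.vectors if isinstance(dataset, DatasetMatrix) else np.asarray(dataset, float)
    if dims not in (2, 3):
        raise ConfigurationError("dims must be 2 or 3")
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ConfigurationError(
            f"perplexity {perplexity} too large for {n} trials (need n > 3 * perplexity)"
        )
    # learning rate n / early_exaggeration, floored at 10: the common "auto"
    # floor of 50 overshoots on datasets of a few dozen well-separated
    # trials, leaving clusters shattered
    tsne = TSNE(
        n_components=dims,
        perplexity=perplexity,
        random_state=int(seed) % (2**31),
        init="pca",
        max_iter=int(max_iter),
        learning_rate=max(n / 12.0, 10.0),
    )
    coords = tsne.fit_transform(X)
    return EmbeddingResult(coords=coords, perplexity=perplexity, seed=int(seed),
                           n_input_dims=X.shape[1])


def weighted_knn_predict(
    train_coords: np.ndarray,
    train_labels: np.ndarray,
    query_coords: np.ndarray,
    k: int = 10,
) -> np.ndarray:
    """Inverse-square-distance weighted kNN vote.

    Each of the k nearest training points votes with weight d^-2 (distance
    floored at 1e-12, so a query coinciding with a training point takes that
    point's label). Ties break towards the lexicographically smallest label.
    """
    train = np.atleast_2d(np.asarray(train_coords, dtype=float))
    query = np.atleast_2d(np.asarray(query_coords, dtype=float))
    labels = np.asarray(train_labels)
    if train.shape[0] == 0:
        raise ConfigurationError("empty training set")
    if labels.shape[0] != train.shape[0]:
        raise ValueError("train_labels must match train_coords")
    k = min(int(k), train.shape[0])
    classes = np.unique(labels)  # sorted -> argmax tie-break is lexicographic
    class_idx = np.searchsorted(classes, labels)

    d2 = ((query[:, None, :] - train[None, :, :]) ** 2).sum(axis=2)
    d = np.sqrt(d2)
    # stable sort so equidistant neighbours resolve by training order
    nn = np.argsort(d, axis=1, kind="stable")[:, :k]
    w = 1.0 / np.maximum(np.take_along_axis(d, nn, axis=1), EPS_DISTANCE) ** 2
    votes = np.zeros((query.shape[0], classes.shape[0]))
    for c in range(classes.shape[0]):
        votes[:, c] = np.where(class_idx[nn] == c, w, 0.0).sum(axis=1)
    return classes[np.argmax(votes, axis=1)]


def cross_validate(
    embedding: EmbeddingResult | np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Stratified k-fold cross-validation of the weighted kNN classifier.

    Folds are a seeded stratified partition of the trials; each fold serves
    once as the test set. Classes with a single trial cannot be stratified
    and are kept in the training set only (with a warning).
    """
    coords = embedding.coords if isinstance(embedding, EmbeddingResult) else np.asarray(embedding)
    labels = np.asarray(labels)
    if labels.shape[0] != coords.shape[0]:
        raise ValueError("labels must match the number of embedded trials")
    classes, counts = np.unique(labels, return_counts=True)
    singletons = classes[counts < 2]
    if singletons.size:
        warnings.warn(
            f"classes {list(map(str, singletons))} have a single trial; "
            "kept in training folds only", stacklevel=2,
        )
    foldable = ~np.isin(labels, singletons)
    idx_foldable = np.nonzero(foldable)[0]

    n_folds_eff = min(n_folds, int(counts[counts >= 2].min())) if idx_foldable.size else n_folds
    if n_folds_eff < n_folds:
        warnings.warn(
            f"reducing folds {n_folds} -> {n_folds_eff}: smallest class has "
            f"only {n_folds_eff} trials", stacklevel=2,
        )
    skf = StratifiedKFold(n_splits=n_folds_eff, shuffle=True, random_state=int(seed) % (2**31))

    class_pos = {c: i for i, c in enumerate(classes)}
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    fold_acc = []
    for train_sub, test_sub in skf.split(idx_foldable, labels[idx_foldable]):
        test_idx = idx_foldable[test_sub]
        train_idx = np.setdiff1d(np.arange(labels.shape[0]), test_idx)
        pred = weighted_knn_predict(coords[train_idx], labels[train_idx],
                                    coords[test_idx], k=k_neighbors)
        truth = labels[test_idx]
        fold_acc.append(float(np.mean(pred == truth)))
        for t, p in zip(truth, pred):
            confusion[class_pos[t], class_pos[p]] += 1

    mean_accuracy = float(np.trace(confusion) / confusion.sum())
    return ClassificationReport(
        per_fold_accuracy=np.asarray(fold_acc),
        mean_accuracy=mean_accuracy,
        confusion=confusion,
        class_order=classes,
        k_neighbors=k_neighbors,
        n_folds=n_folds_eff,
    )


def cross_validate_features(
    dataset: DatasetMatrix | np.ndarray,
    labels: np.ndarray,
    k_neighbors: int = 10,
    n_folds: int = 5,
    seed: int = 0,
) -> ClassificationReport:
    """Leakage-free variant: weighted kNN directly in the z-normalised
    feature space, so test trials never influence any fitted component."""
    X = dataset.vectors if isinstance(dataset, DatasetMatrix) else np.asarray(dataset, float)
    return cross_validate(X, labels, k_neighbors=k_neighbors, n_folds=n_folds, seed=seed)


def confusion_by_hand_size(report: ClassificationReport, hand_sizes: dict) -> ClassificationReport:
    """Permute the confusion matrix rows/columns by ascending hand size.

    Confusion concentrated near the diagonal of the reordered matrix would
    indicate that misclassifications happen between similarly sized hands.
    """
    try:
        sizes = np.array([float(hand_sizes[c]) for c in report.class_order])
    except KeyError as e:
        raise MetadataError(f"missing hand size for subject {e.args[0]!r}") from e
    order = np.argsort(sizes, kind="stable")
    return replace(
        report,
        confusion=report.confusion[np.ix_(order, order)],
        class_order=report.class_order[order],
    )


def classify_objects(
    dataset: DatasetMatrix,
    perplexity: float = 50.0,
    dims: int = 3,
    k_neighbors: int = 10,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 1000,
) -> ClassificationReport:
    """Grip-type (object-level) clustering quality: the same pipeline with
    object identity as the class label and a larger perplexity (default 50)
    appropriate for a few big clusters."""
    emb = embed(dataset, dims=dims, perplexity=perplexity, seed=seed, max_iter=max_iter)
    return cross_validate(emb, dataset.objects, k_neighbors=k_neighbors,
                          n_folds=n_folds, seed=seed)


class GraspPatternModel:
    """Subject- (or object-) identification model over a trial dataset.

    A thin statsmodels-style front end to the pipeline: construct from a
    :class:`~graspid.features.DatasetMatrix`, call :meth:`fit` to run the
    embedding and cross-validated classification, and inspect the returned
    :class:`GraspPatternResults`.

    Parameters
    ----------
    dataset : DatasetMatrix
        Z-normalised trials.
    target : {"subject", "object"}
        Class label to recover.
    holdout : {"embedded", "feature_space"}
        ``embedded`` reproduces the original pipeline (kNN on a t-SNE fitted
        to all trials); ``feature_space`` is the leakage-free alternative.
    """

    def __init__(
        self,
        dataset: DatasetMatrix,
        target: str = "subject",
        settings: PipelineSettings | None = None,
        holdout: str = "embedded",
    ) -> None:
        if target not in ("subject", "object"):
            raise ConfigurationError("target must be 'subject' or 'object'")
        if holdout not in ("embedded", "feature_space"):
            raise ConfigurationError("holdout must be 'embedded' or 'feature_space'")
        self.dataset = dataset
        self.target = target
        self.settings = settings or PipelineSettings()
        self.holdout = holdout

    @property
    def labels(self) -> np.ndarray:
        return self.dataset.subjects if self.target == "subject" else self.dataset.objects

    def fit(self, seed: int = 0) -> "GraspPatternResults":
        s = self.settings
        embedding = None
        if self.holdout == "embedded":
            embedding = embed(self.dataset, dims=s.dims, perplexity=s.perplexity,
                              seed=seed, max_iter=s.tsne_max_iter)
            report = cross_validate(embedding, self.labels, k_neighbors=s.k_neighbors,
                                    n_folds=s.n_folds, seed=seed)
        else:
            report = cross_validate_features(self.dataset, self.labels,
                                             k_neighbors=s.k_neighbors,
                                             n_folds=s.n_folds, seed=seed)
        return GraspPatternResults(model=self, embedding=embedding, report=report, seed=seed)


@dataclass
class GraspPatternResults:
    """Fitted classification results: embedding coordinates, per-fold and
    pooled accuracies, and the confusion matrix."""

    model: GraspPatternModel
    embedding: EmbeddingResult | None
    report: ClassificationReport
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return self.report.mean_accuracy

    def confusion_by_hand_size(self) -> ClassificationReport:
        hs = self.model.dataset.hand_sizes
        if hs is None:
            raise MetadataError("dataset carries no hand sizes")
        return confusion_by_hand_size(self.report, hs)

    def plot_embedding(self, ax=None, **kwargs):
        from .plotting import plot_embedding
        if self.embedding is None:
            raise ConfigurationError("no embedding was fitted (feature-space holdout)")
        return plot_embedding(self.embedding, self.model.labels, ax=ax, **kwargs)

    def summary(self) -> str:
        s = self.model.settings
        r = self.report
        lines = [
            "Grasp pattern classification",
            "=" * 46,
            f"target:            {self.model.target}",
            f"trials:            {self.model.dataset.n_trials}",
            f"classes:           {r.class_order.size}",
            f"feature vector:    {self.model.dataset.vectors.shape[1]}",
            f"holdout:           {self.model.holdout}",
            f"embedding:         t-SNE dims={s.dims} perplexity={s.perplexity}"
            if self.embedding is not None else "embedding:         (none)",
            f"classifier:        kNN k={r.k_neighbors}, weights d^-2",
            f"cross-validation:  {r.n_folds} stratified folds, seed {self.seed}",
            "-" * 46,
            "fold accuracies:   " + ", ".join(f"{a:.2%}" for a in r.per_fold_accuracy),
            f"mean accuracy:     {r.mean_accuracy:.2%}",
            f"chance level:      {1.0 / r.class_order.size:.2%}",
        ]
        return "\n".join(lines)
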