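"""Predicting key ontology classes from coverage profiles.

Primary-data similarity is decided by first predicting metadata classes
from TPM profiles and then intersecting the predicted classes of two
datasets.  The pipeline: random-forest importance ranking filters the
feature space to the top 1,000 features (dropping constitutively or lowly
expressed ones), then a multi-layer perceptron is trained per
(assembly, experiment type, metadata field, feature class) combination.
Labels are the key ontology parent classes of each record's annotated
term, which makes the problem multi-label (a histone mark can sit under
two location classes at once).

Training follows an 80/10/10 train/validation/test split and only runs
when at least 100 labelled datasets are available; the held-out test
accuracy (exact label-set match) is recorded on the model.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.preprocessing import StandardScaler

from .coverage import DatasetProfile
from .ontology import OntologySet

__all__ = [
    "ClassifierConfig",
    "ClassifierModel",
    "ClassPrediction",
    "CohortSplit",
    "derive_labels",
    "select_features",
    "split_cohort",
    "train_classifier",
    "predict_classes",
    "primary_similarity",
    "save_model",
    "load_model",
]


@dataclass
class ClassifierConfig:
    """Hyperparameters for feature filtering, splitting and MLP training."""

    top_k_features: int = 1000
    split_fractions: tuple[float, float, float] = (0.8, 0.1, 0.1)
    min_training_cohort: int = 100
    random_seed: int = 0
    hidden_layer_sizes: tuple[int, ...] = (128,)
    max_epochs: int = 200
    patience: int = 10
    n_trees: int = 100
    decision_threshold: float = 0.5

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.top_k_features < 1:
            raise ValueError("top_k_features must be >= 1")
        if self.min_training_cohort < 1:
            raise ValueError("min_training_cohort must be >= 1")


@dataclass
class ClassifierModel:
    """A trained per-(assembly, experiment type, field, feature class) predictor."""

    assembly: str
    experiment_type: str
    metadata_field: str
    feature_class: str
    selected_feature_indices: np.ndarray
    class_labels: tuple[str, ...]
    predictor: MLPClassifier = field(repr=False)
    scaler: StandardScaler = field(repr=False)
    test_accuracy: float = 0.0
    per_class_accuracy: dict[str, float] = field(default_factory=dict)
    decision_threshold: float = 0.5


@dataclass(frozen=True)
class ClassPrediction:
    """Per-class membership scores and the thresholded predicted set."""

    dataset_id: str
    metadata_field: str
    predicted_classes: frozenset[str]
    scores: dict[str, float]


@dataclass(frozen=True)
class CohortSplit:
    train: np.ndarray
    validation: np.ndarray
    test: np.ndarray


def derive_labels(
    records: Sequence, config: OntologySet, metadata_field: str = "cell_type"
) -> dict[str, frozenset[str]]:
    """Map each record to the key-class set of its annotated term.

    ``metadata_field`` is ``cell_type`` or ``target``.  Records whose term
    does not match, or matches a term with no key ancestor, are excluded
    (with a warning): they cannot contribute a training label.
    """
    labels: dict[str, frozenset[str]] = {}
    for rec in records:
        term = getattr(rec, metadata_field)
        if term is None:
            continue
        if metadata_field == "cell_type":
            hit = config.cell_type_ontology.fuzzy_match(term, config.fuzzy_threshold)
            classes = (
                config.cell_type_ontology.key_parents(hit[0]) if hit is not None else frozenset()
            )
        else:
            classes = frozenset()
            for onto in config.target_ontologies:
                hit = onto.fuzzy_match(term, config.fuzzy_threshold)
                if hit is not None:
                    classes = onto.key_parents(hit[0])
                    break
        if not classes:
            warnings.warn(
                f"record {rec.dataset_id}: {metadata_field}={term!r} has no key-class "
                "label; excluded from training"
            )
            continue
        labels[rec.dataset_id] = classes
    return labels


def _transform(matrix: np.ndarray) -> np.ndarray:
    """Variance-stabilize TPM: log2(TPM + 1)."""
    return np.log2(np.asarray(matrix, dtype=float) + 1.0)


def _indicator(label_sets: Sequence[frozenset[str]]) -> tuple[np.ndarray, tuple[str, ...]]:
    classes = tuple(sorted(set().union(*label_sets)))
    idx = {c: j for j, c in enumerate(classes)}
    Y = np.zeros((len(label_sets), len(classes)), dtype=int)
    for i, labels in enumerate(label_sets):
        for c in labels:
            Y[i, idx[c]] = 1
    return Y, classes


def select_features(
    matrix: np.ndarray, label_sets: Sequence[frozenset[str]], config: ClassifierConfig
) -> np.ndarray:
    """Top-k feature indices by random-forest importance.

    Importance is impurity-based, computed by a seeded forest fit on the
    log-transformed matrix against the multi-label indicator targets.
    Returns min(top_k, n_features) indices in importance-rank order, ties
    broken toward the lower index (deterministic given the seed).
    """
    X = _transform(matrix)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("matrix must be 2-D with at least one feature")
    if len(label_sets) != X.shape[0]:
        raise ValueError("one label set per dataset required")
    if len(set(label_sets)) < 2:
        raise ValueError("feature importance undefined with a single label class")
    Y, _ = _indicator(label_sets)
    rf = RandomForestClassifier(
        n_estimators=config.n_trees, random_state=config.random_seed, n_jobs=1
    )
    rf.fit(X, Y)
    k = min(config.top_k_features, X.shape[1])
    order = np.argsort(-rf.feature_importances_, kind="stable")
    return order[:k]


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def split_cohort(
    n: int,
    config: ClassifierConfig,
    seed: int | None = None,
    label_sets: Sequence[frozenset[str]] | None = None,
) -> CohortSplit | None:
    """Partition ``n`` datasets into train/validation/test index arrays.

    Returns None — a refusal signal, not an error — when the cohort is
    smaller than ``min_training_cohort``.  Sizes are
    (round(0.8n), round(0.1n), remainder), which reproduces 80/10/10 at
    n = 100.  Splits stratify on the primary (lexicographically smallest)
    label when every stratum is large enough, else fall back to a plain
    seeded shuffle.
    """
    if n < config.min_training_cohort:
        warnings.warn(
            f"training refused: {n} datasets < minimum cohort of "
            f"{config.min_training_cohort}"
        )
        return None
    seed = config.random_seed if seed is None else seed
    f_train, f_val, _ = config.split_fractions
    n_train = _round_half_up(f_train * n)
    n_val = _round_half_up(f_val * n)
    n_test = n - n_train - n_val
    indices = np.arange(n)

    strata = None
    if label_sets is not None:
        primary = np.array([min(ls) if ls else "" for ls in label_sets])
        counts = {lab: int((primary == lab).sum()) for lab in set(primary)}
        if all(c >= 3 for c in counts.values()) and len(counts) > 1:
            strata = primary
    if strata is not None:
        try:
            train, rest = train_test_split(
                indices, train_size=n_train, random_state=seed, stratify=strata
            )
            val, test = train_test_split(
                rest, train_size=n_val, random_state=seed, stratify=strata[rest]
            )
            return CohortSplit(np.sort(train), np.sort(val), np.sort(test))
        except ValueError:
            pass  # a stratum too small for the second split: plain shuffle
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return CohortSplit(
        np.sort(perm[:n_train]),
        np.sort(perm[n_train : n_train + n_val]),
        np.sort(perm[n_train + n_val :]),
    )


def _val_loss(mlp: MLPClassifier, X: np.ndarray, Y: np.ndarray) -> float:
    """Mean binary cross-entropy over classes on the validation split."""
    P = np.clip(np.asarray(mlp.predict_proba(X), dtype=float), 1e-10, 1 - 1e-10)
    if P.ndim == 1:
        P = P[:, None]
    return float(-np.mean(Y * np.log(P) + (1 - Y) * np.log(1 - P)))


def train_classifier(
    matrix: np.ndarray,
    label_sets: Sequence[frozenset[str]],
    config: ClassifierConfig,
    feature_indices: np.ndarray | None = None,
    *,
    assembly: str = "",
    experiment_type: str = "",
    metadata_field: str = "cell_type",
    feature_class: str = "transcript",
) -> ClassifierModel | None:
    """Train the MLP on a labelled cohort; None when the size gate refuses.

    The model is fit on the training split with early stopping monitored
    on the validation split (patience in epochs), the best-epoch weights
    are restored, and exact-set accuracy is computed on the test split.
    Zero-signal (all-zero) rows are dropped before the gate is applied.
    """
    matrix = np.asarray(matrix, dtype=float)
    keep = matrix.sum(axis=1) > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-signal datasets from training")
        matrix = matrix[keep]
        label_sets = [ls for ls, k in zip(label_sets, keep) if k]
    if len(set(label_sets)) < 2:
        raise ValueError("training requires at least two distinct label sets")

    n = matrix.shape[0]
    split = split_cohort(n, config, config.random_seed, label_sets)
    if split is None:
        return None
    if feature_indices is None:
        feature_indices = select_features(matrix, label_sets, config)
    feature_indices = np.asarray(feature_indices)

    Y, classes = _indicator(label_sets)
    X = _transform(matrix[:, feature_indices])
    scaler = StandardScaler().fit(X[split.train])
    Xs = scaler.transform(X)

    mlp = MLPClassifier(
        hidden_layer_sizes=config.hidden_layer_sizes,
        activation="relu",
        solver="adam",
        max_iter=1,
        warm_start=True,
        random_state=config.random_seed,
    )
    best_loss, best_weights, stale = np.inf, None, 0
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        for _epoch in range(config.max_epochs):
            mlp.fit(Xs[split.train], Y[split.train])
            loss = _val_loss(mlp, Xs[split.validation], Y[split.validation])
            if loss < best_loss - 1e-6:
                best_loss, stale = loss, 0
                best_weights = (
                    [c.copy() for c in mlp.coefs_],
                    [b.copy() for b in mlp.intercepts_],
                )
            else:
                stale += 1
                if stale >= config.patience:
                    break
    if best_weights is not None:
        mlp.coefs_, mlp.intercepts_ = best_weights

    P_test = np.asarray(mlp.predict_proba(Xs[split.test]), dtype=float)
    if P_test.ndim == 1:
        P_test = P_test[:, None]
    pred = (P_test >= config.decision_threshold).astype(int)
    test_acc = float(np.all(pred == Y[split.test], axis=1).mean())
    per_class = {
        c: float((pred[:, j] == Y[split.test, j]).mean()) for j, c in enumerate(classes)
    }
    return ClassifierModel(
        assembly=assembly,
        experiment_type=experiment_type,
        metadata_field=metadata_field,
        feature_class=feature_class,
        selected_feature_indices=feature_indices,
        class_labels=classes,
        predictor=mlp,
        scaler=scaler,
        test_accuracy=test_acc,
        per_class_accuracy=per_class,
        decision_threshold=config.decision_threshold,
    )


def predict_classes(model: ClassifierModel, profile: DatasetProfile | np.ndarray) -> ClassPrediction:
    """Score a profile against every class label; threshold gives the set.

    All-zero degenerate profiles are allowed (the predicted set may be
    empty).  Deterministic for a fixed model.
    """
    if isinstance(profile, DatasetProfile):
        for attr in ("assembly", "experiment_type", "feature_class"):
            want = getattr(model, attr)
            have = getattr(profile, attr)
            if want and want != have:
                raise ValueError(f"profile {attr} {have!r} does not match model {want!r}")
        vec, dataset_id = profile.tpm, profile.dataset_id
    else:
        vec, dataset_id = np.asarray(profile, dtype=float), "<anonymous>"
    if vec.ndim != 1 or vec.shape[0] <= int(model.selected_feature_indices.max()):
        raise ValueError("profile dimension incompatible with model feature indices")
    x = model.scaler.transform(_transform(vec[model.selected_feature_indices])[None, :])
    P = np.asarray(model.predictor.predict_proba(x), dtype=float).ravel()
    scores = {c: float(p) for c, p in zip(model.class_labels, P)}
    predicted = frozenset(c for c, p in scores.items() if p >= model.decision_threshold)
    return ClassPrediction(dataset_id, model.metadata_field, predicted, scores)


def primary_similarity(
    preds_a: Mapping[str, ClassPrediction], preds_b: Mapping[str, ClassPrediction]
) -> bool:
    """Categorical primary-data similarity from predicted class sets.

    ``preds_*`` map metadata field -> prediction.  Similar iff predicted
    cell-type sets intersect and, where a target prediction exists on both
    sides, predicted target sets intersect too.  Symmetric and reflexive.
    """
    ct_a, ct_b = preds_a.get("cell_type"), preds_b.get("cell_type")
    if ct_a is None or ct_b is None:
        return False
    if not (ct_a.predicted_classes & ct_b.predicted_classes):
        return False
    tg_a, tg_b = preds_a.get("target"), preds_b.get("target")
    if tg_a is not None and tg_b is not None:
        return bool(tg_a.predicted_classes & tg_b.predicted_classes)
    return True


# ---------------------------------------------------------------------------
# persistence: JSON metadata + npz weights


def save_model(model: ClassifierModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "assembly": model.assembly,
        "experiment_type": model.experiment_type,
        "metadata_field": model.metadata_field,
        "feature_class": model.feature_class,
        "class_labels": list(model.class_labels),
        "selected_feature_indices": model.selected_feature_indices.tolist(),
        "test_accuracy": model.test_accuracy,
        "per_class_accuracy": model.per_class_accuracy,
        "decision_threshold": model.decision_threshold,
        "hidden_layer_sizes": list(model.predictor.hidden_layer_sizes),
    }
    with open(directory / "model.json", "w") as fh:
        json.dump(meta, fh, indent=1)
    arrays = {"scaler_mean": model.scaler.mean_, "scaler_scale": model.scaler.scale_}
    for i, (c, b) in enumerate(zip(model.predictor.coefs_, model.predictor.intercepts_)):
        arrays[f"coef_{i}"] = c
        arrays[f"intercept_{i}"] = b
    np.savez(directory / "weights.npz", **arrays)


def load_model(directory: str | Path) -> ClassifierModel:
    directory = Path(directory)
    with open(directory / "model.json") as fh:
        meta = json.load(fh)
    data = np.load(directory / "weights.npz")
    n_layers = sum(1 for k in data.files if k.startswith("coef_"))
    coefs = [data[f"coef_{i}"] for i in range(n_layers)]
    intercepts = [data[f"intercept_{i}"] for i in range(n_layers)]

    scaler = StandardScaler()
    scaler.mean_ = data["scaler_mean"]
    scaler.scale_ = data["scaler_scale"]
    scaler.var_ = scaler.scale_**2
    scaler.n_features_in_ = scaler.mean_.shape[0]

    n_classes = len(meta["class_labels"])
    mlp = MLPClassifier(hidden_layer_sizes=tuple(meta["hidden_layer_sizes"]))
    # minimal fit on dummy data to build internals, then overwrite weights
    dummy_X = np.zeros((2, scaler.n_features_in_))
    dummy_Y = np.vstack([np.zeros(n_classes, dtype=int), np.ones(n_classes, dtype=int)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mlp.partial_fit(dummy_X, dummy_Y, classes=np.arange(n_classes))
    mlp.coefs_, mlp.intercepts_ = coefs, intercepts
    return ClassifierModel(
        assembly=meta["assembly"],
        experiment_type=meta["experiment_type"],
        metadata_field=meta["metadata_field"],
        feature_class=meta["feature_class"],
        selected_feature_indices=np.asarray(meta["selected_feature_indices"]),
        class_labels=tuple(meta["class_labels"]),
        predictor=mlp,
        scaler=scaler,
        test_accuracy=meta["test_accuracy"],
        per_class_accuracy=meta["per_class_accuracy"],
        decision_threshold=meta["decision_threshold"],
    )
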