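"""Per-pathway binary classifiers under repeated stratified cross-validation.

Three model families are benchmarked: random forests, gradient-boosted
trees (XGBoost) and a multilayer perceptron.  Tree models consume the raw
count features; the MLP consumes features compressed to 10% width by a
bottleneck autoencoder.  Each (family × category × training-dataset) task
gets its own classifier — 3 × 12 × 2 = 72 under the defaults — trained and
evaluated over many independently drawn stratified 95/5 train/test splits.
When training on the full dataset a fold's test set is scored three ways
(full, ambiguous members, non-ambiguous members); when training on the
non-ambiguous subset it is scored on the fold plus the fixed, entire
ambiguous subset.  The ambiguous subset is never trained on: it is too
small, and that restriction is enforced here rather than advisory.

Hyperparameter search spaces follow the published tuning table; the search
backend is seeded random search with a single stratified 80/20 inner
validation split scored by MCC.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import matthews_corrcoef
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler
from xgboost import XGBClassifier

from .dataset_pipeline import BenchmarkDataset
from .evaluation import binary_metrics, confusion_from_predictions

__all__ = [
    "FAMILIES",
    "SEARCH_SPACES",
    "ModelSpec",
    "ClassifierTask",
    "FoldPlan",
    "EncoderSpec",
    "Autoencoder",
    "enumerate_tasks",
    "stratified_folds",
    "make_fold_plans",
    "build_estimator",
    "tune_hyperparameters",
    "fit_autoencoder",
    "run_cv",
    "run_benchmark",
]

FAMILIES = ("random_forest", "gradient_boosted_trees", "mlp")
TRAINING_DATASETS = ("full", "non_ambiguous")

#: Tuned hyperparameter spaces per family.  ("float", lo, hi),
#: ("log", lo, hi), ("int", lo, hi) or ("cat", [choices]).
SEARCH_SPACES: dict[str, dict[str, tuple]] = {
    "gradient_boosted_trees": {
        "alpha": ("float", 0.0, 2.0),
        "booster": ("cat", ["dart", "gbtree"]),
        "eta": ("float", 0.01, 0.5),
        "lambda": ("float", 0.0, 2.0),
        "max_depth": ("int", 6, 9),
        "min_split_loss": ("float", 0.0, 2.0),
        "scale_pos_weight": ("float", 0.5, 2.0),
        "subsample": ("float", 0.2, 1.0),
    },
    "random_forest": {
        "ccp_alpha": ("float", 0.0, 0.9),
        "class_weight": ("cat", ["balanced", "balanced_subsample"]),
        "criterion": ("cat", ["entropy", "gini", "log_loss"]),
    },
    "mlp": {
        "activation": ("cat", ["relu", "tanh", "logistic"]),
        "beta_1": ("float", 0.0001, 0.99999),
        "beta_2": ("float", 0.2, 0.99999),
        "epsilon": ("log", 1e-8, 1e-4),
        "jitter": ("log", 1e-5, 0.05),
        "alpha": ("log", 1e-6, 0.005),
        "learning_rate": ("log", 1e-5, 1e-3),
        "n_layers": ("int", 2, 5),
        "negative_class_weight": ("float", 0.2, 1.0),
        "positive_class_weight": ("float", 1.0, 5.0),
        "train_set_augmentation_size": ("float", 0.001, 1.0),
    },
}


@dataclass(frozen=True)
class ModelSpec:
    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        space = SEARCH_SPACES[self.family]
        for name, value in self.hyperparameters.items():
            if name in ("n_estimators", "max_iter", "hidden_width"):
                continue  # capacity knobs outside the tuned space
            if name not in space:
                raise ValueError(
                    f"hyperparameter {name!r} not in the {self.family} search space"
                )
            kind = space[name]
            if kind[0] in ("float", "log") and not (kind[1] <= value <= kind[2]):
                raise ValueError(f"{name}={value} outside [{kind[1]}, {kind[2]}]")
            if kind[0] == "int" and not (kind[1] <= int(value) <= kind[2]):
                raise ValueError(f"{name}={value} outside [{kind[1]}, {kind[2]}]")
            if kind[0] == "cat" and value not in kind[1]:
                raise ValueError(f"{name}={value!r} not one of {kind[1]}")


@dataclass(frozen=True)
class ClassifierTask:
    category: str
    training_dataset: str  # full | non_ambiguous
    family: str

    def __post_init__(self) -> None:
        if self.training_dataset not in TRAINING_DATASETS:
            raise ValueError(f"unknown training dataset {self.training_dataset!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")


@dataclass
class FoldPlan:
    fold_index: int
    train_idx: np.ndarray
    test_partitions: dict[str, np.ndarray]


@dataclass
class EncoderSpec:
    """Bottleneck autoencoder configuration.

    The encoded width is ``floor(latent_fraction × input width)``.  The
    default is a single linear bottleneck layer trained by Adam: at desk
    scale a linear autoencoder recovers the principal subspace reliably,
    which is all the compression step needs.
    """

    latent_fraction: float = 0.10
    layers: int = 1
    activation: str = "identity"
    learning_rate: float = 1e-3
    max_iter: int = 600

    def __post_init__(self) -> None:
        if not 0.0 < self.latent_fraction < 1.0:
            raise ValueError("latent_fraction must be in (0, 1)")
        if self.layers < 1 or self.layers % 2 == 0:
            raise ValueError("layers must be a positive odd number (bottleneck centered)")


def enumerate_tasks(
    families: Sequence[str] = FAMILIES,
    categories: Sequence[str] | None = None,
    training_datasets: Sequence[str] = TRAINING_DATASETS,
) -> list[ClassifierTask]:
    """Full cross product of families × categories × training datasets.

    The defaults (3 families, 12 categories, 2 training datasets) yield the
    72 classifier configurations of the benchmark.
    """
    from .dataset_pipeline import DEFAULT_CATEGORIES

    categories = list(categories) if categories is not None else list(DEFAULT_CATEGORIES)
    if not families or not categories or not training_datasets:
        raise ValueError("every task axis must be non-empty")
    if len(set(categories)) != len(categories):
        raise ValueError("duplicate category names")
    return [
        ClassifierTask(category=c, training_dataset=d, family=f)
        for f in families
        for c in categories
        for d in training_datasets
    ]


def stratified_folds(
    labels: np.ndarray,
    n_folds: int,
    test_frac: float = 0.05,
    seed: int = 0,
    category: str = "",
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Independently drawn stratified train/test splits.

    Each fold is a fresh 95/5 (by default) stratified split — folds may
    overlap across iterations, matching repeated random subsampling rather
    than a partitioned k-fold.  Reproducible from the seed.
    """
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError(
            f"category {category or '<unnamed>'} has a single class; cannot stratify"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=n_folds, test_size=test_frac, random_state=seed
    )
    return [(tr.copy(), te.copy()) for tr, te in splitter.split(np.zeros(len(y)), y)]


def make_fold_plans(
    labels: np.ndarray,
    ambiguous_mask: np.ndarray,
    training_dataset: str,
    n_folds: int,
    test_frac: float = 0.05,
    seed: int = 0,
    category: str = "",
) -> list[FoldPlan]:
    """Fold plans with the test partitions the benchmark protocol scores.

    Training on ``full``: the fold's test set is scored as a whole and as
    its ambiguous / non-ambiguous members.  Training on ``non_ambiguous``:
    splits are drawn within the non-ambiguous subset only, and each fold is
    scored on its (non-ambiguous) test set plus the fixed entire ambiguous
    subset (``ambiguous_all``) — the one partition allowed to be the same
    across folds.
    """
    y = np.asarray(labels, dtype=bool)
    amb = np.asarray(ambiguous_mask, dtype=bool)
    plans: list[FoldPlan] = []
    if training_dataset == "full":
        for i, (tr, te) in enumerate(
            stratified_folds(y, n_folds, test_frac, seed, category)
        ):
            plans.append(
                FoldPlan(
                    fold_index=i,
                    train_idx=tr,
                    test_partitions={
                        "full": te,
                        "ambiguous": te[amb[te]],
                        "non_ambiguous": te[~amb[te]],
                    },
                )
            )
    elif training_dataset == "non_ambiguous":
        non_idx = np.flatnonzero(~amb)
        amb_idx = np.flatnonzero(amb)
        for i, (tr, te) in enumerate(
            stratified_folds(y[non_idx], n_folds, test_frac, seed, category)
        ):
            plans.append(
                FoldPlan(
                    fold_index=i,
                    train_idx=non_idx[tr],
                    test_partitions={
                        "non_ambiguous": non_idx[te],
                        "ambiguous_all": amb_idx,
                    },
                )
            )
    else:
        raise ValueError(f"unknown training dataset {training_dataset!r}")
    return plans


class _MLPWithOptions:
    """scikit-learn MLP with the benchmark's training-time extras.

    Adds Gaussian input jitter, class-weighted resampling (implementing
    positive/negative class weights for a model without native sample
    weights) and train-set augmentation (a fraction of jittered copies
    appended to the training data).
    """

    def __init__(self, hp: dict, seed: int):
        self.hp = dict(hp)
        self.seed = seed
        n_layers = int(hp.get("n_layers", 2))
        width = int(hp.get("hidden_width", 128))
        self._clf = MLPClassifier(
            hidden_layer_sizes=tuple([width] * n_layers),
            activation=hp.get("activation", "relu"),
            alpha=float(hp.get("alpha", 1e-4)),
            learning_rate_init=float(hp.get("learning_rate", 3e-4)),
            beta_1=float(hp.get("beta_1", 0.9)),
            beta_2=float(hp.get("beta_2", 0.999)),
            epsilon=float(hp.get("epsilon", 1e-8)),
            max_iter=int(hp.get("max_iter", 2000)),
            random_state=seed,
        )
        self._scaler = StandardScaler()

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_MLPWithOptions":
        rng = np.random.default_rng(self.seed)
        X = self._scaler.fit_transform(np.asarray(X, dtype=float))
        y = np.asarray(y, dtype=int)
        jitter = float(self.hp.get("jitter", 0.0))
        aug = float(self.hp.get("train_set_augmentation_size", 0.0))
        w_pos = float(self.hp.get("positive_class_weight", 1.0))
        w_neg = float(self.hp.get("negative_class_weight", 1.0))
        if w_pos != 1.0 or w_neg != 1.0:
            # weighted resampling to the same training size
            w = np.where(y == 1, w_pos, w_neg).astype(float)
            idx = rng.choice(len(y), size=len(y), replace=True, p=w / w.sum())
            # make sure both classes survive the resample
            if len(np.unique(y[idx])) < 2:
                idx[0] = int(np.flatnonzero(y == 1)[0])
                idx[1] = int(np.flatnonzero(y == 0)[0])
            X, y = X[idx], y[idx]
        if aug > 0.0:
            k = max(1, int(round(aug * len(y))))
            idx = rng.choice(len(y), size=k, replace=True)
            Xa = X[idx] + rng.normal(0.0, max(jitter, 1e-6), size=(k, X.shape[1]))
            X = np.vstack([X, Xa])
            y = np.concatenate([y, y[idx]])
        elif jitter > 0.0:
            X = X + rng.normal(0.0, jitter, size=X.shape)
        self._clf.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self._clf.predict(self._scaler.transform(np.asarray(X, dtype=float)))


def build_estimator(spec: ModelSpec, n_estimators: int = 100):
    """Instantiate a fitted-API estimator for a model spec."""
    hp = spec.hyperparameters
    if spec.family == "random_forest":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", n_estimators)),
            criterion=hp.get("criterion", "gini"),
            ccp_alpha=float(hp.get("ccp_alpha", 0.0)),
            class_weight=hp.get("class_weight"),
            random_state=spec.seed,
            n_jobs=1,
        )
    if spec.family == "gradient_boosted_trees":
        return XGBClassifier(
            n_estimators=int(hp.get("n_estimators", n_estimators)),
            booster=hp.get("booster", "gbtree"),
            learning_rate=float(hp.get("eta", 0.3)),
            reg_alpha=float(hp.get("alpha", 0.0)),
            reg_lambda=float(hp.get("lambda", 1.0)),
            max_depth=int(hp.get("max_depth", 6)),
            gamma=float(hp.get("min_split_loss", 0.0)),
            scale_pos_weight=float(hp.get("scale_pos_weight", 1.0)),
            subsample=float(hp.get("subsample", 1.0)),
            tree_method="hist",
            random_state=spec.seed,
            n_jobs=1,
            eval_metric="logloss",
        )
    if spec.family == "mlp":
        return _MLPWithOptions(hp, spec.seed)
    raise ValueError(f"unknown model family {spec.family!r}")


def _sample_space(space: dict[str, tuple], rng: np.random.Generator) -> dict:
    hp: dict = {}
    for name, kind in space.items():
        if kind[0] == "float":
            hp[name] = float(rng.uniform(kind[1], kind[2]))
        elif kind[0] == "log":
            hp[name] = float(np.exp(rng.uniform(math.log(kind[1]), math.log(kind[2]))))
        elif kind[0] == "int":
            hp[name] = int(rng.integers(kind[1], kind[2] + 1))
        elif kind[0] == "cat":
            hp[name] = kind[1][int(rng.integers(0, len(kind[1])))]
        else:  # pragma: no cover
            raise ValueError(f"bad space entry {name}: {kind}")
    return hp


def tune_hyperparameters(
    X: np.ndarray,
    y: np.ndarray,
    family: str,
    budget: int = 25,
    seed: int = 0,
    search_space: dict[str, tuple] | None = None,
    n_estimators: int = 100,
) -> ModelSpec:
    """Seeded random search over the family's space, scored by validation MCC.

    Each candidate is evaluated on a single stratified 80/20 split of the
    provided training data; the best spec is returned and every returned
    value lies inside the declared space.
    """
    if budget < 1:
        raise ValueError("tuning budget must be >= 1")
    space = search_space or SEARCH_SPACES[family]
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=bool)
    splitter = StratifiedShuffleSplit(n_splits=1, test_size=0.2, random_state=seed)
    tr, va = next(splitter.split(np.zeros(len(y)), y))
    best: tuple[float, ModelSpec] | None = None
    for trial in range(budget):
        hp = _sample_space(space, rng)
        spec = ModelSpec(family=family, hyperparameters=hp, seed=seed + trial)
        est = build_estimator(spec, n_estimators=n_estimators)
        est.fit(X[tr], y[tr])
        score = matthews_corrcoef(y[va], est.predict(X[va]))
        if best is None or score > best[0]:
            best = (score, spec)
    return best[1]


class Autoencoder:
    """Bottleneck autoencoder; ``transform`` applies the encoder half.

    Inputs are centered (not variance-rescaled: the compression operates in
    raw count units, so the reconstruction objective concentrates capacity
    on the columns that actually vary rather than inflating rare
    one-compound colors), then an MLP regressor is trained to reproduce
    them through a bottleneck of width
    ``floor(latent_fraction × n_features)``; the encoder is the forward
    pass through the layers up to and including the bottleneck.
    """

    def __init__(self, spec: EncoderSpec | None = None, seed: int = 0):
        self.spec = spec or EncoderSpec()
        self.seed = seed
        self.latent_width_: int | None = None

    def fit(self, X: np.ndarray) -> "Autoencoder":
        X = np.asarray(X, dtype=float)
        n_features = X.shape[1]
        if n_features < 10:
            raise ValueError("autoencoder input must have at least 10 features")
        m = encoded_width(n_features, self.spec.latent_fraction)
        if m < 1:
            raise ValueError("latent width is 0; increase latent_fraction")
        self.latent_width_ = m
        half = (self.spec.layers - 1) // 2
        # geometric interpolation between input width and bottleneck
        sizes_down = [
            max(m, int(round(n_features * (m / n_features) ** (i / (half + 1)))))
            for i in range(1, half + 1)
        ]
        hidden = tuple(sizes_down + [m] + sizes_down[::-1])
        self._scaler = StandardScaler(with_std=False)
        Xs = self._scaler.fit_transform(X)
        self._net = MLPRegressor(
            hidden_layer_sizes=hidden,
            activation=self.spec.activation,
            learning_rate_init=self.spec.learning_rate,
            max_iter=self.spec.max_iter,
            random_state=self.seed,
            tol=1e-8,
        )
        self._net.fit(Xs, Xs)
        self._n_encode_layers = half + 1
        return self

    def _activate(self, Z: np.ndarray) -> np.ndarray:
        act = self.spec.activation
        if act == "identity":
            return Z
        if act == "relu":
            return np.maximum(Z, 0.0)
        if act == "tanh":
            return np.tanh(Z)
        if act == "logistic":
            return 1.0 / (1.0 + np.exp(-Z))
        raise ValueError(f"unknown activation {act!r}")

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = self._scaler.transform(np.asarray(X, dtype=float))
        for layer in range(self._n_encode_layers):
            Z = self._activate(Z @ self._net.coefs_[layer] + self._net.intercepts_[layer])
        return Z

    def reconstruction_error(self, X: np.ndarray) -> float:
        """Mean squared reconstruction error in standardized units."""
        Xs = self._scaler.transform(np.asarray(X, dtype=float))
        return float(np.mean((self._net.predict(Xs) - Xs) ** 2))


def encoded_width(n_features: int, latent_fraction: float = 0.10) -> int:
    """floor(latent_fraction × n_features): the compressed feature width."""
    return int(math.floor(latent_fraction * n_features))


def fit_autoencoder(
    X: np.ndarray, spec: EncoderSpec | None = None, seed: int = 0
) -> Autoencoder:
    """Train the compression autoencoder on a feature matrix."""
    return Autoencoder(spec, seed).fit(np.asarray(X, dtype=float))


def run_cv(
    X: np.ndarray,
    y: np.ndarray,
    plans: list[FoldPlan],
    spec: ModelSpec,
    collect_importance: bool = False,
    n_estimators: int = 100,
) -> tuple[pd.DataFrame, np.ndarray | None]:
    """Fit once per fold, score each test partition exactly once.

    Returns a long-format metric frame (fold, partition, metric, value,
    valid) and, if requested and the family exposes it, a (folds ×
    features) raw importance array.
    """
    y = np.asarray(y, dtype=bool)
    n = len(y)
    rows = []
    importances: list[np.ndarray] = []
    for plan in plans:
        if plan.train_idx.max(initial=-1) >= n:
            raise ValueError(f"fold {plan.fold_index} references unknown row indices")
        est = build_estimator(
            ModelSpec(spec.family, spec.hyperparameters, seed=spec.seed + plan.fold_index),
            n_estimators=n_estimators,
        )
        est.fit(X[plan.train_idx], y[plan.train_idx])
        if collect_importance and hasattr(est, "feature_importances_"):
            importances.append(np.asarray(est.feature_importances_, dtype=float))
        for pname, te in plan.test_partitions.items():
            if len(te) == 0:
                continue  # empty partition: row absent, not zero-filled
            pred = np.asarray(est.predict(X[te]), dtype=bool)
            counts = confusion_from_predictions(y[te], pred)
            for metric, (value, valid) in binary_metrics(counts).items():
                rows.append((plan.fold_index, pname, metric, value, valid))
    frame = pd.DataFrame(rows, columns=["fold", "partition", "metric", "value", "valid"])
    imp = np.vstack(importances) if importances else None
    return frame, imp


def run_benchmark(
    dataset: BenchmarkDataset,
    families: Sequence[str] = FAMILIES,
    categories: Sequence[str] | None = None,
    training_datasets: Sequence[str] = TRAINING_DATASETS,
    n_folds: int = 50,
    test_frac: float = 0.05,
    seed: int = 0,
    n_estimators: int = 100,
    tune_budget: int = 0,
    encoder_spec: EncoderSpec | None = None,
    collect_importance: bool = True,
) -> tuple[pd.DataFrame, dict[ClassifierTask, np.ndarray]]:
    """Run every task of the benchmark on one dataset.

    MLP tasks consume autoencoder-compressed features (fit once on the full
    feature matrix and applied identically to every subset); tree tasks
    consume the raw counts.  ``tune_budget > 0`` runs a per-task random
    search on the task's training rows before the CV loop.  Returns the
    long metric frame (task columns + fold/partition/metric/value/valid)
    and per-task raw importance arrays for tree families.
    """
    cats = list(categories) if categories is not None else list(dataset.categories)
    tasks = enumerate_tasks(families, cats, training_datasets)
    labels = dataset.labels_frame()
    amb = dataset.ambiguous_mask()
    X_raw = dataset.features.values().astype(float)
    X_enc = None
    if "mlp" in families:
        X_enc = fit_autoencoder(X_raw, encoder_spec, seed=seed).transform(X_raw)
    frames = []
    importance_store: dict[ClassifierTask, np.ndarray] = {}
    for ti, task in enumerate(tasks):
        y = labels[task.category].to_numpy()
        X = X_enc if task.family == "mlp" else X_raw
        try:
            plans = make_fold_plans(
                y, amb, task.training_dataset, n_folds, test_frac,
                seed=seed + 1000 * ti, category=task.category,
            )
        except ValueError as exc:
            import warnings

            warnings.warn(
                f"skipping task {task}: {exc}", stacklevel=2
            )
            continue
        if tune_budget > 0:
            train_rows = np.unique(np.concatenate([p.train_idx for p in plans]))
            spec = tune_hyperparameters(
                X[train_rows], y[train_rows], task.family,
                budget=tune_budget, seed=seed + ti, n_estimators=n_estimators,
            )
        else:
            spec = ModelSpec(task.family, {}, seed=seed + ti)
        frame, imp = run_cv(
            X, y, plans, spec,
            collect_importance=collect_importance and task.family != "mlp",
            n_estimators=n_estimators,
        )
        frame.insert(0, "family", task.family)
        frame.insert(0, "training_dataset", task.training_dataset)
        frame.insert(0, "category", task.category)
        frames.append(frame)
        if imp is not None:
            importance_store[task] = imp
    return pd.concat(frames, ignore_index=True), importance_store
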