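"""Multi-label classification of nucleosome binding modes.

A One-vs-Rest SVM consumes the precomputed Gaussian similarity kernel:
one binary SVM per binding mode, all sharing the same kernel matrix.
Hyperparameters (subsequence length, mixing weight alpha, SVM C) are
tuned by nested cross-validation — an inner grid search selects on
inner-fold micro-AUPR, outer folds give the reported test metrics.
Off-the-shelf baselines (logistic regression, kNN, SVM on standard
kernels, random forest) operate on the mean-of-embeddings feature
vector and are tuned on their conventional grids.

Binding-mode labels are not mutually exclusive and are extremely
imbalanced (one mode may have only 3 positives out of 167 sequences);
micro-AUPR pools all label-sample pairs and therefore tolerates folds
in which a rare label has no positives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, KFold
from sklearn.multiclass import OneVsRestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import ValidationError
from .gaussian import GaussianRep
from .kernel import DEFAULT_ALPHA, KernelMatrix, build_cross_kernel, build_kernel_matrix
from .metrics import confusion, mcc, micro_aupr, subset_accuracy

logger = logging.getLogger(__name__)

#: The seven experimentally characterized nucleosome interaction modes.
DEFAULT_LABEL_NAMES = [
    "end",
    "periodic",
    "groove",
    "dyad",
    "gyre-spanning",
    "orientational",
    "nucleosome-stability",
]


@dataclass
class MultiLabelDataset:
    """Sequence ids with an n x m binary binding-mode label matrix."""

    ids: list[str]
    labels: np.ndarray
    label_names: list[str] = field(default_factory=lambda: list(DEFAULT_LABEL_NAMES))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2 or self.labels.shape[0] != len(self.ids):
            raise ValidationError("label matrix shape does not match id count")
        if self.labels.shape[1] != len(self.label_names):
            raise ValidationError("label matrix width does not match label names")
        if len(set(self.label_names)) != len(self.label_names):
            raise ValidationError("label names must be unique")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValidationError("labels must be binary")
        if (self.labels.sum(axis=1) == 0).any():
            bad = [self.ids[i] for i in np.where(self.labels.sum(axis=1) == 0)[0][:5]]
            raise ValidationError(
                f"every sequence needs at least one positive label; offending ids: {bad}"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return self.labels.shape[1]

    def subset(self, idx) -> "MultiLabelDataset":
        idx = np.asarray(idx)
        ds = object.__new__(MultiLabelDataset)
        ds.ids = [self.ids[i] for i in idx]
        ds.labels = self.labels[idx]
        ds.label_names = list(self.label_names)
        return ds


def read_label_table(path) -> MultiLabelDataset:
    """Read a delimited label table: first column id, then 0/1 columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    ids = df.iloc[:, 0].astype(str).tolist()
    names = [str(c) for c in df.columns[1:]]
    for i, row in enumerate(df.itertuples(index=False)):
        vals = row[1:]
        if any(v not in (0, 1) for v in vals):
            raise ValidationError(f"non-binary label in row {i + 1} (id {ids[i]!r})")
    return MultiLabelDataset(ids=ids, labels=df.iloc[:, 1:].to_numpy(), label_names=names)


def write_label_table(dataset: MultiLabelDataset, path) -> None:
    df = pd.DataFrame(dataset.labels, columns=dataset.label_names)
    df.insert(0, "id", dataset.ids)
    df.to_csv(path, sep="\t", index=False)


def assemble_training_set(
    dataset_ids: list[str],
    labels: np.ndarray,
    label_names: list[str],
    test_ids: set[str] | None = None,
) -> MultiLabelDataset:
    """Apply the dataset filtering rules to a raw annotation table.

    Sequences with no positive binding mode are removed (a multi-label
    classifier needs at least one class per sample), then any sequence
    reserved for an external test set is held out. Both removals are
    logged so the bookkeeping stays auditable.
    """
    labels = np.asarray(labels, dtype=int)
    has_label = labels.sum(axis=1) > 0
    n_unlabeled = int((~has_label).sum())
    test_ids = test_ids or set()
    keep = [i for i in range(len(dataset_ids)) if has_label[i] and dataset_ids[i] not in test_ids]
    n_test = int(has_label.sum()) - len(keep)
    logger.info(
        "assemble_training_set: %d input, %d with no mode removed, %d test held out, %d kept",
        len(dataset_ids), n_unlabeled, n_test, len(keep),
    )
    return MultiLabelDataset(
        ids=[dataset_ids[i] for i in keep], labels=labels[keep], label_names=list(label_names)
    )


@dataclass
class HyperParams:
    l_s: int = 4
    alpha: float = DEFAULT_ALPHA
    svm_C: float = 1.0


@dataclass
class CVConfig:
    outer_folds: int = 10
    inner_folds: int = 10
    seed: int = 0
    grid: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValidationError("fold counts must be >= 2")


@dataclass
class PredictionResult:
    ids: list[str]
    scores: np.ndarray
    predictions: np.ndarray
    label_names: list[str]


# ---------------------------------------------------------------------------
# One-vs-Rest SVM on the precomputed kernel
# ---------------------------------------------------------------------------


@dataclass
class OvRKernelSVM:
    """Per-label SVMs sharing one precomputed kernel.

    Labels whose training column is single-class cannot be fit by an SVM
    and become flagged constant predictors (needed under CV for modes
    with a handful of positives).
    """

    train_ids: list[str]
    label_names: list[str]
    C: float
    models: list = field(default_factory=list)
    constant_labels: dict[int, int] = field(default_factory=dict)


def fit_ovr_svm(K_train: KernelMatrix, labels: np.ndarray, C: float = 1.0,
                label_names: list[str] | None = None) -> OvRKernelSVM:
    """Fit one binary SVM per label column on the precomputed kernel."""
    labels = np.asarray(labels, dtype=int)
    if not K_train.is_square or K_train.values.shape[0] != labels.shape[0]:
        raise ValidationError("kernel must be square and aligned with the label rows")
    if labels.ndim == 1:
        labels = labels[:, None]
    names = label_names or [f"label_{j}" for j in range(labels.shape[1])]
    handle = OvRKernelSVM(train_ids=list(K_train.row_ids), label_names=names, C=C)
    for j in range(labels.shape[1]):
        col = labels[:, j]
        classes = np.unique(col)
        if classes.size == 1:
            handle.models.append(None)
            handle.constant_labels[j] = int(classes[0])
            logger.warning("label %r is single-class; using a constant predictor", names[j])
            continue
        clf = SVC(kernel="precomputed", C=C)
        clf.fit(K_train.values, col)
        handle.models.append(clf)
    return handle


def predict(model: OvRKernelSVM, K_cross: KernelMatrix) -> PredictionResult:
    """Score test rows against the training columns of a cross kernel.

    ``K_cross`` rows are test sequences; its columns must align with the
    model's training ids. Predictions are sign(decision value > 0);
    constant labels give every sample the same +-1 score.
    """
    cols = K_cross.col_ids if K_cross.col_ids is not None else K_cross.row_ids
    if cols != model.train_ids:
        raise ValidationError("cross-kernel columns are not aligned with the training ids")
    n = K_cross.values.shape[0]
    m = len(model.models)
    scores = np.zeros((n, m))
    for j, clf in enumerate(model.models):
        if clf is None:
            scores[:, j] = 1.0 if model.constant_labels[j] == 1 else -1.0
        else:
            scores[:, j] = clf.decision_function(K_cross.values)
    return PredictionResult(
        ids=list(K_cross.row_ids),
        scores=scores,
        predictions=(scores > 0).astype(int),
        label_names=list(model.label_names),
    )


# ---------------------------------------------------------------------------
# Baselines on mean-of-embeddings features
# ---------------------------------------------------------------------------

#: Conventional tuning grids for the four baseline families. The
#: subsequence length (3, 4, 5, 6) varies at the featurization layer and
#: is swept by the caller, not inside these grids.
BASELINE_GRIDS = {
    "LR": [
        {"estimator__penalty": [None]},
        {"estimator__penalty": ["l1"], "estimator__C": [100, 10, 1, 0.1, 0.01],
         "estimator__solver": ["saga"]},
        {"estimator__penalty": ["l2"], "estimator__C": [100, 10, 1, 0.1, 0.01]},
        {"estimator__penalty": ["elasticnet"], "estimator__C": [100, 10, 1, 0.1, 0.01],
         "estimator__solver": ["saga"], "estimator__l1_ratio": [0.5]},
    ],
    "kNN": {
        "estimator__n_neighbors": [1, 3, 5, 7, 9, 11, 13, 15, 17, 19, 21],
        "estimator__weights": ["uniform", "distance"],
        "estimator__metric": ["euclidean", "manhattan", "minkowski"],
    },
    "SVM": {
        "estimator__kernel": ["linear", "poly", "rbf", "sigmoid"],
        "estimator__C": [50, 10, 1.0, 0.1, 0.01],
    },
    "RF": {
        "estimator__max_features": ["sqrt", "log2"],
        "estimator__n_estimators": [10, 100, 200, 500, 1000],
    },
}


def _baseline_estimator(method: str, seed: int):
    if method == "LR":
        return LogisticRegression(max_iter=2000)
    if method == "kNN":
        return KNeighborsClassifier()
    if method == "SVM":
        return SVC()
    if method == "RF":
        return RandomForestClassifier(random_state=seed)
    raise ValidationError(f"unknown baseline method {method!r}; expected LR, kNN, SVM or RF")


def _decision_scores(estimator, X) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        s = estimator.decision_function(X)
    else:
        s = estimator.predict_proba(X)
    s = np.asarray(s)
    return s if s.ndim == 2 else s[:, None]


def _micro_aupr_scorer(estimator, X, y) -> float:
    y = np.asarray(y)
    if y.sum() == 0:
        return 0.0
    return micro_aupr(y if y.ndim == 2 else y[:, None], _decision_scores(estimator, X))


def fit_baseline(features: np.ndarray, labels: np.ndarray, method: str,
                 grid=None, cv: CVConfig | None = None):
    """Tune and fit a One-vs-Rest baseline on mean-feature vectors.

    The grid (default: the conventional per-method grids above) is
    searched by inner cross-validation scored on micro-AUPR.
    """
    cv = cv or CVConfig(outer_folds=2, inner_folds=3)
    est = OneVsRestClassifier(_baseline_estimator(method, cv.seed))
    grid = grid if grid is not None else BASELINE_GRIDS[method]
    inner = KFold(n_splits=cv.inner_folds, shuffle=True, random_state=cv.seed)
    search = GridSearchCV(est, grid, scoring=_micro_aupr_scorer, cv=inner, n_jobs=None)
    labels = np.asarray(labels, dtype=int)
    search.fit(np.asarray(features, dtype=float), labels)
    return search


# ---------------------------------------------------------------------------
# Fold construction
# ---------------------------------------------------------------------------


def multilabel_stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Iteratively stratified fold assignment for multi-label data.

    Greedy label-by-rarity assignment: repeatedly take the label with
    fewest remaining positives and deal its samples to the folds most in
    need of that label, tie-breaking by overall fold deficit then at
    random. Returns an integer fold id per sample; every sample appears
    in exactly one fold.
    """
    rng = np.random.default_rng(seed)
    Y = np.asarray(labels, dtype=int)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, m = Y.shape
    assigned = np.full(n, -1, dtype=int)
    fold_sizes = np.zeros(n_folds)
    desired_size = n / n_folds
    desired_label = Y.sum(axis=0) / n_folds  # per-fold positives target
    fold_label = np.zeros((n_folds, m))
    remaining = set(range(n))

    while remaining:
        rem_idx = np.fromiter(remaining, dtype=int)
        counts = Y[rem_idx].sum(axis=0)
        active = np.where(counts > 0)[0]
        if active.size == 0:
            # label-free leftovers: deal to smallest folds
            for i in rng.permutation(rem_idx):
                f = int(np.argmin(fold_sizes + rng.random(n_folds) * 1e-9))
                assigned[i] = f
                fold_sizes[f] += 1
            break
        lab = active[np.argmin(counts[active])]
        members = rem_idx[Y[rem_idx, lab] == 1]
        for i in rng.permutation(members):
            need = desired_label[lab] - fold_label[:, lab]
            best = need + 1e-6 * (desired_size - fold_sizes) + rng.random(n_folds) * 1e-9
            f = int(np.argmax(best))
            assigned[i] = f
            fold_sizes[f] += 1
            fold_label[f] += Y[i]
            remaining.discard(int(i))
    return assigned


def _fold_indices(labels: np.ndarray, n_folds: int, seed: int):
    assigned = multilabel_stratified_folds(labels, n_folds, seed)
    for f in range(n_folds):
        test = np.where(assigned == f)[0]
        train = np.where(assigned != f)[0]
        if test.size == 0 or train.size == 0:
            raise ValidationError(f"fold {f} is empty; too many folds for {labels.shape[0]} samples")
        yield train, test


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

DEFAULT_GRID = {"l_s": [4], "alpha": [0.0, 0.1, 0.3, 0.5, 0.7, 1.0], "C": [0.1, 1.0, 10.0]}


def _grid_combos(grid: dict) -> list[HyperParams]:
    g = {**DEFAULT_GRID, **(grid or {})}
    combos = [
        HyperParams(l_s=ls, alpha=a, svm_C=c)
        for ls, a, c in product(g["l_s"], g["alpha"], g["C"])
    ]
    return combos


def _inner_score(reps: list[GaussianRep], Y: np.ndarray, hp: HyperParams,
                 inner_folds: int, seed: int) -> float:
    """Mean inner-fold micro-AUPR for one hyperparameter combination."""
    scores = []
    for tr, va in _fold_indices(Y, inner_folds, seed):
        if Y[va].sum() == 0:
            continue
        K_tr = build_kernel_matrix([reps[i] for i in tr], hp.alpha)
        model = fit_ovr_svm(K_tr, Y[tr], C=hp.svm_C)
        K_va = build_cross_kernel([reps[i] for i in va], [reps[i] for i in tr], hp.alpha)
        pred = predict(model, K_va)
        scores.append(micro_aupr(Y[va], pred.scores))
    if not scores:
        raise ValidationError("no inner fold contained a positive label")
    return float(np.mean(scores))


def nested_cv(dataset: MultiLabelDataset, reps_factory: dict[int, list[GaussianRep]],
              cv: CVConfig, fold_assignment: np.ndarray | None = None) -> dict:
    """Nested cross-validation of the kernel SVM.

    ``reps_factory`` maps each candidate subsequence length to the
    Gaussian representations of all sequences, aligned with
    ``dataset.ids``. Outer folds partition the samples once per seed;
    the inner grid search (subsequence length, alpha, C) selects on mean
    inner micro-AUPR, ties broken toward smaller C then smaller
    subsequence length; the winning combination is refit on the outer
    training fold and scored on the held-out fold.

    Returns per-fold records, pooled test predictions, and mean +- sd of
    micro-AUPR and subset accuracy across outer folds.
    """
    if dataset.n < cv.outer_folds:
        raise ValidationError("fewer samples than outer folds")
    for ls, reps in reps_factory.items():
        if len(reps) != dataset.n:
            raise ValidationError(f"representations for l_s={ls} not aligned with dataset")
    grid = dict(cv.grid) if cv.grid else {}
    grid.setdefault("l_s", sorted(reps_factory))
    combos = _grid_combos(grid)
    for hp in combos:
        if hp.l_s not in reps_factory:
            raise ValidationError(f"no representations supplied for l_s={hp.l_s}")

    Y = dataset.labels
    folds = []
    pooled_true, pooled_scores, pooled_pred, pooled_ids = [], [], [], []
    if fold_assignment is None:
        fold_assignment = multilabel_stratified_folds(Y, cv.outer_folds, cv.seed)
    else:
        fold_assignment = np.asarray(fold_assignment, dtype=int)
        if fold_assignment.shape != (dataset.n,):
            raise ValidationError("fold assignment length does not match dataset")
    for f in range(cv.outer_folds):
        test = np.where(fold_assignment == f)[0]
        train = np.where(fold_assignment != f)[0]
        best_hp, best_score = None, -np.inf
        for hp in combos:
            reps_tr = [reps_factory[hp.l_s][i] for i in train]
            s = _inner_score(reps_tr, Y[train], hp, cv.inner_folds, cv.seed + 1)
            better = s > best_score + 1e-12
            tie = abs(s - best_score) <= 1e-12 and best_hp is not None and (
                (hp.svm_C, hp.l_s) < (best_hp.svm_C, best_hp.l_s)
            )
            if better or tie:
                best_hp, best_score = hp, max(s, best_score)
        reps = reps_factory[best_hp.l_s]
        K_tr = build_kernel_matrix([reps[i] for i in train], best_hp.alpha)
        model = fit_ovr_svm(K_tr, Y[train], C=best_hp.svm_C, label_names=dataset.label_names)
        K_te = build_cross_kernel([reps[i] for i in test], [reps[i] for i in train], best_hp.alpha)
        pred = predict(model, K_te)
        rec = {
            "fold": f,
            "test_indices": test.tolist(),
            "hyperparams": {"l_s": best_hp.l_s, "alpha": best_hp.alpha, "C": best_hp.svm_C},
            "inner_micro_aupr": best_score,
            "micro_aupr": micro_aupr(Y[test], pred.scores) if Y[test].sum() else np.nan,
            "subset_accuracy": subset_accuracy(Y[test], pred.predictions),
        }
        folds.append(rec)
        pooled_true.append(Y[test])
        pooled_scores.append(pred.scores)
        pooled_pred.append(pred.predictions)
        pooled_ids.extend(pred.ids)
        logger.info("outer fold %d: %s", f, rec["hyperparams"])

    auprs = np.array([r["micro_aupr"] for r in folds], dtype=float)
    accs = np.array([r["subset_accuracy"] for r in folds], dtype=float)
    return {
        "folds": folds,
        "fold_assignment": fold_assignment.tolist(),
        "micro_aupr_mean": float(np.nanmean(auprs)),
        "micro_aupr_sd": float(np.nanstd(auprs)),
        "subset_accuracy_mean": float(accs.mean()),
        "subset_accuracy_sd": float(accs.std()),
        "pooled": PredictionResult(
            ids=pooled_ids,
            scores=np.vstack(pooled_scores),
            predictions=np.vstack(pooled_pred),
            label_names=list(dataset.label_names),
        ),
        "pooled_true": np.vstack(pooled_true),
    }


def binary_mode_classifier(dataset: MultiLabelDataset, mode_name: str,
                           reps_factory: dict[int, list[GaussianRep]],
                           cv: CVConfig) -> dict:
    """Nested-CV binary classifier for one binding mode.

    Restricts the label matrix to a single column and runs the same
    machinery; reports pooled micro-AUPR, accuracy and MCC over the
    outer test folds.
    """
    if mode_name not in dataset.label_names:
        raise ValidationError(f"unknown binding mode {mode_name!r}; have {dataset.label_names}")
    j = dataset.label_names.index(mode_name)
    col = dataset.labels[:, j]
    if col.sum() == 0:
        raise ValidationError(f"mode {mode_name!r} has no positive samples")
    if col.sum() == col.size:
        raise ValidationError(f"mode {mode_name!r} has no negative samples")
    binary = object.__new__(MultiLabelDataset)
    binary.ids = list(dataset.ids)
    binary.labels = col[:, None]
    binary.label_names = [mode_name]
    res = nested_cv(binary, reps_factory, cv)
    y_true = res["pooled_true"].ravel()
    y_pred = res["pooled"].predictions.ravel()
    c = confusion(y_true, y_pred)
    res["pooled_micro_aupr"] = micro_aupr(y_true, res["pooled"].scores.ravel())
    res["pooled_accuracy"] = c.accuracy
    res["pooled_mcc"] = mcc(c)
    res["confusion"] = c
    return res
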