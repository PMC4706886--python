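"""RBF-SVM training, cross-validated evaluation, and system comparison.

The classifier is a support vector machine with a radial-basis-function
kernel.  (C, gamma) are chosen by grid search over the canonical LIBSVM
ranges (C in 2^-5..2^15, gamma in 2^-15..2^3, steps of 2^2) with inner
stratified cross-validation; features are z-scored with training-set
statistics before the kernel.  Evaluation is stratified 10-fold
cross-validation reporting per-fold accuracy (%) and ROC AUC; feature
selection and standardization are refit inside every training fold so no
test-fold information leaks into the model.  Two systems are compared by a
two-sample pooled-variance t-test on their accuracy samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConsistencyError, InputError, ParameterError
from .feature_selection import ROCFeatureSelector

DEFAULT_C_GRID = tuple(float(2.0**e) for e in range(-5, 16, 2))
DEFAULT_GAMMA_GRID = tuple(float(2.0**e) for e in range(-15, 4, 2))


@dataclass(frozen=True)
class SVMConfig:
    """RBF-SVM hyperparameter search space."""

    C_grid: tuple[float, ...] = DEFAULT_C_GRID
    gamma_grid: tuple[float, ...] = DEFAULT_GAMMA_GRID
    inner_folds: int = 5

    def __post_init__(self):
        if not self.C_grid or not self.gamma_grid:
            raise ParameterError("hyperparameter grids must be non-empty")
        if any(c <= 0 for c in self.C_grid) or any(g <= 0 for g in self.gamma_grid):
            raise ParameterError("C and gamma must be positive")
        if self.inner_folds < 2:
            raise ParameterError("inner_folds must be >= 2")


@dataclass(frozen=True)
class LabeledDataset:
    """Question feature vectors (n x p) with binary labels."""

    features: np.ndarray
    labels: np.ndarray
    question_ids: tuple[str, ...] = ()

    def __post_init__(self):
        x = np.asarray(self.features, dtype=float)
        y = np.asarray(self.labels).astype(int).ravel()
        if x.ndim != 2 or x.shape[0] != y.size:
            raise ConsistencyError("features must be (n_samples, n_features)")
        if not np.isin(y, (0, 1)).all():
            raise InputError("labels must be 0 or 1")
        qids = tuple(self.question_ids) or tuple(f"q{i}" for i in range(y.size))
        if len(qids) != y.size:
            raise ConsistencyError("question_ids length mismatch")
        object.__setattr__(self, "features", x)
        object.__setattr__(self, "labels", y)
        object.__setattr__(self, "question_ids", qids)

    def __len__(self) -> int:
        return self.labels.size


@dataclass(frozen=True)
class CVResult:
    """Per-fold accuracies (%) and AUCs of one cross-validation run."""

    fold_accuracies: tuple[float, ...]
    fold_aucs: tuple[float, ...]
    seed: int

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def mean_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sd_auc(self) -> float:
        return float(np.std(self.fold_aucs, ddof=1))

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": list(self.fold_accuracies),
            "fold_aucs": list(self.fold_aucs),
            "mean_accuracy": self.mean_accuracy,
            "sd_accuracy": self.sd_accuracy,
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample t-test between two systems' accuracy samples."""

    t_statistic: float
    p_value: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "p_value": self.p_value,
            "mean_a": self.mean_a,
            "sd_a": self.sd_a,
            "mean_b": self.mean_b,
            "sd_b": self.sd_b,
        }


def _check_two_classes(y: np.ndarray) -> None:
    if np.unique(y).size < 2:
        raise InputError("training data must contain both classes")


def train_svm(train: LabeledDataset, cfg: SVMConfig | None = None, seed: int = 0):
    """Grid-searched RBF-SVM fit on standardized training features.

    Returns the fitted search object (predict / decision_function follow the
    refit best model).  Inner-CV accuracy ties resolve to the smaller C,
    then the smaller gamma.
    """
    cfg = cfg or SVMConfig()
    _check_two_classes(train.labels)
    pipe = Pipeline([("scale", StandardScaler()), ("svc", SVC(kernel="rbf"))])
    # ascending grids: GridSearchCV keeps the first best, giving the tie rule
    grid = {
        "svc__C": sorted(cfg.C_grid),
        "svc__gamma": sorted(cfg.gamma_grid),
    }
    inner = StratifiedKFold(
        n_splits=cfg.inner_folds, shuffle=True, random_state=int(seed) % 2**31
    )
    search = GridSearchCV(pipe, grid, scoring="accuracy", cv=inner, n_jobs=None)
    search.fit(train.features, train.labels)
    return search


def balanced_subset(
    data: LabeledDataset, n_per_class: int, seed: int = 0
) -> LabeledDataset:
    """Draw exactly n_per_class samples of each class, without replacement."""
    rng = np.random.default_rng(seed)
    idx = []
    for cls in (0, 1):
        pool = np.flatnonzero(data.labels == cls)
        if pool.size < n_per_class:
            raise InputError(
                f"class {cls} has {pool.size} samples, need {n_per_class}"
            )
        idx.append(rng.choice(pool, size=n_per_class, replace=False))
    sel = np.sort(np.concatenate(idx))
    return LabeledDataset(
        data.features[sel],
        data.labels[sel],
        tuple(data.question_ids[i] for i in sel),
    )


def evaluate_cv(
    data: LabeledDataset,
    folds: int = 10,
    cfg: SVMConfig | None = None,
    seed: int = 0,
    n_selected_features: int | None = None,
    selection_scope: str = "per-fold",
) -> CVResult:
    """Stratified k-fold cross-validation of the full training recipe.

    Each fold's model is built from scratch on its training part: ROC
    feature selection (when ``n_selected_features`` is set), z-scoring, and
    the grid-searched SVM.  ``selection_scope="global"`` instead fits the
    selector once on the whole dataset before splitting — a deliberately
    leaky variant kept for protocol comparison.
    """
    cfg = cfg or SVMConfig()
    if selection_scope not in ("per-fold", "global"):
        raise ParameterError("selection_scope must be 'per-fold' or 'global'")
    y = data.labels
    _check_two_classes(y)
    if min(np.bincount(y)) < folds:
        raise InputError(f"need at least {folds} samples per class")
    x = data.features
    if selection_scope == "global" and n_selected_features:
        x = ROCFeatureSelector(n_selected_features).fit_transform(x, y)
    outer = StratifiedKFold(n_splits=folds, shuffle=True, random_state=int(seed) % 2**31)
    fold_seeds = np.random.SeedSequence(seed).generate_state(folds) % 2**31
    accs, aucs = [], []
    for f, (tr, te) in enumerate(outer.split(x, y)):
        xtr, xte = x[tr], x[te]
        if selection_scope == "per-fold" and n_selected_features:
            sel = ROCFeatureSelector(n_selected_features).fit(xtr, y[tr])
            xtr, xte = sel.transform(xtr), sel.transform(xte)
        model = train_svm(
            LabeledDataset(xtr, y[tr]), cfg, seed=int(fold_seeds[f])
        )
        pred = model.predict(xte)
        score = model.decision_function(xte)
        accs.append(100.0 * float(np.mean(pred == y[te])))
        aucs.append(float(roc_auc_score(y[te], score)))
    return CVResult(tuple(accs), tuple(aucs), seed=seed)


def repeated_cv(
    data: LabeledDataset,
    repeats: int = 5,
    folds: int = 10,
    cfg: SVMConfig | None = None,
    seed: int = 0,
    n_selected_features: int | None = None,
    selection_scope: str = "per-fold",
) -> list[CVResult]:
    """R independent CV runs, each reshuffling folds with a derived seed.

    Yields R x folds fold accuracies in total — the sampling protocol behind
    the two-system comparison (e.g. 5 repeats x 10 folds = 50 accuracies).
    """
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    rep_seeds = np.random.SeedSequence([int(seed), 0xC5]).generate_state(repeats) % 2**31
    return [
        evaluate_cv(
            data,
            folds=folds,
            cfg=cfg,
            seed=int(s),
            n_selected_features=n_selected_features,
            selection_scope=selection_scope,
        )
        for s in rep_seeds
    ]


def fold_accuracies(results: list[CVResult]) -> np.ndarray:
    """Flatten repeated-CV results into one accuracy vector."""
    return np.concatenate([r.fold_accuracies for r in results])


def compare_systems(acc_a, acc_b, equal_var: bool = True) -> ComparisonResult:
    """Two-sample t-test (pooled variance by default; Welch optional).

    Degenerate zero-variance inputs are defined explicitly: identical
    constant samples give t = 0, p = 1; constant samples with different
    means give an infinite t and p = 0.
    """
    a = np.asarray(acc_a, dtype=float).ravel()
    b = np.asarray(acc_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise InputError("each accuracy sample needs at least 2 values")
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va == 0 and vb == 0:
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t = float(np.inf if a.mean() > b.mean() else -np.inf)
            p = 0.0
    else:
        t, p = stats.ttest_ind(a, b, equal_var=equal_var)
        t, p = float(t), float(p)
    return ComparisonResult(
        t_statistic=t,
        p_value=p,
        mean_a=float(a.mean()),
        sd_a=float(np.sqrt(va)),
        mean_b=float(b.mean()),
        sd_b=float(np.sqrt(vb)),
    )
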