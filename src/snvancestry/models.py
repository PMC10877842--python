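"""Ancestry classifiers: gradient-boosted trees, RBF-SVMs, and the
two-level continental/subcontinental hierarchy.

Two estimator families cover the two training regimes:

* :class:`GradientBoostedAncestryClassifier` (XGBoost) for cohorts
  simulated from aggregate allele frequencies, where training data is
  cheap and the feature count is large;
* :class:`RbfSvmAncestryClassifier` for real individual-level cohorts,
  with the C penalty tuned by stratified 5-fold cross-validation (shuffled)
  maximising macro-F1 and gamma left at the library default ("scale").

Subcontinental models are trained separately per continental group; at
prediction time each sub-model's probabilities are multiplied by the
parent's continental probability and reported *without renormalisation*,
so the weighted child probabilities of a parent sum exactly to that
parent's continental probability.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    confusion_matrix,
    f1_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC
from sklearn.utils.multiclass import unique_labels
from sklearn.utils.validation import check_is_fitted, validate_data

from .containers import (
    AlleleFrequencyTable,
    GenotypeMatrix,
    ValidationError,
    VariantKey,
)
from .features import (
    ChiSquareSNVSelector,
    chi_square_scan,
    filter_by_pvalue,
)
from .simulate import SimulationConfig, simulate_individuals

PROB_TOL = 1e-6


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------


class GradientBoostedAncestryClassifier(ClassifierMixin, BaseEstimator):
    """Multiclass gradient-boosted decision trees over 0/1/2 genotype dosages.

    A thin, seed-stable wrapper around ``xgboost.XGBClassifier``; training
    is single-threaded by default so identical seeds give identical models.

    Parameters
    ----------
    n_estimators, max_depth, learning_rate : usual boosting knobs.
    random_state : seed for the boosting process.
    n_jobs : XGBoost thread count; >1 trades determinism for speed.
    """

    def __init__(
        self,
        n_estimators: int = 200,
        max_depth: int = 4,
        learning_rate: float = 0.3,
        random_state: int = 0,
        n_jobs: int = 1,
    ):
        self.n_estimators = n_estimators
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.random_state = random_state
        self.n_jobs = n_jobs

    def fit(self, X, y):
        import xgboost as xgb

        X = validate_data(self, X, dtype=np.float32, ensure_2d=True)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValidationError("training requires >= 2 classes")
        if X.shape[1] == 0:
            raise ValidationError("no features to train on")
        y_enc = np.searchsorted(self.classes_, y)
        self._booster = xgb.XGBClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
            n_jobs=self.n_jobs,
            tree_method="hist",
            objective="multi:softprob",
            num_class=len(self.classes_),
        )
        self._booster.fit(X, y_enc)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_booster")
        X = validate_data(self, X, dtype=np.float32, ensure_2d=True, reset=False)
        proba = self._booster.predict_proba(X)
        if proba.ndim == 1 or proba.shape[1] == 1:  # degenerate binary output
            proba = np.column_stack([1.0 - proba.ravel(), proba.ravel()])
        return proba

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]

    def get_booster(self):
        check_is_fitted(self, "_booster")
        return self._booster.get_booster()


class RbfSvmAncestryClassifier(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM with C chosen by shuffled stratified 5-fold CV on macro-F1.

    gamma stays at the library default ("scale"); Platt scaling (libsvm's
    built-in sigmoid calibration with internal CV) turns decision values
    into a probability simplex, which the hierarchical weighting consumes.

    Attributes
    ----------
    C_ : the selected penalty (an element of ``C_grid``).
    cv_macro_f1_ : dict C -> mean macro-F1 over folds.
    cv_fold_predictions_ : dict C -> (y_true, y_pred) concatenated over folds.
    """

    def __init__(
        self,
        C_grid: tuple = (0.1, 1.0, 10.0, 100.0),
        n_splits: int = 5,
        random_state: int = 0,
        allow_fold_reduction: bool = True,
    ):
        self.C_grid = C_grid
        self.n_splits = n_splits
        self.random_state = random_state
        self.allow_fold_reduction = allow_fold_reduction

    def fit(self, X, y):
        X = validate_data(self, X, dtype=np.float64, ensure_2d=True)
        y = np.asarray(y)
        self.classes_ = unique_labels(y)
        if len(self.classes_) < 2:
            raise ValidationError("training requires >= 2 classes")
        if not self.C_grid:
            raise ValidationError("C_grid must be non-empty")
        _, counts = np.unique(y, return_counts=True)
        n_splits = self.n_splits
        if counts.min() < n_splits:
            if not self.allow_fold_reduction:
                raise ValidationError(
                    f"smallest class has {counts.min()} samples < {n_splits} folds"
                )
            n_splits = max(2, int(counts.min()))
        self.n_splits_used_ = n_splits
        skf = StratifiedKFold(
            n_splits=n_splits, shuffle=True, random_state=self.random_state
        )
        self.cv_macro_f1_ = {}
        self.cv_fold_predictions_ = {}
        for C in self.C_grid:
            trues, preds, scores = [], [], []
            for tr, va in skf.split(X, y):
                est = SVC(C=C, kernel="rbf", gamma="scale")
                est.fit(X[tr], y[tr])
                yp = est.predict(X[va])
                trues.append(y[va])
                preds.append(yp)
                scores.append(f1_score(y[va], yp, average="macro"))
            self.cv_macro_f1_[C] = float(np.mean(scores))
            self.cv_fold_predictions_[C] = (
                np.concatenate(trues),
                np.concatenate(preds),
            )
        # ties resolve to the smallest C (weakest regularisation penalty)
        self.C_ = min(
            self.C_grid, key=lambda C: (-self.cv_macro_f1_[C], C)
        )
        import warnings

        self._svc = SVC(
            C=self.C_,
            kernel="rbf",
            gamma="scale",
            probability=True,
            random_state=self.random_state,
        )
        with warnings.catch_warnings():
            # libsvm's built-in Platt calibration is deprecated upstream but
            # remains the recorded calibration method of this estimator
            warnings.simplefilter("ignore", FutureWarning)
            self._svc.fit(X, y)
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "_svc")
        X = validate_data(self, X, dtype=np.float64, ensure_2d=True, reset=False)
        proba = self._svc.predict_proba(X)
        # align column order to self.classes_
        order = np.searchsorted(self.classes_, self._svc.classes_)
        out = np.empty_like(proba)
        out[:, order] = proba
        return out

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


# ---------------------------------------------------------------------------
# trained-model containers
# ---------------------------------------------------------------------------


@dataclass
class TrainedClassifier:
    """A fitted estimator plus the variant feature list and label set it expects."""

    kind: str  # "GBT" | "SVM_RBF"
    feature_list: list[VariantKey]
    label_set: list[str]
    estimator: object
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("GBT", "SVM_RBF"):
            raise ValidationError(f"unknown classifier kind {self.kind!r}")

    @property
    def build(self) -> str:
        builds = {v.build for v in self.feature_list}
        return builds.pop() if len(builds) == 1 else "unknown"


@dataclass
class HierarchicalModelSet:
    """Continental classifier plus per-continent subcontinental classifiers."""

    continental: TrainedClassifier
    sub_models: dict[str, TrainedClassifier] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for parent in self.sub_models:
            if parent not in self.continental.label_set:
                raise ValidationError(
                    f"sub-model parent {parent!r} is not a continental label"
                )


@dataclass
class AncestryReport:
    """Per-sample ancestry probabilities at both hierarchy levels.

    ``weighted_sub_probs[(parent, child)]`` is the child sub-model
    probability multiplied by the parent's continental probability (no
    renormalisation), so summing a parent's children recovers exactly the
    parent's continental probability.
    """

    sample: str
    continental_probs: dict[str, float]
    weighted_sub_probs: dict[tuple, float]
    top_continental: str
    top_subcontinental: tuple | None
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        total = sum(self.continental_probs.values())
        if abs(total - 1.0) > PROB_TOL:
            raise ValidationError(f"continental probabilities sum to {total}")
        parents = {p for (p, _c) in self.weighted_sub_probs}
        for parent in parents:
            child_sum = sum(
                v for (p, _c), v in self.weighted_sub_probs.items() if p == parent
            )
            if abs(child_sum - self.continental_probs[parent]) > PROB_TOL:
                raise ValidationError(
                    f"children of {parent!r} sum to {child_sum}, parent prob "
                    f"{self.continental_probs[parent]}"
                )

    def to_dict(self, ndigits: int = 6) -> dict:
        sub: dict[str, dict[str, float]] = {}
        for (parent, child), v in sorted(self.weighted_sub_probs.items()):
            sub.setdefault(parent, {})[child] = round(v, ndigits)
        return {
            "sample": self.sample,
            "continental": {
                k: round(v, ndigits)
                for k, v in sorted(self.continental_probs.items())
            },
            "subcontinental": sub,
            "top": {
                "continental": self.top_continental,
                "subcontinental": (
                    list(self.top_subcontinental)
                    if self.top_subcontinental
                    else None
                ),
            },
            "provenance": self.provenance,
        }


@dataclass
class GridSearchResult:
    """Outcome of the nested (population size x p-value threshold) search."""

    cells: list[dict]  # size, p_threshold, mean_accuracy, accuracies, n_features
    selected_size: int
    selected_p_threshold: float
    holdout_accuracy: float

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.cells)


# ---------------------------------------------------------------------------
# training entry points
# ---------------------------------------------------------------------------


def _matrix_xy(matrix: GenotypeMatrix, labels: dict[str, str] | None):
    if labels is not None:
        y = np.array([labels[s] for s in matrix.samples])
    else:
        y = matrix.label_array()
    return matrix.values.astype(np.float32), y


def train_gbt(
    matrix: GenotypeMatrix,
    labels: dict[str, str] | None = None,
    hyperparams: dict | None = None,
    seed: int = 0,
) -> TrainedClassifier:
    """Fit a gradient-boosted tree classifier on a labelled genotype matrix."""
    if matrix.n_variants == 0:
        raise ValidationError("no features: cannot train on an empty matrix")
    X, y = _matrix_xy(matrix, labels)
    hp = dict(hyperparams or {})
    est = GradientBoostedAncestryClassifier(random_state=seed, **hp)
    est.fit(X, y)
    return TrainedClassifier(
        kind="GBT",
        feature_list=list(matrix.variants),
        label_set=[str(c) for c in est.classes_],
        estimator=est,
        metadata={"seed": seed, "hyperparams": est.get_params()},
    )


def train_svm_rbf(
    matrix: GenotypeMatrix,
    labels: dict[str, str] | None = None,
    C_grid: tuple = (0.1, 1.0, 10.0, 100.0),
    seed: int = 0,
) -> TrainedClassifier:
    """Fit the RBF-SVM classifier (C tuned by stratified 5-fold macro-F1)."""
    if matrix.n_variants == 0:
        raise ValidationError("no features: cannot train on an empty matrix")
    X, y = _matrix_xy(matrix, labels)
    est = RbfSvmAncestryClassifier(C_grid=tuple(C_grid), random_state=seed)
    est.fit(X.astype(np.float64), y)
    return TrainedClassifier(
        kind="SVM_RBF",
        feature_list=list(matrix.variants),
        label_set=[str(c) for c in est.classes_],
        estimator=est,
        metadata={
            "seed": seed,
            "selected_C": est.C_,
            "cv_macro_f1": est.cv_macro_f1_,
            "calibration": "platt-sigmoid (libsvm internal CV)",
        },
    )


def align_to_features(
    matrix: GenotypeMatrix, feature_list: list[VariantKey]
) -> np.ndarray:
    """Reorder/zero-fill matrix columns onto a model's feature list.

    Features absent from the matrix become 0 (the reference/missing code);
    genome builds must agree.  Returns a dense (n_samples, n_features)
    float array and is the single alignment path used by all predictors.
    """
    if matrix.n_variants and feature_list:
        m_build = {v.build for v in matrix.variants}
        f_build = {v.build for v in feature_list}
        if (
            len(m_build) == 1
            and len(f_build) == 1
            and "unknown" not in (m_build | f_build)
            and m_build != f_build
        ):
            raise ValidationError(
                f"genome build mismatch: matrix {m_build.pop()!r} vs "
                f"model {f_build.pop()!r}"
            )
    # identity is (chrom,pos,ref,alt); build participates only in the check
    pos = {
        (v.chrom, v.pos, v.ref, v.alt): i for i, v in enumerate(matrix.variants)
    }
    X = np.zeros((matrix.n_samples, len(feature_list)), dtype=np.float32)
    for j, v in enumerate(feature_list):
        i = pos.get((v.chrom, v.pos, v.ref, v.alt))
        if i is not None:
            X[:, j] = matrix.values[:, i]
    return X


def feature_overlap_fraction(
    matrix: GenotypeMatrix, feature_list: list[VariantKey]
) -> float:
    have = {(v.chrom, v.pos, v.ref, v.alt) for v in matrix.variants}
    if not feature_list:
        return 0.0
    hit = sum(1 for v in feature_list if (v.chrom, v.pos, v.ref, v.alt) in have)
    return hit / len(feature_list)


def predict_probabilities(
    model: TrainedClassifier, matrix: GenotypeMatrix
) -> np.ndarray:
    """Probability matrix (n_samples x |label_set|), rows on the simplex."""
    X = align_to_features(matrix, model.feature_list)
    proba = model.estimator.predict_proba(X)
    rowsum = proba.sum(axis=1)
    if not np.allclose(rowsum, 1.0, atol=PROB_TOL):
        raise ValidationError("probability rows do not sum to 1")
    return proba


def hierarchical_predict(
    models: HierarchicalModelSet, matrix: GenotypeMatrix
) -> list[AncestryReport]:
    """One report per sample: continental probabilities plus weighted
    subcontinental probabilities (child prob x parent prob, unnormalised)."""
    cont_proba = predict_probabilities(models.continental, matrix)
    cont_labels = models.continental.label_set
    sub_proba = {
        parent: predict_probabilities(sub, matrix)
        for parent, sub in models.sub_models.items()
    }
    reports = []
    for i, sample in enumerate(matrix.samples):
        cont = {lab: float(cont_proba[i, j]) for j, lab in enumerate(cont_labels)}
        weighted: dict[tuple, float] = {}
        for parent, proba in sub_proba.items():
            sub_labels = models.sub_models[parent].label_set
            for j, child in enumerate(sub_labels):
                weighted[(parent, child)] = float(proba[i, j]) * cont[parent]
        # argmax with deterministic lexicographic tie-break
        top_cont = min(cont, key=lambda k: (-cont[k], k))
        top_sub = (
            min(weighted, key=lambda k: (-weighted[k], k)) if weighted else None
        )
        report = AncestryReport(
            sample=sample,
            continental_probs=cont,
            weighted_sub_probs=weighted,
            top_continental=top_cont,
            top_subcontinental=top_sub,
            provenance={
                "continental_kind": models.continental.kind,
                "n_sub_models": len(models.sub_models),
            },
        )
        report.validate()
        reports.append(report)
    return reports


def evaluate(
    model: TrainedClassifier, matrix: GenotypeMatrix, labels: dict[str, str] | None = None
) -> dict:
    """Accuracy, macro-F1, per-class confusion counts and OvR ROC / PR AUCs."""
    _, y = _matrix_xy(matrix, labels)
    label_set = model.label_set
    if not set(y) & set(label_set):
        raise ValidationError(
            f"no overlap between sample labels {sorted(set(y))[:5]} and model "
            f"labels {label_set[:5]}; map labels to the model's level first"
        )
    proba = predict_probabilities(model, matrix)
    pred = np.array(label_set)[np.argmax(proba, axis=1)]
    y_bin = np.stack([(y == lab).astype(int) for lab in label_set], axis=1)
    roc, pr = {}, {}
    for j, lab in enumerate(label_set):
        if 0 < y_bin[:, j].sum() < len(y):
            roc[lab] = float(roc_auc_score(y_bin[:, j], proba[:, j]))
            pr[lab] = float(average_precision_score(y_bin[:, j], proba[:, j]))
        else:
            roc[lab] = float("nan")
            pr[lab] = float("nan")
    finite_roc = [v for v in roc.values() if np.isfinite(v)]
    finite_pr = [v for v in pr.values() if np.isfinite(v)]
    return {
        "accuracy": float(accuracy_score(y, pred)),
        "macro_f1": float(
            f1_score(y, pred, average="macro", labels=label_set, zero_division=0)
        ),
        "confusion": confusion_matrix(y, pred, labels=label_set).tolist(),
        "labels": list(label_set),
        "roc_auc": roc,
        "pr_auc": pr,
        "macro_roc_auc": float(np.mean(finite_roc)) if finite_roc else float("nan"),
        "macro_pr_auc": float(np.mean(finite_pr)) if finite_pr else float("nan"),
    }


# ---------------------------------------------------------------------------
# nested grid search on simulated cohorts
# ---------------------------------------------------------------------------


def _sub_seed(seed_seq: np.random.SeedSequence) -> int:
    return int(seed_seq.generate_state(1)[0] % (2**31 - 1))


def grid_search_simulation(
    aft: AlleleFrequencyTable,
    size_grid: list[int],
    pvalue_grid: list[float],
    repeats: int = 5,
    seed: int = 0,
    gbt_hyperparams: dict | None = None,
    holdout_fraction: float = 0.2,
) -> tuple[GridSearchResult, TrainedClassifier]:
    """Nested search over (population size, chi-square p-value threshold).

    For each grid cell, a cohort of ``size`` individuals per population is
    simulated, split 80/20 (stratified), the chi-square scan run *on the
    training portion only*, sub-threshold SNVs dropped, a GBT trained and
    validation accuracy recorded; this repeats ``repeats`` times and the
    mean accuracy ranks the cell.  Ties prefer the smallest threshold,
    then the smallest size.  The winning configuration is retrained on a
    full fresh cohort and scored on a freshly simulated holdout
    (``holdout_fraction`` of the training size per population).

    Cells whose threshold eliminates every feature are recorded as failed
    (NaN accuracy) rather than aborting the search.
    """
    if not size_grid or not pvalue_grid:
        raise ValidationError("size_grid and pvalue_grid must be non-empty")
    root = np.random.SeedSequence(seed)
    cohort_seeds, split_seeds, final_seq = root.spawn(3)
    cell_acc = {
        (size, p): [] for size in size_grid for p in pvalue_grid
    }
    cell_nfeat = {(size, p): [] for size in size_grid for p in pvalue_grid}
    cohort_children = cohort_seeds.spawn(len(size_grid) * repeats)
    split_children = split_seeds.spawn(len(size_grid) * repeats)
    k = 0
    for size in size_grid:
        for rep in range(repeats):
            cohort = simulate_individuals(
                aft,
                SimulationConfig(
                    n_per_population=size, seed=_sub_seed(cohort_children[k])
                ),
            )
            X, y = _matrix_xy(cohort, None)
            idx_tr, idx_va = train_test_split(
                np.arange(len(y)),
                test_size=0.2,
                stratify=y,
                random_state=_sub_seed(split_children[k]),
            )
            k += 1
            # scan on the training portion only (no leakage into validation)
            train_matrix = cohort.select_samples(
                [cohort.samples[i] for i in idx_tr]
            )
            scan = chi_square_scan(train_matrix)
            log10_p = scan.log10_pvalues
            for p in pvalue_grid:
                keep = log10_p <= np.log10(p)
                n_kept = int(keep.sum())
                cell_nfeat[(size, p)].append(n_kept)
                if n_kept == 0:
                    cell_acc[(size, p)].append(float("nan"))
                    continue
                est = GradientBoostedAncestryClassifier(
                    random_state=seed, **(gbt_hyperparams or {})
                )
                est.fit(X[np.ix_(idx_tr, np.where(keep)[0])], y[idx_tr])
                pred = est.predict(X[np.ix_(idx_va, np.where(keep)[0])])
                cell_acc[(size, p)].append(float(np.mean(pred == y[idx_va])))

    cells = []
    for size in size_grid:
        for p in pvalue_grid:
            accs = cell_acc[(size, p)]
            mean_acc = float(np.nanmean(accs)) if not all(
                np.isnan(a) for a in accs
            ) else float("nan")
            cells.append(
                {
                    "size": size,
                    "p_threshold": p,
                    "mean_accuracy": mean_acc,
                    "accuracies": accs,
                    "mean_n_features": float(np.mean(cell_nfeat[(size, p)])),
                }
            )
    valid = [c for c in cells if np.isfinite(c["mean_accuracy"])]
    if not valid:
        raise ValidationError(
            "every grid cell failed (no features retained at any threshold)"
        )
    best = min(
        valid, key=lambda c: (-c["mean_accuracy"], c["p_threshold"], c["size"])
    )
    sel_size, sel_p = best["size"], best["p_threshold"]

    # retrain on a full fresh cohort at the winning configuration
    final_children = final_seq.spawn(2)
    final_cohort = simulate_individuals(
        aft,
        SimulationConfig(n_per_population=sel_size, seed=_sub_seed(final_children[0])),
    )
    scan = chi_square_scan(final_cohort)
    kept = filter_by_pvalue(scan, sel_p)
    if not kept:
        raise ValidationError("no features retained at the selected threshold")
    kept_set = set(kept)
    final_matrix = final_cohort.select_variants(
        [v in kept_set for v in final_cohort.variants]
    )
    model = train_gbt(final_matrix, hyperparams=gbt_hyperparams, seed=seed)
    model.metadata.update(
        {"grid_selected_size": sel_size, "grid_selected_p_threshold": sel_p}
    )
    holdout_n = max(1, int(round(holdout_fraction * sel_size)))
    holdout = simulate_individuals(
        aft,
        SimulationConfig(
            n_per_population=holdout_n, seed=_sub_seed(final_children[1])
        ),
    )
    holdout_acc = evaluate(model, holdout)["accuracy"]
    result = GridSearchResult(
        cells=cells,
        selected_size=sel_size,
        selected_p_threshold=sel_p,
        holdout_accuracy=holdout_acc,
    )
    return result, model


# ---------------------------------------------------------------------------
# hierarchy training
# ---------------------------------------------------------------------------


def _parent_labels(labels: dict[str, str], hierarchy: dict[str, str]) -> dict[str, str]:
    missing = sorted({v for v in labels.values() if v not in hierarchy})
    if missing:
        raise ValidationError(
            f"hierarchy missing parents for populations: {missing[:5]}"
        )
    return {s: hierarchy[lab] for s, lab in labels.items()}


def train_hierarchical(
    matrix: GenotypeMatrix,
    hierarchy: dict[str, str] | None,
    kind: str = "GBT",
    p_threshold: float | None = None,
    seed: int = 0,
    gbt_hyperparams: dict | None = None,
    C_grid: tuple = (0.1, 1.0, 10.0, 100.0),
) -> HierarchicalModelSet:
    """Train the continental model and one sub-model per continental group.

    ``matrix.labels`` carries the subpopulation labels; ``hierarchy`` maps
    subpopulation -> continental label (``None`` trains a flat single-level
    set from the labels as-is).  When ``p_threshold`` is given, each model
    runs its own chi-square scan on its own training samples and keeps
    only retained SNVs.  Continents with a single subpopulation get no
    sub-model (nothing to distinguish).
    """
    labels = dict(matrix.labels or {})
    if not labels:
        raise ValidationError("matrix must carry population labels")

    def fit_one(sub_matrix: GenotypeMatrix, sub_labels: dict[str, str], rank: int):
        train_m = sub_matrix
        if p_threshold is not None:
            scan = chi_square_scan(sub_matrix, sub_labels)
            kept = set(filter_by_pvalue(scan, p_threshold))
            if not kept:
                raise ValidationError(
                    f"no features retained at p<={p_threshold} for this model"
                )
            train_m = sub_matrix.select_variants(
                [v in kept for v in sub_matrix.variants]
            )
        if kind == "GBT":
            return train_gbt(
                train_m, sub_labels, hyperparams=gbt_hyperparams, seed=seed + rank
            )
        if kind == "SVM_RBF":
            return train_svm_rbf(train_m, sub_labels, C_grid=C_grid, seed=seed + rank)
        raise ValidationError(f"unknown classifier kind {kind!r}")

    if hierarchy is None:
        continental = fit_one(matrix, labels, 0)
        return HierarchicalModelSet(continental=continental, sub_models={})

    parent = _parent_labels(labels, hierarchy)
    continental = fit_one(matrix, parent, 0)
    sub_models: dict[str, TrainedClassifier] = {}
    for rank, cont in enumerate(sorted(set(parent.values())), start=1):
        members = [s for s in matrix.samples if parent[s] == cont]
        member_subs = {labels[s] for s in members}
        if len(member_subs) < 2:
            continue
        sub_matrix = matrix.select_samples(members)
        sub_models[cont] = fit_one(
            sub_matrix, {s: labels[s] for s in members}, rank
        )
    return HierarchicalModelSet(continental=continental, sub_models=sub_models)


def config_digest(obj) -> str:
    """Stable short digest of a JSON-serialisable configuration mapping."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
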