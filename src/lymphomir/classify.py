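"""Nested cross-validated classification of diagnostic classes.

Two learners are supported, each tuned over its full grid inside the
inner loop and evaluated on the outer loop so that no validation sample
ever influences feature ranking, standardization or hyperparameter
choice:

* elastic-net penalized logistic regression (binary, one lymphoma
  entity or the pooled lymphomas against the reactive class), grid of
  3 feature percentages x 9 inverse regularization strengths x 5 L1
  ratios = 135 combinations, 10-fold inner / 5-fold outer;
* random forest (all three classes at once), grid of 3 depths x 2
  bootstrap settings x 4 max-feature rules x 2 split criteria = 48
  combinations, 3-fold inner / 5-fold outer, with a pooled out-of-fold
  confusion matrix and permutation importance.

Feature selection inside the logistic pipeline ranks miRNAs by
ascending training-fold t-test p-value and keeps the top percentage
(minimum one feature).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from ._utils import derive_seed, require
from .diffexpr import _t_test_matrix
from .io import CLASS_LABELS, SampleAnnotation
from .normalize import NormalizedMatrix

# ---------------------------------------------------------------------------
# Specs and grids
# ---------------------------------------------------------------------------


@dataclass
class CvSpec:
    """Nested cross-validation layout."""

    outer_folds: int = 5
    inner_folds: int = 10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        require(self.outer_folds >= 2 and self.inner_folds >= 2, "folds must be >= 2")


@dataclass
class LrGrid:
    """Hyperparameter grid for the elastic-net logistic pipeline."""

    feature_percentages: tuple[float, ...] = (5.0, 10.0, 20.0)
    inv_regularization: tuple[float, ...] = (
        1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0, 100.0, 1000.0, 1e4,
    )
    l1_ratios: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)

    def __post_init__(self) -> None:
        require(
            len(self.feature_percentages) > 0
            and len(self.inv_regularization) > 0
            and len(self.l1_ratios) > 0,
            "grid axes must be non-empty",
        )
        require(
            all(0 < p <= 100 for p in self.feature_percentages),
            "feature percentages must lie in (0, 100]",
        )

    @property
    def n_combinations(self) -> int:
        return (
            len(self.feature_percentages)
            * len(self.inv_regularization)
            * len(self.l1_ratios)
        )

    def combinations(self) -> list[dict]:
        """Enumerate in tie-break order: smaller feature percentage,
        then smaller inverse regularization, then larger L1 ratio."""
        return [
            {"feature_percentage": p, "inv_reg": c, "l1_ratio": l1}
            for p in sorted(self.feature_percentages)
            for c in sorted(self.inv_regularization)
            for l1 in sorted(self.l1_ratios, reverse=True)
        ]


@dataclass
class RfGrid:
    """Hyperparameter grid for the random forest."""

    max_depths: tuple[int, ...] = (2, 3, 4)
    bootstrap: tuple[bool, ...] = (True, False)
    max_features: tuple = ("auto", "sqrt", "log2", None)
    criterion: tuple[str, ...] = ("gini", "entropy")
    n_trees: int = 500

    def __post_init__(self) -> None:
        require(
            len(self.max_depths) > 0
            and len(self.bootstrap) > 0
            and len(self.max_features) > 0
            and len(self.criterion) > 0,
            "grid axes must be non-empty",
        )

    @property
    def n_combinations(self) -> int:
        return (
            len(self.max_depths)
            * len(self.bootstrap)
            * len(self.max_features)
            * len(self.criterion)
        )

    def combinations(self) -> list[dict]:
        return [
            {"max_depth": d, "bootstrap": b, "max_features": f, "criterion": c}
            for d in self.max_depths
            for b in self.bootstrap
            for f in self.max_features
            for c in self.criterion
        ]


# ---------------------------------------------------------------------------
# Results
# ---------------------------------------------------------------------------


@dataclass
class ModelResult:
    """Outcome of one nested-CV run."""

    comparison: str
    fold_aucs: np.ndarray
    mean_auc: float
    ci_halfwidth: float  # 95% CI half-width (t distribution over folds)
    best_auc: float
    best_params: list[dict]
    selected_features: list[list[str]]
    oof_scores: pd.Series | pd.DataFrame  # one out-of-fold score row per sample

    def __post_init__(self) -> None:
        require(bool(np.all((self.fold_aucs >= 0) & (self.fold_aucs <= 1))),
                "fold AUCs outside [0, 1]")

    def to_dict(self) -> dict:
        return {
            "comparison": self.comparison,
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "ci_halfwidth": float(self.ci_halfwidth),
            "best_auc": float(self.best_auc),
            "best_params": self.best_params,
            "selected_features": self.selected_features,
        }


@dataclass
class ConfusionMatrix:
    """Pooled out-of-fold 3x3 confusion (rows actual, columns predicted)."""

    counts: pd.DataFrame
    fractions: pd.DataFrame

    def __post_init__(self) -> None:
        sums = self.fractions.sum(axis=1)
        require(bool(np.allclose(sums, 1.0)), "confusion fractions must row-normalize")


@dataclass
class ImportanceTable:
    """Permutation importance per miRNA: mean and SD over repeats."""

    table: pd.DataFrame  # index mirna_id; columns mean_importance, std

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("mean_importance", ascending=False)


@dataclass
class RfCvResult:
    """Random-forest nested-CV bundle, keeping per-fold fitted models so
    that permutation importance can be aggregated across outer folds."""

    model_result: ModelResult
    confusion: ConfusionMatrix
    fold_models: list  # (fitted forest, validation sample ids)
    feature_ids: list[str]


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def auc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUC with midrank tie correction."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels.astype(bool)
    n1 = int(pos.sum())
    n0 = len(labels) - n1
    require(n1 > 0 and n0 > 0, "AUC needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def rank_features(
    X: np.ndarray, y: np.ndarray, feature_ids: Sequence[str], percentage: float
) -> list[str]:
    """Rank features by ascending two-sample t-test p-value on the
    training data and keep the top ``percentage`` (minimum one).

    ``X`` is samples x features; ``y`` a binary vector.  Ties in p are
    broken by feature order for determinism.
    """
    require(percentage > 0, "percentage must be positive")
    y = np.asarray(y).astype(bool)
    _, p = _t_test_matrix(X[y].T, X[~y].T)
    order = np.argsort(p, kind="mergesort")
    k = max(1, int(np.round(percentage / 100.0 * X.shape[1])))
    return [feature_ids[i] for i in order[:k]]


@dataclass
class FittedLogistic:
    """Elastic-net logistic model plus the training standardization."""

    model: LogisticRegression
    mean: np.ndarray
    scale: np.ndarray
    feature_ids: list[str]
    converged: bool

    @property
    def coef_(self) -> np.ndarray:
        return self.model.coef_.ravel()

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Probability of the positive class for new samples."""
        Z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        return self.model.predict_proba(Z)[:, 1]

    # sklearn-compatible aliases so generic tooling works on this object
    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict_proba((np.asarray(X, float) - self.mean) / self.scale)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict((np.asarray(X, float) - self.mean) / self.scale)


def fit_elastic_logistic(
    X: np.ndarray,
    y: np.ndarray,
    inv_reg: float,
    l1_ratio: float,
    feature_ids: Sequence[str] | None = None,
    max_iter: int = 2000,
) -> FittedLogistic:
    """Fit a standardized elastic-net logistic regression.

    The objective is cross-entropy plus
    ``(1/inv_reg) * [l1_ratio * L1 + (1 - l1_ratio)/2 * L2]`` over the
    coefficients, i.e. scikit-learn's C parameterization with
    ``C = inv_reg``.  Features are standardized with training-fold
    statistics (constant features get unit scale).  Non-convergence
    within the iteration cap at tolerance 1e-6 is flagged on the result
    and the best iterate returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0.0] = 1.0
    Z = (X - mean) / scale
    model = LogisticRegression(
        solver="saga",
        C=float(inv_reg),
        l1_ratio=float(l1_ratio),
        tol=1e-6,
        max_iter=max_iter,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(Z, y)
    converged = int(np.max(model.n_iter_)) < max_iter
    ids = list(feature_ids) if feature_ids is not None else [str(i) for i in range(X.shape[1])]
    return FittedLogistic(model=model, mean=mean, scale=scale, feature_ids=ids, converged=converged)


def _fold_ci(fold_aucs: np.ndarray) -> float:
    """95% CI half-width: t_{0.975, k-1} * SD / sqrt(k) over fold AUCs."""
    k = len(fold_aucs)
    sd = float(np.std(fold_aucs, ddof=1))
    return float(stats.t.ppf(0.975, df=k - 1) * sd / np.sqrt(k))


def _effective_inner_folds(y: np.ndarray, requested: int) -> int:
    """Stratification cannot produce more folds than the rarest class."""
    _, counts = np.unique(y, return_counts=True)
    n = min(requested, int(counts.min()))
    if n < requested:
        warnings.warn(
            f"inner folds reduced from {requested} to {n} (rarest class size)",
            stacklevel=2,
        )
    return max(2, n)


# ---------------------------------------------------------------------------
# Nested CV: elastic-net logistic regression
# ---------------------------------------------------------------------------


def nested_cv_logistic(
    nm: NormalizedMatrix,
    ann: SampleAnnotation,
    positive: str | Iterable[str],
    negative: str | Iterable[str],
    grid: LrGrid | None = None,
    spec: CvSpec | None = None,
    comparison: str | None = None,
) -> ModelResult:
    """Nested-CV elastic-net logistic regression for a binary contrast.

    For every outer training split, the inner stratified CV evaluates
    all grid combinations (feature ranking and standardization refit
    inside each inner training split); the combination with the highest
    mean inner AUC wins, with ties broken toward the smaller feature
    percentage, then smaller inverse regularization, then larger L1
    ratio.  The winner is refit on the full outer training split and
    scored on the held-out outer fold.
    """
    grid = grid or LrGrid()
    spec = spec or CvSpec(outer_folds=5, inner_folds=10)
    pos = {positive} if isinstance(positive, str) else set(positive)
    neg = {negative} if isinstance(negative, str) else set(negative)
    require(not pos & neg, "positive and negative classes overlap")

    samples = [s for s in nm.sample_ids if s in set(ann.samples_of(pos | neg))]
    ann.check_covers(samples)
    X_all = nm.values[samples].T.to_numpy()  # samples x features
    feature_ids = list(nm.values.index)
    y_all = np.array([1 if ann.labels[s] in pos else 0 for s in samples])
    require(
        y_all.sum() >= spec.outer_folds and (len(y_all) - y_all.sum()) >= spec.outer_folds,
        "each class needs at least outer_folds samples",
    )

    combos = grid.combinations()
    outer = StratifiedKFold(
        n_splits=spec.outer_folds, shuffle=True, random_state=derive_seed(spec.seed, "outer")
    )
    fold_aucs = np.zeros(spec.outer_folds)
    best_params: list[dict] = []
    selected: list[list[str]] = []
    oof = pd.Series(np.nan, index=pd.Index(samples, name="sample_id"), name="score")

    for fold, (tr, va) in enumerate(outer.split(X_all, y_all)):
        X_tr, y_tr = X_all[tr], y_all[tr]
        n_inner = _effective_inner_folds(y_tr, spec.inner_folds)
        inner = StratifiedKFold(
            n_splits=n_inner,
            shuffle=True,
            random_state=derive_seed(spec.seed, "inner", str(fold)),
        )
        sums = np.zeros(len(combos))
        for itr, iva in inner.split(X_tr, y_tr):
            Xa, ya = X_tr[itr], y_tr[itr]
            Xb, yb = X_tr[iva], y_tr[iva]
            # rank once per split, reuse across percentages
            _, pvals = _t_test_matrix(Xa[ya == 1].T, Xa[ya == 0].T)
            order = np.argsort(pvals, kind="mergesort")
            ci = 0
            for pct in sorted(grid.feature_percentages):
                k = max(1, int(np.round(pct / 100.0 * X_tr.shape[1])))
                sel = order[:k]
                Za_raw, Zb_raw = Xa[:, sel], Xb[:, sel]
                mu = Za_raw.mean(axis=0)
                sd = Za_raw.std(axis=0)
                sd[sd == 0.0] = 1.0
                Za = (Za_raw - mu) / sd
                Zb = (Zb_raw - mu) / sd
                for c in sorted(grid.inv_regularization):
                    for l1 in sorted(grid.l1_ratios, reverse=True):
                        model = LogisticRegression(
                            solver="saga",
                            C=float(c),
                            l1_ratio=float(l1),
                            tol=1e-6,
                            max_iter=300,
                            random_state=0,
                        )
                        with warnings.catch_warnings():
                            warnings.simplefilter("ignore", ConvergenceWarning)
                            model.fit(Za, ya)
                        s = model.predict_proba(Zb)[:, 1]
                        sums[ci] += auc(s, yb)
                        ci += 1
        mean_inner = sums / n_inner
        best_idx = int(np.argmax(mean_inner))  # first max wins = tie-break order
        winner = combos[best_idx]
        best_params.append(dict(winner))

        sel_ids = rank_features(X_tr, y_tr, feature_ids, winner["feature_percentage"])
        selected.append(sel_ids)
        sel_idx = [feature_ids.index(f) for f in sel_ids]
        fitted = fit_elastic_logistic(
            X_tr[:, sel_idx], y_tr, winner["inv_reg"], winner["l1_ratio"], sel_ids
        )
        scores_va = fitted.decision_scores(X_all[va][:, sel_idx])
        fold_aucs[fold] = auc(scores_va, y_all[va])
        oof.iloc[va] = scores_va

    require(not oof.isna().any(), "every sample must get exactly one out-of-fold score")
    return ModelResult(
        comparison=comparison or f"{'+'.join(sorted(pos))}_vs_{'+'.join(sorted(neg))}",
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        ci_halfwidth=_fold_ci(fold_aucs),
        best_auc=float(fold_aucs.max()),
        best_params=best_params,
        selected_features=selected,
        oof_scores=oof,
    )


# ---------------------------------------------------------------------------
# Nested CV: random forest (3 classes)
# ---------------------------------------------------------------------------


def _macro_ovr_auc(proba: np.ndarray, y: np.ndarray, classes: np.ndarray) -> float:
    """Macro-averaged one-vs-rest AUC; classes absent from y are skipped."""
    vals = []
    for k, cls in enumerate(classes):
        mask = y == cls
        if 0 < mask.sum() < len(y):
            vals.append(auc(proba[:, k], mask))
    require(len(vals) > 0, "macro AUC needs at least one class contrast")
    return float(np.mean(vals))


def _make_forest(params: dict, n_trees: int, seed: int) -> RandomForestClassifier:
    mf = params["max_features"]
    if mf == "auto":  # conventional classification meaning
        mf = "sqrt"
    return RandomForestClassifier(
        n_estimators=n_trees,
        max_depth=params["max_depth"],
        bootstrap=params["bootstrap"],
        max_features=mf,
        criterion=params["criterion"],
        random_state=seed,
        n_jobs=1,
    )


def nested_cv_random_forest(
    nm: NormalizedMatrix,
    ann: SampleAnnotation,
    grid: RfGrid | None = None,
    spec: CvSpec | None = None,
) -> RfCvResult:
    """Three-class random forest with nested CV.

    Inner 3-fold selection maximizes mean one-vs-rest macro AUC; the
    confusion matrix pools the single out-of-fold prediction of every
    sample across the outer folds, so counts are integers summing to
    the cohort size.
    """
    grid = grid or RfGrid()
    spec = spec or CvSpec(outer_folds=5, inner_folds=3)
    samples = [s for s in nm.sample_ids if s in set(ann.sample_ids)]
    ann.check_covers(samples)
    X_all = nm.values[samples].T.to_numpy()
    y_all = np.array([ann.labels[s] for s in samples])
    classes = np.array(CLASS_LABELS)
    for cls in classes:
        require(
            (y_all == cls).sum() >= spec.outer_folds,
            f"class {cls} needs at least outer_folds samples",
        )

    combos = grid.combinations()
    outer = StratifiedKFold(
        n_splits=spec.outer_folds, shuffle=True, random_state=derive_seed(spec.seed, "rf_outer")
    )
    fold_aucs = np.zeros(spec.outer_folds)
    best_params: list[dict] = []
    fold_models = []
    oof_proba = pd.DataFrame(
        np.nan, index=pd.Index(samples, name="sample_id"), columns=list(classes)
    )
    oof_pred = pd.Series("", index=pd.Index(samples, name="sample_id"))

    for fold, (tr, va) in enumerate(outer.split(X_all, y_all)):
        X_tr, y_tr = X_all[tr], y_all[tr]
        n_inner = _effective_inner_folds(y_tr, spec.inner_folds)
        inner = StratifiedKFold(
            n_splits=n_inner,
            shuffle=True,
            random_state=derive_seed(spec.seed, "rf_inner", str(fold)),
        )
        sums = np.zeros(len(combos))
        splits = list(inner.split(X_tr, y_tr))
        for ci, params in enumerate(combos):
            for itr, iva in splits:
                forest = _make_forest(params, grid.n_trees, derive_seed(spec.seed, "rf_fit", str(fold)))
                forest.fit(X_tr[itr], y_tr[itr])
                proba = forest.predict_proba(X_tr[iva])
                # align probability columns to the canonical class order
                aligned = np.zeros((len(iva), len(classes)))
                for k, cls in enumerate(classes):
                    if cls in forest.classes_:
                        aligned[:, k] = proba[:, list(forest.classes_).index(cls)]
                sums[ci] += _macro_ovr_auc(aligned, y_tr[iva], classes)
        best_idx = int(np.argmax(sums / n_inner))
        winner = combos[best_idx]
        best_params.append(dict(winner))

        forest = _make_forest(winner, grid.n_trees, derive_seed(spec.seed, "rf_refit", str(fold)))
        forest.fit(X_tr, y_tr)
        proba = forest.predict_proba(X_all[va])
        aligned = np.zeros((len(va), len(classes)))
        for k, cls in enumerate(classes):
            if cls in forest.classes_:
                aligned[:, k] = proba[:, list(forest.classes_).index(cls)]
        fold_aucs[fold] = _macro_ovr_auc(aligned, y_all[va], classes)
        oof_proba.iloc[va] = aligned
        oof_pred.iloc[va] = forest.predict(X_all[va])
        fold_models.append((forest, [samples[i] for i in va]))

    counts = pd.DataFrame(0, index=list(classes), columns=list(classes))
    for s in samples:
        counts.loc[ann.labels[s], oof_pred[s]] += 1
    fractions = counts.div(counts.sum(axis=1), axis=0)

    model_result = ModelResult(
        comparison="RLN_vs_nTFHL_vs_nPTCL",
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        ci_halfwidth=_fold_ci(fold_aucs),
        best_auc=float(fold_aucs.max()),
        best_params=best_params,
        selected_features=[list(nm.values.index)] * spec.outer_folds,
        oof_scores=oof_proba,
    )
    confusion = ConfusionMatrix(counts=counts, fractions=fractions)
    return RfCvResult(
        model_result=model_result,
        confusion=confusion,
        fold_models=fold_models,
        feature_ids=list(nm.values.index),
    )


# ---------------------------------------------------------------------------
# Permutation importance
# ---------------------------------------------------------------------------


def permutation_importance(
    model,
    X_val: np.ndarray,
    y_val: np.ndarray,
    feature_ids: Sequence[str],
    repeats: int = 20,
    seed: int = 0,
) -> ImportanceTable:
    """Held-out permutation importance of every feature.

    Importance of feature f = baseline metric minus the mean metric
    after shuffling column f, over ``repeats`` independent shuffles.
    The metric is AUC of the positive-class probability for binary
    models and accuracy for multi-class models.  A feature the model
    ignores scores exactly zero.
    """
    require(repeats >= 2, "repeats must be >= 2")
    X_val = np.asarray(X_val, dtype=float)
    y_val = np.asarray(y_val)
    rng = np.random.default_rng(seed)
    classes = getattr(model, "classes_", None)
    if classes is None:
        classes = getattr(model.model, "classes_", None)
    binary = classes is not None and len(classes) == 2

    def metric(X: np.ndarray) -> float:
        if binary:
            return auc(model.predict_proba(X)[:, 1], y_val == classes[1])
        return float((model.predict(X) == y_val).mean())

    baseline = metric(X_val)
    means = np.zeros(len(feature_ids))
    stds = np.zeros(len(feature_ids))
    for j in range(X_val.shape[1]):
        drops = np.zeros(repeats)
        Xp = X_val.copy()
        for r in range(repeats):
            Xp[:, j] = rng.permutation(X_val[:, j])
            drops[r] = baseline - metric(Xp)
        means[j] = drops.mean()
        stds[j] = drops.std(ddof=1)
    table = pd.DataFrame(
        {"mean_importance": means, "std": stds},
        index=pd.Index(list(feature_ids), name="mirna_id"),
    )
    return ImportanceTable(table=table)


def rf_importance_table(
    rf: RfCvResult,
    nm: NormalizedMatrix,
    ann: SampleAnnotation,
    repeats: int = 20,
    seed: int = 0,
) -> ImportanceTable:
    """Permutation importance aggregated across outer folds.

    Each outer fold's refit forest is evaluated on its own validation
    samples; per-feature drops are pooled over (fold, repeat) pairs.
    """
    all_drops: dict[str, list[float]] = {f: [] for f in rf.feature_ids}
    for fold, (forest, val_samples) in enumerate(rf.fold_models):
        X_val = nm.values[val_samples].T.to_numpy()
        y_val = np.array([ann.labels[s] for s in val_samples])
        tbl = permutation_importance(
            forest, X_val, y_val, rf.feature_ids, repeats=repeats,
            seed=derive_seed(seed, "importance", str(fold)),
        )
        for f in rf.feature_ids:
            all_drops[f].append(float(tbl.table.loc[f, "mean_importance"]))
    table = pd.DataFrame(
        {
            "mean_importance": [float(np.mean(all_drops[f])) for f in rf.feature_ids],
            "std": [float(np.std(all_drops[f], ddof=1)) for f in rf.feature_ids],
        },
        index=pd.Index(rf.feature_ids, name="mirna_id"),
    )
    return ImportanceTable(table=table)


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------


def common_panel(
    results: Sequence[ModelResult], min_fold_frequency: float = 0.8
) -> set[str]:
    """Intersection of per-comparison stable feature sets.

    A feature is stable within one result when it was selected in at
    least ``min_fold_frequency`` of that run's outer folds.
    """
    require(len(results) >= 1, "need at least one model result")
    stable_sets = []
    for r in results:
        n_folds = len(r.selected_features)
        threshold = min_fold_frequency * n_folds
        counts: dict[str, int] = {}
        for fold_feats in r.selected_features:
            for f in fold_feats:
                counts[f] = counts.get(f, 0) + 1
        stable_sets.append({f for f, c in counts.items() if c >= threshold})
    return set.intersection(*stable_sets)
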