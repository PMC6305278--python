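"""One-vs-rest random-forest prediction of Gleason-score groups.

Three binary tasks (G1 vs rest, G2 vs rest, G3 vs rest) are each evaluated
with stratified 5-fold cross-validation of a 500-tree random forest, plus
an optional balanced 40/20 train/test hold-out run.  Feature importance is
the out-of-bag permutation importance: for every tree, the increase in
out-of-bag misclassification error after permuting one feature's values
among that tree's OOB samples, normalized per fold by the standard
deviation of the per-tree increases and averaged across folds.  A positive
value marks a predictive feature; values near or below zero mark features
the forest does not rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

logger = logging.getLogger(__name__)

TASK_LABELS = {1: "G1-vs-rest", 2: "G2-vs-rest", 3: "G3-vs-rest"}


@dataclass(frozen=True)
class RFConfig:
    """Random-forest and resampling settings.

    Defaults follow the canonical random-forest recipe: 500 unpruned trees,
    sqrt-of-features subsampling at each split, bootstrap resampling, and
    stratified 5-fold cross-validation.  All randomness (folds, bootstrap,
    permutations, hold-out draws) derives from ``seed``.
    """

    n_trees: int = 500
    n_folds: int = 5
    seed: int = 0
    max_features: str = "sqrt"
    importance_normalize: str = "tree_sd"  # or "none"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def one_vs_rest_labels(groups, target: int) -> np.ndarray:
    """Binary labels: 1 for the target group, 0 for all others."""
    groups = np.asarray(groups)
    y = (groups == target).astype(int)
    if y.sum() == 0:
        raise ValueError(f"target group {target} absent from cohort")
    if y.sum() == y.size:
        raise ValueError(f"target group {target} has no negatives")
    return y


def roc_auc(scores, labels) -> float:
    """AUC = P(random positive outscores random negative), ties count half."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def binary_metrics(scores, labels, threshold: float = 0.5) -> dict[str, float]:
    """AUC, accuracy, NPV, PPV from scores and binary labels."""
    labels = np.asarray(labels)
    pred = (np.asarray(scores, dtype=float) >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    n = labels.size
    return {
        "auc": roc_auc(scores, labels),
        "accuracy": (tp + tn) / n,
        "npv": tn / (tn + fn) if (tn + fn) > 0 else np.nan,
        "ppv": tp / (tp + fp) if (tp + fp) > 0 else np.nan,
        "tp": tp, "tn": tn, "fp": fp, "fn": fn,
    }


class OOBPermutationForest(ClassifierMixin, BaseEstimator):
    """Random forest with per-tree out-of-bag permutation importance.

    A thin estimator over :class:`~sklearn.ensemble.RandomForestClassifier`
    that retains each tree's bootstrap membership so the Breiman-style OOB
    permutation importance can be computed (scikit-learn's own
    ``permutation_importance`` works on a held-out set, not per-tree OOB
    samples).

    Parameters
    ----------
    n_trees : int
    max_features : str
    seed : int
    normalize : {"tree_sd", "none"}
        Divide the mean per-tree error increase by the SD of the per-tree
        increases ("the ensemble's standard deviation") or report the raw
        mean.

    Attributes
    ----------
    forest_ : fitted RandomForestClassifier
    oob_indices_ : list of arrays, per-tree out-of-bag row indices
    """

    def __init__(self, n_trees: int = 500, max_features: str = "sqrt",
                 seed: int = 0, normalize: str = "tree_sd"):
        self.n_trees = n_trees
        self.max_features = max_features
        self.seed = seed
        self.normalize = normalize

    def fit(self, X, y) -> "OOBPermutationForest":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2:
            raise ValueError("X must be 2D")
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            bootstrap=True,
            random_state=self.seed,
            n_jobs=1,
        )
        self.forest_.fit(X, y)
        self.classes_ = self.forest_.classes_
        n = X.shape[0]
        self.n_features_in_ = X.shape[1]
        self.oob_indices_ = [
            np.setdiff1d(np.arange(n), np.unique(s))
            for s in self.forest_.estimators_samples_
        ]
        self._X = X
        self._y = y
        return self

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict_proba(np.asarray(X, dtype=float))

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "forest_")
        return self.forest_.predict(np.asarray(X, dtype=float))

    def positive_scores(self, X) -> np.ndarray:
        """Probability of the positive (label 1) class."""
        proba = self.predict_proba(X)
        pos = int(np.where(self.classes_ == 1)[0][0])
        return proba[:, pos]

    def oob_permutation_importance(
        self, rng: np.random.Generator | int | None = None
    ) -> np.ndarray:
        """Normalized mean OOB error increase per feature.

        For tree t with OOB set O_t: d_{t,f} = err(permute feature f on
        O_t) - err(O_t).  Returns mean_t d_{t,f} / sd_t d_{t,f} (or the raw
        mean when ``normalize="none"``).  Trees with fewer than 2 OOB
        samples are skipped.
        """
        check_is_fitted(self, "forest_")
        rng = np.random.default_rng(rng)
        n_features = self._X.shape[1]
        deltas = []
        for tree, oob in zip(self.forest_.estimators_, self.oob_indices_):
            if oob.size < 2:
                continue
            Xo = self._X[oob]
            yo = self._y[oob]
            base_err = float(np.mean(tree.predict(Xo) != yo))
            row = np.empty(n_features)
            for f in range(n_features):
                Xp = Xo.copy()
                Xp[:, f] = Xp[rng.permutation(oob.size), f]
                row[f] = float(np.mean(tree.predict(Xp) != yo)) - base_err
            deltas.append(row)
        if not deltas:
            raise ValueError("no tree retained out-of-bag samples")
        d = np.asarray(deltas)
        mean = d.mean(axis=0)
        if self.normalize == "none":
            return mean
        if self.normalize != "tree_sd":
            raise ValueError(f"unknown normalization: {self.normalize!r}")
        sd = d.std(axis=0, ddof=0)
        out = np.zeros(n_features)
        nonzero = sd > 0
        out[nonzero] = mean[nonzero] / sd[nonzero]
        return out


@dataclass
class CVResult:
    """Per-task cross-validation outcome."""

    task: str
    fold_metrics: pd.DataFrame              # folds x (auc, accuracy, npv, ppv)
    confusion: dict[str, int]               # pooled out-of-fold, threshold 0.5
    oof_scores: pd.Series                   # out-of-fold positive-class scores
    importance: pd.Series | None = None     # 41 normalized importances

    @property
    def mean_metrics(self) -> pd.Series:
        return self.fold_metrics[["auc", "accuracy", "npv", "ppv"]].mean()


def _fold_seeds(seed: int, n: int) -> list[int]:
    """Independent per-fold seeds below 2**31 from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2**31)]


def crossval_rf(
    table,
    target: int,
    cfg: RFConfig = RFConfig(),
    compute_importance: bool = True,
) -> CVResult:
    """Stratified k-fold cross-validation of the one-vs-rest forest.

    ``table`` is a CohortFeatureTable.  Per fold the forest is fitted on
    k-1 subsets and scored on the held-out subset; AUC/accuracy/NPV/PPV are
    reported per fold and averaged, and the pooled out-of-fold hard
    predictions (threshold 0.5) form the confusion matrix.  Importance is
    the fold-averaged OOB permutation importance.
    """
    X = table.data.to_numpy(dtype=float)
    y = one_vs_rest_labels(table.groups.to_numpy(), target)
    counts = np.bincount(y)
    if counts.min() < cfg.n_folds:
        raise ValueError(
            f"each class needs >= {cfg.n_folds} members for "
            f"{cfg.n_folds}-fold CV, got {counts.tolist()}"
        )
    skf = StratifiedKFold(
        n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed % (2**31)
    )
    seeds = _fold_seeds(cfg.seed, cfg.n_folds)
    fold_rows = []
    oof = pd.Series(np.nan, index=table.data.index, dtype=float)
    importances = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = OOBPermutationForest(
            n_trees=cfg.n_trees,
            max_features=cfg.max_features,
            seed=seeds[fold],
            normalize=cfg.importance_normalize,
        ).fit(X[tr], y[tr])
        scores = model.positive_scores(X[te])
        oof.iloc[te] = scores
        fold_rows.append(binary_metrics(scores, y[te]))
        if compute_importance:
            importances.append(
                model.oob_permutation_importance(
                    np.random.default_rng(seeds[fold])
                )
            )
    fold_metrics = pd.DataFrame(fold_rows)
    pred = (oof.to_numpy() >= 0.5).astype(int)
    confusion = {
        "tp": int(np.sum((pred == 1) & (y == 1))),
        "tn": int(np.sum((pred == 0) & (y == 0))),
        "fp": int(np.sum((pred == 1) & (y == 0))),
        "fn": int(np.sum((pred == 0) & (y == 1))),
    }
    importance = None
    if compute_importance:
        importance = pd.Series(
            np.mean(importances, axis=0), index=table.data.columns
        )
    return CVResult(
        task=TASK_LABELS.get(target, f"G{target}-vs-rest"),
        fold_metrics=fold_metrics,
        confusion=confusion,
        oof_scores=oof,
        importance=importance,
    )


def holdout_rf(
    table,
    target: int,
    n_train: int = 40,
    n_test: int = 20,
    cfg: RFConfig = RFConfig(),
    prescaled: bool = True,
) -> dict[str, float]:
    """Balanced train/test hold-out evaluation of one one-vs-rest task.

    Draws class-balanced, disjoint train (n_train) and test (n_test)
    subsets with the config seed, fits one forest on the training subset
    and reports AUC/accuracy/NPV/PPV on the test subset.  With
    ``prescaled=False`` the raw table is min-max scaled using training-set
    parameters only (no leakage).  Patients left over after the draw are
    unused, and their count is logged.
    """
    from .features import apply_scaling, scale_features

    y = one_vs_rest_labels(table.groups.to_numpy(), target)
    n_pos_needed = n_train // 2 + n_test // 2
    counts = np.bincount(y)
    if counts[1] < n_pos_needed or counts[0] < n_pos_needed:
        raise ValueError(
            f"balanced {n_train}/{n_test} split needs {n_pos_needed} patients "
            f"per class, got positives={counts[1]}, negatives={counts[0]}"
        )
    rng = np.random.default_rng(cfg.seed)
    pos = rng.permutation(np.where(y == 1)[0])
    neg = rng.permutation(np.where(y == 0)[0])
    tr = np.concatenate([pos[: n_train // 2], neg[: n_train // 2]])
    te = np.concatenate(
        [pos[n_train // 2: n_pos_needed], neg[n_train // 2: n_pos_needed]]
    )
    unused = len(y) - tr.size - te.size
    logger.info("hold-out split leaves %d of %d patients unused", unused, len(y))
    X_tr = table.data.iloc[tr]
    X_te = table.data.iloc[te]
    if not prescaled:
        import dataclasses

        sub = dataclasses.replace(
            table, data=X_tr, groups=table.groups.iloc[tr], scaled=False,
            scaling_params=None,
        )
        scaled = scale_features(sub)
        X_tr = scaled.data
        X_te = apply_scaling(X_te, scaled.scaling_params)
    model = OOBPermutationForest(
        n_trees=cfg.n_trees, max_features=cfg.max_features,
        seed=_fold_seeds(cfg.seed, 1)[0],
    ).fit(X_tr.to_numpy(dtype=float), y[tr])
    scores = model.positive_scores(X_te.to_numpy(dtype=float))
    out = binary_metrics(scores, y[te])
    out["n_train"] = int(tr.size)
    out["n_test"] = int(te.size)
    out["n_unused"] = int(unused)
    return out


def permutation_importance_profile(
    table, cfg: RFConfig = RFConfig()
) -> pd.DataFrame:
    """41 x 3 table of fold-averaged OOB permutation importances."""
    cols = {}
    for target in (1, 2, 3):
        res = crossval_rf(table, target, cfg, compute_importance=True)
        cols[res.task] = res.importance
    return pd.DataFrame(cols)


def run_modality_comparison(
    tables: dict[str, "object"],
    cfg: RFConfig = RFConfig(),
    n_train: int = 40,
    n_test: int = 20,
) -> pd.DataFrame:
    """Hold-out metrics per task for each feature mode (mean / T2 / ADC).

    All tables must describe the same patients in the same order.
    """
    ids = None
    for mode, t in tables.items():
        cur = list(t.data.index)
        if ids is None:
            ids = cur
        elif cur != ids:
            raise ValueError(f"patient IDs misaligned in table {mode!r}")
    rows = []
    for mode, t in tables.items():
        for target in (1, 2, 3):
            m = holdout_rf(t, target, n_train=n_train, n_test=n_test, cfg=cfg)
            rows.append(
                {"modality": mode, "task": TASK_LABELS[target], **m}
            )
    return pd.DataFrame(rows)
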