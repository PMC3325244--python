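"""Multi-marker diagnostic classification.

An RBF-kernel support-vector machine is evaluated under repeated
stratified k-fold cross-validation with *nested* miRNA subset selection:
within every training fold, miRNAs are ranked by a univariate
Wilcoxon-Mann-Whitney score computed on that fold only, and the top-k
panel is used to fit the SVM; the held-out fold is touched only for
prediction.  A grid of panel sizes is evaluated per repetition and the
best size (by pooled held-out accuracy) is reported for that repetition.

Permutation controls rerun the identical procedure after randomly
permuting the class labels; with nested selection their accuracy and AUC
sit at chance, which is the over-fitting check the design exists for.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from ._util import child_seed
from .datatypes import CONTROL_LABELS, ExpressionMatrix

__all__ = [
    "CVConfig",
    "CVEvaluation",
    "stratified_folds",
    "select_features",
    "cross_validate",
    "permutation_control",
    "roc_auc",
]


@dataclass
class CVConfig:
    """Cross-validation and SVM settings.

    ``subset_sizes`` is the panel-size grid explored per repetition; the
    defaults bracket the panel sizes a pancreatic-disease signature is
    reported to need (about five markers in tissue, a few dozen in blood).
    ``gamma="scale"`` is the 1/(n_features * variance) heuristic.
    """

    k_folds: int = 10
    n_repetitions: int = 100
    subset_sizes: tuple[int, ...] = (5, 10, 20, 36, 50, 100)
    C: float = 1.0
    gamma: float | str = "scale"
    kernel: str = "rbf"
    seed: int = 0
    n_permutation_reps: int = 100

    def validate(self, class_counts: dict | None = None) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_repetitions < 1 or self.n_permutation_reps < 1:
            raise ValueError("repetition counts must be positive")
        if any(s <= 0 for s in self.subset_sizes):
            raise ValueError("subset sizes must be positive")
        if self.C <= 0:
            raise ValueError("C must be positive")


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Assign each sample to one of ``k`` folds, stratified by class.

    Overall fold sizes differ by at most one, and so do the per-class
    counts across folds.  ``k`` equal to the sample count gives
    leave-one-out (singleton folds, no stratification needed).
    Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError("more folds than samples")
    if k == n:
        return np.arange(n)
    counts = pd.Series(labels).value_counts()
    if (counts < k).any():
        small = counts[counts < k].index.tolist()
        raise ValueError(f"classes smaller than k={k}: {small}")
    skf = StratifiedKFold(n_splits=k, shuffle=True,
                          random_state=int(seed) % (2**31))
    assignment = np.empty(n, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
        assignment[test_idx] = fold
    return assignment


def _wmw_ranking_pvalues(x: np.ndarray, mask_a: np.ndarray) -> np.ndarray:
    """Two-sided normal-approximation WMW p-value per column, vectorized.

    Used only to *rank* features inside CV folds; on continuous expression
    values ties are measure-zero, so the ordering matches the exact test.
    """
    n = x.shape[0]
    n_a = int(mask_a.sum())
    n_b = n - n_a
    ranks = stats.rankdata(x, axis=0)
    u_a = ranks[mask_a].sum(axis=0) - n_a * (n_a + 1) / 2.0
    mean = n_a * n_b / 2.0
    sd = np.sqrt(n_a * n_b * (n + 1) / 12.0)
    z = np.abs(u_a - mean) / sd
    return 2.0 * stats.norm.sf(z)


def select_features(train: pd.DataFrame, train_labels: np.ndarray,
                    size: int) -> list[str]:
    """Top ``size`` miRNAs of the training fold by WMW p-value.

    Deterministic: ties in p are broken lexicographically by miRNA id.
    Never sees held-out samples — callers must pass training rows only.
    """
    if size <= 0:
        raise ValueError("size must be positive")
    if size > train.shape[1]:
        raise ValueError("size exceeds the number of miRNAs")
    labels = np.asarray(train_labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("binary labels required")
    p = _wmw_ranking_pvalues(train.to_numpy(), labels == classes[0])
    order = sorted(range(train.shape[1]),
                   key=lambda j: (p[j], str(train.columns[j])))
    return [str(train.columns[j]) for j in order[:size]]


def _positive_label(classes: np.ndarray, positive_label=None):
    """Disease class treated as "positive" for sensitivity/AUC."""
    if positive_label is not None:
        if positive_label not in classes:
            raise ValueError(f"{positive_label!r} not among class labels")
        return positive_label
    non_control = [c for c in classes if str(c).lower() not in CONTROL_LABELS]
    if len(non_control) == 1:
        return non_control[0]
    return sorted(classes, key=str)[-1]


def roc_auc(decision_values: np.ndarray,
            labels: np.ndarray, positive_label) -> tuple[np.ndarray, float]:
    """ROC curve (FPR/TPR points) and trapezoid AUC from decision values.

    Equivalent to Mann-Whitney pair counting with ties scored one half.
    """
    labels = np.asarray(labels)
    y = labels == positive_label
    if y.all() or not y.any():
        raise ValueError("both classes required")
    fpr, tpr, _ = roc_curve(y.astype(int), decision_values)
    return np.column_stack([fpr, tpr]), float(roc_auc_score(y, decision_values))


@dataclass
class CVEvaluation:
    """Outcome of repeated cross-validation (real or permuted labels).

    ``per_repetition`` holds accuracy, sensitivity, specificity, AUC and
    the chosen panel size of each repetition; ``aggregate`` holds the mean
    and percentile 95% CI of each metric across repetitions; ``roc_points``
    is the ROC of all held-out decision values pooled over repetitions.
    """

    mode: str  # "real-labels" or "permuted-labels"
    positive_label: str
    per_repetition: pd.DataFrame
    aggregate: dict[str, dict[str, float]]
    roc_points: np.ndarray
    selected_features: list[list[list[str]]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "positive_label": str(self.positive_label),
            "aggregate": self.aggregate,
            "per_repetition": self.per_repetition.to_dict(orient="records"),
            "roc_points": [[float(a), float(b)] for a, b in self.roc_points],
            "selected_features": self.selected_features,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1,
                                         sort_keys=True))


#: Inner folds used to pick the panel size inside each training fold.
INNER_K = 5


def _fit_predict(frame, train, test, feats, y, config):
    clf = SVC(C=config.C, kernel=config.kernel, gamma=config.gamma)
    clf.fit(frame.loc[train, feats].to_numpy(), y[train])
    xt = frame.loc[test, feats].to_numpy()
    return clf, clf.predict(xt), clf.decision_function(xt)


def _choose_size(frame: pd.DataFrame, y: np.ndarray, sizes: list[int],
                 config: CVConfig, seed: int) -> int:
    """Panel size by inner stratified CV on the training fold only.

    Feature ranking is redone inside every inner training split, so the
    choice uses no information outside the (outer) training fold.  Ties
    favour the smaller panel.
    """
    if len(sizes) == 1:
        return sizes[0]
    counts = pd.Series(y).value_counts()
    inner_k = min(INNER_K, int(counts.min()))
    if inner_k < 2:
        return sizes[0]
    folds = stratified_folds(y, inner_k, seed)
    hits = {s: 0 for s in sizes}
    for fold in np.unique(folds):
        val = folds == fold
        tr = ~val
        ranked = select_features(frame.loc[tr], y[tr], max(sizes))
        for s in sizes:
            _, pred, _ = _fit_predict(frame, tr, val, ranked[:s], y, config)
            hits[s] += int(np.sum(pred == y[val]))
    return min(sizes, key=lambda s: (-hits[s], s))


def _cv_pass(frame: pd.DataFrame, y: np.ndarray, pos, config: CVConfig,
             fold_seed: int):
    """One stratified k-fold pass; selection and size choice are nested.

    Within each training fold, miRNAs are ranked (training samples only)
    and the panel size is picked by inner cross-validation of that fold;
    the held-out fold is used exclusively for prediction.  Returns the
    per-repetition record, the pooled held-out decision values, and the
    per-fold feature panels.
    """
    n = len(y)
    sizes = sorted({min(s, frame.shape[1]) for s in config.subset_sizes})
    folds = stratified_folds(y, config.k_folds, fold_seed)
    inner_seeds = np.random.SeedSequence(fold_seed).generate_state(
        config.k_folds + 1)[1:]

    preds = np.empty(n, dtype=object)
    decisions = np.empty(n, dtype=float)
    fold_panels: list[list[str]] = []
    fold_sizes: list[int] = []
    for fold in np.unique(folds):
        test = folds == fold
        train = ~test
        size = _choose_size(frame.loc[train], y[train], sizes, config,
                            int(inner_seeds[fold]))
        ranked = select_features(frame.loc[train], y[train], size)
        fold_panels.append(ranked)
        fold_sizes.append(size)
        clf, preds[test], dec = _fit_predict(frame, train, test, ranked,
                                             y, config)
        if clf.classes_[1] != pos:  # orient scores toward the positive class
            dec = -dec
        decisions[test] = dec

    is_pos = y == pos
    modal_size = pd.Series(fold_sizes).mode().min()
    record = {
        "accuracy": float(np.mean(preds == y)),
        "sensitivity": float(np.mean(preds[is_pos] == y[is_pos])),
        "specificity": float(np.mean(preds[~is_pos] == y[~is_pos])),
        "auc": roc_auc(decisions, y, pos)[1],
        "chosen_subset_size": int(modal_size),
    }
    return record, decisions, fold_panels


def _aggregate(records: pd.DataFrame) -> dict[str, dict[str, float]]:
    agg = {}
    for col in ("accuracy", "sensitivity", "specificity", "auc"):
        vals = records[col].to_numpy()
        agg[col] = {
            "mean": float(np.mean(vals)),
            "ci_low": float(np.percentile(vals, 2.5)),
            "ci_high": float(np.percentile(vals, 97.5)),
        }
    return agg


def _as_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, ExpressionMatrix):
        return matrix.data
    return matrix


def cross_validate(matrix, labels, config: CVConfig,
                   positive_label=None,
                   feature_subset: list[str] | None = None) -> CVEvaluation:
    """Repeated stratified k-fold CV with in-fold feature selection.

    Each repetition draws fresh stratified folds; within each training
    fold miRNAs are re-ranked and the SVM refit, so no information from
    held-out samples reaches training.  ``feature_subset`` restricts the
    matrix to a fixed panel *before* CV (bypassing in-fold selection for
    that panel) — useful to quantify the optimistic bias of selecting
    features outside the loop.
    """
    frame = _as_frame(matrix)
    y = np.asarray(labels)
    if len(y) != len(frame):
        raise ValueError("labels must align with matrix samples")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    config.validate()
    pos = _positive_label(classes, positive_label)
    if feature_subset is not None:
        frame = frame[list(feature_subset)]

    records, all_dec, all_y, panels = [], [], [], []
    root = child_seed(config.seed, "cross_validate")
    rep_seeds = root.generate_state(config.n_repetitions)
    for r in range(config.n_repetitions):
        rec, dec, fold_panels = _cv_pass(frame, y, pos, config,
                                         int(rep_seeds[r]))
        records.append(rec)
        all_dec.append(dec)
        all_y.append(y)
        panels.append(fold_panels)

    per_rep = pd.DataFrame.from_records(records)
    pooled_roc, _ = roc_auc(np.concatenate(all_dec), np.concatenate(all_y), pos)
    return CVEvaluation("real-labels", str(pos), per_rep,
                        _aggregate(per_rep), pooled_roc, panels)


def permutation_control(matrix, labels, config: CVConfig,
                        positive_label=None) -> CVEvaluation:
    """Chance-level control: label-permuted repetitions of the full CV.

    Each of ``config.n_permutation_reps`` repetitions permutes the class
    labels independently, then runs one complete stratified k-fold pass
    with in-fold feature selection.  Strong real-label performance with
    chance-level permuted performance rules out over-fitting as the
    explanation.
    """
    frame = _as_frame(matrix)
    y = np.asarray(labels)
    if len(y) != len(frame):
        raise ValueError("labels must align with matrix samples")
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    config.validate()
    pos = _positive_label(classes, positive_label)

    records, all_dec, all_y, panels = [], [], [], []
    root = child_seed(config.seed, "permutation_control")
    rng = np.random.default_rng(root)
    rep_seeds = root.generate_state(config.n_permutation_reps)
    for r in range(config.n_permutation_reps):
        y_perm = rng.permutation(y)
        rec, dec, fold_panels = _cv_pass(frame, y_perm, pos, config,
                                         int(rep_seeds[r]))
        records.append(rec)
        all_dec.append(dec)
        all_y.append(y_perm)
        panels.append(fold_panels)

    per_rep = pd.DataFrame.from_records(records)
    pooled_roc, _ = roc_auc(np.concatenate(all_dec), np.concatenate(all_y), pos)
    return CVEvaluation("permuted-labels", str(pos), per_rep,
                        _aggregate(per_rep), pooled_roc, panels)
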