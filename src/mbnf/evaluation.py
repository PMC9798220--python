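"""Edge features, t-test selection and nested cross-validated SVM.

Classification follows the standard connectome-as-features recipe: the
upper triangle of each subject's (fused) network becomes an edge
vector, a two-sample t-test on the training subjects keeps edges with
p < alpha, and a linear SVM (C = 1) separates the groups.  Hyper-
parameters of the network construction step (PC edge-keep fraction or
SR lambda) are chosen by an inner 5-fold CV nested inside each outer
training fold, so neither feature selection nor model selection ever
sees test subjects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = ["EdgeFeatureMatrix", "ConfusionCounts", "CvReport",
           "edge_index", "edge_vector", "TTestSelector", "ttest_select",
           "confusion_metrics", "nested_cv_classify",
           "paired_ttest_compare", "noise_robustness_experiment"]


def edge_index(P: int) -> list[tuple[int, int]]:
    """Row-major upper-triangle (i < j) edge ordering."""
    iu = np.triu_indices(P, k=1)
    return list(zip(iu[0].tolist(), iu[1].tolist()))


def edge_vector(W: np.ndarray) -> np.ndarray:
    """Vectorise a symmetric network's upper triangle (length P(P-1)/2)."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("expected a square matrix")
    if np.abs(W - W.T).max() > 1e-9:
        raise ValueError("matrix is not symmetric")
    return W[np.triu_indices(W.shape[0], k=1)]


@dataclass
class EdgeFeatureMatrix:
    """Subjects x edges feature matrix with its edge ordering and labels."""

    values: np.ndarray
    edge_index: list
    labels: np.ndarray

    @classmethod
    def from_networks(cls, networks, labels) -> "EdgeFeatureMatrix":
        nets = np.asarray(networks, dtype=float)
        feats = np.stack([edge_vector(W) for W in nets])
        return cls(values=feats, edge_index=edge_index(nets.shape[1]),
                   labels=np.asarray(labels, dtype=int))


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class CvReport:
    """Mean +/- sd classification metrics over repeated nested CV."""

    acc_mean: float
    acc_sd: float
    sen_mean: float
    sen_sd: float
    spe_mean: float
    spe_sd: float
    auc_mean: float
    auc_sd: float
    n_repeats: int
    n_folds: int
    chosen_hyperparams: list = field(default_factory=list)
    seed: int = 0
    acc_per_repeat: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "acc": [self.acc_mean, self.acc_sd],
            "sen": [self.sen_mean, self.sen_sd],
            "spe": [self.spe_mean, self.spe_sd],
            "auc": [self.auc_mean, self.auc_sd],
            "n_repeats": self.n_repeats, "n_folds": self.n_folds,
            "chosen_hyperparams": self.chosen_hyperparams, "seed": self.seed,
            "acc_per_repeat": list(self.acc_per_repeat),
        }


class TTestSelector(SelectorMixin, BaseEstimator):
    """Keep features whose two-sample t-test gives p < alpha.

    Pooled-variance test by default (``equal_var=False`` switches to
    Welch).  Features with zero variance in both groups are never
    selected.  If nothing passes, the single smallest-p feature is kept
    so a downstream classifier always has input.
    """

    def __init__(self, alpha: float = 0.05, equal_var: bool = True):
        self.alpha = alpha
        self.equal_var = equal_var

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) != 2:
            raise ValueError("t-test selection needs exactly two classes")
        a, b = X[y == classes[0]], X[y == classes[1]]
        degenerate = (a.std(axis=0) == 0) & (b.std(axis=0) == 0)
        if degenerate.any():
            logger.warning("%d zero-variance edges excluded from selection",
                           int(degenerate.sum()))
        with np.errstate(divide="ignore", invalid="ignore"):
            t, p = stats.ttest_ind(a, b, axis=0, equal_var=self.equal_var)
        p = np.where(degenerate | np.isnan(p), 1.0, p)
        mask = p < self.alpha
        if not mask.any():
            mask[int(np.argmin(p))] = True
        self.tvalues_ = np.where(np.isnan(t), 0.0, t)
        self.pvalues_ = p
        self.support_mask_ = mask
        self.n_features_in_ = X.shape[1]
        return self

    def _get_support_mask(self):
        return self.support_mask_


def ttest_select(features: np.ndarray, labels, alpha: float = 0.05,
                 equal_var: bool = True) -> np.ndarray:
    """Boolean mask of edges with two-sample t-test p < alpha."""
    sel = TTestSelector(alpha=alpha, equal_var=equal_var)
    sel.fit(np.asarray(features, dtype=float), np.asarray(labels))
    # the convenience wrapper reports the raw threshold mask without the
    # keep-at-least-one fallback
    return sel.pvalues_ < alpha


def confusion_metrics(c: ConfusionCounts) -> tuple[float, float, float]:
    """(ACC, SEN, SPE) percentages from confusion counts."""
    total = c.tp + c.tn + c.fp + c.fn
    if c.tp + c.fn == 0 or c.tn + c.fp == 0:
        raise ValueError("a class is absent from the test set")
    acc = 100.0 * (c.tp + c.tn) / total
    sen = 100.0 * c.tp / (c.tp + c.fn)
    spe = 100.0 * c.tn / (c.tn + c.fp)
    return acc, sen, spe


def _as_feature_dict(networks_by_param, labels) -> dict:
    """Normalise input to {grid value: N x E feature matrix}."""
    out = {}
    for key, value in networks_by_param.items():
        arr = np.asarray(value, dtype=float)
        if arr.ndim == 3:
            arr = np.stack([edge_vector(W) for W in arr])
        if arr.shape[0] != len(labels):
            raise ValueError(f"grid value {key}: subject count mismatch")
        out[key] = arr
    return out


def _make_pipeline(alpha: float, C: float) -> Pipeline:
    return Pipeline([
        ("select", TTestSelector(alpha=alpha)),
        ("svm", SVC(kernel="linear", C=C)),
    ])


def nested_cv_classify(networks_by_param: dict, labels,
                       n_repeats: int = 10, seed: int = 0,
                       n_folds: int = 5, alpha: float = 0.05,
                       C: float = 1.0) -> CvReport:
    """Repeated stratified nested k-fold evaluation.

    ``networks_by_param`` maps each hyperparameter grid value to the
    per-subject networks (N x P x P) or edge-feature matrix (N x E)
    built at that value.  For each outer fold, an inner stratified
    k-fold on the outer-training subjects picks the grid value with the
    highest mean inner accuracy (ties break toward the smaller value);
    t-test selection and the linear SVM are then fit on the outer-
    training subjects only.  Per-repeat metrics pool the outer folds'
    confusion counts and decision scores; means and sds are taken over
    repeats.
    """
    labels = np.asarray(labels, dtype=int)
    feats = _as_feature_dict(networks_by_param, labels)
    grid = sorted(feats)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    counts = np.bincount(labels, minlength=2)
    if counts.min() < n_folds:
        raise ValueError("too few subjects per class for stratified folds")

    master = np.random.default_rng(seed)
    accs, sens, spes, aucs = [], [], [], []
    chosen_all = []
    for _ in range(n_repeats):
        rs_outer = int(master.integers(2**31))
        rs_inner = int(master.integers(2**31))
        outer = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                random_state=rs_outer)
        c = ConfusionCounts(0, 0, 0, 0)
        scores, score_labels = [], []
        chosen_repeat = []
        for tr, te in outer.split(feats[grid[0]], labels):
            best_val, best_acc = grid[0], -1.0
            inner = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                    random_state=rs_inner)
            for val in grid:
                X = feats[val]
                fold_accs = []
                for itr, ite in inner.split(X[tr], labels[tr]):
                    pipe = _make_pipeline(alpha, C)
                    pipe.fit(X[tr][itr], labels[tr][itr])
                    fold_accs.append(pipe.score(X[tr][ite], labels[tr][ite]))
                mean_acc = float(np.mean(fold_accs))
                if mean_acc > best_acc + 1e-12:  # ties keep smaller value
                    best_acc, best_val = mean_acc, val
            chosen_repeat.append(best_val)
            X = feats[best_val]
            pipe = _make_pipeline(alpha, C)
            pipe.fit(X[tr], labels[tr])
            pred = pipe.predict(X[te])
            truth = labels[te]
            c.tp += int(np.sum((pred == 1) & (truth == 1)))
            c.tn += int(np.sum((pred == 0) & (truth == 0)))
            c.fp += int(np.sum((pred == 1) & (truth == 0)))
            c.fn += int(np.sum((pred == 0) & (truth == 1)))
            scores.append(pipe.decision_function(X[te]))
            score_labels.append(truth)
        acc, sen, spe = confusion_metrics(c)
        auc = 100.0 * roc_auc_score(np.concatenate(score_labels),
                                    np.concatenate(scores))
        accs.append(acc)
        sens.append(sen)
        spes.append(spe)
        aucs.append(auc)
        chosen_all.append(chosen_repeat)

    def ms(v):
        return float(np.mean(v)), float(np.std(v))

    (am, asd), (sm, ssd) = ms(accs), ms(sens)
    (pm, psd), (um, usd) = ms(spes), ms(aucs)
    return CvReport(acc_mean=am, acc_sd=asd, sen_mean=sm, sen_sd=ssd,
                    spe_mean=pm, spe_sd=psd, auc_mean=um, auc_sd=usd,
                    n_repeats=n_repeats, n_folds=n_folds,
                    chosen_hyperparams=chosen_all, seed=seed,
                    acc_per_repeat=accs)


def paired_ttest_compare(metric_series_a, metric_series_b,
                         alpha: float = 0.05) -> tuple[float, bool]:
    """Two-sided paired t-test on per-repeat metrics (same splits).

    Returns (p, significant).  All-zero differences make the statistic
    undefined; p is NaN and the flag False.
    """
    a = np.asarray(metric_series_a, dtype=float)
    b = np.asarray(metric_series_b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need equal-length paired series of length >= 2")
    diffs = a - b
    if np.std(diffs) == 0:
        return float("nan"), False
    t, p = stats.ttest_rel(a, b)
    return float(p), bool(p < alpha)


def noise_robustness_experiment(networks, labels, sd_grid,
                                n_repeats: int = 10, seed: int = 0,
                                n_folds: int = 5, alpha: float = 0.05,
                                C: float = 1.0) -> list[dict]:
    """Classification accuracy as network noise grows.

    For each sd in ``sd_grid``, symmetric Gaussian noise (drawn on the
    upper triangle and mirrored) is added to every subject's network
    and the full classification pipeline is re-run with the same CV
    seed.  Returns one record per sd: {"sd", "acc_mean", "acc_sd"}.
    """
    nets = np.asarray(networks, dtype=float)
    sd_grid = list(sd_grid)
    if any(s < 0 for s in sd_grid):
        raise ValueError("noise sd must be non-negative")
    if sorted(sd_grid) != sd_grid:
        raise ValueError("sd_grid must be ascending")
    P = nets.shape[1]
    iu = np.triu_indices(P, k=1)
    noise_rng = np.random.default_rng(seed + 1)
    table = []
    for sd in sd_grid:
        perturbed = nets.copy()
        if sd > 0:
            for W in perturbed:
                noise = np.zeros((P, P))
                noise[iu] = sd * noise_rng.standard_normal(len(iu[0]))
                W += noise + noise.T
        report = nested_cv_classify({0.0: perturbed}, labels,
                                    n_repeats=n_repeats, seed=seed,
                                    n_folds=n_folds, alpha=alpha, C=C)
        table.append({"sd": float(sd), "acc_mean": report.acc_mean,
                      "acc_sd": report.acc_sd})
    return table
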