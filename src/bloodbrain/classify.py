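"""Blood-based classification of dependence status (CIE vs Air).

Three interpretable model families — logistic regression with elastic-net
regularization, random forest, and partial least squares discriminant
analysis (PLSDA) — are evaluated under repeated stratified k-fold
cross-validation.  Normalization is leakage-safe: log-CPM is per-sample,
and gene-wise centering/scaling coefficients are estimated on the training
folds only and applied unchanged to the test fold.  Hyperparameters are
chosen by an inner cross-validation on the training folds; performance
metrics (accuracy, sensitivity, specificity, FPR, MCC, AUROC) are averaged
across all repeated folds, and variable importances come from a final model
fit on all samples.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from bloodbrain.ingest import CountMatrix

__all__ = [
    "ClassifierConfig",
    "ClassifierReport",
    "default_grid",
    "repeated_cv_split",
    "fold_normalize",
    "fit_model",
    "metrics",
    "roc_auc",
    "run_classification",
]

MODEL_NAMES = ("elastic_net_lr", "random_forest", "plsda")


@dataclasses.dataclass
class ClassifierConfig:
    """Cross-validation plan and hyperparameter grid for one model family."""

    model: str
    k_folds: int = 5
    repeats: int = 10
    seed: int = 0
    grid: list[dict] | None = None  # None -> default_grid at fit time
    inner_k: int = 5

    def __post_init__(self):
        if self.model not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.model!r}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.grid is not None and not self.grid:
            raise ValueError("hyperparameter grid must be nonempty")


def default_grid(model: str, n_genes: int) -> list[dict]:
    """Default hyperparameter grids.

    Elastic net scans mixing alpha in {0, 0.1, ..., 1} crossed with 50
    log-spaced penalties; random forest scans mtry in {sqrt(p), p/10, p/4};
    PLSDA scans 1-5 components.
    """
    if model == "elastic_net_lr":
        alphas = np.round(np.linspace(0.0, 1.0, 11), 2)
        lambdas = np.logspace(-3, 1, 50)
        return [{"alpha": float(a), "lam": float(l)} for a in alphas for l in lambdas]
    if model == "random_forest":
        mtrys = sorted({max(1, int(np.sqrt(n_genes))), max(1, n_genes // 10), max(1, n_genes // 4)})
        return [{"mtry": m, "n_trees": 500} for m in mtrys]
    if model == "plsda":
        return [{"ncomp": c} for c in range(1, 6)]
    raise ValueError(f"unknown model {model!r}")


def repeated_cv_split(labels: np.ndarray, k: int, repeats: int, seed: int):
    """Seeded repeated stratified k-fold plan.

    Yields (repeat, fold, train_idx, test_idx); within each repeat the test
    folds partition the samples and preserve the class ratio to within one
    sample.
    """
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) != 2:
        raise ValueError("need exactly two classes")
    if counts.min() < k:
        raise ValueError(f"smallest class has {counts.min()} members < k={k}")
    plan = []
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for fold, (train, test) in enumerate(splitter.split(np.zeros(len(labels)), labels)):
            plan.append((rep, fold, train, test))
    return plan


def fold_normalize(
    train_counts: np.ndarray,
    test_counts: np.ndarray | None,
    prior: float = 0.5,
):
    """Leakage-safe normalization of count folds.

    Inputs are samples x genes count arrays.  Each sample is converted to
    log-CPM with its own library size (no cross-sample coefficient), then
    genes are centered and scaled using mean/sd from the training samples
    only.  Zero-sd genes are scaled by 1.  Returns (train_z, test_z, stats).
    """
    def _logcpm(mat):
        mat = np.asarray(mat, dtype=float)
        lib = mat.sum(axis=1, keepdims=True)
        if (lib <= 0).any():
            raise ValueError("sample with zero library size")
        return np.log2((mat + prior) / (lib + 2.0 * prior) * 1e6)

    train = _logcpm(train_counts)
    mean = train.mean(axis=0)
    sd = train.std(axis=0)
    constant = sd < 1e-8  # tolerance: log2-CPM of identical columns is not bit-equal
    scale = np.where(constant, 1.0, sd)
    train_z = (train - mean) / scale
    test_z = None
    if test_counts is not None:
        test_z = (_logcpm(test_counts) - mean) / scale
    return train_z, test_z, {"mean": mean, "sd": scale, "flagged_constant": constant}


class _ElasticNetLR:
    """Penalized logistic regression: lam * (alpha*L1 + (1-alpha)/2 * L2)."""

    def __init__(self, alpha: float, lam: float, max_iter: int = 10_000, tol: float = 1e-7):
        self.alpha, self.lam = alpha, lam
        self.max_iter, self.tol = max_iter, tol

    def fit(self, X, y):
        n = X.shape[0]
        # scikit-learn minimizes sum-loss + (1/C)*penalty; the per-sample
        # average-loss parameterization maps to C = 1 / (n * lam)
        self._clf = LogisticRegression(
            solver="saga",
            l1_ratio=self.alpha,
            C=1.0 / (n * self.lam),
            max_iter=self.max_iter,
            tol=self.tol,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            try:
                self._clf.fit(X, y)
            except ConvergenceWarning as exc:
                raise RuntimeError(
                    f"elastic-net LR failed to converge (alpha={self.alpha}, "
                    f"lam={self.lam}, max_iter={self.max_iter}, tol={self.tol})"
                ) from exc
        return self

    def scores(self, X):
        return self._clf.predict_proba(X)[:, 1]

    def predict(self, X):
        return (self.scores(X) >= 0.5).astype(int)

    def importance(self):
        coef = self._clf.coef_.ravel()
        return coef, np.abs(coef)

    @property
    def n_features_used(self):
        return int(np.count_nonzero(self._clf.coef_.ravel()))


class _RandomForest:
    """Bagged CART forest with Gini splits and mtry features per split."""

    def __init__(self, mtry: int, n_trees: int = 500, seed: int = 0):
        self.mtry, self.n_trees, self.seed = mtry, n_trees, seed

    def fit(self, X, y):
        if self.mtry > X.shape[1]:
            raise ValueError("mtry exceeds the number of genes")
        self._clf = RandomForestClassifier(
            n_estimators=self.n_trees,
            max_features=self.mtry,
            criterion="gini",
            random_state=self.seed,
            oob_score=False,
        )
        self._clf.fit(X, y)
        return self

    def scores(self, X):
        # fraction of trees voting for the positive class
        votes = np.stack([tree.predict(X) for tree in self._clf.estimators_])
        return votes.mean(axis=0)

    def predict(self, X):
        return (self.scores(X) >= 0.5).astype(int)

    def importance(self):
        imp = self._clf.feature_importances_
        return imp, imp

    @property
    def n_features_used(self):
        return int(np.count_nonzero(self._clf.feature_importances_))


class _PLSDA:
    """PLS regression against the 0/1 label; class scores are the predictor."""

    def __init__(self, ncomp: int):
        self.ncomp = ncomp

    def fit(self, X, y):
        rank = min(X.shape[0] - 1, X.shape[1])
        if self.ncomp > rank:
            raise ValueError(f"ncomp={self.ncomp} exceeds the predictor rank {rank}")
        self._pls = PLSRegression(n_components=self.ncomp, scale=False)
        y = np.asarray(y, dtype=float)
        self._pls.fit(X, y)
        fitted = self._pls.predict(X).ravel()
        self._threshold = 0.5 * (fitted[y == 1].mean() + fitted[y == 0].mean())
        return self

    def scores(self, X):
        return self._pls.predict(X).ravel()

    def predict(self, X):
        return (self.scores(X) >= self._threshold).astype(int)

    def importance(self):
        # weighted sums of absolute per-component regression coefficients,
        # weights proportional to each component's reduction in response SS
        rot = self._pls.x_rotations_  # (p, A)
        q = self._pls.y_loadings_.ravel()  # (A,)
        t = self._pls.x_scores_  # (n, A)
        ss = q**2 * (t**2).sum(axis=0)
        w = ss / ss.sum() if ss.sum() > 0 else np.full(len(ss), 1.0 / len(ss))
        per_comp = np.abs(rot * q[None, :])  # |coef contribution| per component
        imp = per_comp @ w
        signed = (rot * q[None, :]) @ w
        return signed, imp

    @property
    def n_features_used(self):
        return int(self._pls.x_rotations_.shape[0])


def fit_model(model: str, X, y, params: dict, seed: int = 0):
    if model == "elastic_net_lr":
        return _ElasticNetLR(params["alpha"], params["lam"]).fit(X, y)
    if model == "random_forest":
        return _RandomForest(params["mtry"], params.get("n_trees", 500), seed).fit(X, y)
    if model == "plsda":
        return _PLSDA(params["ncomp"]).fit(X, y)
    raise ValueError(f"unknown model {model!r}")


def metrics(tp: int, fn: int, tn: int, fp: int) -> dict[str, float]:
    """Confusion-matrix metrics: accuracy, sensitivity, specificity, FPR, MCC.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as
    0 when any denominator factor vanishes.
    """
    if min(tp, fn, tn, fp) < 0:
        raise ValueError("negative confusion-matrix cells")
    total = tp + fn + tn + fp
    if total == 0:
        raise ValueError("empty confusion matrix")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("rate metrics need both classes present")
    acc = (tp + tn) / total
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    fpr = 1.0 - spec
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = 0.0 if denom == 0 else (tp * tn - fp * fn) / np.sqrt(denom)
    return {
        "accuracy": acc,
        "sensitivity": sens,
        "specificity": spec,
        "fpr": fpr,
        "mcc": float(mcc),
    }


def roc_auc(scores, labels):
    """ROC curve and trapezoidal AUROC.

    Thresholds sweep the sorted unique scores; the curve is the set of
    (FPR, TPR) points closed at (0,0) and (1,1).  The trapezoidal area
    equals the Mann-Whitney concordance probability (ties count one half).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos, neg = (labels == 1).sum(), (labels == 0).sum()
    if pos == 0 or neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    tps = np.cumsum(sorted_labels)
    fps = np.cumsum(1 - sorted_labels)
    # collapse ties: keep the last point of each distinct score
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tpr = np.r_[0.0, tps[distinct] / pos]
    fpr = np.r_[0.0, fps[distinct] / neg]
    auc = float(np.trapezoid(tpr, fpr))
    points = pd.DataFrame({"fpr": fpr, "tpr": tpr})
    return points, auc


def _inner_select(model: str, X, y, grid: list[dict], k: int, seed: int) -> dict:
    """Inner CV hyperparameter selection by accuracy.

    Ties break toward the smaller penalty / component count / mtry so the
    simplest model among equals wins deterministically.
    """
    classes, counts = np.unique(y, return_counts=True)
    k_eff = min(k, int(counts.min()))
    if k_eff < 2:
        raise ValueError("too few samples for inner cross-validation")
    splitter = StratifiedKFold(n_splits=k_eff, shuffle=True, random_state=seed)
    folds = list(splitter.split(np.zeros(len(y)), y))
    results = []
    for params in grid:
        correct = 0
        total = 0
        try:
            for train, test in folds:
                mdl = fit_model(model, X[train], y[train], params, seed=seed)
                pred = mdl.predict(X[test])
                correct += int((pred == y[test]).sum())
                total += len(test)
        except RuntimeError:  # e.g. no convergence at a near-zero penalty
            continue
        results.append((correct / total, params))
    if not results:
        raise RuntimeError("no hyperparameter combination could be fit")

    def tiebreak(item):
        acc, params = item
        return (
            -acc,
            params.get("lam", 0.0),
            params.get("ncomp", 0),
            params.get("mtry", 0),
            params.get("alpha", 0.0),
        )

    results.sort(key=tiebreak)
    return results[0][1]


@dataclasses.dataclass
class ClassifierReport:
    """Averaged CV performance, ROC points, and final-model importances."""

    model: str
    metrics: dict[str, float]
    fold_metrics: pd.DataFrame
    roc_points: pd.DataFrame
    importance: pd.DataFrame
    selected_params: dict
    n_features_used: int


def run_classification(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    configs: list[ClassifierConfig],
    positive_group: str = "CIE",
    normalize_inner: bool = True,
) -> dict[str, ClassifierReport]:
    """Repeated-CV evaluation of all configured models on one tissue.

    ``metadata`` must cover exactly the samples of ``counts`` (one tissue,
    one sex); mixed tissues are rejected.  Outer folds estimate
    performance with inner-CV hyperparameter selection per training fold;
    importances come from a final all-data fit with hyperparameters chosen
    by inner CV on the full data.
    """
    meta = metadata.set_index("sample_id").loc[counts.samples]
    if meta["tissue"].nunique() != 1:
        raise ValueError("classification input mixes tissues")
    y = (meta["group"] == positive_group).to_numpy().astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both groups must be present")
    X_counts = counts.counts.T  # samples x genes
    genes = counts.genes

    reports = {}
    for config in configs:
        grid = config.grid or default_grid(config.model, counts.n_genes)
        plan = repeated_cv_split(y, config.k_folds, config.repeats, config.seed)
        rows = []
        roc_accum = []
        for rep, fold, train, test in plan:
            train_z, test_z, _ = fold_normalize(X_counts[train], X_counts[test])
            if len(grid) > 1:
                params = _inner_select(
                    config.model, train_z, y[train], grid,
                    config.inner_k, config.seed + rep,
                )
            else:
                params = grid[0]
            mdl = fit_model(config.model, train_z, y[train], params, seed=config.seed + rep)
            scores = mdl.scores(test_z)
            pred = mdl.predict(test_z)
            tp = int(((pred == 1) & (y[test] == 1)).sum())
            fn = int(((pred == 0) & (y[test] == 1)).sum())
            tn = int(((pred == 0) & (y[test] == 0)).sum())
            fp = int(((pred == 1) & (y[test] == 0)).sum())
            row = {"repeat": rep, "fold": fold, **metrics(tp, fn, tn, fp)}
            if len(np.unique(y[test])) == 2:
                _, auc = roc_auc(scores, y[test])
                row["auroc"] = auc
            rows.append(row)
            roc_accum.append((scores, y[test]))
        fold_metrics = pd.DataFrame(rows)
        averaged = fold_metrics.drop(columns=["repeat", "fold"]).mean().to_dict()

        pooled_scores = np.concatenate([s for s, _ in roc_accum])
        pooled_labels = np.concatenate([l for _, l in roc_accum])
        roc_points, _pooled_auc = roc_auc(pooled_scores, pooled_labels)

        all_z, _, _ = fold_normalize(X_counts, None)
        if len(grid) > 1:
            final_params = _inner_select(
                config.model, all_z, y, grid, config.inner_k, config.seed
            )
        else:
            final_params = grid[0]
        final = fit_model(config.model, all_z, y, final_params, seed=config.seed)
        signed, magnitude = final.importance()
        importance = (
            pd.DataFrame({"gene": genes, "importance": magnitude, "signed": signed})
            .sort_values("importance", ascending=False, kind="stable")
            .reset_index(drop=True)
        )
        reports[config.model] = ClassifierReport(
            model=config.model,
            metrics=averaged,
            fold_metrics=fold_metrics,
            roc_points=roc_points,
            importance=importance,
            selected_params=final_params,
            n_features_used=final.n_features_used,
        )
    return reports
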