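"""Wrapped channel/feature selection by cross-validated regularization paths.

The wrapped protocol fits the penalized classifier itself over a geometric
lambda path (from the critical lambda_max down), scores each (alpha, lambda)
pair by mean held-out accuracy under stratified k-fold cross-validation, and
refits the winner on the full training set.  Features are z-scored with
training-fold statistics only; the stored standardizer is re-applied at test
time, so held-out data never influences standardization, path construction
or the CV choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .model import (GroupStructure, PenaltySpec, class_probabilities,
                    indicator_from_labels)
from .solver import SGLFit, SolverSettings, fit, kkt_lambda_max

__all__ = ["PathSpec", "Standardizer", "FitResult", "build_lambda_path",
           "fit_path", "cross_validate", "select", "evaluate"]


@dataclass(frozen=True)
class PathSpec:
    """Grid and fold layout for the cross-validated selection."""

    alpha_grid: tuple = (0.0, 0.25, 0.5, 0.75, 1.0)
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    folds: int = 10
    stratified: bool = True
    fold_seed: int = 0
    selection_rule: str = "max"
    scoring: str = "accuracy"
    relaxed: bool = False

    def __post_init__(self):
        if self.selection_rule not in ("max", "1se"):
            raise ValueError(
                f"unknown selection_rule {self.selection_rule!r}")
        if self.scoring not in ("accuracy", "deviance"):
            raise ValueError(f"unknown scoring {self.scoring!r}")
        if len(self.alpha_grid) == 0:
            raise ValueError("alpha_grid must be nonempty")
        if any(not 0 <= a <= 1 for a in self.alpha_grid):
            raise ValueError("alpha values must lie in [0, 1]")
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")
        if not 0 < self.lambda_min_ratio < 1:
            raise ValueError("lambda_min_ratio must lie in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class Standardizer:
    """Per-column z-scoring with training statistics (zero-variance guard)."""

    mean: np.ndarray
    scale: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardizer":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.scale


@dataclass
class FitResult:
    """Outcome of the wrapped selection: model, selection and diagnostics."""

    beta: np.ndarray
    intercept: np.ndarray | None
    classes: np.ndarray
    group_index: np.ndarray
    standardizer: Standardizer
    chosen_alpha: float
    chosen_lambda: float
    cv_table: pd.DataFrame
    selected_channels: list
    selected_features: list
    fit_intercept: bool = True
    test_error: float | None = None
    diagnostics: dict = field(default_factory=dict)


def build_lambda_path(X: np.ndarray, Y: np.ndarray, groups: GroupStructure,
                      alpha: float, spec: PathSpec,
                      weights: np.ndarray | None = None,
                      fit_intercept: bool = True) -> np.ndarray:
    """Descending geometric lambda grid from lambda_max down.

    The head of the path is the smallest lambda with an all-zero penalized
    solution, so warm-started fits start from the trivially-known solution.
    """
    lam_max = kkt_lambda_max(X, Y, groups, alpha, weights, fit_intercept)
    if spec.n_lambda == 1:
        return np.asarray([lam_max])
    return lam_max * spec.lambda_min_ratio ** (
        np.arange(spec.n_lambda) / (spec.n_lambda - 1))


def fit_path(X: np.ndarray, Y: np.ndarray, groups: GroupStructure,
             alpha: float, lams: np.ndarray,
             settings: SolverSettings | None = None,
             fit_intercept: bool = True) -> list[SGLFit]:
    """Warm-started fits along a descending lambda path."""
    settings = settings or SolverSettings()
    fits: list[SGLFit] = []
    beta0 = None
    b0 = None
    for lam in lams:
        res = fit(X, Y, groups, PenaltySpec(lam=lam, alpha=alpha),
                  settings, beta0=beta0, intercept0=b0,
                  fit_intercept=fit_intercept)
        fits.append(res)
        beta0 = res.beta
        b0 = res.intercept
    return fits


def _relaxed_scores(Ztr, ytr, Zte, classes, fits):
    """Debiased fold scoring: refit each support unpenalized before scoring.

    Removes the shrinkage bias of the penalized coefficients so CV scores
    reflect the support rather than the amount of regularization (the
    relaxed-lasso idea).  Refits (plain maximum-likelihood logistic
    regression) are cached per distinct support along the path.  Returns
    held-out probability matrices in the package's class order, one per path
    entry.
    """
    import warnings

    from sklearn.exceptions import ConvergenceWarning
    from sklearn.linear_model import LogisticRegression

    cache: dict = {}
    n_tr = Ztr.shape[0]
    out = []
    for res in fits:
        support = np.flatnonzero(np.any(res.beta != 0.0, axis=1))
        key = support.tobytes()
        if key not in cache:
            if support.size == 0 or support.size > n_tr // 2:
                # empty support (intercept only) or too many parameters for
                # a stable unpenalized refit: score the penalized fit itself
                cache[key] = None
            else:
                clf = LogisticRegression(C=np.inf, solver="lbfgs",
                                         max_iter=200, tol=1e-6)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    clf.fit(Ztr[:, support], ytr)
                cache[key] = (clf, support)
        entry = cache[key]
        if entry is None:
            out.append(class_probabilities(Zte, res.beta, res.intercept))
        else:
            clf, supp = entry
            P = np.zeros((Zte.shape[0], classes.size))
            raw = clf.predict_proba(Zte[:, supp])
            for k, c in enumerate(clf.classes_):
                P[:, int(np.flatnonzero(classes == c)[0])] = raw[:, k]
            out.append(P)
    return out


def _check_fold_feasible(y: np.ndarray, folds: int) -> None:
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"a class has only {counts.min()} samples, fewer than the "
            f"{folds} folds requested; every training fold must contain all "
            "classes — use fewer folds")


def cross_validate(X: np.ndarray, y: np.ndarray, group_index: np.ndarray,
                   path_spec: PathSpec | None = None,
                   settings: SolverSettings | None = None,
                   fit_intercept: bool = True) -> FitResult:
    """10-fold (by default) CV over the (alpha, lambda) grid, then refit.

    The lambda grid for each alpha is built once from the full training set
    (standardized), so fold scores are averaged over a common grid.  Under
    the default ``selection_rule="max"`` the chosen pair maximizes mean
    held-out accuracy with ties broken toward larger lambda (sparser), then
    larger alpha; ``"1se"`` instead takes the sparsest pair whose mean
    accuracy is within one standard error of the best — the usual choice when
    the goal is support identification rather than raw accuracy.
    """
    path_spec = path_spec or PathSpec()
    settings = settings or SolverSettings()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    groups = GroupStructure(group_index)
    Y_all, classes = indicator_from_labels(y)
    _check_fold_feasible(y, path_spec.folds)

    full_scaler = Standardizer.fit(X)
    Z_full = full_scaler.transform(X)
    k = classes.size - 1
    lam_grids = {}
    for alpha in path_spec.alpha_grid:
        w = groups.weights(settings.group_weight_mode, k)
        lam_grids[alpha] = build_lambda_path(Z_full, Y_all, groups, alpha,
                                             path_spec, w, fit_intercept)

    if path_spec.stratified:
        splitter = StratifiedKFold(n_splits=path_spec.folds, shuffle=True,
                                   random_state=path_spec.fold_seed)
    else:
        splitter = KFold(n_splits=path_spec.folds, shuffle=True,
                         random_state=path_spec.fold_seed)
    shape = (len(path_spec.alpha_grid), path_spec.n_lambda, path_spec.folds)
    acc = np.zeros(shape)
    dev = np.zeros(shape)
    class_pos = {c: i for i, c in enumerate(classes)}
    for f, (tr, te) in enumerate(splitter.split(X, y)):
        scaler = Standardizer.fit(X[tr])
        Ztr = scaler.transform(X[tr])
        Zte = scaler.transform(X[te])
        Ytr, _ = indicator_from_labels(y[tr], classes)
        te_pos = np.array([class_pos[c] for c in y[te]])
        for a_i, alpha in enumerate(path_spec.alpha_grid):
            fits = fit_path(Ztr, Ytr, groups, alpha, lam_grids[alpha],
                            settings, fit_intercept)
            if path_spec.relaxed:
                probs = _relaxed_scores(Ztr, y[tr], Zte, classes, fits)
            else:
                probs = [class_probabilities(Zte, r.beta, r.intercept)
                         for r in fits]
            for l_i, P in enumerate(probs):
                pred = classes[np.argmax(P, axis=1)]
                acc[a_i, l_i, f] = float(np.mean(pred == y[te]))
                p_true = np.clip(P[np.arange(te_pos.size), te_pos],
                                 1e-300, None)
                dev[a_i, l_i, f] = float(-2.0 * np.mean(np.log(p_true)))
    mean_acc = acc.mean(axis=2)
    mean_dev = dev.mean(axis=2)

    rows = []
    for a_i, alpha in enumerate(path_spec.alpha_grid):
        for l_i in range(path_spec.n_lambda):
            rows.append({"alpha": alpha, "lambda_index": l_i,
                         "lam": lam_grids[alpha][l_i],
                         "mean_cv_accuracy": mean_acc[a_i, l_i],
                         "mean_cv_deviance": mean_dev[a_i, l_i]})
    cv_table = pd.DataFrame(rows)

    # score to maximize: held-out accuracy, or negated held-out deviance
    score_folds = acc if path_spec.scoring == "accuracy" else -dev
    score = score_folds.mean(axis=2)
    # best score; ties -> larger lambda (sparser), then larger alpha
    best = max(
        ((score[a_i, l_i], lam_grids[alpha][l_i], alpha, a_i, l_i)
         for a_i, alpha in enumerate(path_spec.alpha_grid)
         for l_i in range(path_spec.n_lambda)),
        key=lambda t: (t[0], t[1], t[2]))
    if path_spec.selection_rule == "1se":
        # sparsest model whose score is within one standard error of the best
        _, _, _, a_m, l_m = best
        se = float(score_folds[a_m, l_m].std(ddof=1)) \
            / np.sqrt(path_spec.folds)
        floor = score[a_m, l_m] - se
        best = max(
            ((score[a_i, l_i], lam_grids[alpha][l_i], alpha, a_i, l_i)
             for a_i, alpha in enumerate(path_spec.alpha_grid)
             for l_i in range(path_spec.n_lambda)
             if score[a_i, l_i] >= floor),
            key=lambda t: (t[1], t[2]))
    _, chosen_lam, chosen_alpha, a_best, l_best = best

    # refit on the full training set, warm-started down the chosen path
    lams = lam_grids[chosen_alpha][:l_best + 1]
    final = fit_path(Z_full, Y_all, groups, chosen_alpha, lams, settings,
                     fit_intercept)[-1]
    sel_channels, sel_features = select(final.beta, groups)
    return FitResult(
        beta=final.beta, intercept=final.intercept, classes=classes,
        group_index=np.asarray(group_index), standardizer=full_scaler,
        chosen_alpha=float(chosen_alpha), chosen_lambda=float(chosen_lam),
        cv_table=cv_table, selected_channels=sel_channels,
        selected_features=sel_features, fit_intercept=fit_intercept,
        diagnostics={"converged": final.converged, "kkt": final.kkt,
                     "n_outer": final.n_outer,
                     "best_mean_cv_accuracy": float(mean_acc[a_best, l_best]),
                     "fold_seed": path_spec.fold_seed})


def select(beta: np.ndarray, groups: GroupStructure
           ) -> tuple[list[int], list[int]]:
    """Nonzero pattern as selection: features with any nonzero coefficient
    across the free classes, and channels whose block contains any such
    feature."""
    beta = np.atleast_2d(np.asarray(beta, dtype=float).T).T
    nz_feature = np.any(beta != 0.0, axis=1)
    features = np.flatnonzero(nz_feature)
    channels = [int(groups.ids[j]) for j, sl in enumerate(groups.slices)
                if nz_feature[sl].any()]
    return channels, features.tolist()


def evaluate(result: FitResult, X_test: np.ndarray,
             y_test: np.ndarray) -> float:
    """Misclassification fraction on held-out data.

    Applies the stored training standardization, predicts the class of
    maximum probability (ties break toward the lower class index), and
    returns the error rate.
    """
    Z = result.standardizer.transform(X_test)
    P = class_probabilities(Z, result.beta, result.intercept)
    pred = result.classes[np.argmax(P, axis=1)]
    y_test = np.asarray(y_test)
    return float(np.mean(pred != y_test))
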