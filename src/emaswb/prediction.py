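"""Language-based prediction of drinking outcomes.

Ridge regression over document or person embeddings with 10-fold
cross-validation.  Within-person analyses group folds by person so that no
participant's days straddle a fold's train/test boundary.  All
transformations that look at the data -- feature standardization,
univariate feature selection, PCA, and the ridge penalty choice -- are fit
on training rows only; accuracy is the Pearson correlation between pooled
out-of-fold predictions and the observed outcome.

An "as-written" mode is also provided that mimics a protocol sometimes
described in applied work: pick the best fold model and evaluate it on a
single held-out fold.  It is reported for comparison only; the pooled
out-of-fold estimate is the default because the single-fold variant is
higher-variance and selection-biased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stats import SteigerResult, compare_dependent_accuracies

__all__ = [
    "make_cv_plan",
    "CvPlan",
    "ridge_cv",
    "PredictionResult",
    "reduce_dims",
    "compare_accuracies",
]

DEFAULT_ALPHAS = tuple(10.0 ** np.arange(-3, 6))


@dataclass(frozen=True)
class CvPlan:
    fold: np.ndarray          # fold id per unit
    groups: np.ndarray        # grouping label per unit
    k: int
    seed: int

    def __post_init__(self) -> None:
        if set(np.unique(self.fold)) - set(range(self.k)):
            raise ValueError("fold ids out of range")


def make_cv_plan(n_units: int, k: int = 10, groups=None, seed: int = 0) -> CvPlan:
    """Near-equal-size fold assignment, optionally grouped.

    With ``groups``, whole groups are assigned to folds (balanced by unit
    count, largest groups first), so no group appears in two folds.
    """
    if groups is None:
        groups = np.arange(n_units)
    groups = np.asarray(groups)
    if groups.shape[0] != n_units:
        raise ValueError("groups misaligned with units")
    uniq, counts = np.unique(groups, return_counts=True)
    if uniq.size < k:
        raise ValueError(f"need at least {k} groups; got {uniq.size}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq.size)
    uniq, counts = uniq[order], counts[order]
    big_first = np.argsort(-counts, kind="stable")
    load = np.zeros(k)
    assign: dict = {}
    for gi in big_first:
        f = int(np.argmin(load))
        assign[uniq[gi]] = f
        load[f] += counts[gi]
    fold = np.array([assign[g] for g in groups])
    return CvPlan(fold=fold, groups=groups, k=k, seed=seed)


@dataclass
class PredictionResult:
    y_pred: np.ndarray
    y_true: np.ndarray
    fold: np.ndarray
    r: float
    alphas: dict = field(default_factory=dict)
    mode: str = "pooled"
    n: int = 0


def _standardize_train(Xtr: np.ndarray, Xte: np.ndarray):
    mu = Xtr.mean(axis=0)
    sd = Xtr.std(axis=0)
    sd[sd == 0] = 1.0
    return (Xtr - mu) / sd, (Xte - mu) / sd


def _pick_alpha(Xtr, ytr, gtr, alphas, seed, inner_k=5) -> float:
    """Inner grouped CV on the training rows; mean-squared-error criterion."""
    from sklearn.linear_model import Ridge

    uniq = np.unique(gtr)
    kk = min(inner_k, uniq.size)
    if kk < 2:
        return float(alphas[len(alphas) // 2])
    inner = make_cv_plan(len(ytr), k=kk, groups=gtr, seed=seed)
    errs = np.zeros(len(alphas))
    for f in range(kk):
        te = inner.fold == f
        Xa, Xb = _standardize_train(Xtr[~te], Xtr[te])
        mu_y = ytr[~te].mean()
        for ai, a in enumerate(alphas):
            m = Ridge(alpha=a).fit(Xa, ytr[~te] - mu_y)
            errs[ai] += ((m.predict(Xb) + mu_y - ytr[te]) ** 2).sum()
    return float(alphas[int(np.argmin(errs))])


def ridge_cv(X, y, plan: CvPlan, alphas=DEFAULT_ALPHAS, mode: str = "pooled",
             reduction: tuple[int, int] | None = None) -> PredictionResult:
    """Cross-validated ridge accuracy.

    ``mode='pooled'`` assembles out-of-fold predictions over all folds and
    reports their Pearson correlation with the observed outcome.
    ``mode='as_written'`` selects the fold model with the best inner
    criterion and reports its accuracy on its own held-out fold alone.
    ``reduction=(n_select, n_components)`` applies training-only univariate
    feature selection followed by PCA inside every fold.
    """
    from sklearn.linear_model import Ridge

    X = np.asarray(X, float)
    y = np.asarray(y, float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y are misaligned")
    if np.std(y) == 0:
        raise ValueError("constant outcome: accuracy r is undefined")
    y_pred = np.full(y.shape, np.nan)
    chosen: dict = {}
    fold_scores = []
    for f in range(plan.k):
        te = plan.fold == f
        Xtr, Xte = X[~te], X[te]
        ytr = y[~te]
        if reduction is not None:
            Xtr, Xte = reduce_dims(Xtr, ytr, Xte, *reduction)
        alpha = _pick_alpha(Xtr, ytr, plan.groups[~te], alphas, seed=plan.seed + f)
        Xa, Xb = _standardize_train(Xtr, Xte)
        mu_y = ytr.mean()
        model = Ridge(alpha=alpha).fit(Xa, ytr - mu_y)
        y_pred[te] = model.predict(Xb) + mu_y
        chosen[f] = alpha
        if te.sum() >= 3 and np.std(y[te]) > 0 and np.std(y_pred[te]) > 0:
            fold_scores.append((f, float(np.corrcoef(y_pred[te], y[te])[0, 1])))
        else:
            fold_scores.append((f, np.nan))

    if mode == "pooled":
        r = float(np.corrcoef(y_pred, y)[0, 1])
        return PredictionResult(y_pred=y_pred, y_true=y, fold=plan.fold, r=r,
                                alphas=chosen, mode=mode, n=int(y.size))
    if mode == "as_written":
        valid = [(f, s) for f, s in fold_scores if np.isfinite(s)]
        best_f, best_r = max(valid, key=lambda t: t[1])
        te = plan.fold == best_f
        return PredictionResult(y_pred=y_pred[te], y_true=y[te],
                                fold=plan.fold[te], r=float(best_r),
                                alphas={best_f: chosen[best_f]}, mode=mode,
                                n=int(te.sum()))
    raise ValueError(f"unknown mode {mode!r}")


def reduce_dims(X_train, y_train, X_test, n_select: int, n_components: int):
    """Training-only univariate selection + PCA; applied to test rows.

    Features are ranked by |corr(feature, y)| on training rows;
    zero-variance features are dropped with a warning.  PCA is fit on the
    selected training columns and applied to the test columns.  No test
    labels are consulted anywhere.
    """
    import warnings

    from sklearn.decomposition import PCA

    Xtr = np.asarray(X_train, float)
    Xte = np.asarray(X_test, float)
    ytr = np.asarray(y_train, float)
    if n_select > Xtr.shape[1]:
        raise ValueError("n_select exceeds the number of features")
    if n_components > n_select:
        raise ValueError("n_components exceeds n_select")
    sd = Xtr.std(axis=0)
    ok = sd > 0
    if not ok.all():
        warnings.warn(f"dropping {int((~ok).sum())} zero-variance features")
    idx_ok = np.flatnonzero(ok)
    Xc = Xtr[:, idx_ok] - Xtr[:, idx_ok].mean(axis=0)
    yc = ytr - ytr.mean()
    denom = np.sqrt((Xc ** 2).sum(axis=0) * (yc ** 2).sum())
    corr = np.zeros(idx_ok.size) if denom.max() == 0 else (Xc.T @ yc) / denom
    n_sel = min(n_select, idx_ok.size)
    top = idx_ok[np.argsort(-np.abs(corr), kind="stable")[:n_sel]]
    n_comp = min(n_components, n_sel, Xtr.shape[0])
    pca = PCA(n_components=n_comp, random_state=0).fit(Xtr[:, top])
    return pca.transform(Xtr[:, top]), pca.transform(Xte[:, top])


def compare_accuracies(r_language: float, r_rating: float, r_convergence: float,
                       n_language: int, n_rating: int) -> SteigerResult:
    """Steiger comparison of two predictive accuracies of the same outcome.

    Accuracies are compared as magnitudes |r|; the effective n is the mean
    of the two analyses' sample sizes.
    """
    return compare_dependent_accuracies(r_language, r_rating, r_convergence,
                                        n_language, n_rating)
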