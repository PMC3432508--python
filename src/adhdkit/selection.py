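"""Hybrid feature selection: BSS/WSS filter ranking followed by SVM-RFE.

The filter stage ranks each feature by the ratio of its between-class sum of
squares to its within-class sum of squares and keeps the top-scoring subset.
The wrapper stage (recursive feature elimination driven by an RBF-kernel SVM)
then refines that subset by repeatedly discarding the features whose removal
perturbs the SVM margin least.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

__all__ = [
    "SelectionConfig",
    "RfeStep",
    "SelectionResult",
    "bss_wss_scores",
    "filter_top",
    "svm_rfe",
    "hybrid_select",
]


@dataclass
class SelectionConfig:
    """Parameters of the hybrid filter + wrapper selection.

    filter_keep: how many features survive the BSS/WSS filter (count, or a
        fraction in (0, 1)); None keeps everything.
    rfe: whether to run SVM-RFE after filtering.
    elim_fraction: fraction of surviving features removed per RFE iteration.
    min_features / accuracy_threshold: RFE stopping rules; RFE stops as soon
        as the inner-CV accuracy reaches the threshold (if set) or the
        surviving set is no larger than min_features.
    C, sigma: RBF-SVM parameters for the RFE fits (sigma=None uses
        sqrt(p/2), i.e. gamma = 1/p for p input features).
    """

    filter_keep: int | float | None = 2000
    rfe: bool = True
    elim_fraction: float = 0.1
    min_features: int = 50
    accuracy_threshold: float | None = None
    inner_folds: int = 5
    C: float = 1.0
    sigma: float | None = None
    standardize: bool = True


@dataclass
class RfeStep:
    iteration: int
    surviving: np.ndarray
    cv_accuracy: float
    degenerate: bool = False


@dataclass
class SelectionResult:
    filter_scores: np.ndarray
    filtered: np.ndarray
    rfe_history: list[RfeStep] = field(default_factory=list)
    final: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.final is None:
            self.final = self.filtered

    def to_dict(self) -> dict:
        return {
            "filter_scores": [None if not np.isfinite(s) else float(s) for s in self.filter_scores],
            "filtered": [int(i) for i in self.filtered],
            "rfe_history": [
                {
                    "iteration": step.iteration,
                    "surviving": [int(i) for i in step.surviving],
                    "cv_accuracy": float(step.cv_accuracy),
                    "degenerate": bool(step.degenerate),
                }
                for step in self.rfe_history
            ],
            "final": [int(i) for i in self.final],
        }


def _check_two_classes(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly two classes, got {classes.tolist()}")
    return classes


def bss_wss_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Between- to within-class sum-of-squares ratio, per feature.

    With class means fbar_c and grand mean fbar,

        r_i = sum_c n_c (fbar_ic - fbar_i)^2 / sum_c sum_{j in c} (f_ij - fbar_ic)^2.

    Features that separate the classes perfectly (WSS = 0, BSS > 0) score
    +inf; features constant everywhere score 0.
    """
    X = np.asarray(X, dtype=float)
    classes = _check_two_classes(y)
    grand = X.mean(axis=0)
    bss = np.zeros(X.shape[1])
    wss = np.zeros(X.shape[1])
    for c in classes:
        Xc = X[np.asarray(y) == c]
        mc = Xc.mean(axis=0)
        bss += Xc.shape[0] * (mc - grand) ** 2
        wss += ((Xc - mc) ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = bss / wss
    r[(wss == 0) & (bss > 0)] = np.inf
    r[(wss == 0) & (bss == 0)] = 0.0
    return r


def filter_top(scores: np.ndarray, keep: int | float) -> np.ndarray:
    """Indices (ascending) of the ``keep`` largest scores; ties favor the
    smaller index.  ``keep`` in (0, 1) is treated as a fraction."""
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    if isinstance(keep, float) and 0 < keep < 1:
        keep = max(1, int(round(keep * n)))
    keep = int(keep)
    if keep < 1:
        raise ValueError("keep must be at least 1")
    if keep > n:
        warnings.warn(
            f"keep={keep} exceeds {n} features; keeping all", UserWarning, stacklevel=2
        )
        keep = n
    order = np.argsort(-scores, kind="stable")  # stable: ties keep smaller index first
    return np.sort(order[:keep])


def _rfe_margin_scores(X: np.ndarray, svc: SVC, sigma: float) -> np.ndarray:
    """Margin-change ranking for RBF SVM-RFE.

    For feature i, score_i = (1/2)(a' K a - a' K^(-i) a) with a the signed
    dual coefficients and K^(-i) the RBF kernel recomputed with feature i
    removed; for the RBF kernel K^(-i) = K * exp(d_i^2 / (2 sigma^2)) where
    d_i is the pairwise difference in feature i.  Small scores mean removing
    the feature barely changes the margin.
    """
    sv = svc.support_
    a = svc.dual_coef_[0]
    Xs = X[sv]
    gamma = 1.0 / (2.0 * sigma**2)
    K = _sk_rbf(Xs, Xs, gamma=gamma)
    base = a @ K @ a
    scores = np.empty(X.shape[1])
    for i in range(X.shape[1]):
        d2 = (Xs[:, i][:, None] - Xs[:, i][None, :]) ** 2
        K_noi = K * np.exp(gamma * d2)
        scores[i] = 0.5 * (base - a @ K_noi @ a)
    return scores


def svm_rfe(
    X: np.ndarray,
    y: np.ndarray,
    C: float = 1.0,
    sigma: float | None = None,
    elim_fraction: float = 0.1,
    min_features: int = 50,
    accuracy_threshold: float | None = None,
    inner_folds: int = 5,
    seed: int = 0,
    standardize: bool = True,
) -> SelectionResult:
    """Recursive feature elimination with an RBF-kernel SVM.

    Each iteration fits the SVM on the surviving features, estimates subset
    quality by stratified inner-CV accuracy, and eliminates the
    ceil(elim_fraction * surviving) lowest-ranked features (at least one,
    never dropping below ``min_features``).  Rank ties are broken by
    eliminating the smaller feature index first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    _check_two_classes(y)
    if not 0 < elim_fraction < 1:
        raise ValueError("elim_fraction must be in (0, 1)")
    p = X.shape[1]
    if standardize:
        mu, sd = X.mean(axis=0), X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if sigma is None:
        sigma = math.sqrt(p / 2.0)  # gamma = 1/p
    gamma = 1.0 / (2.0 * sigma**2)
    class_counts = np.unique(y, return_counts=True)[1]
    folds = max(2, min(inner_folds, int(class_counts.min())))

    surviving = np.arange(p)
    history: list[RfeStep] = []
    iteration = 0
    while True:
        Xs = X[:, surviving]
        svc = SVC(C=C, kernel="rbf", gamma=gamma).fit(Xs, y)
        degenerate = np.unique(svc.predict(Xs)).size < 2
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        acc = float(
            cross_val_score(SVC(C=C, kernel="rbf", gamma=gamma), Xs, y, cv=cv).mean()
        )
        if accuracy_threshold is not None and acc >= accuracy_threshold:
            break
        if surviving.size <= min_features:
            break
        scores = _rfe_margin_scores(Xs, svc, sigma)
        n_elim = max(1, math.ceil(elim_fraction * surviving.size))
        n_elim = min(n_elim, surviving.size - min_features)
        # ascending score, then ascending index, to break ties
        order = np.lexsort((np.arange(surviving.size), scores))
        drop = np.zeros(surviving.size, dtype=bool)
        drop[order[:n_elim]] = True
        history.append(
            RfeStep(
                iteration=iteration,
                surviving=surviving.copy(),
                cv_accuracy=acc,
                degenerate=degenerate,
            )
        )
        surviving = surviving[~drop]
        iteration += 1
    return SelectionResult(
        filter_scores=np.full(p, np.nan),
        filtered=np.arange(p),
        rfe_history=history,
        final=surviving,
    )


def hybrid_select(
    X: np.ndarray, y: np.ndarray, config: SelectionConfig | None = None, seed: int = 0
) -> SelectionResult:
    """BSS/WSS filter followed by SVM-RFE; indices refer to the input columns."""
    if config is None:
        config = SelectionConfig()
    X = np.asarray(X, dtype=float)
    scores = bss_wss_scores(X, y)
    if config.filter_keep is None:
        filtered = np.arange(X.shape[1])
    else:
        filtered = filter_top(scores, config.filter_keep)
    if not config.rfe or filtered.size <= config.min_features:
        return SelectionResult(filter_scores=scores, filtered=filtered, final=filtered)
    rfe = svm_rfe(
        X[:, filtered],
        y,
        C=config.C,
        sigma=config.sigma,
        elim_fraction=config.elim_fraction,
        min_features=config.min_features,
        accuracy_threshold=config.accuracy_threshold,
        inner_folds=config.inner_folds,
        seed=seed,
        standardize=config.standardize,
    )
    history = [
        RfeStep(s.iteration, filtered[s.surviving], s.cv_accuracy, s.degenerate)
        for s in rfe.rfe_history
    ]
    return SelectionResult(
        filter_scores=scores,
        filtered=filtered,
        rfe_history=history,
        final=filtered[rfe.final],
    )
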