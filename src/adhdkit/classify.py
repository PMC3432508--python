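"""RBF-SVM classification: inner-CV grid search, nested outer CV,
hierarchical two-stage diagnosis, and multi-kernel fusion of modalities.

The nested cross-validation keeps one tenth of each class out per outer
fold; feature selection, standardization, and hyper-parameter tuning run on
the training portion only, so the pooled held-out predictions give an
unbiased estimate of generalization.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics.pairwise import rbf_kernel as _sk_rbf
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .selection import SelectionConfig, SelectionResult, hybrid_select

__all__ = [
    "SvmParams",
    "TrainedModel",
    "CvPlan",
    "PipelineConfig",
    "FoldResult",
    "NestedCvResult",
    "MklModel",
    "rbf_kernel",
    "rbf_gram",
    "default_grid",
    "grid_search",
    "train_binary",
    "make_cv_plan",
    "nested_cv",
    "fit_hierarchical",
    "hierarchical_predict",
    "mkl_train",
    "undersample",
]


def rbf_kernel(x1: np.ndarray, x2: np.ndarray, sigma: float) -> float:
    """Gaussian similarity exp(-||x1 - x2||^2 / (2 sigma^2)) in (0, 1]."""
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    x1 = np.asarray(x1, dtype=float).ravel()
    x2 = np.asarray(x2, dtype=float).ravel()
    if x1.shape != x2.shape:
        raise ValueError("vectors must have equal dimensionality")
    return float(np.exp(-np.sum((x1 - x2) ** 2) / (2.0 * sigma**2)))


def rbf_gram(X1: np.ndarray, X2: np.ndarray, sigma: float) -> np.ndarray:
    """Pairwise RBF kernel matrix between the rows of X1 and X2."""
    if sigma <= 0:
        raise ValueError("kernel width sigma must be positive")
    return _sk_rbf(np.asarray(X1, float), np.asarray(X2, float), gamma=1.0 / (2.0 * sigma**2))


@dataclass
class SvmParams:
    C: float = 1.0
    sigma: float = 1.0
    class_weight: str | dict | None = None

    def __post_init__(self) -> None:
        if self.C <= 0 or self.sigma <= 0:
            raise ValueError("C and sigma must be positive")

    @property
    def gamma(self) -> float:
        return 1.0 / (2.0 * self.sigma**2)


@dataclass
class TrainedModel:
    """A fitted RBF-SVM plus the standardization applied at training time."""

    svc: SVC
    params: SvmParams
    feature_ids: list[str] | None = None
    mean: np.ndarray | None = None
    std: np.ndarray | None = None

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if self.mean is not None:
            X = (X - self.mean) / self.std
        return X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc.decision_function(self._prepare(X))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc.predict(self._prepare(X))

    @property
    def support_(self) -> np.ndarray:
        return self.svc.support_

    @property
    def dual_coef_(self) -> np.ndarray:
        return self.svc.dual_coef_

    @property
    def intercept_(self) -> float:
        return float(self.svc.intercept_[0])


def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """The standard log2 lattice: C in 2^{-5..15}, gamma in 2^{-15..3}
    (step 2), with sigma = sqrt(1 / (2 gamma))."""
    C_values = 2.0 ** np.arange(-5, 16, 2)
    gammas = 2.0 ** np.arange(-15, 4, 2)
    sigma_values = np.sqrt(1.0 / (2.0 * gammas))
    return C_values, sigma_values


def train_binary(
    X: np.ndarray,
    y: np.ndarray,
    params: SvmParams,
    feature_ids: list[str] | None = None,
    standardize: bool = False,
) -> TrainedModel:
    """Fit a soft-margin RBF-kernel SVM; decision score is
    sum_j lambda_j y_j K(x_j, x) + b."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("training labels must contain exactly two classes")
    mean = std = None
    if standardize:
        mean, std = X.mean(axis=0), X.std(axis=0)
        std = np.where(std == 0, 1.0, std)
        X = (X - mean) / std
    svc = SVC(C=params.C, kernel="rbf", gamma=params.gamma, class_weight=params.class_weight)
    svc.fit(X, y)
    return TrainedModel(svc=svc, params=params, feature_ids=feature_ids, mean=mean, std=std)


def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    C_values: np.ndarray | None = None,
    sigma_values: np.ndarray | None = None,
    inner_folds: int = 5,
    seed: int = 0,
) -> tuple[SvmParams, np.ndarray]:
    """Exhaustive (C, sigma) search scored by stratified inner-CV accuracy.

    Returns the best parameters and the full accuracy table (C x sigma).
    Ties favor the smaller C, then the larger sigma.
    """
    if C_values is None or sigma_values is None:
        dC, ds = default_grid()
        C_values = dC if C_values is None else np.asarray(C_values, float)
        sigma_values = ds if sigma_values is None else np.asarray(sigma_values, float)
    C_values = np.asarray(C_values, dtype=float)
    sigma_values = np.asarray(sigma_values, dtype=float)
    if C_values.size == 0 or sigma_values.size == 0:
        raise ValueError("grid must be nonempty")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    counts = np.unique(y, return_counts=True)[1]
    folds = max(2, min(inner_folds, int(counts.min())))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(cv.split(X, y))

    table = np.zeros((C_values.size, sigma_values.size))
    best = (-np.inf, None)
    # iterate C ascending and sigma descending so the first strict maximum
    # realizes the tie-break (smaller C, then larger sigma)
    sigma_order = np.argsort(-sigma_values, kind="stable")
    for ci, C in enumerate(C_values):
        for si in sigma_order:
            sigma = sigma_values[si]
            gamma = 1.0 / (2.0 * sigma**2)
            accs = []
            for tr, te in splits:
                svc = SVC(C=C, kernel="rbf", gamma=gamma).fit(X[tr], y[tr])
                accs.append(float(np.mean(svc.predict(X[te]) == y[te])))
            acc = float(np.mean(accs))
            table[ci, si] = acc
            if acc > best[0]:
                best = (acc, SvmParams(C=float(C), sigma=float(sigma)))
    return best[1], table


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------


@dataclass
class CvPlan:
    """Outer-fold assignment: fold_ids[i] in {0..n_folds-1} per subject."""

    fold_ids: np.ndarray
    n_folds: int
    inner_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        self.fold_ids = np.asarray(self.fold_ids, dtype=int)
        present = np.unique(self.fold_ids)
        if not np.array_equal(present, np.arange(self.n_folds)):
            raise ValueError("fold ids must cover 0..n_folds-1 and partition subjects")


def make_cv_plan(
    y: np.ndarray,
    site: np.ndarray | None = None,
    n_folds: int = 10,
    inner_folds: int = 5,
    seed: int = 0,
) -> CvPlan:
    """Stratified outer folds: by class always, additionally by site when a
    site vector is given and every (class, site) cell is large enough."""
    y = np.asarray(y)
    strata = y.astype(str)
    if site is not None:
        combo = np.char.add(np.char.add(strata, "|"), np.asarray(site).astype(str))
        _, counts = np.unique(combo, return_counts=True)
        if counts.min() >= n_folds:
            strata = combo
        else:
            warnings.warn(
                "some (class, site) cells are smaller than the fold count; "
                "stratifying by class only",
                UserWarning,
                stacklevel=2,
            )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_ids = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(cv.split(np.zeros(len(y)), strata)):
        fold_ids[test_idx] = f
    return CvPlan(fold_ids=fold_ids, n_folds=n_folds, inner_folds=inner_folds, seed=seed)


@dataclass
class PipelineConfig:
    """Per-fold training pipeline: selection -> grid search -> SVM fit."""

    selection: SelectionConfig | None = None
    C_values: np.ndarray | None = None
    sigma_values: np.ndarray | None = None
    inner_folds: int = 5
    standardize: bool = True


@dataclass
class FoldResult:
    fold: int
    test_idx: np.ndarray
    selected: np.ndarray
    params: SvmParams
    y_pred: np.ndarray
    scores: np.ndarray


@dataclass
class NestedCvResult:
    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    fold_ids: np.ndarray
    folds: list[FoldResult] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.y_pred == self.y_true))


def nested_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: PipelineConfig | None = None,
    plan: CvPlan | None = None,
) -> NestedCvResult:
    """Leakage-free nested cross-validation of the full pipeline.

    For each outer fold, standardization statistics, the selected feature
    subset, and the tuned (C, sigma) come from the training portion only;
    the held-out tenth is then scored once.  Predictions are pooled over
    folds, so every subject is predicted exactly once.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if config is None:
        config = PipelineConfig()
    if plan is None:
        plan = make_cv_plan(y)
    if plan.fold_ids.shape[0] != len(y):
        raise ValueError("CV plan length does not match number of subjects")

    y_pred = np.empty_like(y)
    scores = np.empty(len(y), dtype=float)
    folds: list[FoldResult] = []
    for f in range(plan.n_folds):
        test = plan.fold_ids == f
        train = ~test
        y_tr = y[train]
        if np.unique(y_tr).size < 2:
            raise ValueError(f"outer fold {f}: training portion has a single class")
        X_tr, X_te = X[train], X[test]
        if config.standardize:
            mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            X_tr, X_te = (X_tr - mu) / sd, (X_te - mu) / sd
        fold_seed = plan.seed * 1009 + f  # distinct, reproducible per fold
        if config.selection is not None:
            sel_cfg = config.selection
            sel = hybrid_select(X_tr, y_tr, sel_cfg, seed=fold_seed)
            selected = sel.final
        else:
            selected = np.arange(X.shape[1])
        params, _ = grid_search(
            X_tr[:, selected],
            y_tr,
            C_values=config.C_values,
            sigma_values=config.sigma_values,
            inner_folds=config.inner_folds,
            seed=fold_seed,
        )
        model = train_binary(X_tr[:, selected], y_tr, params)
        pred = model.predict(X_te[:, selected])
        sc = model.decision_function(X_te[:, selected])
        y_pred[test] = pred
        scores[test] = sc
        folds.append(
            FoldResult(
                fold=f,
                test_idx=np.flatnonzero(test),
                selected=selected,
                params=params,
                y_pred=pred,
                scores=sc,
            )
        )
    return NestedCvResult(
        y_true=y.copy(), y_pred=y_pred, scores=scores, fold_ids=plan.fold_ids.copy(), folds=folds
    )


# ---------------------------------------------------------------------------
# hierarchical two-stage diagnosis
# ---------------------------------------------------------------------------


def fit_hierarchical(
    X: np.ndarray,
    labels: np.ndarray,
    params1: SvmParams,
    params2: SvmParams | None = None,
    standardize: bool = True,
) -> tuple[TrainedModel, TrainedModel | None]:
    """Fit the two-stage classifier: ADHD-vs-TDC, then ADHD-C vs ADHD-I.

    Stage 2 is trained on the ADHD-labeled training subjects only; it is
    None when the training set contains a single ADHD subtype.
    """
    labels = np.asarray(labels).astype(str)
    y1 = np.where(labels == "TDC", "TDC", "ADHD")
    stage1 = train_binary(X, y1, params1, standardize=standardize)
    adhd = labels != "TDC"
    subtypes = np.unique(labels[adhd])
    stage2 = None
    if subtypes.size == 2:
        stage2 = train_binary(
            X[adhd], labels[adhd], params2 or params1, standardize=standardize
        )
    return stage1, stage2


def hierarchical_predict(
    stage1: TrainedModel, stage2: TrainedModel | None, X: np.ndarray
) -> np.ndarray:
    """Stage-1 TDC predictions pass through; ADHD predictions are refined
    into a subtype by stage 2."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    pred1 = stage1.predict(X)
    out = pred1.astype(object)
    is_adhd = pred1 != "TDC"
    if is_adhd.any():
        if stage2 is None:
            raise ValueError("stage-1 predicted ADHD but no stage-2 model is available")
        out[is_adhd] = stage2.predict(X[is_adhd])
    return out.astype(str)


# ---------------------------------------------------------------------------
# multi-kernel learning
# ---------------------------------------------------------------------------


def _project_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection onto the probability simplex."""
    u = np.sort(v)[::-1]
    css = np.cumsum(u) - 1.0
    rho = np.flatnonzero(u - css / np.arange(1, v.size + 1) > 0)[-1]
    theta = css[rho] / (rho + 1.0)
    return np.maximum(v - theta, 0.0)


@dataclass
class MklModel:
    """SVM over a convex combination sum_k beta_k K_k of sub-kernels.

    Decision for new samples: provide the cross-kernels K_k(test, train)
    in the same modality order used at training time.
    """

    beta: np.ndarray
    svc: SVC
    y: np.ndarray
    objective: float

    def combined(self, test_kernels: list[np.ndarray]) -> np.ndarray:
        if len(test_kernels) != self.beta.size:
            raise ValueError("kernel count does not match trained sub-kernel weights")
        return sum(b * K for b, K in zip(self.beta, test_kernels))

    def decision_function(self, test_kernels: list[np.ndarray]) -> np.ndarray:
        return self.svc.decision_function(self.combined(test_kernels))

    def predict(self, test_kernels: list[np.ndarray]) -> np.ndarray:
        return self.svc.predict(self.combined(test_kernels))


def _fit_combined(kernels, beta, y, C):
    Kc = sum(b * K for b, K in zip(beta, kernels))
    svc = SVC(C=C, kernel="precomputed").fit(Kc, y)
    a = np.zeros(len(y))
    a[svc.support_] = svc.dual_coef_[0]
    # soft-margin dual objective at the optimum (to be minimized over beta)
    obj = float(np.sum(np.abs(a)) - 0.5 * a @ Kc @ a)
    return svc, a, obj


def mkl_train(
    kernels: list[np.ndarray],
    y: np.ndarray,
    C: float = 1.0,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> MklModel:
    """Learn sub-kernel weights beta (beta_k >= 0, sum beta_k = 1) and SVM
    dual coefficients jointly.

    Alternates an exact SVM solve on the combined kernel with a projected
    gradient step on beta minimizing the optimal-margin objective over the
    L1 simplex (SimpleMKL-style); with a single kernel this reduces to the
    plain kernel SVM.
    """
    y = np.asarray(y)
    kernels = [np.asarray(K, dtype=float) for K in kernels]
    if not kernels:
        raise ValueError("need at least one kernel")
    n = len(y)
    for K in kernels:
        if K.shape != (n, n):
            raise ValueError(
                f"kernel shape {K.shape} inconsistent with {n} training subjects"
            )
    m = len(kernels)
    beta = np.full(m, 1.0 / m)
    svc, a, obj = _fit_combined(kernels, beta, y, C)
    if m > 1:
        for _ in range(max_iter):
            grad = np.array([-0.5 * a @ K @ a for K in kernels])
            gnorm = np.linalg.norm(grad - grad.mean())
            if gnorm < 1e-12:
                break
            improved = False
            for eta in (1.0, 0.3, 0.1, 0.03, 0.01):
                beta_try = _project_simplex(beta - eta * grad / gnorm)
                if np.abs(beta_try - beta).max() < tol:
                    continue
                svc_t, a_t, obj_t = _fit_combined(kernels, beta_try, y, C)
                if obj_t < obj - 1e-12:
                    beta, svc, a, obj = beta_try, svc_t, a_t, obj_t
                    improved = True
                    break
            if not improved:
                break
    return MklModel(beta=beta, svc=svc, y=y.copy(), objective=obj)


# ---------------------------------------------------------------------------
# class-imbalance handling
# ---------------------------------------------------------------------------


def undersample(y: np.ndarray, ratio_target: float = 1.0, seed: int = 0) -> np.ndarray:
    """Random majority-class undersampling to a majority:minority ratio of at
    most ``ratio_target``; returns the sorted retained subject indices."""
    if ratio_target < 1:
        raise ValueError("ratio_target must be at least 1 (majority:minority)")
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("undersampling expects binary labels")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_maj / n_min <= ratio_target:
        warnings.warn(
            f"class ratio {n_maj / n_min:.2f} already at or below the target "
            f"{ratio_target}; keeping all subjects",
            UserWarning,
            stacklevel=2,
        )
        return np.arange(len(y))
    n_keep = math.floor(ratio_target * n_min)
    rng = np.random.default_rng(seed)
    maj_idx = np.flatnonzero(y == majority)
    kept_maj = rng.choice(maj_idx, size=n_keep, replace=False)
    return np.sort(np.concatenate([np.flatnonzero(y == minority), kept_maj]))
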