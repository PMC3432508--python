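"""Top-level orchestration: phenotype filtering, per-modality nested CV,
optional multi-kernel fusion, and manifest/report writing.

A run is a pure function of its configuration (which embeds every seed):
rerunning with the same config reproduces identical manifests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .classify import (
    CvPlan,
    PipelineConfig,
    make_cv_plan,
    mkl_train,
    nested_cv,
    rbf_gram,
    undersample,
)
from .metrics import evaluate_predictions
from .selection import SelectionConfig

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything a full run needs; serializable to/from JSON."""

    phenotype: str = ""
    modalities: dict[str, str] = field(default_factory=dict)  # name -> table path
    positive_class: str = "ADHD"
    filter_keep: int | None = 200
    rfe: bool = True
    elim_fraction: float = 0.1
    min_features: int = 20
    accuracy_threshold: float | None = None
    C_values: list[float] | None = None
    sigma_values: list[float] | None = None
    outer_folds: int = 10
    inner_folds: int = 5
    seed: int = 0
    mkl: bool = False
    mkl_C: float = 1.0
    undersample_ratio: float | None = None
    stratify_by_site: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _selection_config(cfg: RunConfig) -> SelectionConfig:
    return SelectionConfig(
        filter_keep=cfg.filter_keep,
        rfe=cfg.rfe,
        elim_fraction=cfg.elim_fraction,
        min_features=cfg.min_features,
        accuracy_threshold=cfg.accuracy_threshold,
        inner_folds=cfg.inner_folds,
        standardize=False,  # nested_cv standardizes per outer fold
    )


def _pipeline_config(cfg: RunConfig) -> PipelineConfig:
    return PipelineConfig(
        selection=_selection_config(cfg),
        C_values=None if cfg.C_values is None else np.asarray(cfg.C_values, float),
        sigma_values=None if cfg.sigma_values is None else np.asarray(cfg.sigma_values, float),
        inner_folds=cfg.inner_folds,
        standardize=True,
    )


def _mkl_crossval(
    matrices: dict[str, np.ndarray],
    results: dict,
    y: np.ndarray,
    plan: CvPlan,
    C: float,
):
    """Multi-kernel fusion over the same outer folds, reusing each
    modality's per-fold selected features and tuned kernel width."""
    n = len(y)
    y_pred = np.empty_like(y)
    scores = np.empty(n)
    betas = []
    for f in range(plan.n_folds):
        test = plan.fold_ids == f
        train = ~test
        train_kernels, test_kernels = [], []
        for name in sorted(matrices):
            X = matrices[name]
            fold = results[name].folds[f]
            mu, sd = X[train].mean(axis=0), X[train].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            Xs = (X - mu) / sd
            sel = fold.selected
            sigma = fold.params.sigma
            train_kernels.append(rbf_gram(Xs[train][:, sel], Xs[train][:, sel], sigma))
            test_kernels.append(rbf_gram(Xs[test][:, sel], Xs[train][:, sel], sigma))
        model = mkl_train(train_kernels, y[train], C=C)
        y_pred[test] = model.predict(test_kernels)
        scores[test] = model.decision_function(test_kernels)
        betas.append(model.beta)
    return y_pred, scores, np.array(betas)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the full framework and write manifests + per-modality reports.

    Returns a summary dict with one entry per modality (plus ``"mkl"`` when
    fusion is enabled), each holding the pooled evaluation report.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    phenotype = kio.read_phenotype(config.phenotype)
    retained, exclusion_log = kio.filter_subjects(phenotype)
    labels3 = retained["dx"].to_numpy()
    y = np.where(labels3 == "TDC", "TDC", "ADHD")

    kept = np.arange(len(y))
    if config.undersample_ratio is not None:
        kept = undersample(y, config.undersample_ratio, seed=config.seed)
        retained = retained.iloc[kept]
        y = y[kept]

    matrices: dict[str, np.ndarray] = {}
    for name, path in sorted(config.modalities.items()):
        fm = kio.read_feature_table(path, modality=name)
        order = {s: i for i, s in enumerate(fm.subject_ids)}
        missing = [s for s in retained["id"] if s not in order]
        if missing:
            raise ValueError(f"modality {name!r}: missing subjects {missing[:5]}")
        rows = [order[s] for s in retained["id"]]
        matrices[name] = fm.X[rows]

    site = retained["site"].to_numpy() if config.stratify_by_site else None
    plan = make_cv_plan(
        y, site=site, n_folds=config.outer_folds,
        inner_folds=config.inner_folds, seed=config.seed,
    )
    pcfg = _pipeline_config(config)

    summary: dict = {}
    results: dict = {}
    for name, X in sorted(matrices.items()):
        res = nested_cv(X, y, config=pcfg, plan=plan)
        results[name] = res
        report = evaluate_predictions(
            y, res.y_pred, res.scores, positive_class=config.positive_class,
            fold_ids=plan.fold_ids,
        )
        summary[name] = report.to_dict()
        preds = pd.DataFrame(
            {
                "subject": retained["id"].to_numpy(),
                "score": res.scores,
                "label": res.y_pred,
                "fold": plan.fold_ids,
            }
        )
        preds.to_csv(out / f"predictions_{name}.tsv", sep="\t", index=False)
        with open(out / f"report_{name}.json", "w") as fh:
            json.dump(summary[name], fh, indent=2, sort_keys=True)

    if config.mkl and len(matrices) > 1:
        y_pred, scores, betas = _mkl_crossval(matrices, results, y, plan, config.mkl_C)
        report = evaluate_predictions(
            y, y_pred, scores, positive_class=config.positive_class, fold_ids=plan.fold_ids
        )
        summary["mkl"] = report.to_dict()
        summary["mkl"]["beta_per_fold"] = {
            name: [round(float(b), 6) for b in betas[:, i]]
            for i, name in enumerate(sorted(matrices))
        }
        with open(out / "report_mkl.json", "w") as fh:
            json.dump(summary["mkl"], fh, indent=2, sort_keys=True)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "exclusion_log": exclusion_log,
        "n_subjects": int(len(y)),
        "class_counts": {c: int(n) for c, n in zip(*np.unique(y, return_counts=True))},
        "fold_ids": plan.fold_ids.tolist(),
        "undersampled_kept": kept.tolist() if config.undersample_ratio is not None else None,
        "modalities": sorted(matrices),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return summary
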