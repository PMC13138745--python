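"""Metrics, cross-validation, holdout evaluation and gene-set comparisons."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import StratifiedKFold

from .labels import LabelSet
from .tables import FeatureTable
from .tritrain import (
    BaseLearnerSpec,
    TrainConfig,
    TriTrainer,
    fit_tritraining_arrays,
)

__all__ = [
    "METRICS",
    "EvalReport",
    "binary_metrics",
    "threshold_free_metrics",
    "cross_validate",
    "evaluate_on_holdout",
    "gene_set_score_comparison",
]

METRICS = ("accuracy", "auroc", "auprc", "f1", "precision", "recall")


@dataclass
class EvalReport:
    """Per-fold metrics with mean and standard deviation aggregates."""

    per_fold: pd.DataFrame  # one row per fold, columns = METRICS
    fold_assignments: dict[str, int]
    seed: int

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.mean()

    @property
    def std(self) -> pd.Series:
        return self.per_fold.std(ddof=1)

    def summary(self) -> str:
        lines = [f"{k}: {self.mean[k]:.3f} +/- {self.std[k]:.3f}" for k in METRICS]
        return "\n".join(lines)


def binary_metrics(predicted_labels, true_labels) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from hard 0/1 labels.

    With no positive predictions, precision is reported as 0 with a warning
    rather than raising.
    """
    pred = np.asarray(predicted_labels)
    true = np.asarray(true_labels)
    if pred.shape != true.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {true.shape}")
    if pred.sum() == 0:
        warnings.warn("no positive predictions; precision reported as 0",
                      UserWarning, stacklevel=2)
    return {
        "accuracy": float(accuracy_score(true, pred)),
        "precision": float(precision_score(true, pred, zero_division=0)),
        "recall": float(recall_score(true, pred, zero_division=0)),
        "f1": float(f1_score(true, pred, zero_division=0)),
    }


def threshold_free_metrics(scores, true_labels) -> dict[str, float]:
    """AUROC (Mann–Whitney with ties counted 1/2) and AUPRC."""
    scores = np.asarray(scores, dtype=float)
    true = np.asarray(true_labels)
    if np.unique(true).size < 2:
        raise ValueError("both classes required for threshold-free metrics")
    return {
        "auroc": float(roc_auc_score(true, scores)),
        "auprc": float(average_precision_score(true, scores)),
    }


def _all_metrics(scores: np.ndarray, true: np.ndarray) -> dict[str, float]:
    out = threshold_free_metrics(scores, true)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        out.update(binary_metrics((scores > 0.5).astype(int), true))
    return out


def cross_validate(
    table: FeatureTable,
    labels: LabelSet,
    model_spec: TrainConfig | BaseLearnerSpec | None = None,
    k: int = 10,
    seed: int = 0,
) -> EvalReport:
    """Stratified k-fold cross-validation of a model specification.

    ``model_spec`` may be a :class:`TrainConfig` (tri-training, with the
    table's unlabeled genes available inside each fold) or a single
    :class:`BaseLearnerSpec` (supervised baseline).  Class balancing runs
    inside each training fold only, never before splitting.
    """
    model_spec = model_spec or TrainConfig()
    genes = [g for g in labels.labeled if g in set(table.gene_ids)]
    y = np.array([1 if labels.label[g] == "positive" else 0 for g in genes])
    for cls, n in zip(*np.unique(y, return_counts=True)):
        if n < k:
            raise ValueError(
                f"class {cls} has {n} members < k={k} folds; use a smaller k"
            )
    X = table.df.loc[genes].to_numpy(dtype=float)
    unl = [g for g in labels.unlabeled if g in set(table.gene_ids)]
    X_u = table.df.loc[unl].to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    rows, assignments = [], {}
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        for i in te:
            assignments[genes[i]] = fold
        trainer = _fit_spec(model_spec, X[tr], y[tr], X_u, seed=seed * 1000 + fold)
        scores = trainer.predict_proba(X[te])
        rows.append(_all_metrics(scores, y[te]))
    per_fold = pd.DataFrame(rows, columns=list(METRICS))
    return EvalReport(per_fold=per_fold, fold_assignments=assignments, seed=seed)


def _fit_spec(spec, X_l, y_l, X_u, seed: int) -> TriTrainer:
    """Fit either a tri-training config or a single supervised learner.

    Supervised baselines reuse the same SMOTE-balanced fit path with the one
    spec replicated, zero rounds, and no unlabeled pool, so comparisons
    differ only in the semi-supervised step.
    """
    if isinstance(spec, BaseLearnerSpec):
        cfg = TrainConfig(learner_specs=(spec, spec, spec), seed=seed, max_rounds=1)
        return fit_tritraining_arrays(X_l, y_l, np.empty((0, X_l.shape[1])), cfg)
    cfg = TrainConfig(
        learner_specs=spec.learner_specs, seed=seed, smote_m=spec.smote_m,
        smote_k=spec.smote_k, max_rounds=spec.max_rounds, combine=spec.combine,
    )
    return fit_tritraining_arrays(X_l, y_l, X_u, cfg)


def evaluate_on_holdout(
    results_or_trainer, table: FeatureTable, test_labels: LabelSet
) -> dict[str, float]:
    """Score the held-out test genes and return all six metrics.

    Raises when any test gene was in the training partition (leakage guard).
    Classification threshold is 0.5 on the ensemble score.
    """
    from .model import CaserResults
    from .tritrain import score_genes

    if isinstance(results_or_trainer, CaserResults):
        trainer = results_or_trainer.trainer
        fit_labels = results_or_trainer.model.labels
        if fit_labels.partition:
            train_genes = {g for g in fit_labels.labeled
                           if fit_labels.partition.get(g) == "train"}
        else:
            train_genes = set(fit_labels.labeled)
    else:
        trainer = results_or_trainer
        train_genes = {
            g for g in test_labels.labeled
            if test_labels.partition.get(g) == "train"
        }
    test_genes = [
        g for g in test_labels.labeled
        if test_labels.partition.get(g, "test") == "test"
    ]
    overlap = set(test_genes) & train_genes
    if overlap:
        raise ValueError(f"test genes overlap training genes: {sorted(overlap)[:5]}")
    test_genes = [g for g in test_genes if g in set(table.gene_ids)]
    y = np.array([1 if test_labels.label[g] == "positive" else 0 for g in test_genes])
    sub = FeatureTable(
        table.df.loc[test_genes], dict(table.categories), dict(table.value_kind)
    )
    scores = score_genes(trainer, sub).to_numpy()
    return _all_metrics(scores, y)


def gene_set_score_comparison(
    scores: pd.Series, set_a, set_b, alternative: str = "greater"
) -> tuple[float, float]:
    """One-tailed Wilcoxon rank-sum comparison of two gene sets' scores.

    Exact p for small samples (n_a + n_b <= 20, no ties), normal
    approximation with tie correction otherwise.  Returns (U statistic, p).
    """
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    a = scores.reindex([g for g in set_a if g in scores.index]).dropna()
    b = scores.reindex([g for g in set_b if g in scores.index]).dropna()
    if a.empty or b.empty:
        raise ValueError("a gene set has no scored members")
    pooled = np.concatenate([a.to_numpy(), b.to_numpy()])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (len(a) + len(b) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
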