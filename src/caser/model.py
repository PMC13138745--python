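"""Model/Results interface for cER prioritization.

:class:`CaserModel` bundles a feature table, a label set, and a training
configuration; :meth:`CaserModel.fit` returns a :class:`CaserResults`
holding the fitted tri-training ensemble, per-gene scores, and methods for
permutation significance and a text summary — the same shape statsmodels
uses for its estimators.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import tables as _tables
from .labels import LabelSet
from .significance import bh_adjust, build_null_distribution, empirical_pvalues
from .tables import FeatureTable
from .tritrain import TrainConfig, TriTrainer, fit_tritraining, score_genes

__all__ = ["CaserModel", "CaserResults"]


class CaserModel:
    """Semi-supervised prioritizer of cancer-associated epigenetic regulators.

    Parameters
    ----------
    table : FeatureTable
        Gene x feature matrix.  Imputation (median for numeric, zero for
        counts) and population z-scoring are applied on construction unless
        ``preprocess=False``.
    labels : LabelSet
        Positive/negative/unlabeled assignment with optional train/test
        partition; the unlabeled genes form the semi-supervised pool.
    config : TrainConfig, optional
        Kernel ensemble, SMOTE neighborhood and seed settings.
    """

    def __init__(self, table: FeatureTable, labels: LabelSet,
                 config: TrainConfig | None = None, preprocess: bool = True):
        if preprocess:
            table = _tables.zscore_normalize(_tables.impute_missing(table))
        self.table = table
        self.labels = labels
        self.config = config or TrainConfig()

    @classmethod
    def from_dataframes(cls, features: pd.DataFrame, labels: LabelSet,
                        config: TrainConfig | None = None, **kwargs):
        """Build from a plain genes x features DataFrame."""
        return cls(FeatureTable(features.astype(float)), labels, config, **kwargs)

    def fit(self) -> "CaserResults":
        trainer = fit_tritraining(self.table, self.labels, self.config)
        scores = score_genes(trainer, self.table)
        return CaserResults(self, trainer, scores)


class CaserResults:
    """Fitted ensemble, per-gene cER scores, and significance machinery."""

    def __init__(self, model: CaserModel, trainer: TriTrainer, scores: pd.Series):
        self.model = model
        self.trainer = trainer
        self.scores = scores
        self.null_ = None
        self.table_ = None  # populated by prioritize()

    def score(self, table: FeatureTable | None = None) -> pd.Series:
        """cER score for each gene of ``table`` (default: the training table)."""
        return score_genes(self.trainer, table or self.model.table)

    def prioritize(self, iterations: int = 100, threshold: float = 0.1,
                   seed: int | None = None) -> pd.DataFrame:
        """Attach permutation p-values, BH q-values and significance calls.

        Returns (and caches as ``table_``) a frame with columns gene, score,
        p, q, significant, novel — novel meaning significant but absent from
        the train/test labeled sets.
        """
        seed = self.model.config.seed if seed is None else seed
        self.null_ = build_null_distribution(
            self.trainer, self.model.table, iterations=iterations, seed=seed
        )
        p = empirical_pvalues(self.scores.to_numpy(), self.null_)
        q, significant = bh_adjust(p, threshold=threshold)
        labeled = set(self.model.labels.labeled)
        genes = list(self.scores.index)
        out = pd.DataFrame({
            "gene": genes,
            "score": self.scores.to_numpy(),
            "p": p,
            "q": q,
            "significant": significant,
            "novel": [s and g not in labeled for g, s in zip(genes, significant)],
        })
        out = out.sort_values(
            ["score", "gene"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)
        self.table_ = out
        return out

    def summary(self, top: int = 10) -> str:
        """Plain-text summary of the fit and, if computed, the top calls."""
        cfg = self.model.config
        kernels = ", ".join(s.kernel for s in cfg.learner_specs)
        n_sig = int(self.table_["significant"].sum()) if self.table_ is not None else None
        n_nov = int(self.table_["novel"].sum()) if self.table_ is not None else None
        lines = [
            "CASER tri-training prioritization",
            "=" * 48,
            f"genes scored:        {len(self.scores)}",
            f"labeled pool:        {self.trainer.n_labeled}",
            f"unlabeled pool:      {self.trainer.n_unlabeled}",
            f"base kernels:        {kernels}",
            f"accepted updates:    {sum(1 for h in self.trainer.history if h['accepted'])}",
            f"seed:                {cfg.seed}",
        ]
        if n_sig is not None:
            lines += [
                f"significant (q<.1):  {n_sig}",
                f"novel significant:   {n_nov}",
                "",
                "top-ranked genes:",
                self.table_.head(top).to_string(
                    index=False,
                    formatters={"score": "{:.4f}".format, "p": "{:.4f}".format,
                                "q": "{:.4f}".format},
                ),
            ]
        return "\n".join(lines)
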