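"""End-to-end pan-cancer, subtype, and dual-role prioritization runs.

A run is: impute and z-score the feature table, fit the tri-training
ensemble on the labeled training genes with the unlabeled pool, score every
gene, build the 100-iteration permutation null, convert to empirical
p-values and BH q-values, and flag significant (q < 0.1) and novel
(significant but outside the labeled sets) genes.  Subtype runs repeat the
identical procedure per functional subtype; dual-role genes are those
significant in at least two subtype runs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import pandas as pd

from .labels import LabelSet
from .model import CaserModel
from .tables import FeatureTable
from .tritrain import TrainConfig

__all__ = [
    "PrioritizationRun",
    "run_pan_cancer",
    "run_subtypes",
    "dual_role_genes",
]


@dataclass
class PrioritizationRun:
    """One complete prioritization: ranked results plus provenance."""

    results: pd.DataFrame  # gene, score, p, q, significant, novel
    labels: LabelSet
    config: TrainConfig
    iterations: int
    threshold: float
    seed: int
    provenance: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> list[str]:
        return list(self.results.loc[self.results["significant"], "gene"])

    @property
    def novel_genes(self) -> list[str]:
        return list(self.results.loc[self.results["novel"], "gene"])

    def write(self, path, provenance_path=None) -> None:
        """Ranked TSV; optional JSON provenance sidecar."""
        out = self.results.copy()
        out["score"] = out["score"].map("{:.10g}".format)
        out["p"] = out["p"].map("{:.10g}".format)
        out["q"] = out["q"].map("{:.10g}".format)
        out.to_csv(path, sep="\t", index=False)
        if provenance_path:
            with open(provenance_path, "w") as fh:
                json.dump(self.provenance, fh, indent=2, sort_keys=True)


def run_pan_cancer(
    table: FeatureTable,
    labels: LabelSet,
    config: TrainConfig | None = None,
    iterations: int = 100,
    threshold: float = 0.1,
) -> PrioritizationRun:
    """Fit, score, and test every gene in the table against the permutation
    null; the full pipeline behind the pan-cancer (and, with alternative
    feature tables, cancer-specific) prioritization."""
    config = config or TrainConfig()
    results = CaserModel(table, labels, config).fit()
    frame = results.prioritize(iterations=iterations, threshold=threshold,
                               seed=config.seed)
    import caser

    return PrioritizationRun(
        results=frame,
        labels=labels,
        config=config,
        iterations=iterations,
        threshold=threshold,
        seed=config.seed,
        provenance={
            "seed": config.seed,
            "iterations": iterations,
            "threshold": threshold,
            "n_genes": table.n_genes,
            "n_features": table.n_features,
            "version": caser.__version__,
        },
    )


def run_subtypes(
    table: FeatureTable,
    subtype_labelsets: dict[str, LabelSet],
    config: TrainConfig | None = None,
    iterations: int = 100,
    threshold: float = 0.1,
) -> dict[str, PrioritizationRun]:
    """One independent prioritization per subtype, identical settings."""
    runs: dict[str, PrioritizationRun] = {}
    for subtype, labels in subtype_labelsets.items():
        if not labels.positives or not labels.negatives:
            warnings.warn(f"subtype {subtype!r} lacks a class; skipped",
                          UserWarning, stacklevel=2)
            continue
        runs[subtype] = run_pan_cancer(
            table, labels, config, iterations=iterations, threshold=threshold
        )
    if not runs:
        raise ValueError("every subtype was skipped; nothing to run")
    return runs


def dual_role_genes(
    subtype_runs: dict[str, PrioritizationRun]
) -> pd.DataFrame:
    """Genes significant in >= 2 subtype runs.

    ``is_novel`` means the gene is not a labeled (positive or negative) gene
    in any of the subtype label sets it was called in.
    """
    if len(subtype_runs) < 2:
        raise ValueError("dual-role aggregation needs at least two subtype runs")
    hits: dict[str, list[str]] = {}
    for subtype, run in subtype_runs.items():
        for g in run.significant_genes:
            hits.setdefault(g, []).append(subtype)
    rows = []
    for gene, subtypes in sorted(hits.items()):
        if len(subtypes) < 2:
            continue
        novel = all(
            gene not in set(subtype_runs[s].labels.labeled) for s in subtypes
        )
        rows.append({
            "gene": gene,
            "subtypes": ";".join(sorted(subtypes)),
            "n_subtypes": len(subtypes),
            "is_novel": novel,
        })
    return pd.DataFrame(rows, columns=["gene", "subtypes", "n_subtypes", "is_novel"])
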