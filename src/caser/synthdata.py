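"""Synthetic feature tables, labels, and raw-omics fixtures.

The classification generator emulates the study conditions the pipeline was
designed for: a small labeled pool of positive and negative genes inside a
much larger unlabeled pool, class-conditional Gaussian features where an
informative subset is mean-shifted in the positive class, block correlation
through shared latent factors, and completely-at-random missingness.  With
one informative feature of effect size e, the population AUROC of that
feature is Phi(e / sqrt(2)), which pins the generator's difficulty scale to
a closed form.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FUNCTIONAL_CLASSES, LOF_CLASSES
from .labels import LabelSet
from .tables import CATEGORIES, FeatureTable

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "generate_classification_data",
    "generate_null_table",
    "generate_mutation_records",
    "generate_peaks",
    "generate_phase_counts",
    "generate_raw_fixtures",
]


@dataclass
class SimConfig:
    """Synthetic study conditions.

    Defaults mirror the regime the prioritizer targets: 20 features, half of
    them informative with a 1.5-sd mean shift in positives, 15 + 15 labeled
    genes against 400 unlabeled ones, in a 1,000-gene table.
    """

    n_genes: int = 1000
    n_features: int = 20
    informative_fraction: float = 0.5
    effect_size: float = 1.5
    n_labeled_pos: int = 15
    n_labeled_neg: int = 15
    n_unlabeled: int = 400
    missing_rate: float = 0.0
    correlation_block_size: int = 5
    positive_fraction: float = 0.3
    seed: int = 0

    def __post_init__(self):
        n_labeled = self.n_labeled_pos + self.n_labeled_neg
        if n_labeled + self.n_unlabeled > self.n_genes:
            raise ValueError("labeled + unlabeled pools exceed n_genes")
        if not 0 <= self.informative_fraction <= 1:
            raise ValueError("informative_fraction must be in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticDataset:
    """Generated table and labels plus the ground-truth class of every gene.

    ``holdout_genes`` are genes outside both the labeled and unlabeled
    pools; they never touch training and serve as an evaluation set with
    known truth.
    """

    table: FeatureTable
    labels: LabelSet
    truth: pd.Series  # 1 = true positive class, 0 = background
    unlabeled_pool: list[str]
    holdout_genes: list[str]

    def __iter__(self):  # allow  table, labels = generate_classification_data(cfg)
        return iter((self.table, self.labels))

    def training_view(self) -> tuple[FeatureTable, LabelSet]:
        """Table/labels restricted to the labeled + unlabeled pools."""
        keep = [g for g in self.table.gene_ids
                if g in set(self.labels.labeled) | set(self.unlabeled_pool)]
        sub = FeatureTable(self.table.df.loc[keep],
                           dict(self.table.categories), dict(self.table.value_kind))
        labels = LabelSet(
            keep, {g: self.labels.label[g] for g in keep},
            {g: p for g, p in self.labels.partition.items() if g in set(keep)},
        )
        return sub, labels

    def holdout_xy(self) -> tuple[FeatureTable, np.ndarray]:
        sub = FeatureTable(self.table.df.loc[self.holdout_genes],
                           dict(self.table.categories), dict(self.table.value_kind))
        return sub, self.truth.loc[self.holdout_genes].to_numpy()


#: latent-factor loading for block correlation; residual scaled to keep
#: unit marginal variance
_BLOCK_LOADING = 0.5


def generate_classification_data(cfg: SimConfig) -> SyntheticDataset:
    """Class-conditional Gaussian gene x feature table with labeled pools.

    Every gene gets a true class (Bernoulli ``positive_fraction``); positive
    genes are shifted by ``effect_size`` standard deviations on the
    informative features.  Labeled pools are drawn per class, the unlabeled
    pool from the remainder; leftover genes stay outside both pools and make
    a natural holdout.
    """
    rng = np.random.default_rng(cfg.seed)
    n, d = cfg.n_genes, cfg.n_features
    truth = (rng.random(n) < cfg.positive_fraction).astype(int)
    # need enough genes of each class for the labeled pools
    while truth.sum() < cfg.n_labeled_pos + 1 or (n - truth.sum()) < cfg.n_labeled_neg + 1:
        truth = (rng.random(n) < cfg.positive_fraction).astype(int)

    eps = rng.standard_normal((n, d))
    x = np.empty((n, d))
    bs = max(1, cfg.correlation_block_size)
    for start in range(0, d, bs):
        width = min(bs, d - start)
        z = rng.standard_normal(n)
        resid = np.sqrt(1.0 - _BLOCK_LOADING**2)
        x[:, start:start + width] = (
            _BLOCK_LOADING * z[:, None] + resid * eps[:, start:start + width]
        )
    n_inf = int(round(cfg.informative_fraction * d))
    x[truth == 1, :n_inf] += cfg.effect_size

    if cfg.missing_rate > 0:
        mask = rng.random((n, d)) < cfg.missing_rate
        x = np.where(mask, np.nan, x)

    genes = [f"G{i:05d}" for i in range(n)]
    feats = [f"f{j:03d}" for j in range(d)]
    categories = {f: CATEGORIES[j % len(CATEGORIES)] for j, f in enumerate(feats)}
    table = FeatureTable(pd.DataFrame(x, index=genes, columns=feats), categories)

    pos_idx = rng.permutation(np.flatnonzero(truth == 1))
    neg_idx = rng.permutation(np.flatnonzero(truth == 0))
    lab_pos = pos_idx[:cfg.n_labeled_pos]
    lab_neg = neg_idx[:cfg.n_labeled_neg]
    labeled = set(lab_pos) | set(lab_neg)
    rest = rng.permutation([i for i in range(n) if i not in labeled])
    unlabeled = set(rest[:cfg.n_unlabeled])

    label = {}
    partition = {}
    for i, g in enumerate(genes):
        if i in labeled:
            label[g] = "positive" if truth[i] == 1 else "negative"
            partition[g] = "train"
        else:
            label[g] = "unlabeled"
    labels = LabelSet(genes, label, partition)
    return SyntheticDataset(
        table=table,
        labels=labels,
        truth=pd.Series(truth, index=genes, name="truth"),
        unlabeled_pool=[genes[i] for i in sorted(unlabeled)],
        holdout_genes=[genes[i] for i in range(n)
                       if i not in labeled and i not in unlabeled],
    )


def generate_null_table(n_genes: int, n_features: int, seed: int = 0) -> FeatureTable:
    """i.i.d. standard-Gaussian features with no class signal."""
    if n_genes <= 0 or n_features <= 0:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    feats = [f"f{j:03d}" for j in range(n_features)]
    return FeatureTable(
        pd.DataFrame(rng.standard_normal((n_genes, n_features)),
                     index=genes, columns=feats)
    )


# -- raw-omics fixtures ----------------------------------------------------

def generate_mutation_records(
    n_records: int, lof_fraction: float = 0.3, n_genes: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Mutation records with an exact LoF share; rest spread over the other
    functional classes uniformly."""
    rng = np.random.default_rng(seed)
    n_lof = int(round(lof_fraction * n_records))
    other = [c for c in FUNCTIONAL_CLASSES if c not in LOF_CLASSES]
    classes = [str(rng.choice(LOF_CLASSES)) for _ in range(n_lof)]
    classes += [str(rng.choice(other)) for _ in range(n_records - n_lof)]
    rng.shuffle(classes)
    genes = [f"G{rng.integers(n_genes):03d}" for _ in range(n_records)]
    return pd.DataFrame({"gene": genes, "functional_class": classes})


def generate_peaks(
    gaps, chrom: str = "chr1", peak_len: int = 500, start: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """A chain of peaks separated by the requested inter-peak gaps.

    ``gaps`` straddling the 3,000 bp merge threshold exercise the boundary
    of the merge rule exactly.
    """
    rng = np.random.default_rng(seed)
    rows = []
    pos = start
    rows.append({"chrom": chrom, "start": pos, "end": pos + peak_len,
                 "height": float(rng.integers(1, 100))})
    for gap in gaps:
        pos = rows[-1]["end"] + gap
        rows.append({"chrom": chrom, "start": pos, "end": pos + peak_len,
                     "height": float(rng.integers(1, 100))})
    return pd.DataFrame(rows)


def generate_phase_counts(
    n_genes: int = 5, n_phases: int = 6, skew: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Wide phase-count frame; ``skew`` > 0 pushes reads toward late phases,
    < 0 toward early phases."""
    rng = np.random.default_rng(seed)
    phases = np.arange(n_phases)
    weights = np.exp(skew * (phases - (n_phases - 1) / 2))
    weights /= weights.sum()
    counts = rng.multinomial(1000, weights, size=n_genes).astype(float)
    df = pd.DataFrame(
        counts,
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"phase{p}" for p in phases],
    )
    df.index.name = "gene"
    return df


def generate_raw_fixtures(outdir, seed: int = 0, n_mutations: int = 100,
                          lof_fraction: float = 0.3,
                          gaps=(2999, 3000, 3001)) -> dict[str, Path]:
    """Write mutation TSV, peak BED, and phase-count TSV fixtures."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    muts = generate_mutation_records(n_mutations, lof_fraction, seed=seed)
    paths["mutations"] = outdir / "mutations.tsv"
    muts.to_csv(paths["mutations"], sep="\t", index=False)

    peaks = generate_peaks(gaps, seed=seed)
    paths["peaks"] = outdir / "peaks.bed"
    peaks.to_csv(paths["peaks"], sep="\t", index=False, header=False)

    early = generate_phase_counts(skew=-1.0, seed=seed)
    paths["phase_counts"] = outdir / "phase_counts.tsv"
    early.to_csv(paths["phase_counts"], sep="\t")
    return paths
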