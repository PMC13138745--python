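"""Monte-Carlo permutation null, empirical p-values, and BH q-values.

The null is built by independently permuting every feature column across
genes (destroying gene/feature association while preserving each feature's
marginal distribution) and re-scoring the permuted table with the already
fitted model.  All null scores across iterations and genes are pooled into
one empirical null; each gene's p-value is the fraction of null scores
equal to or exceeding its observed score.  Benjamini–Hochberg adjustment
then yields q-values, with genes called significant at q < 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables import FeatureTable

__all__ = [
    "NullDistribution",
    "permute_feature_columns",
    "build_null_distribution",
    "empirical_pvalues",
    "bh_adjust",
]


@dataclass
class NullDistribution:
    """Pooled cER scores from permuted feature tables."""

    iterations: int
    null_scores: np.ndarray
    seed: int

    def __post_init__(self):
        self.null_scores = np.asarray(self.null_scores, dtype=float)
        if self.iterations <= 0:
            raise ValueError("iterations must be positive")
        if self.null_scores.size == 0:
            raise ValueError("null distribution is empty")


def permute_feature_columns(table: FeatureTable, seed: int) -> FeatureTable:
    """Independently permute each feature column across genes.

    Per-column value multisets are preserved exactly; only the gene/feature
    association is destroyed.  The permutation is drawn in canonical
    (sorted-gene) order, so the result per gene does not depend on the row
    order of the input table.
    """
    rng = np.random.default_rng(seed)
    canon = np.argsort(table.df.index.to_numpy(), kind="mergesort")
    x = table.values[canon].copy()
    for j in range(x.shape[1]):
        x[:, j] = x[rng.permutation(x.shape[0]), j]
    back = np.empty_like(canon)
    back[canon] = np.arange(len(canon))
    df = pd.DataFrame(x[back], index=table.df.index, columns=table.df.columns)
    return table._with_df(df)


def build_null_distribution(
    model, table: FeatureTable, iterations: int = 100, seed: int = 0
) -> NullDistribution:
    """Score ``iterations`` permuted copies of ``table`` with ``model``.

    ``model`` is a fitted :class:`~caser.tritrain.TriTrainer`; the default
    100 iterations give a pooled null of 100 x n_genes scores.
    """
    from .tritrain import score_genes

    child_seeds = np.random.SeedSequence(seed).generate_state(iterations)
    pools = []
    for it in range(iterations):
        permuted = permute_feature_columns(table, int(child_seeds[it] % (2**31)))
        pools.append(score_genes(model, permuted).to_numpy())
    return NullDistribution(
        iterations=iterations, null_scores=np.concatenate(pools), seed=seed
    )


def empirical_pvalues(observed, null: NullDistribution,
                      add_one_correction: bool = False) -> np.ndarray:
    """p(g) = fraction of pooled null scores >= the observed score of g.

    Ties count toward the p-value ("equal to or exceeding"), and p = 0 is
    allowed; ``add_one_correction`` switches to (k+1)/(N+1) for users who
    prefer a strictly positive lower bound.
    """
    obs = np.asarray(observed, dtype=float)
    pool = np.sort(null.null_scores)
    n = pool.size
    # count of null >= x  ==  n - (number strictly below x)
    below = np.searchsorted(pool, obs, side="left")
    k = n - below
    if add_one_correction:
        return (k + 1) / (n + 1)
    return k / n


def bh_adjust(p, threshold: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg q-values and the q < threshold significance call.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending order statistics,
    mapped back to the input order; equal p always receive equal q.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    # stable sort + running minimum already give tied p identical q
    return q, q < threshold
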