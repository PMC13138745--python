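"""Borderline-SMOTE oversampling for the imbalanced labeled pool.

Synthetic minority samples are drawn only from "danger" minority points —
points whose m-neighborhood is at least half majority but not entirely
majority (entirely-majority points are treated as noise and never used as
synthesis anchors).  Each synthetic point is a convex combination of a
danger point and one of its k nearest minority neighbors, which keeps all
synthetic mass inside the minority manifold near the class boundary.
"""

from __future__ import annotations

import numpy as np
from sklearn.neighbors import NearestNeighbors

__all__ = ["borderline_smote"]


def borderline_smote(
    X,
    y,
    seed: int = 0,
    m_neighbors: int = 10,
    k_neighbors: int = 5,
    return_parents: bool = False,
):
    """Balance a binary dataset by borderline-SMOTE oversampling.

    Parameters
    ----------
    X : array-like of shape (n, d)
    y : array-like of binary labels (any two values; the rarer is minority)
    seed : int
        Seeds anchor/neighbor/gap draws.
    m_neighbors : int
        Neighborhood size used to flag danger points (majority count in
        [m/2, m)).
    k_neighbors : int
        Number of minority neighbors a synthetic point interpolates toward.
    return_parents : bool
        Also return an (n_synthetic, 2) array of row indices into the
        original minority matrix giving each synthetic point's two parents.

    Returns
    -------
    X_out, y_out  (and parent index pairs if requested).  Originals come
    first, synthetic rows are appended; an already balanced input is
    returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("borderline_smote requires exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    n_needed = int(n_maj - n_min)
    if n_needed == 0:
        if return_parents:
            return X.copy(), y.copy(), np.empty((0, 2), dtype=int)
        return X.copy(), y.copy()

    min_idx = np.flatnonzero(y == minority)
    X_min = X[min_idx]
    if n_min < k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} samples but k_neighbors={k_neighbors} "
            "requires k+1; reduce k_neighbors"
        )

    # danger detection on the full dataset
    m = min(m_neighbors, X.shape[0] - 1)
    nn_all = NearestNeighbors(n_neighbors=m + 1).fit(X)
    _, neigh = nn_all.kneighbors(X_min)
    maj_counts = (y[neigh[:, 1:]] != minority).sum(axis=1)
    danger_local = np.flatnonzero((maj_counts >= m / 2) & (maj_counts < m))
    if danger_local.size == 0:
        # classes so well separated that no minority point borders the
        # majority: fall back to plain SMOTE over non-noise minority points
        non_noise = np.flatnonzero(maj_counts < m)
        danger_local = non_noise if non_noise.size else np.arange(n_min)

    # minority-only neighbor graph for interpolation targets
    nn_min = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X_min)
    _, min_neigh = nn_min.kneighbors(X_min[danger_local])

    rng = np.random.default_rng(seed)
    anchors = rng.integers(0, danger_local.size, size=n_needed)
    picks = rng.integers(1, k_neighbors + 1, size=n_needed)  # skip self at 0
    gaps = rng.random(n_needed)

    a_local = danger_local[anchors]
    b_local = min_neigh[anchors, picks]
    X_syn = X_min[a_local] + gaps[:, None] * (X_min[b_local] - X_min[a_local])

    X_out = np.vstack([X, X_syn])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    if return_parents:
        return X_out, y_out, np.column_stack([a_local, b_local])
    return X_out, y_out
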