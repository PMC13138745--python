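"""Tri-training: a semi-supervised ensemble of three kernel SVMs.

Three base classifiers are initialized on bootstrap resamples of the
(borderline-SMOTE balanced) labeled pool.  Each round, a classifier may be
retrained on the labeled pool plus the unlabeled points its two peers agree
on, but only while the peers' estimated error keeps shrinking fast enough
that the extra pseudo-labels are expected to help (the Zhou–Li acceptance
conditions).  Pseudo-labels are re-derived from scratch every round, so a
point mislabeled early does not persist.  The ensemble's gene score is the
mean of the three calibrated positive-class probabilities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.calibration import CalibratedClassifierCV
from sklearn.svm import SVC

from .labels import LabelSet
from .tables import FeatureTable

__all__ = [
    "KERNELS",
    "BaseLearnerSpec",
    "TrainConfig",
    "TriTrainer",
    "fit_tritraining",
    "score_genes",
]

KERNELS = ("rbf", "sigmoid", "polynomial")
_SKLEARN_KERNEL = {"rbf": "rbf", "sigmoid": "sigmoid", "polynomial": "poly"}


@dataclass(frozen=True)
class BaseLearnerSpec:
    """Configuration of one SVM base learner."""

    kernel: str = "rbf"
    C: float = 1.0
    gamma: str | float = "scale"
    coef0: float = 0.0
    degree: int = 3
    calibrate: bool = True

    def __post_init__(self):
        if self.kernel not in KERNELS:
            raise ValueError(f"kernel must be one of {KERNELS}, got {self.kernel!r}")

    def build(self, seed: int) -> "_KernelLearner":
        svc = SVC(
            kernel=_SKLEARN_KERNEL[self.kernel],
            C=self.C,
            gamma=self.gamma,
            coef0=self.coef0,
            degree=self.degree,
            random_state=int(seed),
        )
        return _KernelLearner(svc, calibrate=self.calibrate)


class _KernelLearner:
    """SVC with Platt-style sigmoid probability calibration.

    Calibration uses out-of-fold decision values (5 stratified folds, fewer
    when a class is tiny); when calibration is off or infeasible the margin
    is squashed through a plain logistic.
    """

    def __init__(self, svc: SVC, calibrate: bool = True):
        self.svc = svc
        self.calibrate = calibrate
        self.est_ = None

    def fit(self, X, y) -> "_KernelLearner":
        counts = np.bincount(np.asarray(y, dtype=int))
        cv = min(5, int(counts[counts > 0].min()))
        if self.calibrate and cv >= 2:
            self.est_ = CalibratedClassifierCV(
                self.svc, method="sigmoid", ensemble=False, cv=cv
            ).fit(X, y)
        else:
            self.est_ = self.svc.fit(X, y)
        self.classes_ = self.est_.classes_
        return self

    def predict_proba_pos(self, X) -> np.ndarray:
        if hasattr(self.est_, "predict_proba"):
            pos = list(self.classes_).index(1)
            return self.est_.predict_proba(X)[:, pos]
        margin = self.est_.decision_function(X)
        if self.classes_[1] != 1:
            margin = -margin
        return 1.0 / (1.0 + np.exp(-margin))


#: one RBF plus two sigmoid kernels — the configuration that maximized
#: held-out performance among the kernel combinations screened
DEFAULT_LEARNERS = (
    BaseLearnerSpec(kernel="rbf"),
    BaseLearnerSpec(kernel="sigmoid"),
    BaseLearnerSpec(kernel="sigmoid"),
)


@dataclass
class TrainConfig:
    """Settings for one tri-training fit.

    ``smote_m`` / ``smote_k`` are the borderline-SMOTE neighborhood sizes;
    ``combine`` selects how the three probabilities become one score
    (``"mean_proba"`` or ``"vote"``).
    """

    learner_specs: tuple = DEFAULT_LEARNERS
    seed: int = 0
    smote_m: int = 10
    smote_k: int = 5
    max_rounds: int = 10
    combine: str = "mean_proba"

    def __post_init__(self):
        if len(self.learner_specs) != 3:
            raise ValueError("tri-training requires exactly 3 learner specs")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.combine not in ("mean_proba", "vote"):
            raise ValueError("combine must be 'mean_proba' or 'vote'")


def _learner_proba(learner: "_KernelLearner", X: np.ndarray) -> np.ndarray:
    return learner.predict_proba_pos(X)


def _predict(learner: "_KernelLearner", X: np.ndarray) -> np.ndarray:
    # probability exactly 0.5 resolves to the negative class
    return (_learner_proba(learner, X) > 0.5).astype(int)


@dataclass
class TriTrainer:
    """A fitted tri-training ensemble plus its per-round bookkeeping.

    ``history`` rows carry, per learner evaluation: the round index, the
    peer-agreement error ``e`` on the labeled pool, the pseudo-label count
    ``l``, the previous accepted ``(e_prev, l_prev)`` pair, and whether the
    update was accepted.
    """

    learners: list
    config: TrainConfig
    feature_names: list[str]
    history: list[dict] = field(default_factory=list)
    n_labeled: int = 0
    n_unlabeled: int = 0

    def predict_proba(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        probs = np.column_stack([_learner_proba(h, X) for h in self.learners])
        if self.config.combine == "vote":
            return (probs > 0.5).mean(axis=1)
        return probs.mean(axis=1)

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X) > 0.5).astype(int)


def _bootstrap(rng: np.random.Generator, n: int, y: np.ndarray) -> np.ndarray:
    """Bootstrap index vector guaranteed to keep both classes."""
    for _ in range(100):
        idx = rng.integers(0, n, size=n)
        if np.unique(y[idx]).size == 2:
            return idx
    raise RuntimeError("could not draw a two-class bootstrap sample")


def _measure_error(hj: SVC, hk: SVC, X: np.ndarray, y: np.ndarray) -> float:
    """Error of the (j, k) joint prediction on points where they agree."""
    pj, pk = _predict(hj, X), _predict(hk, X)
    agree = pj == pk
    if not agree.any():
        return 0.5
    return float((pj[agree] != y[agree]).mean())


def fit_tritraining_arrays(
    X_labeled, y_labeled, X_unlabeled, config: TrainConfig,
    feature_names: list[str] | None = None,
) -> TriTrainer:
    """Fit tri-training from raw arrays.

    ``y_labeled`` uses 1 for the positive class and 0 for the negative;
    ``X_unlabeled`` may be empty, in which case the fit degenerates to a
    bagged ensemble of the three base learners.
    """
    from .smote import borderline_smote

    X_l = np.asarray(X_labeled, dtype=float)
    y_l = np.asarray(y_labeled, dtype=int)
    X_u = np.asarray(X_unlabeled, dtype=float)
    if X_u.size == 0:
        X_u = X_u.reshape(0, X_l.shape[1])
    if not np.isfinite(X_l).all() or not np.isfinite(X_u).all():
        raise ValueError("non-finite feature values; impute/normalize first")
    if np.unique(y_l).size < 2:
        raise ValueError("labeled pool must contain both classes")

    root = np.random.SeedSequence(config.seed)
    s_smote, s_boot, s_fit, s_sub = root.spawn(4)
    rng_boot = np.random.default_rng(s_boot)
    rng_sub = np.random.default_rng(s_sub)
    fit_seeds = np.random.default_rng(s_fit).integers(
        0, 2**31 - 1, size=3 * (config.max_rounds + 1)
    )
    seed_iter = iter(fit_seeds.tolist())

    # balance the labeled pool once; pseudo-labels are never balanced
    smote_seed = int(np.random.default_rng(s_smote).integers(0, 2**31 - 1))
    k = min(config.smote_k, int(np.bincount(y_l).min()) - 1)
    if k >= 1:
        X_bal, y_bal = borderline_smote(
            X_l, y_l, seed=smote_seed, m_neighbors=config.smote_m, k_neighbors=k
        )
    else:
        X_bal, y_bal = X_l, y_l

    learners = []
    for spec in config.learner_specs:
        idx = _bootstrap(rng_boot, len(y_bal), y_bal)
        h = spec.build(next(seed_iter))
        h.fit(X_bal[idx], y_bal[idx])
        learners.append(h)

    e_prime = [0.5, 0.5, 0.5]
    l_prime = [0.0, 0.0, 0.0]
    history: list[dict] = []

    for rnd in range(config.max_rounds):
        updates: list[np.ndarray | None] = [None, None, None]
        errors = [0.5, 0.5, 0.5]
        pseudo: list[tuple[np.ndarray, np.ndarray] | None] = [None, None, None]
        if len(X_u):
            peer_pred = [_predict(h, X_u) for h in learners]
        for i in range(3):
            j, kk = (i + 1) % 3, (i + 2) % 3
            e_i = _measure_error(learners[j], learners[kk], X_l, y_l)
            errors[i] = e_i
            if e_i >= e_prime[i] or not len(X_u):
                continue
            agree = peer_pred[j] == peer_pred[kk]
            cand = np.flatnonzero(agree)
            if cand.size == 0:
                continue
            cand_y = peer_pred[j][cand]
            if l_prime[i] == 0:
                l_prime[i] = math.floor(e_i / (e_prime[i] - e_i) + 1)
            if l_prime[i] < cand.size:
                if e_i * cand.size < e_prime[i] * l_prime[i]:
                    pseudo[i] = (cand, cand_y)
                elif l_prime[i] > e_i / (e_prime[i] - e_i):
                    n_sub = math.ceil(e_prime[i] * l_prime[i] / e_i - 1)
                    keep = rng_sub.choice(cand.size, size=n_sub, replace=False)
                    pseudo[i] = (cand[keep], cand_y[keep])
        any_update = False
        for i in range(3):
            if pseudo[i] is None:
                continue
            cand, cand_y = pseudo[i]
            history.append({
                "round": rnd, "learner": i, "e": errors[i], "l": int(cand.size),
                "e_prev": e_prime[i], "l_prev": l_prime[i], "accepted": True,
            })
            spec = config.learner_specs[i]
            h = spec.build(next(seed_iter))
            h.fit(
                np.vstack([X_bal, X_u[cand]]),
                np.concatenate([y_bal, cand_y]),
            )
            learners[i] = h
            e_prime[i] = errors[i]
            l_prime[i] = float(cand.size)
            any_update = True
        if not any_update:
            break

    return TriTrainer(
        learners=learners,
        config=config,
        feature_names=list(feature_names or []),
        history=history,
        n_labeled=len(y_l),
        n_unlabeled=len(X_u),
    )


def fit_tritraining(
    table: FeatureTable, labels: LabelSet, config: TrainConfig | None = None
) -> TriTrainer:
    """Fit the ensemble from a feature table and a label set.

    The labeled pool is the train-partition positive/negative genes (or all
    labeled genes when no partition was assigned); the unlabeled pool is
    every gene labeled ``unlabeled`` that is present in the table.
    """
    config = config or TrainConfig()
    if table.has_missing():
        raise ValueError("feature table has missing values; impute first")
    in_table = set(table.gene_ids)
    if labels.partition:
        pool = [g for g in labels.labeled
                if labels.partition.get(g) == "train" and g in in_table]
    else:
        pool = [g for g in labels.labeled if g in in_table]
    unlabeled = [g for g in labels.unlabeled if g in in_table]
    if not pool:
        raise ValueError("no labeled training genes found in the table")
    y = np.array([1 if labels.label[g] == "positive" else 0 for g in pool])
    X_l = table.df.loc[pool].to_numpy(dtype=float)
    X_u = table.df.loc[unlabeled].to_numpy(dtype=float)
    return fit_tritraining_arrays(
        X_l, y, X_u, config, feature_names=table.feature_names
    )


def score_genes(model: TriTrainer, table: FeatureTable) -> pd.Series:
    """Per-gene cER score in [0, 1]: the ensemble positive-class probability.

    Table columns are reconciled with the training features by name; any
    missing or extra feature is an error.
    """
    if model.feature_names:
        missing = [f for f in model.feature_names if f not in table.df.columns]
        extra = [f for f in table.df.columns if f not in model.feature_names]
        if missing or extra:
            raise ValueError(
                f"feature mismatch; missing={missing[:5]} extra={extra[:5]}"
            )
        X = table.df[model.feature_names].to_numpy(dtype=float)
    else:
        X = table.values
    scores = model.predict_proba(X)
    return pd.Series(scores, index=table.df.index, name="cer_score")
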