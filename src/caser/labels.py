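"""Label construction for cancer-associated epigenetic regulator (cER) genes.

Positive genes are epigenetic regulator genes (ERGs) backed by at least two
of four cancer-gene databases and carrying a recognized epigenetic domain,
after removing low loss-of-function-burden genes; negatives are ERGs on a
curated neutral-gene list; every other ERG goes to the unlabeled pool that
the semi-supervised learner draws from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SUBTYPES",
    "CANCER_DBS",
    "GeneAnnotation",
    "LabelSet",
    "build_cer_labels",
    "split_train_test",
    "build_subtype_labels",
    "read_annotations",
    "write_labelset",
    "read_labelset",
]

SUBTYPES = ("reader", "writer", "eraser", "remodeler")
CANCER_DBS = ("CancerMine", "CGC", "NCG", "OncoKB")


@dataclass
class GeneAnnotation:
    """Per-gene evidence used to assign training labels.

    ``lof_per_cds`` is the gene's loss-of-function mutation count normalized
    by coding-sequence length; ``db_membership`` lists which of the four
    cancer-gene resources contain the gene.
    """

    gene_id: str
    is_ERG: bool = False
    db_membership: frozenset = frozenset()
    has_epigenetic_domain: bool = False
    lof_per_cds: float = 0.0
    is_neutral: bool = False
    subtypes: frozenset = frozenset()

    def __post_init__(self):
        self.db_membership = frozenset(self.db_membership)
        self.subtypes = frozenset(self.subtypes)
        if self.lof_per_cds < 0:
            raise ValueError(f"{self.gene_id}: lof_per_cds must be >= 0")
        bad = self.db_membership - set(CANCER_DBS)
        if bad:
            raise ValueError(f"{self.gene_id}: unknown database(s) {sorted(bad)}")
        bad = self.subtypes - set(SUBTYPES)
        if bad:
            raise ValueError(f"{self.gene_id}: unknown subtype(s) {sorted(bad)}")


@dataclass
class LabelSet:
    """Per-gene label (positive / negative / unlabeled) plus partition.

    ``partition`` maps labeled genes to ``"train"`` or ``"test"``;
    ``subtype`` maps genes to their functional subtype set.
    """

    gene_ids: list[str]
    label: dict[str, str]
    partition: dict[str, str] = field(default_factory=dict)
    subtype: dict[str, frozenset] = field(default_factory=dict)

    def __post_init__(self):
        for g, lab in self.label.items():
            if lab not in ("positive", "negative", "unlabeled"):
                raise ValueError(f"{g}: bad label {lab!r}")
        for g, part in self.partition.items():
            if part not in ("train", "test"):
                raise ValueError(f"{g}: bad partition {part!r}")
            if self.label.get(g, "unlabeled") == "unlabeled":
                raise ValueError(f"{g}: partitioned but unlabeled")

    def genes_with(self, label: str, partition: str | None = None) -> list[str]:
        out = []
        for g in self.gene_ids:
            if self.label.get(g) != label:
                continue
            if partition is not None and self.partition.get(g) != partition:
                continue
            out.append(g)
        return out

    @property
    def positives(self) -> list[str]:
        return self.genes_with("positive")

    @property
    def negatives(self) -> list[str]:
        return self.genes_with("negative")

    @property
    def unlabeled(self) -> list[str]:
        return self.genes_with("unlabeled")

    @property
    def labeled(self) -> list[str]:
        return [g for g in self.gene_ids if self.label.get(g) in ("positive", "negative")]


def build_cer_labels(
    annotations: list[GeneAnnotation],
    background_lof,
    lof_quantile: float = 0.2,
    exclude_low_lof: bool = True,
) -> LabelSet:
    """Assign positive / negative / unlabeled labels from gene annotations.

    A gene is positive when it is an ERG, appears in at least two cancer-gene
    databases, carries an epigenetic domain, and survives the LoF-burden
    filter; negative when it is an ERG on the neutral list; all remaining
    ERGs are unlabeled.  The LoF threshold is the ``1 - lof_quantile``
    quantile of ``background_lof`` (the CDS-normalized LoF rates of all
    protein-coding genes).  With ``exclude_low_lof`` (default) genes below
    the threshold are excluded from the positive set; the opposite reading
    (keep only the top quantile is false, i.e. exclude high) is available by
    passing ``exclude_low_lof=False``.
    """
    if not annotations:
        raise ValueError("no annotations supplied")
    background_lof = np.asarray(list(background_lof), dtype=float)
    if background_lof.size == 0:
        raise ValueError("background_lof must be nonempty")
    if not 0 < lof_quantile < 1:
        raise ValueError("lof_quantile must be in (0, 1)")
    threshold = float(np.quantile(background_lof, 1.0 - lof_quantile))

    label: dict[str, str] = {}
    subtype: dict[str, frozenset] = {}
    gene_ids: list[str] = []
    for ann in annotations:
        gene_ids.append(ann.gene_id)
        if not ann.is_ERG:
            label[ann.gene_id] = "unlabeled"
            continue
        subtype[ann.gene_id] = ann.subtypes
        if ann.is_neutral:
            label[ann.gene_id] = "negative"
            continue
        is_pos = len(ann.db_membership) >= 2 and ann.has_epigenetic_domain
        if is_pos and exclude_low_lof and ann.lof_per_cds < threshold:
            is_pos = False
        if is_pos and not exclude_low_lof and ann.lof_per_cds >= threshold:
            is_pos = False
        label[ann.gene_id] = "positive" if is_pos else "unlabeled"

    ls = LabelSet(gene_ids, label, {}, subtype)
    if not ls.positives or not ls.negatives:
        raise ValueError(
            "label construction produced "
            f"{len(ls.positives)} positives and {len(ls.negatives)} negatives; "
            "a trainable label set needs both classes"
        )
    return ls


def split_train_test(labels: LabelSet, ratio: float = 0.8, seed: int = 0) -> LabelSet:
    """Stratified train/test split of the labeled genes.

    Per class, ``round(ratio * n)`` genes (round half up) go to train, the
    rest to test.  Deterministic given ``seed``.
    """
    if not 0 < ratio < 1:
        raise ValueError("ratio must be in (0, 1)")
    rng = np.random.default_rng(seed)
    partition: dict[str, str] = {}
    for cls in ("positive", "negative"):
        genes = labels.genes_with(cls)
        if len(genes) < 2:
            raise ValueError(f"class {cls!r} has {len(genes)} member(s); need >= 2")
        n_train = int(np.floor(ratio * len(genes) + 0.5))  # round half up
        n_train = min(max(n_train, 1), len(genes) - 1)
        order = rng.permutation(len(genes))
        for pos, idx in enumerate(order):
            partition[genes[idx]] = "train" if pos < n_train else "test"
    return LabelSet(list(labels.gene_ids), dict(labels.label), partition,
                    dict(labels.subtype))


def build_subtype_labels(
    annotations: list[GeneAnnotation], base_labels: LabelSet
) -> dict[str, LabelSet]:
    """One LabelSet per functional subtype (reader/writer/eraser/remodeler).

    Subtype positives are the base positives annotated with that subtype;
    negatives are shared with the base set; every other ERG is unlabeled.
    Subtypes without positives are skipped with a warning.
    """
    subtype_of = {a.gene_id: a.subtypes for a in annotations}
    out: dict[str, LabelSet] = {}
    for st in SUBTYPES:
        label: dict[str, str] = {}
        partition: dict[str, str] = {}
        for g in base_labels.gene_ids:
            base = base_labels.label.get(g, "unlabeled")
            if base == "positive" and st in subtype_of.get(g, frozenset()):
                label[g] = "positive"
            elif base == "negative":
                label[g] = "negative"
            else:
                label[g] = "unlabeled"
            if label[g] != "unlabeled" and g in base_labels.partition:
                partition[g] = base_labels.partition[g]
        ls = LabelSet(list(base_labels.gene_ids), label, partition,
                      dict(base_labels.subtype))
        if not ls.positives:
            warnings.warn(f"subtype {st!r} has no positive genes; skipped",
                          UserWarning, stacklevel=2)
            continue
        out[st] = ls
    return out


# -- delimited-text round-trips -------------------------------------------

def read_annotations(path) -> list[GeneAnnotation]:
    """Read an annotation TSV.

    Expected columns: gene, is_ERG, CancerMine, CGC, NCG, OncoKB (0/1 flags),
    has_epigenetic_domain, lof_per_cds, is_neutral, subtypes (semicolon list).
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out = []
    for _, row in df.iterrows():
        dbs = frozenset(db for db in CANCER_DBS if row.get(db, "0") in ("1", "True", "true"))
        subs = frozenset(s for s in str(row.get("subtypes", "")).split(";") if s)
        out.append(GeneAnnotation(
            gene_id=row["gene"],
            is_ERG=row.get("is_ERG", "0") in ("1", "True", "true"),
            db_membership=dbs,
            has_epigenetic_domain=row.get("has_epigenetic_domain", "0") in ("1", "True", "true"),
            lof_per_cds=float(row.get("lof_per_cds") or 0.0),
            is_neutral=row.get("is_neutral", "0") in ("1", "True", "true"),
            subtypes=subs,
        ))
    return out


def write_labelset(labels: LabelSet, path) -> None:
    rows = []
    for g in labels.gene_ids:
        rows.append({
            "gene": g,
            "label": labels.label.get(g, "unlabeled"),
            "partition": labels.partition.get(g, ""),
            "subtypes": ";".join(sorted(labels.subtype.get(g, frozenset()))),
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_labelset(path) -> LabelSet:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    gene_ids = list(df["gene"])
    label = dict(zip(df["gene"], df["label"]))
    partition = {g: p for g, p in zip(df["gene"], df.get("partition", "")) if p}
    subtype = {
        g: frozenset(x for x in s.split(";") if x)
        for g, s in zip(df["gene"], df.get("subtypes", ""))
    }
    return LabelSet(gene_ids, label, partition, subtype)
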