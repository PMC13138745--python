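"""Formula-defined derived features from small raw-omics inputs.

Covers the ratio-metric mutation features (pseudocounted class-count
ratios), copy-number gain/deletion percentages, epigenomic peak merging
within a 3 kb gap with length/height summaries, the S50 replication-timing
midpoint from Repli-seq phase counts, super-enhancer overlap percentages
across cell lines, and paired cancer/normal ratio features such as
differential methylation.  Interval coordinates are 0-based half-open
throughout (BED convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FUNCTIONAL_CLASSES",
    "MutationRecord",
    "Peak",
    "PhaseCounts",
    "ratio_metric_features",
    "cna_percentages",
    "merge_peaks_and_summarize",
    "s50_score",
    "overlap_percentage",
    "paired_ratio_feature",
    "classify_missense_impact",
    "nearest_interval",
    "read_mutation_records",
    "read_peaks_bed",
    "read_phase_counts",
]

FUNCTIONAL_CLASSES = (
    "silent",
    "missense_LoFI",
    "missense_HiFI",
    "nonsense",
    "frameshift",
    "splice_site",
    "inactivating_other",
)

#: benign = silent + low-functional-impact missense
BENIGN_CLASSES = ("silent", "missense_LoFI")
#: loss-of-function = splice-site + nonsense + frameshift
LOF_CLASSES = ("splice_site", "nonsense", "frameshift")
#: inactivating additionally includes start-loss / nonstop style events
INACTIVATING_CLASSES = LOF_CLASSES + ("inactivating_other",)


@dataclass(frozen=True)
class MutationRecord:
    gene_id: str
    functional_class: str

    def __post_init__(self):
        if self.functional_class not in FUNCTIONAL_CLASSES:
            raise ValueError(
                f"unknown functional_class {self.functional_class!r} "
                f"for gene {self.gene_id!r}"
            )


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    height: float = 0.0

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )
        if self.height < 0:
            raise ValueError("peak height must be >= 0")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PhaseCounts:
    """Per-gene read counts across replication phases, early to late."""

    gene_id: str
    counts: np.ndarray
    library_sizes: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        self.library_sizes = np.asarray(self.library_sizes, dtype=float)
        if self.counts.size < 2:
            raise ValueError("need counts for at least two phases")
        if self.counts.size != self.library_sizes.size:
            raise ValueError("counts and library_sizes length mismatch")
        if (self.counts < 0).any() or (self.library_sizes <= 0).any():
            raise ValueError("counts must be >= 0 and library sizes > 0")


def ratio_metric_features(
    records: list[MutationRecord], pseudocount: float = 1.0, genes=None
) -> pd.DataFrame:
    """Pseudocounted mutation class-count ratios per gene.

    Each ratio is ``(count_num + pc) / (count_den + pc)`` so genes with no
    mutations in either group score exactly 1.  Emitted columns:
    ``lof_benign_ratio``, ``hifi_missense_benign_ratio`` and
    ``inactivating_total_ratio``.  ``genes`` optionally extends the output
    to mutation-free genes (every ratio exactly 1).
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    counts: dict[str, dict[str, int]] = {}
    for g in genes or ():
        counts.setdefault(g, dict.fromkeys(FUNCTIONAL_CLASSES, 0))
    for rec in records:
        per_gene = counts.setdefault(rec.gene_id, dict.fromkeys(FUNCTIONAL_CLASSES, 0))
        per_gene[rec.functional_class] += 1
    rows = {}
    for gene, c in counts.items():
        benign = sum(c[k] for k in BENIGN_CLASSES)
        lof = sum(c[k] for k in LOF_CLASSES)
        inactivating = sum(c[k] for k in INACTIVATING_CLASSES)
        hifi = c["missense_HiFI"]
        total = sum(c.values())
        pc = pseudocount
        rows[gene] = {
            "lof_benign_ratio": (lof + pc) / (benign + pc),
            "hifi_missense_benign_ratio": (hifi + pc) / (benign + pc),
            "inactivating_total_ratio": (inactivating + pc) / (total + pc),
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")


def cna_percentages(records: list[tuple[str, str]]) -> pd.DataFrame:
    """Copy-number amplification and deletion percentages per gene.

    ``amplification_pct`` is the fraction of a gene's records typed
    ``gain``; ``deletion_pct`` is its complement.  Genes without records
    simply do not appear (their features stay missing until imputation).
    """
    tally: dict[str, list[int]] = {}
    for gene, mut_type in records:
        if mut_type not in ("gain", "loss"):
            raise ValueError(f"unknown mut_type {mut_type!r} for gene {gene!r}")
        entry = tally.setdefault(gene, [0, 0])
        entry[0] += mut_type == "gain"
        entry[1] += 1
    rows = {
        gene: {
            "amplification_pct": n_gain / n_total,
            "deletion_pct": 1.0 - n_gain / n_total,
        }
        for gene, (n_gain, n_total) in tally.items()
    }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("gene")


def merge_peaks_and_summarize(peaks: list[Peak], gap: int = 3000) -> list[Peak]:
    """Merge same-chromosome peaks whose inter-peak distance is <= ``gap``.

    Merging is transitive; the merged peak spans min(start)..max(end) and
    takes the maximum height of its members.  Peak length is recoverable as
    ``end - start``.  The default 3 kb gap matches common epigenomic
    peak-consolidation practice.
    """
    if gap < 0:
        raise ValueError("gap must be >= 0")
    by_chrom: dict[str, list[Peak]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    merged: list[Peak] = []
    for chrom in sorted(by_chrom):
        chrom_peaks = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end))
        cur_start, cur_end, cur_height = (
            chrom_peaks[0].start, chrom_peaks[0].end, chrom_peaks[0].height,
        )
        for p in chrom_peaks[1:]:
            if p.start - cur_end <= gap:
                cur_end = max(cur_end, p.end)
                cur_height = max(cur_height, p.height)
            else:
                merged.append(Peak(chrom, cur_start, cur_end, cur_height))
                cur_start, cur_end, cur_height = p.start, p.end, p.height
        merged.append(Peak(chrom, cur_start, cur_end, cur_height))
    return merged


def s50_score(pc: PhaseCounts) -> float:
    """Replication-timing midpoint in [0, 1] (early -> small).

    Counts are depth-normalized by their per-phase library sizes and turned
    into a fraction profile f over the P phases.  With F the cumulative sum
    and i* the first phase where F >= 0.5, the score interpolates linearly
    within the crossing phase::

        S50 = (i* + (0.5 - F[i*-1]) / f[i*]) / P

    Returns NaN when every count is zero.
    """
    norm = pc.counts / pc.library_sizes
    total = norm.sum()
    if total <= 0:
        return float("nan")
    f = norm / total
    cum = np.cumsum(f)
    i_star = int(np.argmax(cum >= 0.5))
    prev = cum[i_star - 1] if i_star > 0 else 0.0
    # f[i_star] > 0 whenever cum first crosses 0.5 at i_star
    s50 = (i_star + (0.5 - prev) / f[i_star]) / f.size
    return float(s50)


def overlap_percentage(
    gene_interval: Peak, interval_sets: list[list[Peak]]
) -> float:
    """Fraction of cell lines whose intervals overlap the gene interval.

    Overlap means a nonempty intersection under half-open coordinates, so a
    set touching the gene end-to-start does not count.
    """
    if not interval_sets:
        raise ValueError("interval_sets must be nonempty")
    hits = 0
    for intervals in interval_sets:
        for iv in intervals:
            if (
                iv.chrom == gene_interval.chrom
                and iv.start < gene_interval.end
                and gene_interval.start < iv.end
            ):
                hits += 1
                break
    return hits / len(interval_sets)


def paired_ratio_feature(numerator: pd.Series, denominator: pd.Series) -> pd.Series:
    """Per-gene ratio such as methylation in cancer over methylation in
    normal; a zero denominator yields a missing value."""
    num, den = numerator.align(denominator, join="inner")
    if (num < 0).any() or (den < 0).any():
        raise ValueError("paired ratio inputs must be >= 0")
    out = num / den.where(den > 0)
    return out.astype(float)


def classify_missense_impact(
    probabilities: pd.Series, threshold: float = 0.5
) -> pd.Series:
    """Map a per-variant damage probability to HiFI/LoFI classes."""
    return probabilities.map(
        lambda p: "missense_HiFI" if p >= threshold else "missense_LoFI"
    )


def nearest_interval(query: Peak, candidates: list[Peak]) -> Peak:
    """Nearest same-chromosome interval; ties broken by smaller start."""
    same = [c for c in candidates if c.chrom == query.chrom]
    if not same:
        raise ValueError(f"no candidate interval on {query.chrom}")

    def dist(c: Peak) -> int:
        if c.start < query.end and query.start < c.end:
            return 0
        return max(c.start - query.end, query.start - c.end) + 1

    return min(same, key=lambda c: (dist(c), c.start))


# -- text-format readers ---------------------------------------------------

def read_mutation_records(path) -> list[MutationRecord]:
    """Read a two-column TSV (gene, functional_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        MutationRecord(g, c)
        for g, c in zip(df.iloc[:, 0], df.iloc[:, 1])
    ]


def read_peaks_bed(path) -> list[Peak]:
    """Read a BED4+ file: chrom, start, end, height (0-based half-open)."""
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            height = float(parts[3]) if len(parts) > 3 else 0.0
            peaks.append(Peak(parts[0], int(parts[1]), int(parts[2]), height))
    return peaks


def read_phase_counts(path) -> list[PhaseCounts]:
    """Read a wide TSV: gene, then one count column per phase (early->late).

    Library sizes are taken from a final header-encoded row named
    ``__library_size__`` when present, else default to the per-phase totals.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "__library_size__" in df.index:
        lib = df.loc["__library_size__"].to_numpy(dtype=float)
        df = df.drop(index="__library_size__")
    else:
        lib = df.sum(axis=0).to_numpy(dtype=float)
        lib[lib <= 0] = 1.0
    return [PhaseCounts(g, row.to_numpy(dtype=float), lib) for g, row in df.iterrows()]
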