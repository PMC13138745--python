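from collections import Counter

import numpy as np
import pandas as pd
import pytest

from caser.features import (
    FUNCTIONAL_CLASSES,
    MutationRecord,
    Peak,
    PhaseCounts,
    classify_missense_impact,
    cna_percentages,
    merge_peaks_and_summarize,
    nearest_interval,
    overlap_percentage,
    paired_ratio_feature,
    ratio_metric_features,
    s50_score,
)


def _recs(gene, classes):
    return [MutationRecord(gene, c) for c in classes]


class TestRatioMetric:
    def test_pseudocount_formula(self):
        recs = _recs("A", ["nonsense"] * 2 + ["frameshift", "splice_site", "silent"])
        out = ratio_metric_features(recs, pseudocount=1.0)
        # 4 LoF, 1 benign -> (4+1)/(1+1)
        assert out.loc["A", "lof_benign_ratio"] == pytest.approx(2.5)

    def test_mutation_free_gene_scores_one_everywhere(self):
        out = ratio_metric_features([], pseudocount=1.0, genes=["EMPTY"])
        assert (out.loc["EMPTY"] == 1.0).all()

    def test_matches_independent_tally(self, rng):
        classes = [str(rng.choice(FUNCTIONAL_CLASSES)) for _ in range(300)]
        genes = [f"G{rng.integers(6)}" for _ in range(300)]
        recs = [MutationRecord(g, c) for g, c in zip(genes, classes)]
        out = ratio_metric_features(recs, pseudocount=1.0)
        for gene in set(genes):
            tally = Counter(c for g, c in zip(genes, classes) if g == gene)
            benign = tally["silent"] + tally["missense_LoFI"]
            lof = tally["splice_site"] + tally["nonsense"] + tally["frameshift"]
            assert out.loc[gene, "lof_benign_ratio"] == pytest.approx(
                (lof + 1) / (benign + 1)
            )
            assert out.loc[gene, "inactivating_total_ratio"] == pytest.approx(
                (lof + tally["inactivating_other"] + 1) / (sum(tally.values()) + 1)
            )

    def test_ratios_strictly_positive(self, rng):
        recs = _recs("A", ["silent"] * 5)
        out = ratio_metric_features(recs, pseudocount=0.5)
        assert (out > 0).all().all()

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="weird"):
            MutationRecord("A", "weird")


class TestCnaPercentages:
    def test_stated_formula(self):
        out = cna_percentages([("A", "gain")] * 3 + [("A", "loss")])
        assert out.loc["A", "amplification_pct"] == pytest.approx(0.75)
        assert out.loc["A", "deletion_pct"] == pytest.approx(0.25)

    def test_all_gain_boundary(self):
        out = cna_percentages([("A", "gain"), ("A", "gain")])
        assert tuple(out.loc["A"]) == (1.0, 0.0)

    def test_gene_without_records_absent(self):
        out = cna_percentages([("A", "gain")])
        assert "B" not in out.index

    def test_vocabulary_enforced(self):
        with pytest.raises(ValueError, match="amplif"):
            cna_percentages([("A", "amplif")])


def _merge_oracle(peaks, gap):
    """O(n^2) transitive merge: union-find over the within-gap relation."""
    parent = list(range(len(peaks)))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, a in enumerate(peaks):
        for j, b in enumerate(peaks):
            if a.chrom != b.chrom or i == j:
                continue
            dist = max(b.start - a.end, a.start - b.end)
            if dist <= gap:
                parent[find(i)] = find(j)
    groups = {}
    for i, p in enumerate(peaks):
        groups.setdefault(find(i), []).append(p)
    out = []
    for members in groups.values():
        out.append(Peak(
            members[0].chrom,
            min(p.start for p in members),
            max(p.end for p in members),
            max(p.height for p in members),
        ))
    return sorted(out, key=lambda p: (p.chrom, p.start))


class TestMergePeaks:
    def test_within_gap_merges(self):
        merged = merge_peaks_and_summarize(
            [Peak("chr1", 100, 200, 5), Peak("chr1", 2900, 3000, 7)], gap=3000
        )
        assert len(merged) == 1
        assert (merged[0].start, merged[0].end) == (100, 3000)
        assert merged[0].length == 2900 and merged[0].height == 7

    def test_beyond_gap_stays_separate(self):
        merged = merge_peaks_and_summarize(
            [Peak("chr1", 100, 200), Peak("chr1", 3300, 3400)], gap=3000
        )
        assert len(merged) == 2

    def test_gap_boundary_is_inclusive(self):
        at = merge_peaks_and_summarize(
            [Peak("chr1", 0, 100), Peak("chr1", 3100, 3200)], gap=3000
        )
        past = merge_peaks_and_summarize(
            [Peak("chr1", 0, 100), Peak("chr1", 3101, 3201)], gap=3000
        )
        assert len(at) == 1 and len(past) == 2

    def test_matches_quadratic_oracle_and_idempotent(self, rng):
        peaks = []
        for _ in range(200):
            chrom = f"chr{rng.integers(1, 4)}"
            start = int(rng.integers(0, 100_000))
            peaks.append(Peak(chrom, start, start + int(rng.integers(1, 800)),
                              float(rng.integers(0, 50))))
        merged = merge_peaks_and_summarize(peaks, gap=3000)
        oracle = _merge_oracle(peaks, 3000)
        key = lambda p: (p.chrom, p.start, p.end, p.height)
        assert sorted(merged, key=key) == sorted(oracle, key=key)
        again = merge_peaks_and_summarize(merged, gap=3000)
        assert sorted(again, key=key) == sorted(merged, key=key)
        by_chrom = {}
        for p in sorted(merged, key=key):
            prev = by_chrom.get(p.chrom)
            if prev is not None:
                assert p.start - prev.end > 3000
            by_chrom[p.chrom] = p

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError, match="invalid interval"):
            Peak("chr1", 200, 100)


class TestS50:
    def _pc(self, counts, libs=None):
        counts = np.asarray(counts, dtype=float)
        libs = np.ones_like(counts) if libs is None else np.asarray(libs, float)
        return PhaseCounts("G", counts, libs)

    def test_all_mass_in_first_phase(self):
        assert s50_score(self._pc([10, 0, 0, 0, 0, 0])) == pytest.approx(0.5 / 6)

    def test_uniform_counts_midpoint(self):
        assert s50_score(self._pc([3, 3, 3, 3, 3, 3])) == pytest.approx(0.5)

    def test_depth_normalization_matters(self):
        # equal raw counts but late phases sequenced twice as deep -> early shift
        skewed = s50_score(self._pc([5, 5, 5, 5], libs=[1, 1, 2, 2]))
        assert skewed < 0.5

    def test_reversal_symmetry(self, rng):
        for _ in range(50):
            counts = rng.uniform(0.1, 10.0, size=int(rng.integers(2, 9)))
            fwd = s50_score(self._pc(counts))
            rev = s50_score(self._pc(counts[::-1]))
            assert fwd + rev == pytest.approx(1.0, abs=1e-9)

    def test_later_mass_never_decreases_score(self, rng):
        for _ in range(25):
            counts = rng.uniform(0.5, 5.0, size=6)
            shifted = counts.copy()
            shifted[0] -= 0.4
            shifted[-1] += 0.4
            assert s50_score(self._pc(shifted)) >= s50_score(self._pc(counts)) - 1e-12

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(25):
            counts = rng.uniform(0, 3.0, size=5)
            if counts.sum() == 0:
                continue
            assert 0.0 <= s50_score(self._pc(counts)) <= 1.0

    def test_zero_counts_undefined(self):
        assert np.isnan(s50_score(self._pc([0, 0, 0])))


class TestOverlapPercentage:
    GENE = Peak("chr1", 100, 200)

    def test_counting(self):
        sets = [
            [Peak("chr1", 150, 300)],          # overlaps
            [Peak("chr1", 0, 120)],            # overlaps
            [Peak("chr1", 500, 600)],          # no
            [Peak("chr2", 100, 200)],          # wrong chromosome
            [],                                 # empty cell line
        ]
        assert overlap_percentage(self.GENE, sets) == pytest.approx(0.4)

    def test_touching_is_not_overlap_under_half_open(self):
        assert overlap_percentage(self.GENE, [[Peak("chr1", 200, 300)]]) == 0.0

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            overlap_percentage(self.GENE, [])


class TestPairedRatio:
    def test_cancer_over_normal(self):
        out = paired_ratio_feature(pd.Series({"A": 0.6}), pd.Series({"A": 0.3}))
        assert out["A"] == pytest.approx(2.0)

    def test_zero_denominator_is_missing(self):
        out = paired_ratio_feature(pd.Series({"A": 0.6}), pd.Series({"A": 0.0}))
        assert np.isnan(out["A"])

    def test_zero_numerator_is_zero(self):
        out = paired_ratio_feature(pd.Series({"A": 0.0}), pd.Series({"A": 0.5}))
        assert out["A"] == 0.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            paired_ratio_feature(pd.Series({"A": -1.0}), pd.Series({"A": 0.5}))


def test_missense_impact_threshold():
    out = classify_missense_impact(pd.Series([0.2, 0.5, 0.9]))
    assert list(out) == ["missense_LoFI", "missense_HiFI", "missense_HiFI"]


def test_nearest_interval_tie_breaks_on_smaller_start():
    query = Peak("chr1", 1000, 1100)
    left = Peak("chr1", 800, 900)    # 100 bp away
    right = Peak("chr1", 1200, 1300)  # 100 bp away
    assert nearest_interval(query, [right, left]) is left
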