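"""Peak-caller tests: collapse/merge oracles, permutation null, FDR, IgG."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from agorip.align import AlignmentHit
from agorip.peakcall import (
    NullDistribution,
    UniqueRead,
    assign_fdr,
    bound_genes,
    collapse,
    igg_filter,
    merge,
    random_ip_null,
    target_overlap,
)


def hit(start, end, rid="r", chrom="c", strand="+"):
    return AlignmentHit(rid, chrom, strand, start, end, 0)


class TestCollapse:
    def test_identical_placements_merge(self):
        ur = collapse([hit(10, 40, rid=str(i)) for i in range(5)])
        assert ur == [UniqueRead("c", "+", 10, 40, 5)]

    def test_distinct_placements_stay_apart(self):
        ur = collapse([hit(10, 40), hit(11, 41)])
        assert len(ur) == 2

    def test_counts_conserve_hits(self):
        rng = np.random.default_rng(0)
        hits = [hit(int(s), int(s) + 30) for s in rng.integers(0, 200, size=100)]
        assert sum(u.count for u in collapse(hits)) == 100


def brute_clusters(intervals):
    """Union-find oracle over interval overlap (>=1 nt)."""
    parent = list(range(len(intervals)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, (s1, e1) in enumerate(intervals):
        for j, (s2, e2) in enumerate(intervals):
            if i < j and min(e1, e2) > max(s1, s2):
                parent[find(i)] = find(j)
    groups = {}
    for i, iv in enumerate(intervals):
        groups.setdefault(find(i), []).append(iv)
    return sorted(
        (min(s for s, _ in g), max(e for _, e in g), len(g)) for g in groups.values()
    )


class TestMerge:
    def test_overlapping_pair_merges(self):
        clusters = merge([UniqueRead("c", "+", 0, 30, 1), UniqueRead("c", "+", 20, 50, 1)])
        assert [(c.start, c.end, c.count) for c in clusters] == [(0, 50, 2)]

    def test_book_ended_intervals_stay_separate(self):
        clusters = merge([UniqueRead("c", "+", 0, 30, 1), UniqueRead("c", "+", 30, 60, 1)])
        assert len(clusters) == 2

    def test_strands_never_merge(self):
        clusters = merge([UniqueRead("c", "+", 0, 30, 1), UniqueRead("c", "-", 10, 40, 1)])
        assert len(clusters) == 2

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_matches_union_find_oracle(self, seed):
        rng = np.random.default_rng(seed)
        intervals = []
        for _ in range(60):
            s = int(rng.integers(0, 500))
            intervals.append((s, s + int(rng.integers(10, 60))))
        ur = [UniqueRead("c", "+", s, e, 1) for s, e in intervals]
        got = sorted((c.start, c.end, c.count) for c in merge(ur))
        assert got == brute_clusters(intervals)

    def test_count_conservation_through_collapse_merge(self):
        rng = np.random.default_rng(4)
        hits = [hit(int(s), int(s) + 25) for s in rng.integers(0, 400, size=200)]
        clusters = merge(collapse(hits))
        assert sum(c.count for c in clusters) == 200


def mc_null_oracle(exonic_length, read_lengths, repeats, seed):
    """Direct Monte-Carlo re-implementation: place, sort, sweep in Python."""
    rng = np.random.default_rng(seed)
    maxima = []
    for _ in range(repeats):
        placed = sorted(
            (int(rng.integers(0, exonic_length - l + 1)), l) for l in read_lengths
        )
        best = cur = 0
        cur_end = -1
        for s, l in placed:
            if cur and s < cur_end:
                cur += 1
                cur_end = max(cur_end, s + l)
            else:
                cur = 1
                cur_end = s + l
            best = max(best, cur)
        maxima.append(best)
    return np.array(maxima)


class TestRandomIpNull:
    def test_single_read_max_is_one(self):
        null = random_ip_null(1000, [50], repeats=20, seed=0)
        assert (null.max_counts == 1).all()

    def test_span_equals_read_length_forces_one_pile(self):
        null = random_ip_null(100, [100] * 7, repeats=10, seed=0)
        assert (null.max_counts == 7).all()

    def test_read_longer_than_span_errors_naming_gene(self):
        with pytest.raises(ValueError, match="geneX"):
            random_ip_null(40, [50], repeats=5, seed=0, gene="geneX")

    def test_deterministic_for_seed(self):
        a = random_ip_null(5000, [40] * 30, repeats=50, seed=9)
        b = random_ip_null(5000, [40] * 30, repeats=50, seed=9)
        assert (a.max_counts == b.max_counts).all()

    def test_matches_independent_monte_carlo(self):
        lengths = [100] * 50
        null = random_ip_null(10_000, lengths, repeats=1000, seed=5)
        oracle = mc_null_oracle(10_000, lengths, repeats=1000, seed=6)
        ks = stats.ks_2samp(null.max_counts, oracle)
        assert ks.pvalue > 0.01

    def test_mixed_lengths_supported(self):
        null = random_ip_null(2000, [30, 50, 70, 90], repeats=100, seed=1)
        assert null.max_counts.min() >= 1
        assert null.max_counts.max() <= 4


class TestAssignFdr:
    null = NullDistribution(np.array([1, 1, 2, 3]), repeats=4, seed=0)

    def cluster(self, count):
        return merge([UniqueRead("c", "+", 0, 30, count)])[0]

    def test_above_all_maxima_fdr_zero(self):
        peaks = assign_fdr([self.cluster(10)], self.null)
        assert peaks[0].fdr == 0.0 and peaks[0].significant

    def test_below_all_maxima_fdr_one(self):
        peaks = assign_fdr([self.cluster(1)], self.null)
        assert peaks[0].fdr == 1.0 and not peaks[0].significant

    def test_hand_counted_survival_fraction(self):
        peaks = assign_fdr([self.cluster(2)], self.null)
        assert peaks[0].fdr == pytest.approx(0.5)

    def test_ties_share_fdr(self):
        peaks = assign_fdr([self.cluster(2), self.cluster(2)], self.null)
        assert peaks[0].fdr == peaks[1].fdr

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            assign_fdr([self.cluster(1)], NullDistribution(np.array([]), repeats=0, seed=0))


class TestIggFilter:
    def make_peak(self, count, fdr=0.0):
        c = merge([UniqueRead("c", "+", 100, 150, count)])[0]
        return assign_fdr([c], NullDistribution(np.array([1] * 10), 10, 0))[0]

    def test_no_igg_reads_high_ratio_retained(self):
        peaks = igg_filter([self.make_peak(10)], [], min_ratio=2.0)
        assert peaks[0].igg_count == 0
        assert peaks[0].igg_ratio == pytest.approx(11.0)
        assert peaks[0].significant

    def test_equal_counts_dropped(self):
        igg = [hit(100, 150, rid=str(i)) for i in range(10)]
        peaks = igg_filter([self.make_peak(10)], igg, min_ratio=2.0)
        assert peaks[0].igg_ratio == pytest.approx(1.0)
        assert not peaks[0].significant

    def test_only_overlapping_same_strand_igg_counted(self):
        igg = [hit(200, 250), hit(100, 150, strand="-"), hit(60, 101)]
        peaks = igg_filter([self.make_peak(5)], igg)
        assert peaks[0].igg_count == 1  # only the 1-nt overlapper on '+'


class TestBoundGenes:
    def test_no_significant_peaks_empty_set(self):
        null = NullDistribution(np.array([100] * 10), 10, 0)
        clusters = merge([UniqueRead("c", "+", 0, 30, 2)])
        clusters[0].gene = "g1"
        peaks = assign_fdr(clusters, null)
        assert bound_genes(peaks) == set()

    def test_three_peaks_two_genes(self):
        null = NullDistribution(np.array([1] * 10), 10, 0)
        ur = [
            UniqueRead("c", "+", 0, 30, 5),
            UniqueRead("c", "+", 100, 130, 5),
            UniqueRead("c", "+", 200, 230, 5),
        ]
        clusters = merge(ur)
        for c, g in zip(clusters, ["g1", "g1", "g2"]):
            c.gene = g
        assert bound_genes(assign_fdr(clusters, null)) == {"g1", "g2"}


class TestTargetOverlap:
    universe = [f"g{i}" for i in range(20)]

    def test_empty_target_list_p_one(self):
        frame = target_overlap({"g1"}, pd.DataFrame(columns=["mirna", "target"]), self.universe)
        assert frame.empty

    def test_all_targets_bound_exact_hypergeometric(self):
        targets = pd.DataFrame(
            {"mirna": ["miR-x"] * 3, "target": ["g1", "g2", "g3"]}
        )
        bound = {"g1", "g2", "g3", "g4", "g5"}
        frame = target_overlap(bound, targets, self.universe)
        # P(all 3 of 3 targets bound | 5 of 20 bound) = C(5,3)/C(20,3)
        from math import comb

        assert frame["p_hypergeom"].iloc[0] == pytest.approx(comb(5, 3) / comb(20, 3))
        assert frame["n_bound"].iloc[0] == 3

    def test_disjoint_sets_zero_overlap(self):
        targets = pd.DataFrame({"mirna": ["miR-y"], "target": ["g9"]})
        frame = target_overlap({"g1"}, targets, self.universe)
        assert frame["n_bound"].iloc[0] == 0
        assert frame["p_hypergeom"].iloc[0] == pytest.approx(1.0, abs=1e-9)
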