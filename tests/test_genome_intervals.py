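import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from epinorm.genome_intervals import (
    UNASSIGNED,
    CompartmentConfig,
    classify_compartment,
    compartment_distribution,
    count_reads_in_regions,
    group_targets_by_location,
    map_peaks_to_targets,
    nearest_gene,
    pair_peaks,
    venn_overlap,
)
from epinorm.peak_io import GeneAnnotation, GeneModel, Peak, PeakSet

from conftest import random_peakset


def _brute_force_pairing(a: PeakSet, b: PeakSet, min_overlap: int):
    """Quadratic oracle for the greedy one-to-one maximal-overlap matching."""
    available = list(b.peaks)
    pairs, unique_a = [], []
    for pa in a:
        best, best_ov = None, 0
        for pb in available:
            if pb.chrom != pa.chrom:
                continue
            ov = min(pa.end, pb.end) - max(pa.start, pb.start)
            if ov >= min_overlap and ov > best_ov:
                best, best_ov = pb, ov
        if best is None:
            unique_a.append(pa)
        else:
            available.remove(best)
            pairs.append((pa, best))
    return pairs, unique_a, available


def _brute_force_venn(sets, min_overlap):
    out = {}
    for i, ps in enumerate(sets):
        partition = {}
        for p in ps:
            members = frozenset(
                j
                for j, other in enumerate(sets)
                if j != i
                and any(
                    q.chrom == p.chrom
                    and min(p.end, q.end) - max(p.start, q.start) >= min_overlap
                    for q in other
                )
            )
            partition[members] = partition.get(members, 0) + 1
        out[ps.sample_label] = partition
    return out


class TestPairPeaks:
    def test_single_overlap_is_common(self):
        a = PeakSet("a", [Peak("chr1", 100, 200)])
        b = PeakSet("b", [Peak("chr1", 150, 250)])
        pairing = pair_peaks(a, b)
        assert len(pairing.common_pairs) == 1
        assert not pairing.unique_a and not pairing.unique_b

    def test_touching_intervals_do_not_overlap(self):
        a = PeakSet("a", [Peak("chr1", 100, 200)])
        b = PeakSet("b", [Peak("chr1", 200, 300)])
        pairing = pair_peaks(a, b)
        assert not pairing.common_pairs
        assert len(pairing.unique_a) == 1 and len(pairing.unique_b) == 1

    def test_maximal_overlap_wins(self):
        # [0,100) overlaps [10,40) by 30 and [50,90) by 40: the larger wins
        a = PeakSet("a", [Peak("chr1", 0, 100)])
        b = PeakSet("b", [Peak("chr1", 10, 40), Peak("chr1", 50, 90)])
        pairing = pair_peaks(a, b)
        assert pairing.common_pairs[0][1].key == ("chr1", 50, 90)
        assert [p.key for p in pairing.unique_b] == [("chr1", 10, 40)]

    def test_min_overlap_threshold(self):
        a = PeakSet("a", [Peak("chr1", 0, 100)])
        b = PeakSet("b", [Peak("chr1", 95, 200)])
        assert len(pair_peaks(a, b, min_overlap_bp=5).common_pairs) == 1
        assert len(pair_peaks(a, b, min_overlap_bp=6).common_pairs) == 0

    def test_invalid_min_overlap(self):
        a = PeakSet("a", [Peak("chr1", 0, 100)])
        with pytest.raises(ValueError):
            pair_peaks(a, a, min_overlap_bp=0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_partition_property(self, seed):
        """|common| + |unique_a| = |A| and |common| + |unique_b| = |B|."""
        rng = np.random.default_rng(seed)
        a = random_peakset(rng, int(rng.integers(1, 60)), "a")
        b = random_peakset(rng, int(rng.integers(1, 60)), "b")
        pairing = pair_peaks(a, b)
        assert len(pairing.common_pairs) + len(pairing.unique_a) == len(a)
        assert len(pairing.common_pairs) + len(pairing.unique_b) == len(b)

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            a = random_peakset(rng, int(rng.integers(1, 200)), "a")
            b = random_peakset(rng, int(rng.integers(1, 200)), "b")
            got = pair_peaks(a, b)
            pairs, uniq_a, uniq_b = _brute_force_pairing(a, b, 1)
            assert {(x.key, y.key) for x, y in got.common_pairs} == {
                (x.key, y.key) for x, y in pairs
            }
            assert [p.key for p in got.unique_a] == [p.key for p in uniq_a]
            assert sorted(p.key for p in got.unique_b) == sorted(p.key for p in uniq_b)


class TestCountReads:
    def _reads(self, mids, strand="+"):
        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": [m - 18 for m in mids],
                "end": [m + 18 for m in mids],
                "strand": strand,
            }
        )

    def test_midpoints_counted(self):
        regions = PeakSet("r", [Peak("chr1", 100, 200)])
        counts = count_reads_in_regions(self._reads([100, 150, 199, 120, 130]), regions)
        assert counts.tolist() == [5]

    def test_half_open_end_excluded(self):
        regions = PeakSet("r", [Peak("chr1", 100, 200)])
        assert count_reads_in_regions(self._reads([200]), regions).tolist() == [0]
        assert count_reads_in_regions(self._reads([199]), regions).tolist() == [1]

    def test_strand_shift(self):
        regions = PeakSet("r", [Peak("chr1", 200, 300)])
        plus = self._reads([150], "+")
        minus = self._reads([350], "-")
        assert count_reads_in_regions(plus, regions, shift_bp=100).tolist() == [1]
        assert count_reads_in_regions(minus, regions, shift_bp=100).tolist() == [1]
        assert count_reads_in_regions(plus, regions, shift_bp=0).tolist() == [0]

    def test_empty_reads_all_zero(self):
        regions = PeakSet("r", [Peak("chr1", 100, 200)])
        empty = pd.DataFrame(columns=["chrom", "start", "end", "strand"])
        assert count_reads_in_regions(empty, regions).tolist() == [0]


class TestCompartments:
    @pytest.mark.parametrize(
        "anchor,expected",
        [
            (97_000, "proximal_promoter"),  # offset -3000
            (91_000, "distal_promoter"),  # offset -9000
            (106_000, "exon"),  # past the +2 kb proximal window
            (103_000, "intron"),
            (150_000, "intergenic"),
        ],
    )
    def test_plus_strand_labels(self, two_gene_annotation, anchor, expected):
        peak = Peak("chr1", anchor - 50, anchor + 50)
        assert classify_compartment(peak, two_gene_annotation) == expected

    @pytest.mark.parametrize(
        "anchor,expected",
        [
            (312_999, "proximal_promoter"),  # TSS=309999, offset -3000
            (318_999, "distal_promoter"),  # offset -9000
            (301_000, "exon"),
            (304_000, "intron"),
        ],
    )
    def test_minus_strand_windows_are_oriented(self, two_gene_annotation, anchor, expected):
        peak = Peak("chr1", anchor - 50, anchor + 50)
        assert classify_compartment(peak, two_gene_annotation) == expected

    def test_proximal_beats_distal_precedence(self):
        # two genes whose windows overlap at one anchor
        g1 = GeneModel("GA", "chr1", "+", 100_000, 105_000, (100_000,), (105_000,))
        g2 = GeneModel("GB", "chr1", "+", 94_000, 99_000, (94_000,), (99_000,))
        ann = GeneAnnotation([g1, g2])
        # anchor 95_000: -5000 of GA (distal) but +1000 of GB (proximal)
        assert classify_compartment(Peak("chr1", 94_950, 95_050), ann) == "proximal_promoter"

    def test_distribution_sums_to_one(self, two_gene_annotation):
        peaks = PeakSet(
            "s",
            [Peak("chr1", a - 50, a + 50) for a in (97_000, 91_000, 106_000, 700_000)],
        )
        fractions, counts = compartment_distribution(peaks, two_gene_annotation)
        assert abs(sum(fractions.values()) - 1.0) < 1e-9
        assert counts["proximal_promoter"] == 1
        assert counts["intergenic"] == 1

    def test_empty_peakset_raises(self, two_gene_annotation):
        with pytest.raises(ValueError):
            compartment_distribution(PeakSet("s", []), two_gene_annotation)

    def test_single_gene_tiling_never_intergenic_in_span(self):
        g = GeneModel("GA", "chr1", "+", 50_000, 60_000, (50_000,), (60_000,))
        ann = GeneAnnotation([g])
        for anchor in range(40_000, 60_000, 500):
            label = classify_compartment(Peak("chr1", anchor, anchor + 1), ann)
            assert label != "intergenic"


class TestNearestGene:
    def _ann(self, tss_list):
        genes = [
            GeneModel(f"G{i}", "chr1", "+", t, t + 1000, (t,), (t + 1000,))
            for i, t in enumerate(tss_list)
        ]
        return GeneAnnotation(genes)

    def test_minimal_distance(self):
        ann = self._ann([1000, 9000])
        assert nearest_gene(Peak("chr1", 3950, 4050), ann) == "G0"

    def test_tie_breaks_lexicographically(self):
        ann = self._ann([1000, 7000])
        assert nearest_gene(Peak("chr1", 3950, 4050), ann) == "G0"

    def test_no_gene_on_chromosome_unassigned(self):
        ann = self._ann([1000])
        assert nearest_gene(Peak("chr9", 100, 200), ann) == UNASSIGNED

    def test_distance_is_minimal_exhaustive(self):
        rng = np.random.default_rng(3)
        tss = sorted(int(t) for t in rng.choice(1_000_000, size=100, replace=False))
        ann = self._ann(tss)
        gene_tss = {g.name.upper(): g.tss for g in ann}
        for _ in range(200):
            pos = int(rng.integers(0, 1_100_000))
            got = nearest_gene(Peak("chr1", pos, pos + 1), ann)
            best = min(abs(t - pos) for t in tss)
            assert abs(gene_tss[got] - pos) == best

    def test_map_targets_excludes_unassigned(self):
        ann = self._ann([1000])
        peaks = PeakSet("s", [Peak("chr1", 900, 1100), Peak("chrUn", 5, 50)])
        assert map_peaks_to_targets(peaks, ann) == {"G0"}


class TestVenn:
    def test_two_sets_basic(self):
        a = PeakSet("a", [Peak("chr1", 0, 100)])
        b = PeakSet("b", [Peak("chr1", 50, 150)])
        out = venn_overlap([a, b])
        assert out["a"] == {frozenset({1}): 1}
        assert out["b"] == {frozenset({0}): 1}

    def test_disjoint_sets_all_exclusive(self):
        a = PeakSet("a", [Peak("chr1", 0, 100)])
        b = PeakSet("b", [Peak("chr1", 500, 600)])
        out = venn_overlap([a, b])
        assert out["a"] == {frozenset(): 1}

    def test_requires_two_or_three_sets(self):
        a = PeakSet("a", [Peak("chr1", 0, 100)])
        with pytest.raises(ValueError):
            venn_overlap([a])

    def test_counts_sum_to_set_sizes(self):
        rng = np.random.default_rng(11)
        sets = [random_peakset(rng, 50, name) for name in ("a", "b", "c")]
        out = venn_overlap(sets)
        for ps in sets:
            assert sum(out[ps.sample_label].values()) == len(ps)

    def test_agrees_with_quadratic_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            k = int(rng.integers(2, 4))
            sets = [
                random_peakset(rng, int(rng.integers(1, 200)), f"s{i}")
                for i in range(k)
            ]
            assert venn_overlap(sets) == _brute_force_venn(sets, 1)


class TestTargetGrouping:
    def test_promoter_and_distal_peak_gives_both_group(self):
        g = GeneModel("GA", "chr1", "+", 100_000, 110_000, (100_000,), (110_000,))
        ann = GeneAnnotation([g])
        peaks = PeakSet(
            "s",
            [Peak("chr1", 96_950, 97_050),  # proximal window
             Peak("chr1", 149_950, 150_050)],  # 50 kb downstream, still nearest
        )
        groups = group_targets_by_location(peaks, ann)
        assert groups["distal_and_promoter"].genes == {"GA"}

    def test_promoter_only(self):
        g = GeneModel("GA", "chr1", "+", 100_000, 110_000, (100_000,), (110_000,))
        ann = GeneAnnotation([g])
        peaks = PeakSet("s", [Peak("chr1", 96_950, 97_050)])
        groups = group_targets_by_location(peaks, ann)
        assert groups["promoter_only"].genes == {"GA"}
        assert not groups["distal_only"].genes

    def test_groups_partition_targets(self, default_experiment):
        annotation, ko, _, _, _, _ = default_experiment
        groups = group_targets_by_location(ko, annotation)
        sets = [g.genes for g in groups.values()]
        assert sets[0] | sets[1] | sets[2] == map_peaks_to_targets(ko, annotation)
        assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2])
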