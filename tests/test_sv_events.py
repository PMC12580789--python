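import itertools

import numpy as np
import pytest

from cinsig.genome import GenomeModel
from cinsig.sv_events import (
    breakpoint_density,
    classify_cluster,
    cluster_junctions,
    compact_or_sparse,
    detect_chromothripsis_like,
    sv_feature_counts,
)
from cinsig.types import CopyNumberSegment, make_junction

from conftest import random_junctions


def brute_force_clusters(junctions, proximity):
    """Independent oracle: union-find over ALL breakend pairs."""
    n = len(junctions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i, j in itertools.combinations(range(n), 2):
        for b1 in (junctions[i].bnd_a, junctions[i].bnd_b):
            for b2 in (junctions[j].bnd_a, junctions[j].bnd_b):
                if b1.chrom == b2.chrom and abs(b1.pos - b2.pos) <= proximity:
                    parent[find(j)] = find(i)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return {frozenset(g) for g in groups.values()}


class TestClustering:
    def test_two_dels_within_proximity_merge(self):
        j1 = make_junction("S", "chr1", 1_000_000, "+", "chr1", 1_030_000, "-")
        j2 = make_junction("S", "chr1", 1_034_000, "+", "chr1", 1_100_000, "-")
        (cluster,) = cluster_junctions([j1, j2])
        assert len(cluster.junctions) == 2 and cluster.size_class == "pair"

    def test_different_chromosomes_stay_apart(self):
        j1 = make_junction("S", "chr1", 1_000_000, "+", "chr1", 1_030_000, "-")
        j2 = make_junction("S", "chr2", 1_000_000, "+", "chr2", 1_030_000, "-")
        assert len(cluster_junctions([j1, j2])) == 2

    def test_transitive_chain(self):
        # A-B within 3 kb, B-C within 3 kb, A-C 200 kb apart: one cluster
        a = make_junction("S", "chr1", 1_000_000, "+", "chr1", 5_000_000, "-")
        b = make_junction("S", "chr1", 1_003_000, "+", "chr1", 9_000_000, "-")
        c = make_junction("S", "chr1", 1_006_000, "+", "chr1", 1_200_000, "-")
        (cluster,) = cluster_junctions([a, b, c])
        assert set(cluster.junctions) == {a, b, c}

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        junctions = random_junctions(rng, int(rng.integers(1, 50)))
        clusters = cluster_junctions(junctions, proximity=5_000)
        got = {
            frozenset(junctions.index(j) for j in c.junctions) for c in clusters
        }
        assert got == brute_force_clusters(junctions, 5_000)

    def test_order_invariant(self):
        rng = np.random.default_rng(7)
        junctions = random_junctions(rng, 30)
        a = cluster_junctions(junctions)
        b = cluster_junctions(junctions[::-1])
        assert {frozenset(c.junctions) for c in a} == {
            frozenset(c.junctions) for c in b
        }

    def test_mixed_samples_rejected(self):
        j1 = make_junction("S1", "chr1", 100, "+", "chr1", 200_000, "-")
        j2 = make_junction("S2", "chr1", 100, "+", "chr1", 200_000, "-")
        with pytest.raises(ValueError, match="multiple samples"):
            cluster_junctions([j1, j2])


def _singleton(j):
    (cluster,) = cluster_junctions([j])
    return cluster


class TestClassification:
    def test_singleton_del(self):
        j = make_junction("S", "chr2", 10_000_000, "+", "chr2", 10_030_000, "-")
        labeled = classify_cluster(_singleton(j), [])
        assert labeled.labels == {"deletion"}
        assert j.length == 30_000

    def test_reciprocal_inversion_pair(self):
        j1 = make_junction("S", "chr3", 5_000_000, "+", "chr3", 8_000_000, "+",
                           svtype="INV")
        j2 = make_junction("S", "chr3", 5_002_000, "-", "chr3", 8_001_000, "-",
                           svtype="INV")
        (cluster,) = cluster_junctions([j1, j2])
        assert classify_cluster(cluster, []).labels == {"reciprocal"}

    def test_same_orientation_invs_not_reciprocal(self):
        j1 = make_junction("S", "chr3", 5_000_000, "+", "chr3", 8_000_000, "+",
                           svtype="INV")
        j2 = make_junction("S", "chr3", 5_002_000, "+", "chr3", 8_001_000, "+",
                           svtype="INV")
        (cluster,) = cluster_junctions([j1, j2])
        assert "reciprocal" not in classify_cluster(cluster, []).labels

    def test_unbalanced_translocation_needs_cn_step(self):
        j = make_junction("S", "chr1", 40_000_000, "+", "chr9", 60_000_000, "-")
        segs = [
            CopyNumberSegment("S", "chr1", 0, 40_000_000, 3.0),
            CopyNumberSegment("S", "chr1", 40_000_000, 100_000_000, 2.0),
        ]
        assert classify_cluster(_singleton(j), segs).labels == {
            "unbalanced_translocation"
        }
        flat = [CopyNumberSegment("S", "chr1", 0, 100_000_000, 2.0)]
        labeled = classify_cluster(_singleton(j), flat)
        assert labeled.labels == frozenset() and labeled.cn_unavailable

    def test_insertion_pair_topology(self):
        # 20 kb donor on chr1 re-joined on chr2
        j1 = make_junction("S", "chr1", 10_000_000, "+", "chr2", 50_000_000, "-")
        j2 = make_junction("S", "chr1", 10_020_000, "-", "chr2", 50_000_500, "+")
        (cluster,) = cluster_junctions([j1, j2])
        assert classify_cluster(cluster, []).labels == {"insertion"}

    def test_line_flag_overrides_deletion(self):
        j = make_junction("S", "chr1", 1_000_000, "+", "chr1", 1_006_000, "-",
                          flags={"LINE"})
        labels = classify_cluster(_singleton(j), []).labels
        assert "LINE" in labels and "deletion" not in labels


class TestCompactSparse:
    def test_small_footprint_compact(self):
        j = make_junction("S", "chr1", 1_000_000, "+", "chr1", 3_000_000, "-")
        assert compact_or_sparse(_singleton(j)) == "compact"

    def test_large_footprint_sparse(self):
        j1 = make_junction("S", "chr1", 1_000_000, "+", "chr1", 1_004_000, "-")
        j2 = make_junction("S", "chr1", 1_002_000, "+", "chr1", 41_000_000, "-")
        (cluster,) = cluster_junctions([j1, j2])
        assert compact_or_sparse(cluster) == "sparse"

    def test_per_chromosome_rule_inter(self):
        # 1 Mb footprint on each chromosome: compact despite crossing genomes
        j1 = make_junction("S", "chr1", 1_000_000, "+", "chr19", 5_000_000, "-")
        j2 = make_junction("S", "chr1", 1_004_000, "+", "chr19", 5_004_000, "-")
        j3 = make_junction("S", "chr1", 2_000_000, "+", "chr19", 6_000_000, "-")
        cluster = cluster_junctions([j1, j2, j3])
        merged = max(cluster, key=lambda c: len(c.junctions))
        spans = {c: hi - lo for c, (lo, hi) in merged.footprint.items()}
        assert all(s <= 5_000_000 for s in spans.values())
        assert compact_or_sparse(merged) == "compact"


def _oscillating_chromosome(sample, chrom, n_segments, cn_states=(2.0, 3.0),
                            start=10_000_000, width=400_000):
    segs = []
    for i in range(n_segments):
        segs.append(
            CopyNumberSegment(sample, chrom, start + i * width,
                             start + (i + 1) * width, cn_states[i % 2])
        )
    return segs


def _clustered_junctions(sample, chrom, n, start=10_000_000, spacing=400_000):
    juncs = []
    for i in range(n):
        juncs.append(
            make_junction(sample, chrom, start + i * spacing + 100, "+",
                          chrom, start + (i + 1) * spacing - 100, "+",
                          svtype="INV")
        )
    return juncs


class TestChromothripsisLike:
    def test_oscillation_plus_cluster_flags(self):
        segs = _oscillating_chromosome("S", "chr5", 12)
        juncs = _clustered_junctions("S", "chr5", 8)
        flags = detect_chromothripsis_like(segs, juncs)
        assert flags["chr5"]

    def test_no_junctions_no_flag(self):
        segs = _oscillating_chromosome("S", "chr5", 12)
        assert not detect_chromothripsis_like(segs, []).get("chr5", False)

    def test_too_few_junctions_no_flag(self):
        segs = _oscillating_chromosome("S", "chr5", 12)
        juncs = _clustered_junctions("S", "chr5", 3)
        assert not detect_chromothripsis_like(segs, juncs)["chr5"]

    def test_oscillation_elsewhere_not_flagged(self):
        # junctions on chr5 but the oscillating run is far outside the footprint
        segs = _oscillating_chromosome("S", "chr5", 12, start=80_000_000)
        juncs = _clustered_junctions("S", "chr5", 8, start=1_000_000)
        segs += [CopyNumberSegment("S", "chr5", 0, 80_000_000, 2.0)]
        assert not detect_chromothripsis_like(segs, juncs)["chr5"]


class TestFeatureCounts:
    def test_no_junctions_all_zero(self):
        counts = sv_feature_counts("S", [], [])
        assert counts.n_clusters == 0 and counts.simple == 0
        assert counts.deletion_lengths == []

    def test_single_del_bookkeeping(self):
        j = make_junction("S", "chr1", 1_000_000, "+", "chr1", 1_030_000, "-")
        counts = sv_feature_counts("S", [j], [])
        assert (counts.simple, counts.intra, counts.compact) == (1, 1, 1)
        assert counts.deletion_lengths == [30_000]
        assert counts.inter == counts.sparse == 0

    def test_hand_tallied_seven_junction_fixture(self):
        juncs = [
            # two singleton DELs
            make_junction("S", "chr1", 1_000_000, "+", "chr1", 1_030_000, "-"),
            make_junction("S", "chr2", 5_000_000, "+", "chr2", 5_100_000, "-"),
            # reciprocal INV pair
            make_junction("S", "chr3", 5_000_000, "+", "chr3", 8_000_000, "+",
                          svtype="INV"),
            make_junction("S", "chr3", 5_002_000, "-", "chr3", 8_001_000, "-",
                          svtype="INV"),
            # unbalanced TRA with a CN step on chr1
            make_junction("S", "chr1", 40_000_000, "+", "chr9", 60_000_000, "-"),
            # complex trio (chained within proximity on chr4)
            make_junction("S", "chr4", 10_000_000, "+", "chr4", 10_001_000, "+",
                          svtype="INV"),
            make_junction("S", "chr4", 10_001_500, "-", "chr4", 10_002_500, "-",
                          svtype="INV"),
            make_junction("S", "chr4", 10_002_000, "+", "chr4", 10_003_000, "+",
                          svtype="INV"),
        ]
        segs = [
            CopyNumberSegment("S", "chr1", 0, 40_000_000, 3.0),
            CopyNumberSegment("S", "chr1", 40_000_000, 100_000_000, 2.0),
        ]
        counts = sv_feature_counts("S", juncs, segs)
        assert counts.simple == 3  # 2 DELs + 1 unbalanced TRA
        assert counts.complex == 1
        assert counts.inter == 1
        assert counts.intra == 4
        assert counts.reciprocal == 1
        assert counts.unbalanced_translocation == 1
        assert counts.compact + counts.sparse == counts.n_clusters == 5

    def test_partitions_sum_to_total(self):
        rng = np.random.default_rng(3)
        juncs = random_junctions(rng, 40)
        counts = sv_feature_counts("S", juncs, [])
        assert counts.intra + counts.inter == counts.n_clusters
        assert counts.compact + counts.sparse == counts.n_clusters

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        juncs = random_junctions(rng, 25)
        a = sv_feature_counts("S", juncs, [])
        b = sv_feature_counts("S", list(reversed(juncs)), [])
        assert a == b


class TestBreakpointDensity:
    def test_direct_binning(self, toy_genome):
        j = make_junction("S", "chr1", 100_000, "+", "chr1", 700_000, "-")
        df = breakpoint_density([j], toy_genome, bin_size=500_000)
        chr1 = df[df.chrom == "chr1"].set_index("bin_start")["count"]
        assert chr1[0] == 1 and chr1[500_000] == 1
        assert df["count"].sum() == 2

    def test_empty_input_zero_vector(self, toy_genome):
        df = breakpoint_density([], toy_genome)
        assert (df["count"] == 0).all()

    def test_conservation_property(self, toy_genome):
        rng = np.random.default_rng(11)
        juncs = random_junctions(rng, 50)
        df = breakpoint_density(juncs, toy_genome)
        assert df["count"].sum() == 2 * len(juncs)

    def test_out_of_range_breakend_rejected(self, toy_genome):
        j = make_junction("S", "chr1", 100, "+", "chr1", 200_000_000, "-")
        with pytest.raises(ValueError, match="beyond chromosome length"):
            breakpoint_density([j], toy_genome)
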