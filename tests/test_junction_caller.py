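"""Junction calling, the coverage/replicate filter and the 10-nt merge."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bhbscan import (
    FilteredJunction,
    JunctionCluster,
    JunctionObservation,
    call_junctions,
    filter_junctions,
    intron_from_cluster,
    map_split_reads,
    merge_junctions,
    observations_from_sam,
)
from bhbscan.junction_caller import Segment, SplitAlignment

from conftest import oracle_filter, oracle_single_linkage


def _split(read_id, segs, strand="+"):
    q = 0
    out = []
    for a, b in segs:
        ln = b - a + 1
        out.append(Segment(a, b, strand, q, q + ln))
        q += ln
    return SplitAlignment(read_id, "split", out)


# ---------------------------------------------------------------------------
# mapping


class TestMapSplitReads:
    def test_contiguous_read_is_unsplit(self):
        rng = np.random.default_rng(1)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 800))
        read = genome[100:160]
        (aln,) = map_split_reads([("r1", read)], genome)
        assert aln.status == "unsplit"
        assert (aln.segments[0].ref_start, aln.segments[0].ref_end) == (101, 160)

    def test_random_read_unmapped(self):
        rng = np.random.default_rng(0)
        genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 2000))
        read = "".join("ACGT"[i] for i in rng.integers(0, 4, 60))
        (aln,) = map_split_reads([("r1", read)], genome)
        assert aln.status == "unmapped"

    def test_back_junction_read_splits_downstream_first(self, single_locus_world):
        genome, truth, _ = single_locus_world
        t = truth.loci[0]
        circle = genome[t.intron_start - 1 : t.intron_end]
        read = circle[-30:] + circle[:30]  # crosses the ligation point
        (aln,) = map_split_reads([("r1", read)], genome)
        assert aln.status == "split"
        s1, s2 = aln.segments
        assert s1.ref_end == t.intron_end  # downstream genome segment first
        assert s2.ref_start == t.intron_start

    def test_reverse_strand_read_maps(self, single_locus_world):
        genome, _, _ = single_locus_world
        from bhbscan.bhb_detector import reverse_complement

        read = reverse_complement(genome[500:560])
        (aln,) = map_split_reads([("r1", read)], genome)
        assert aln.status == "unsplit"
        assert aln.segments[0].strand == "-"
        assert aln.segments[0].ref_start == 501

    def test_empty_genome_raises(self):
        with pytest.raises(ValueError):
            map_split_reads([("r1", "ACGT" * 10)], "")


# ---------------------------------------------------------------------------
# calling


class TestCallJunctions:
    def test_genomically_ordered_segments_give_linear(self):
        aln = _split("r1", [(100, 150), (200, 250)])
        (obs,) = call_junctions([aln])
        assert (obs.left_site, obs.right_site, obs.topology) == (150, 199, "linear")

    def test_reversed_segments_give_circular(self):
        aln = _split("r1", [(200, 250), (100, 150)])
        (obs,) = call_junctions([aln])
        assert (obs.left_site, obs.right_site, obs.topology) == (99, 250, "circular")
        assert obs.right_site - obs.left_site == 250 - 100 + 1

    def test_unsplit_alignments_give_no_junctions(self):
        alns = [SplitAlignment("r1", "unsplit", [Segment(1, 60, "+", 0, 60)]),
                SplitAlignment("r2", "unmapped", [])]
        assert call_junctions(alns) == []

    def test_three_segment_reads_are_skipped(self, caplog):
        aln = _split("r1", [(100, 130), (200, 230), (300, 330)])
        with caplog.at_level("WARNING", logger="bhbscan.junction_caller"):
            assert call_junctions([aln]) == []
        assert "skipped 1" in caplog.text

    def test_minus_strand_symmetric(self):
        # '-' strand: read order is the reverse of genome-forward order
        plus = _split("r1", [(200, 250), (100, 150)], strand="+")
        minus = _split("r2", [(100, 150), (200, 250)], strand="-")
        (o1,) = call_junctions([plus])
        (o2,) = call_junctions([minus])
        assert (o1.left_site, o1.right_site, o1.topology) == (
            o2.left_site, o2.right_site, o2.topology,
        )


def test_observations_from_sam(tmp_path, single_locus_world):
    genome, truth, _ = single_locus_world
    t = truth.loci[0]
    s, e = t.intron_start, t.intron_end
    # chimeric back-junction read: 40 nt from the intron 3' end, then 35 nt
    # from the intron 5' start; plus one spliced (N-gap) linear read.
    circle = genome[s - 1 : e]
    read = circle[-40:] + circle[:35]
    lines = [
        "@HD\tVN:1.6\tSO:unsorted",
        "@SQ\tSN:synth1\tLN:%d" % len(genome),
        "\t".join([
            "bj1", "0", "synth1", str(e - 40 + 1), "60", "40M35S", "*", "0", "0",
            read, "I" * 75, f"SA:Z:synth1,{s},+,40S35M,60,0;",
        ]),
        "\t".join([
            "bj1", "2048", "synth1", str(s), "60", "40S35M", "*", "0", "0",
            read, "I" * 75, f"SA:Z:synth1,{e - 40 + 1},+,40M35S,60,0;",
        ]),
        "\t".join([
            "lin1", "0", "synth1", "101", "60", "30M100N30M", "*", "0", "0",
            genome[100:130] + genome[230:260], "I" * 60,
        ]),
    ]
    sam = tmp_path / "reads.sam"
    sam.write_text("\n".join(lines) + "\n")
    obs = observations_from_sam(sam, replicate_id=1)
    by_topo = {o.topology: o for o in obs}
    assert by_topo["circular"].left_site == t.left_site
    assert by_topo["circular"].right_site == t.right_site
    assert (by_topo["linear"].left_site, by_topo["linear"].right_site) == (130, 230)


# ---------------------------------------------------------------------------
# filtering


def _obs(left, right, rep, topo="circular", rid="r"):
    return JunctionObservation(left, right, rep, topo, rid)


class TestFilterJunctions:
    @pytest.mark.parametrize(
        "coverage,kept",
        [((3, 2, 5), True), ((2, 2, 2), True), ((3, 0, 5), False), ((1, 2, 2), False)],
    )
    def test_coverage_rule(self, coverage, kept):
        obs = [
            _obs(100, 200, rep, rid=f"r{rep}.{i}")
            for rep, c in enumerate(coverage, start=1)
            for i in range(c)
        ]
        # ensure all three replicates are represented in the pool
        obs += [_obs(900, 990, rep) for rep in (1, 2, 3)]
        got = {(j.left_site, j.right_site) for j in filter_junctions(obs)}
        assert ((100, 200) in got) is kept

    def test_lax_reading_flag(self):
        obs = [_obs(100, 200, 1), _obs(100, 200, 1), _obs(100, 200, 2), _obs(100, 200, 3)]
        assert filter_junctions(obs, min_coverage=2) == []
        lax = filter_junctions(obs, min_coverage=2, require_per_replicate=False)
        assert len(lax) == 1 and lax[0].coverage_per_replicate == (2, 1, 1)

    def test_missing_replicates_raise(self):
        obs = [_obs(100, 200, 1), _obs(100, 200, 2)]
        with pytest.raises(ValueError, match="replicates present"):
            filter_junctions(obs, n_replicates=3)

    def test_brute_force_equivalence_on_random_coverage_vectors(self):
        """1,000 random coverage vectors re-filtered by direct rule
        application must agree with the implementation."""
        rng = np.random.default_rng(42)
        for _ in range(1000 // 50):
            junctions = {}
            obs = []
            for k in range(50):
                left = int(rng.integers(1, 10000))
                right = left + int(rng.integers(20, 500))
                cov = tuple(int(c) for c in rng.integers(0, 4, 3))
                junctions[(left, right)] = cov
                for rep, c in enumerate(cov, start=1):
                    obs.extend(_obs(left, right, rep, rid=f"{k}.{rep}.{i}") for i in range(c))
            if not all(any(c[r] for c in junctions.values()) for r in range(3)):
                continue
            got = sorted((j.left_site, j.right_site) for j in filter_junctions(obs))
            want = oracle_filter(junctions, min_coverage=2, n_replicates=3)
            assert got == want

    @given(
        st.lists(
            st.tuples(st.integers(0, 6), st.integers(0, 6), st.integers(0, 6)),
            min_size=1, max_size=20,
        ),
        st.integers(1, 4),
    )
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_raising_min_coverage_is_monotone(self, covs, min_cov):
        obs = []
        for k, cov in enumerate(covs):
            left = 100 * (k + 1)
            for rep, c in enumerate(cov, start=1):
                obs.extend(_obs(left, left + 50, rep, rid=f"{k}.{rep}.{i}") for i in range(max(c, 1)))
        lo = filter_junctions(obs, min_coverage=min_cov)
        hi = filter_junctions(obs, min_coverage=min_cov + 1)
        assert {(j.left_site, j.right_site) for j in hi} <= {
            (j.left_site, j.right_site) for j in lo
        }


# ---------------------------------------------------------------------------
# merging


def _fj(left, right, cov=(2, 2, 2), topo="circular"):
    return FilteredJunction(left, right, topo, "+", tuple(cov))


class TestMergeJunctions:
    @pytest.mark.parametrize("dleft,n_clusters", [(10, 1), (11, 2)])
    def test_distance_boundary(self, dleft, n_clusters):
        junctions = [_fj(100, 300), _fj(100 + dleft, 300)]
        assert len(merge_junctions(junctions, max_dist=10)) == n_clusters

    def test_singleton(self):
        (cl,) = merge_junctions([_fj(100, 300)])
        assert (cl.representative_left, cl.representative_right) == (100, 300)
        assert cl.members == [(100, 300)]

    def test_topologies_do_not_merge(self):
        junctions = [_fj(100, 300, topo="circular"), _fj(101, 300, topo="linear")]
        assert len(merge_junctions(junctions)) == 2

    def test_representative_is_highest_coverage_member(self):
        junctions = [_fj(100, 300, cov=(2, 2, 2)), _fj(103, 301, cov=(5, 5, 5))]
        (cl,) = merge_junctions(junctions)
        assert (cl.representative_left, cl.representative_right) == (103, 301)
        assert cl.coverage_per_replicate == (7, 7, 7)

    def test_coverage_conservation_and_disjoint_membership(self):
        rng = np.random.default_rng(3)
        junctions = [
            _fj(int(rng.integers(1, 2000)), int(rng.integers(2100, 4000)),
                cov=tuple(int(c) for c in rng.integers(2, 6, 3)))
            for _ in range(60)
        ]
        clusters = merge_junctions(junctions, max_dist=10)
        assert sum(len(c.members) for c in clusters) == len(junctions)
        total_in = sum(j.total_coverage for j in junctions)
        total_out = sum(sum(c.coverage_per_replicate) for c in clusters)
        assert total_in == total_out

    def test_jittered_junctions_recover_three_clusters(self):
        """50 jittered copies of 3 true junctions (jitter <= 5) collapse to
        3 clusters whose representatives are the max-coverage members;
        grouping matches the O(n^2) single-linkage oracle."""
        rng = np.random.default_rng(11)
        true = [(1000, 1200), (5000, 5600), (9000, 9999)]
        junctions = []
        for tl, tr in true:
            junctions.append(_fj(tl, tr, cov=(9, 9, 9)))  # dominant member
            for _ in range(49):
                junctions.append(
                    _fj(tl + int(rng.integers(-5, 6)), tr + int(rng.integers(-5, 6)),
                        cov=(2, 2, 2))
                )
        clusters = merge_junctions(junctions, max_dist=10)
        assert len(clusters) == 3
        assert sorted(
            (c.representative_left, c.representative_right) for c in clusters
        ) == sorted(true)
        points = [(j.left_site, j.right_site) for j in junctions]
        oracle = oracle_single_linkage(points, max_dist=10)
        assert sorted(len(g) for g in oracle) == sorted(len(c.members) for c in clusters)

    def test_matches_brute_force_single_linkage_on_random_instances(self):
        rng = np.random.default_rng(21)
        for _ in range(25):
            n = int(rng.integers(2, 40))
            junctions = [
                _fj(int(rng.integers(0, 300)), 1000 + int(rng.integers(0, 300)))
                for _ in range(n)
            ]
            for d in (0, 3, 10):
                got = merge_junctions(junctions, max_dist=d)
                points = [(j.left_site, j.right_site) for j in junctions]
                want = oracle_single_linkage(points, max_dist=d)
                assert sorted(len(g) for g in want) == sorted(len(c.members) for c in got)

    @given(st.data())
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_raising_max_dist_never_increases_cluster_count(self, data):
        n = data.draw(st.integers(1, 25))
        junctions = [
            _fj(data.draw(st.integers(0, 200)), 500 + data.draw(st.integers(0, 200)))
            for _ in range(n)
        ]
        d = data.draw(st.integers(0, 15))
        assert len(merge_junctions(junctions, max_dist=d + 1)) <= len(
            merge_junctions(junctions, max_dist=d)
        )


# ---------------------------------------------------------------------------
# intron conversion


class TestIntronFromCluster:
    @pytest.mark.parametrize(
        "left,right,length",
        [
            (1_195_172, 1_195_218, 46),
            (2_384_876, 2_384_951, 75),
            (1_165_777, 1_165_880, 103),
            (1_598_083, 1_599_741, 1658),
            (1_600_017, 1_602_996, 2979),
            (2_766_828, 2_769_808, 2980),
            (7, 8, 1),
        ],
    )
    def test_length_is_right_minus_left(self, left, right, length):
        cl = JunctionCluster(left, right, [(left, right)], (2, 2, 2), "circular")
        rec = intron_from_cluster(cl)
        assert rec.length == length
        assert (rec.start, rec.end) == (left + 1, right)

    def test_non_positive_length_raises(self):
        cl = JunctionCluster(10, 10, [(10, 10)], (2, 2, 2), "circular")
        with pytest.raises(ValueError):
            intron_from_cluster(cl)
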