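"""Adjacencies, transition-zone grammar, chimeric breakpoints, cassettes."""

import numpy as np
import pytest

from satarch.annotate import MonomerHit, SatFamily
from satarch.arrays import SatArray, build_arrays
from satarch.core_io import GenomeSequence, Interval
from satarch.junctions import (cassette_census, classify_transitions,
                               detect_chimeric_breakpoint, extract_junction,
                               find_adjacencies, flank_similarity,
                               nearest_family_distance, refine_edge)
from satarch.simulate import mutate_copy, random_dna
from satarch.symmetry import InversionPoint


def _array(family, start, end, contig="c1"):
    hit = MonomerHit(family, Interval(contig, start, end, "+"),
                     95.0, 100.0, 100.0)
    return SatArray(family, Interval(contig, start, end, "."), [hit])


class TestAdjacency:
    def test_basic_pair_and_gap(self):
        arrays = [_array("A", 0, 10_000), _array("B", 10_100, 12_000)]
        adj = find_adjacencies(arrays, "A", "B")
        assert len(adj) == 1
        assert adj[0].gap == 100
        assert adj[0].left.family_id == "A"

    def test_gap_above_bound_excluded(self):
        arrays = [_array("A", 0, 1000), _array("B", 3001, 4000)]
        assert find_adjacencies(arrays, "A", "B", max_gap=1000) == []

    def test_intervening_array_blocks_adjacency(self):
        arrays = [_array("A", 0, 1000), _array("C", 1100, 1200),
                  _array("B", 1300, 2000)]
        assert find_adjacencies(arrays, "A", "B") == []

    def test_alternating_pattern_counts_junctions(self):
        arrays = []
        pos = 0
        for i in range(6):
            fam = "A" if i % 2 == 0 else "B"
            arrays.append(_array(fam, pos, pos + 1000))
            pos += 1500
        adj = find_adjacencies(arrays, "A", "B")
        assert len(adj) == 5

    def test_unknown_family_rejected(self):
        with pytest.raises(KeyError):
            find_adjacencies([_array("A", 0, 10)], "A", "Ghost")


class TestExtractJunction:
    def test_window_coordinates(self, rng):
        seq = random_dna(20_000, 0.5, rng)
        genome = [GenomeSequence("c1", seq)]
        arrays = [_array("A", 1000, 5000), _array("B", 5300, 9000)]
        adj = find_adjacencies(arrays, "A", "B")[0]
        rec = extract_junction(genome, adj, pad=250)
        assert (rec.interval.start, rec.interval.end) == (4750, 5550)
        assert rec.sequence == seq[4750:5550]
        assert not rec.truncated

    def test_pad_exceeding_array_truncated(self, rng):
        seq = random_dna(3_000, 0.5, rng)
        genome = [GenomeSequence("c1", seq)]
        arrays = [_array("A", 100, 200), _array("B", 250, 2000)]
        adj = find_adjacencies(arrays, "A", "B")[0]
        rec = extract_junction(genome, adj, pad=250)
        assert rec.truncated
        assert rec.interval.start == 100  # pad clipped to array length


class TestClassifyTransitions:
    def test_identical_junctions_single_cluster(self):
        clusters = classify_transitions(["ACGTAC" * 50] * 8)
        assert len(clusters) == 1
        assert clusters[0].prevalence == pytest.approx(1.0)

    def test_two_types_with_prevalences(self, rng):
        t1 = random_dna(400, 0.6, rng)
        t2 = random_dna(400, 0.6, rng)
        junctions = ([mutate_copy(t1, 0.02, rng) for _ in range(6)]
                     + [mutate_copy(t2, 0.02, rng) for _ in range(4)])
        clusters = classify_transitions(junctions, identity_threshold=90.0)
        assert [c.size for c in clusters] == [6, 4]
        assert clusters[0].prevalence == pytest.approx(0.6)

    def test_equals_component_oracle(self, rng):
        from satarch import align
        import networkx as nx
        seqs = []
        for template in (random_dna(200, 0.6, rng) for _ in range(3)):
            seqs.extend(mutate_copy(template, 0.03, rng) for _ in range(4))
        clusters = classify_transitions(seqs, identity_threshold=90.0)
        g = nx.Graph()
        g.add_nodes_from(range(len(seqs)))
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                if align.global_identity(seqs[i], seqs[j]) >= 90.0:
                    g.add_edge(i, j)
        expected = sorted((sorted(c) for c in nx.connected_components(g)),
                          key=lambda c: (-len(c), c[0]))
        assert [sorted(c.member_indices) for c in clusters] == expected


class TestChimericBreakpoint:
    def test_clean_splice(self, rng):
        a = random_dna(300, 0.6, rng)
        b = random_dna(300, 0.6, rng)
        res = detect_chimeric_breakpoint(a + b, a, b)
        assert res.breakpoint_offset is not None
        assert abs(res.breakpoint_offset - 300) <= 2
        assert res.duplicated_motif == ""
        assert not res.unclassified

    def test_duplicated_motif_at_breakpoint(self, rng):
        motif = "TTCAAT"
        a = random_dna(150, 0.6, rng) + motif          # donor a ends with it
        b = motif + random_dna(150, 0.6, rng)          # donor b starts with it
        junction = a + b  # motif duplicated across the splice
        res = detect_chimeric_breakpoint(junction, a, b)
        assert res.duplicated_motif == motif
        assert not res.unclassified

    def test_planted_deletion_length(self, rng):
        donor = random_dna(500, 0.6, rng)
        prefix = donor[:200] + donor[260:440]  # 60 bp deletion inside
        b = random_dna(300, 0.6, rng)
        res = detect_chimeric_breakpoint(prefix + b, donor, b)
        assert abs(res.deletion_length - 60) <= 2

    def test_unrelated_junction_unclassified(self, rng):
        res = detect_chimeric_breakpoint(random_dna(200, 0.5, rng),
                                         random_dna(200, 0.5, rng),
                                         random_dna(200, 0.5, rng))
        assert res.unclassified


class TestRefineEdge:
    def test_exact_copies_threshold_one_exact_edge(self, rng):
        fam = SatFamily("F", random_dna(120, 0.6, rng))
        edge = 2000 + 5 * 120
        seq = (random_dna(2_000, 0.5, rng) + fam.consensus * 5
               + random_dna(2_000, 0.5, rng))
        genome = [GenomeSequence("c1", seq)]
        arrays = build_arrays(
            [MonomerHit("F", Interval("c1", 2000 + i * 120,
                                      2000 + (i + 1) * 120, "+"),
                        100.0, 100.0, 100.0) for i in range(5)], [fam])
        refined = refine_edge(genome, arrays[0], fam, threshold=1.0,
                              side="right")
        assert refined == edge

    def test_random_background_edge_within_k(self, rng):
        fam = SatFamily("F", random_dna(120, 0.6, rng))
        copies = "".join(mutate_copy(fam.consensus, 0.03, rng)
                         for _ in range(5))
        seq = random_dna(2_000, 0.5, rng) + copies + random_dna(2_000, 0.5, rng)
        genome = [GenomeSequence("c1", seq)]
        arrays = build_arrays(
            [MonomerHit("F", Interval("c1", 2000 + i * 120,
                                      2000 + (i + 1) * 120, "+"),
                        97.0, 100.0, 100.0) for i in range(5)], [fam])
        for side, true_edge in (("right", 2000 + 600), ("left", 2000)):
            refined = refine_edge(genome, arrays[0], fam, k=12,
                                  threshold=0.5, side=side)
            assert abs(refined - true_edge) <= 12

    def test_edge_pushed_through_homogeneous_region(self, rng):
        fam = SatFamily("F", random_dna(120, 0.6, rng))
        # array annotation covers 3 copies but 5 are present
        seq = (random_dna(1_000, 0.5, rng) + fam.consensus * 5
               + random_dna(1_000, 0.5, rng))
        genome = [GenomeSequence("c1", seq)]
        arrays = build_arrays(
            [MonomerHit("F", Interval("c1", 1000 + i * 120,
                                      1000 + (i + 1) * 120, "+"),
                        100.0, 100.0, 100.0) for i in range(3)], [fam])
        refined = refine_edge(genome, arrays[0], fam, threshold=1.0,
                              side="right", max_extension=400)
        assert refined > 1000 + 3 * 120


class TestCassetteCensus:
    def _setup(self):
        minor = [_array("B", 1000, 3000), _array("B", 10_000, 12_000)]
        points = [InversionPoint("c1", 2000, "+", "-")]
        return minor, points

    def test_triple_and_partial_cells(self):
        from satarch.junctions import Adjacency, JunctionRecord
        minor, points = self._setup()
        major = [_array("A", 0, 900), _array("A", 3100, 4000)]
        recs = []
        for adj, label in (
                (Adjacency(major[0], minor[0], 100, "a_left"), "TRANSc1"),
                (Adjacency(minor[0], major[1], 100, "b_left"), "TRANSc2")):
            rec = JunctionRecord(adj, Interval("c1", 0, 1), "")
            rec.cluster_label = label
            recs.append(rec)
        type_map = {"TRANSc1": "TRANS_1", "TRANSc2": "TRANS_2"}
        report = cassette_census(minor, recs, type_map, points)
        assert report.n_arrays == 2
        assert report.venn["T1&T2&INV"] == 1  # first array: both + inversion
        assert report.venn["none"] == 1       # second array: nothing
        assert sum(report.venn.values()) == report.n_arrays

    def test_missing_inversion_counts_in_pair_region(self):
        from satarch.junctions import Adjacency, JunctionRecord
        minor = [_array("B", 1000, 3000)]
        major = [_array("A", 0, 900), _array("A", 3100, 4000)]
        recs = []
        for adj, label in (
                (Adjacency(major[0], minor[0], 100, "a_left"), "TRANSc1"),
                (Adjacency(minor[0], major[1], 100, "b_left"), "TRANSc2")):
            rec = JunctionRecord(adj, Interval("c1", 0, 1), "")
            rec.cluster_label = label
            recs.append(rec)
        report = cassette_census(minor, recs,
                                 {"TRANSc1": "TRANS_1", "TRANSc2": "TRANS_2"},
                                 [])
        assert report.venn["T1&T2"] == 1
        assert report.triple_count == 0


class TestFlankAndProximity:
    def test_identical_flanks_full_identity(self, rng):
        unit = random_dna(500, 0.6, rng)
        filler = random_dna(1_000, 0.6, rng)
        seq = unit + filler + unit + filler + unit
        genome = [GenomeSequence("c1", seq)]
        arrays = [_array("A", 500, 1500), _array("A", 2000, 3000)]
        fs = flank_similarity(arrays, genome, flank=500)
        assert np.allclose(np.diag(fs.matrix), 100.0)
        assert np.allclose(fs.matrix, fs.matrix.T)
        # both upstream flanks equal `unit`
        up = [i for i, l in enumerate(fs.labels) if l.endswith(":up")]
        assert fs.matrix[up[0], up[1]] == pytest.approx(100.0)

    def test_nearest_family_distance(self):
        xs = [_array("X", 100, 200), _array("X", 5_000, 6_000)]
        ys = [_array("Y", 300, 400), _array("Y", 5_500, 5_600)]
        df = nearest_family_distance(xs, ys)
        assert list(df["nearest_distance"]) == [100.0, 0.0]

    def test_no_neighbor_row(self):
        xs = [_array("X", 0, 10, contig="c2")]
        ys = [_array("Y", 0, 10, contig="c1")]
        df = nearest_family_distance(xs, ys)
        assert np.isnan(df["nearest_distance"].iloc[0])

    def test_exhaustive_distance_oracle(self, rng):
        xs = [_array("X", int(s), int(s) + 100)
              for s in rng.integers(0, 50_000, size=20)]
        ys = [_array("Y", int(s), int(s) + 100)
              for s in rng.integers(0, 50_000, size=20)]
        df = nearest_family_distance(xs, ys)
        for _, row in df.iterrows():
            q = Interval("c1", int(row["start"]), int(row["end"]))
            expected = min(q.gap_to(y.interval) for y in ys)
            assert row["nearest_distance"] == expected
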