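"""K-mer scanning with bounded edit distance; F81 geometry, PCA, k-NN."""

import itertools
import math
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from satarch import comparative as comp
from satarch.core_io import GenomeSequence, revcomp
from satarch.simulate import mutate_copy, random_dna

DNA = st.text(alphabet="ACGT", min_size=0, max_size=30)


class TestKmerize:
    def test_single_kmer_plus_reverse(self):
        ks = comp.kmerize("ACGTTGCAGGTACGAT", 16)
        assert len(ks) == 2  # forward + distinct reverse complement

    def test_palindromic_collapses(self):
        seq = "ACGT" * 4
        assert revcomp(seq) == seq
        assert len(comp.kmerize(seq, 16)) == 1

    def test_count_matches_enumeration(self, rng):
        seq = random_dna(60, 0.5, rng)
        ks = comp.kmerize(seq, 16)
        expected = {seq[i:i + 16] for i in range(45)}
        rc = revcomp(seq)
        expected |= {rc[i:i + 16] for i in range(45)}
        assert ks.kmers == frozenset(expected)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            comp.kmerize("ACGT", 16)


class TestEditDistance:
    def test_examples(self):
        assert comp.edit_distance("ACGT", "ACGT") == 0
        assert comp.edit_distance("ACGT", "ACGA") == 1
        assert comp.edit_distance("", "ACG") == 3

    def test_full_dp_oracle(self, rng):
        def dp(a, b):
            m, n = len(a), len(b)
            d = [[0] * (n + 1) for _ in range(m + 1)]
            for i in range(m + 1):
                d[i][0] = i
            for j in range(n + 1):
                d[0][j] = j
            for i in range(1, m + 1):
                for j in range(1, n + 1):
                    d[i][j] = min(d[i - 1][j] + 1, d[i][j - 1] + 1,
                                  d[i - 1][j - 1] + (a[i - 1] != b[j - 1]))
            return d[m][n]

        for _ in range(200):
            a = random_dna(int(rng.integers(0, 25)) + 1, 0.5, rng)
            b = random_dna(int(rng.integers(0, 25)) + 1, 0.5, rng)
            assert comp.edit_distance(a, b) == dp(a, b)

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(DNA, DNA, DNA)
    def test_metric_properties(self, a, b, c):
        dab = comp.edit_distance(a, b)
        assert dab == comp.edit_distance(b, a)
        assert dab <= comp.edit_distance(a, c) + comp.edit_distance(c, b)
        assert (dab == 0) == (a == b)


def _semi_global_oracle(pat, text, maxd):
    """Distances of the pattern vs every window ending at each position."""
    m, n = len(pat), len(text)
    prev = [0] * (n + 1)
    rows = [prev]
    for i in range(1, m + 1):
        cur = [i] * (n + 1)
        for j in range(1, n + 1):
            cur[j] = min(rows[i - 1][j] + 1, cur[j - 1] + 1,
                         rows[i - 1][j - 1] + (pat[i - 1] != text[j - 1]))
        rows.append(cur)
    return [(j, rows[m][j]) for j in range(1, n + 1) if rows[m][j] <= maxd]


class TestApproxScan:
    def test_exact_match_found_with_zero_distance(self, rng):
        kmer = "ACGTTGCAGGTACGAT"
        bg = random_dna(20_000, 0.5, rng)
        genome = [GenomeSequence("c1", bg[:7000] + kmer + bg[7000:])]
        hits = comp.approx_scan(genome, comp.KmerSet(16, frozenset([kmer])), 3)
        exact = [h for h in hits if h.min_edit_distance == 0]
        assert len(exact) == 1
        assert (exact[0].interval.start, exact[0].interval.end) == (7000, 7016)

    def test_three_substitutions_found_four_not(self, rng):
        kmer = "ACGTTGCAGGTACGAT"
        three = "AAGTTGCTGGTACGAC"  # 3 substitutions
        four = "AAGTTGCTGGAACGAC"   # 4 substitutions
        pad = "G" * 3000            # background that cannot approach the kmer
        genome3 = [GenomeSequence("c1", pad + three + pad)]
        genome4 = [GenomeSequence("c1", pad + four + pad)]
        ks = comp.KmerSet(16, frozenset([kmer]))
        hits3 = comp.approx_scan(genome3, ks, 3)
        assert any(h.min_edit_distance == 3 and
                   abs(h.interval.start - 3000) <= 3 for h in hits3)
        assert comp.approx_scan(genome4, ks, 3) == []

    def test_bruteforce_dp_oracle(self, rng):
        text = random_dna(2_000, 0.5, rng)
        kmers = {random_dna(16, 0.5, rng) for _ in range(8)}
        kmers.add(text[500:516])  # guarantee one exact hit
        genome = [GenomeSequence("c1", text)]
        got = comp.approx_scan(genome, comp.KmerSet(16, frozenset(kmers)), 3)
        # oracle: per-kmer end-position distances, then the same collapse
        per_contig = []
        for pat in sorted(kmers):
            trips = [(e, d, pat)
                     for e, d in _semi_global_oracle(pat, text, 3)]
            per_contig.extend(comp._collapse(trips, 3))
        expected = comp._collapse(per_contig, 3)
        assert [(h.interval.end, h.min_edit_distance, h.source_kmer)
                for h in got] == expected

    def test_zero_distance_equals_exact_search(self, rng):
        text = random_dna(50_000, 0.5, rng)
        kmers = {text[i:i + 16] for i in (100, 9_999, 25_000, 49_980)}
        genome = [GenomeSequence("c1", text)]
        hits = comp.approx_scan(genome, comp.KmerSet(16, frozenset(kmers)), 0)
        expected_ends = set()
        for pat in kmers:
            start = 0
            while True:
                idx = text.find(pat, start)
                if idx < 0:
                    break
                expected_ends.add(idx + 16)
                start = idx + 1
        assert {h.interval.end for h in hits} == expected_ends
        assert all(h.min_edit_distance == 0 for h in hits)


class TestMergeHits:
    def test_merge_behaviour(self, rng):
        kmer = "ACGTTGCAGGTACGAT"
        bg = "G" * 2000
        seq = bg + kmer + kmer + bg  # two abutting copies
        genome = [GenomeSequence("c1", seq)]
        hits = comp.approx_scan(genome, comp.KmerSet(16, frozenset([kmer])), 0)
        regions = comp.merge_hits(hits, max_gap=16)
        assert len(regions) == 1
        assert regions[0].n_hits == len(hits)
        assert regions[0].min_edit_distance == 0


class TestMapBack:
    def test_exact_segment_coverage(self, rng):
        consensus = random_dna(120, 0.6, rng)
        profile = comp.map_back([consensus[40:80]], consensus)
        assert profile.n_mapped == 1
        cov = profile.coverage
        assert cov[40:80].min() == 1
        assert cov[:40].max() == 0 and cov[80:].max() == 0

    def test_common_segment_gives_single_peak(self, rng):
        consensus = random_dna(200, 0.6, rng)
        regions = [mutate_copy(consensus[60:90], 0.03, rng) for _ in range(12)]
        profile = comp.map_back(regions, consensus)
        assert profile.coverage[60:90].mean() > 8
        assert profile.coverage[:50].max() <= 2

    def test_decoys_counted_unmapped(self, rng):
        consensus = random_dna(200, 0.6, rng)
        decoys = [random_dna(40, 0.5, rng) for _ in range(5)]
        profile = comp.map_back(decoys, consensus, min_score=25)
        assert profile.n_unmapped == 5


class TestF81:
    def test_identical_zero(self):
        assert comp.f81_distance("ACGT" * 10, "ACGT" * 10,
                                 [0.25] * 4) == pytest.approx(0.0)

    def test_closed_form(self):
        # equal frequencies: E = 0.75, p = 0.1
        a = "A" * 90 + "C" * 10
        b = "A" * 90 + "G" * 10
        d = comp.f81_distance(a, b, [0.25] * 4)
        assert d == pytest.approx(-0.75 * math.log(1 - 0.1 / 0.75))

    def test_monotone_in_p(self):
        e = 0.75
        ds = [-e * math.log(1 - p / e) for p in np.linspace(0, 0.7, 20)]
        assert all(x < y for x, y in zip(ds, ds[1:]))

    def test_saturated_pair_flagged_infinite(self):
        d = comp.f81_distance("A" * 10, "C" * 10, [0.25] * 4)
        assert math.isinf(d)

    def test_pairwise_deletion(self):
        d = comp.f81_distance("ACGT-N", "ACGAAN", [0.25] * 4)
        # comparable columns: positions 0..3 -> p = 1/4
        assert d == pytest.approx(-0.75 * math.log(1 - 0.25 / 0.75))

    def test_no_comparable_columns_rejected(self):
        with pytest.raises(ValueError):
            comp.f81_distance("----", "AAAA", [0.25] * 4)

    def test_against_ape_dist_dna(self, rng, tmp_path):
        """Cross-check against the reference F81 implementation in R (ape)."""
        anc = random_dna(300, 0.6, rng)
        a, b = anc, mutate_copy(anc, 0.10, rng)
        ours = comp.f81_distance(a, b, comp.base_frequencies([a, b]))
        fa = tmp_path / "pair.fa"
        fa.write_text(f">a\n{a}\n>b\n{b}\n")
        r = subprocess.run(
            ["Rscript", "-e",
             f'suppressMessages(library(ape));'
             f'x<-read.dna("{fa}",format="fasta");'
             f'cat(dist.dna(x, model="F81"))'],
            capture_output=True, text=True, check=True)
        assert ours == pytest.approx(float(r.stdout.strip()), rel=1e-5)


class TestGeometry:
    def _three_family_matrix(self, rng, n_per=8):
        anc = random_dna(200, 0.6, rng)
        seqs, labels = [], []
        for i in range(3):
            fam = mutate_copy(anc, 0.30, rng)
            for j in range(n_per):
                seqs.append(mutate_copy(fam, 0.03, rng))
                labels.append(f"f{i}_{j}")
        return comp.distance_matrix(seqs, labels), labels

    def test_matrix_symmetric_zero_diagonal(self, rng):
        dm, _ = self._three_family_matrix(rng, n_per=4)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0.0)

    def test_pca_identical_sequences_at_origin(self):
        dm = comp.DistanceMatrix(["a", "b", "c"], np.zeros((3, 3)))
        emb = comp.pca_embed(dm)
        assert np.allclose(emb.coordinates, 0.0)
        assert emb.variance_fractions == (0.0, 0.0)

    def test_pca_separates_planted_families(self, rng):
        dm, labels = self._three_family_matrix(rng)
        emb = comp.pca_embed(dm)
        assert emb.variance_fractions[0] >= emb.variance_fractions[1]
        assert sum(emb.variance_fractions) <= 1.0 + 1e-9
        co = emb.coordinates
        groups = [[k for k, l in enumerate(labels)
                   if l.startswith(f"f{i}_")] for i in range(3)]
        within = max(np.linalg.norm(co[a] - co[b])
                     for g in groups
                     for a, b in itertools.combinations(g, 2))
        between = min(np.linalg.norm(co[a] - co[b])
                      for g1, g2 in itertools.combinations(groups, 2)
                      for a in g1 for b in g2)
        assert within < between

    def test_pca_needs_three_sequences(self):
        dm = comp.DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            comp.pca_embed(dm)

    def test_knn_forced_complete_graph(self, rng):
        seqs = [mutate_copy(random_dna(100, 0.6, rng), 0.02, rng)
                for _ in range(6)]
        dm = comp.distance_matrix(seqs)
        g = comp.knn_graph(dm, k=5)
        assert len(g.edges) == 15  # K6

    def test_knn_rejects_small_n(self):
        dm = comp.DistanceMatrix(["a", "b"], np.zeros((2, 2)))
        with pytest.raises(ValueError):
            comp.knn_graph(dm, k=5)

    def test_knn_matches_exhaustive_neighbour_lists(self, rng):
        dm, labels = self._three_family_matrix(rng, n_per=5)
        lists = comp.neighbour_lists(dm, k=5)
        for i, label in enumerate(labels):
            order = sorted((j for j in range(len(labels)) if j != i),
                           key=lambda j: (dm.values[i, j], labels[j]))
            assert lists[label] == [labels[j] for j in order[:5]]

    def test_two_family_graph_splits_into_components(self, rng):
        import networkx as nx
        a = random_dna(150, 0.6, rng)
        b = random_dna(150, 0.6, rng)
        seqs = [mutate_copy(a, 0.02, rng) for _ in range(6)] + \
               [mutate_copy(b, 0.02, rng) for _ in range(6)]
        labels = [f"A{i}" for i in range(6)] + [f"B{i}" for i in range(6)]
        dm = comp.distance_matrix(seqs, labels)
        g = comp.knn_graph(dm, k=3)
        comps = sorted(sorted(c) for c in nx.connected_components(g.graph))
        assert comps == [sorted(labels[:6]), sorted(labels[6:])]
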