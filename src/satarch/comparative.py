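"""Cross-genome ortholog scanning and sequence-population geometry.

Ortholog search: consensus sequences are decomposed into k-mers (k = 16,
both strands) and scanned against a target genome allowing a bounded
Levenshtein distance (<= 3), so diverged relatives invisible to exact search
are still found.  Sequence populations are compared through F81 genetic
distances (d = -E ln(1 - p/E), E = 1 - sum(pi^2)), embedded by PCA and
linked into k-nearest-neighbour graphs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import edlib
import networkx as nx
import numpy as np
from sklearn.decomposition import PCA

from . import align
from ._myers import encode_text, pattern_eq, scan_ends
from .core_io import GenomeSequence, Interval, interval_merge, revcomp

SATURATED = math.inf


@dataclass
class KmerSet:
    k: int
    kmers: frozenset[str]

    def __len__(self) -> int:
        return len(self.kmers)


def kmerize(consensus: str, k: int = 16) -> KmerSet:
    """All overlapping k-mers of a sequence and its reverse complement."""
    consensus = consensus.upper()
    if len(consensus) < k:
        raise ValueError(f"sequence shorter than k={k}")
    fwd = {consensus[i:i + k] for i in range(len(consensus) - k + 1)}
    rc = revcomp(consensus)
    rev = {rc[i:i + k] for i in range(len(rc) - k + 1)}
    return KmerSet(k, frozenset(fwd | rev))


def edit_distance(a: str, b: str) -> int:
    """Unit-cost Levenshtein distance (edlib, global mode)."""
    if not a:
        return len(b)
    if not b:
        return len(a)
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


@dataclass
class ScanHit:
    interval: Interval
    min_edit_distance: int
    source_kmer: str


def _collapse(hits: list[tuple[int, int, str]], max_gap: int
              ) -> list[tuple[int, int, str]]:
    """Group (end, dist, kmer) triples with end positions within max_gap of
    the running group; keep the best (min dist, leftmost, lexicographic)."""
    if not hits:
        return []
    hits.sort(key=lambda t: (t[0], t[1], t[2]))
    out: list[tuple[int, int, str]] = []
    group_end = None
    for end, dist, kmer in hits:
        if group_end is not None and end - group_end <= max_gap:
            prev = out[-1]
            if (dist, end, kmer) < (prev[1], prev[0], prev[2]):
                out[-1] = (end, dist, kmer)
        else:
            out.append((end, dist, kmer))
        group_end = end
    return out


def approx_scan(genome: Sequence[GenomeSequence], kmers: KmerSet,
                max_distance: int = 3) -> list[ScanHit]:
    """Scan a genome for approximate k-mer matches within an edit bound.

    Every locus where some k-mer of the set matches within Levenshtein
    distance <= ``max_distance`` is reported once with the minimal distance
    found (exact matches are guaranteed found: the bit-parallel scan computes
    the true semi-global distance at every end position).  Neighbouring end
    positions within ``max_distance`` bp are collapsed to the best.
    """
    if not kmers.kmers:
        raise ValueError("empty k-mer set")
    k = kmers.k
    patterns = sorted(kmers.kmers)
    out: list[ScanHit] = []
    for contig in genome:
        text = encode_text(contig.residues)
        per_contig: list[tuple[int, int, str]] = []
        for pat in patterns:
            ends, dists = scan_ends(text, pattern_eq(pat), k, max_distance)
            per_contig.extend(
                _collapse([(e, d, pat) for e, d in zip(ends, dists)],
                          max_distance))
        for end, dist, pat in _collapse(per_contig, max_distance):
            start = max(0, end - k)
            out.append(ScanHit(Interval(contig.contig_id, start, end, "."),
                               dist, pat))
    out.sort(key=lambda h: h.interval.sort_key())
    return out


@dataclass
class ScanRegion:
    interval: Interval
    n_hits: int
    min_edit_distance: int


def merge_hits(hits: Sequence[ScanHit], max_gap: int = 16) -> list[ScanRegion]:
    """Merge nearby scan hits into regions carrying hit count and best
    distance (single-linkage on the hit intervals)."""
    merged = interval_merge([h.interval for h in hits], max_gap)
    regions = []
    for iv in merged:
        members = [h for h in hits
                   if h.interval.contig_id == iv.contig_id
                   and h.interval.start >= iv.start
                   and h.interval.end <= iv.end]
        regions.append(ScanRegion(iv, len(members),
                                  min(h.min_edit_distance for h in members)))
    return regions


@dataclass
class MapBackProfile:
    coverage: np.ndarray  # per consensus position: covering region count
    n_mapped: int
    n_unmapped: int


def map_back(region_seqs: Sequence[str], consensus: str,
             min_score: float = 10.0) -> MapBackProfile:
    """Align region sequences onto a consensus and profile their coverage.

    Each region is locally aligned to the consensus on both strands; the best
    alignment (if it reaches ``min_score``) increments the coverage of the
    consensus positions it spans.  Regions aligning nowhere count as
    unmapped.  A profile confined to a narrow segment indicates that the
    similarity comes from a short motif (e.g. an A+T homopolymer) rather than
    from the whole monomer.
    """
    coverage = np.zeros(len(consensus), dtype=np.int64)
    n_mapped = n_unmapped = 0
    for seq in region_seqs:
        best = None
        for cand in (seq, revcomp(seq)):
            aln = align.local_alignment(consensus, cand)
            if best is None or aln.score > best.score:
                best = aln
        if best is None or best.score < min_score:
            n_unmapped += 1
            continue
        n_mapped += 1
        for (c0, c1) in best.aligned[0]:
            coverage[int(c0):int(c1)] += 1
    return MapBackProfile(coverage, n_mapped, n_unmapped)


# ---------------------------------------------------------------------------
# F81 distances, PCA, k-NN graphs
# ---------------------------------------------------------------------------

_ACGT = set("ACGT")


def f81_distance(aligned_a: str, aligned_b: str,
                 base_freqs: Sequence[float]) -> float:
    """F81 model distance between two rows of an alignment.

    d = -E ln(1 - p/E) with E = 1 - sum(pi^2); p is the mismatch proportion
    over columns where both rows carry A/C/G/T (pairwise deletion).
    Saturated pairs (p >= E) return inf and are flagged by callers.
    """
    if len(aligned_a) != len(aligned_b):
        raise ValueError("aligned sequences must have equal length")
    freqs = np.asarray(base_freqs, dtype=float)
    if freqs.shape != (4,) or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-6):
        raise ValueError("base_freqs must be a 4-vector summing to 1")
    n = diff = 0
    for x, y in zip(aligned_a, aligned_b):
        if x in _ACGT and y in _ACGT:
            n += 1
            if x != y:
                diff += 1
    if n == 0:
        raise ValueError("no comparable columns")
    p = diff / n
    e = 1.0 - float(np.sum(freqs ** 2))
    if p >= e:
        return SATURATED
    return -e * math.log(1.0 - p / e)


def base_frequencies(seqs: Sequence[str]) -> np.ndarray:
    """A/C/G/T frequencies pooled over all sequences (gaps/N ignored)."""
    counts = np.zeros(4)
    order = "ACGT"
    for s in seqs:
        for i, b in enumerate(order):
            counts[i] += s.count(b)
    total = counts.sum()
    if total == 0:
        raise ValueError("no A/C/G/T residues")
    return counts / total


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # inf marks saturated pairs

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def saturated(self) -> np.ndarray:
        return ~np.isfinite(self.values)

    def finite_max(self) -> float:
        finite = self.values[np.isfinite(self.values)]
        return float(finite.max()) if finite.size else 0.0


def distance_matrix(seqs: Sequence[str],
                    labels: Sequence[str] | None = None) -> DistanceMatrix:
    """F81 distance matrix of a sequence population.

    Sequences are put into a common coordinate frame by pairwise anchoring to
    the longest sequence (all pairs are then scored on the same column set);
    base frequencies are estimated once from the whole input.
    """
    if labels is None:
        labels = [f"seq{i}" for i in range(len(seqs))]
    if len(labels) != len(seqs):
        raise ValueError("labels/seqs length mismatch")
    anchor = max(seqs, key=lambda s: (len(s), s))
    rows = align.project_to_anchor(anchor, list(seqs))
    freqs = base_frequencies(list(seqs))
    n = len(seqs)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = f81_distance(rows[i], rows[j], freqs)
    return DistanceMatrix(list(labels), values)


@dataclass
class Embedding:
    coordinates: np.ndarray  # n x 2
    variance_fractions: tuple[float, float]


def pca_embed(matrix: DistanceMatrix) -> Embedding:
    """PCA of the distance-matrix rows (saturated entries imputed).

    Rows are treated as feature vectors and column-centered; the first two
    principal axes are returned with their variance fractions.  Saturated
    entries are imputed with 1.5x the largest finite distance.
    """
    if matrix.n < 3:
        raise ValueError("PCA needs at least 3 sequences")
    values = matrix.values.copy()
    if matrix.saturated.any():
        values[~np.isfinite(values)] = 1.5 * matrix.finite_max()
    if np.allclose(values, 0.0):
        return Embedding(np.zeros((matrix.n, 2)), (0.0, 0.0))
    pca = PCA(n_components=2, svd_solver="full")
    coords = pca.fit_transform(values)
    vf = pca.explained_variance_ratio_
    return Embedding(coords, (float(vf[0]), float(vf[1])))


@dataclass
class SeqGraph:
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(u, v, d["weight"]) for u, v, d in self.graph.edges(data=True)]


def knn_graph(matrix: DistanceMatrix, k: int = 5) -> SeqGraph:
    """Undirected graph linking each sequence to its k nearest neighbours.

    Neighbours are ranked by F81 distance with ties broken by label order;
    mutual selections collapse into a single edge.
    """
    n = matrix.n
    if n <= k:
        raise ValueError(f"need more than k={k} sequences, got {n}")
    values = matrix.values.copy()
    if matrix.saturated.any():
        values[~np.isfinite(values)] = 1.5 * matrix.finite_max()
    g = nx.Graph()
    g.add_nodes_from(matrix.labels)
    for i in range(n):
        order = sorted((j for j in range(n) if j != i),
                       key=lambda j: (values[i, j], matrix.labels[j]))
        for j in order[:k]:
            g.add_edge(matrix.labels[i], matrix.labels[j],
                       weight=float(values[i, j]))
    return SeqGraph(g)


def neighbour_lists(matrix: DistanceMatrix, k: int = 5) -> dict[str, list[str]]:
    """Per-sequence ranked k-nearest-neighbour label lists."""
    values = matrix.values
    out: dict[str, list[str]] = {}
    for i in range(matrix.n):
        order = sorted((j for j in range(matrix.n) if j != i),
                       key=lambda j: (values[i, j], matrix.labels[j]))
        out[matrix.labels[i]] = [matrix.labels[j] for j in order[:k]]
    return out
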