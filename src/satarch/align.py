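"""Pairwise alignment helpers shared across modules.

Scoring is pinned for reproducibility: match +1, mismatch -1, gap open -5,
gap extend -1.  Percent identity is matches / alignment columns, so gap
columns count as differences.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from Bio import Align

MATCH = 1
MISMATCH = -1
GAP_OPEN = -5
GAP_EXTEND = -1


def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = mode
    a.match_score = MATCH
    a.mismatch_score = MISMATCH
    a.open_gap_score = GAP_OPEN
    a.extend_gap_score = GAP_EXTEND
    return a


_GLOBAL = _aligner("global")
_LOCAL = _aligner("local")


def global_alignment(a: str, b: str) -> Align.Alignment:
    return _GLOBAL.align(a, b)[0]


def local_alignment(a: str, b: str) -> Align.Alignment:
    return _LOCAL.align(a, b)[0]


def local_score(a: str, b: str) -> float:
    return _LOCAL.score(a, b)


def global_identity(a: str, b: str) -> float:
    """Percent identity of the global pairwise alignment (0..100)."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    aln = global_alignment(a, b)
    counts = aln.counts()
    columns = counts.gaps + counts.identities + counts.mismatches
    return 100.0 * counts.identities / columns


def alignment_columns(aln: Align.Alignment) -> tuple[str, str]:
    """The two gapped rows of a pairwise alignment."""
    return str(aln[0]), str(aln[1])


def project_to_anchor(anchor: str, seqs: Sequence[str]) -> list[str]:
    """Put sequences into the anchor's coordinate frame.

    Each sequence is globally aligned to the anchor; for every anchor
    position the aligned character (or '-') is recorded.  Insertions relative
    to the anchor are dropped, so all outputs have length len(anchor) and all
    pairs are scored over a common column set.
    """
    rows: list[str] = []
    for s in seqs:
        if s == anchor:
            rows.append(anchor)
            continue
        aln = global_alignment(anchor, s)
        row = ["-"] * len(anchor)
        blocks_a, blocks_b = aln.aligned
        for (a0, a1), (b0, b1) in zip(blocks_a, blocks_b):
            for off in range(a1 - a0):
                row[a0 + off] = s[b0 + off]
        rows.append("".join(row))
    return rows


def majority_consensus(seqs: Sequence[str]) -> str:
    """Majority-rule consensus of sequences via anchoring to the longest.

    Columns where the majority character is a gap are dropped; ties go to the
    lexicographically smallest base for determinism.
    """
    if not seqs:
        raise ValueError("no sequences")
    if len(seqs) == 1:
        return seqs[0]
    anchor = max(seqs, key=lambda s: (len(s), s))
    rows = project_to_anchor(anchor, list(seqs))
    out = []
    for col in zip(*rows):
        counts: dict[str, int] = {}
        for ch in col:
            counts[ch] = counts.get(ch, 0) + 1
        best = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
        if best != "-":
            out.append(best)
    return "".join(out)


def identity_matrix(seqs: Sequence[str]) -> np.ndarray:
    """All-vs-all global percent identity (symmetric, 100 on the diagonal)."""
    n = len(seqs)
    mat = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = global_identity(seqs[i], seqs[j])
    return mat


class UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            # lower root wins, keeps labels deterministic
            if rj < ri:
                ri, rj = rj, ri
            self.parent[rj] = ri


def single_linkage_clusters(seqs: Sequence[str],
                            identity_threshold: float) -> list[list[int]]:
    """Single-linkage clustering on pairwise global identity.

    Returns member-index lists ordered by decreasing size (ties: smallest
    first member), equivalent to the connected components of the
    pairwise-identity graph thresholded at ``identity_threshold``.

    Two exact shortcuts keep this near-linear on clustered inputs: identity
    is at most min(len)/max(len) (matches <= shorter length, columns >=
    longer), so length-discordant pairs are skipped without aligning; and
    pairs already connected through earlier links are skipped outright.
    """
    n = len(seqs)
    uf = UnionFind(n)
    ratio = identity_threshold / 100.0
    for i in range(n):
        for j in range(i + 1, n):
            if uf.find(i) == uf.find(j):
                continue
            la, lb = len(seqs[i]), len(seqs[j])
            if min(la, lb) < ratio * max(la, lb):
                continue
            if global_identity(seqs[i], seqs[j]) >= identity_threshold:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def mean_pairwise_identity(seqs: Sequence[str], max_pairs: int = 2000,
                           seed: int = 0) -> float:
    """Mean global identity over all pairs (seeded subsample above max_pairs)."""
    n = len(seqs)
    if n < 2:
        return 100.0
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    if len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[int(i)] for i in sorted(idx)]
    vals = [global_identity(seqs[i], seqs[j]) for i, j in pairs]
    return float(np.mean(vals))
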