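"""Inter-family junction grammar: transition zones, cassettes, proximity.

Where arrays of two satellite families abut, the junction sequence is often a
conserved element rather than a random splice: a family-derived transition
element carrying an internal deletion, or a chimeric element that fuses
truncated monomers of both families with a short duplicated motif at the
breakpoint.  A minor-family array flanked by two such transition elements and
carrying an internal inversion point forms a "cassette" embedded in the major
satellite.  This module detects adjacencies, extracts and clusters junction
sequences, characterizes breakpoints, and censuses cassettes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import align
from .annotate import SatFamily
from .arrays import SatArray
from .core_io import (GenomeSequence, Interval, genome_dict, interval_nearest,
                      revcomp)
from .symmetry import InversionPoint

MIN_DUPLICATED_MOTIF = 4  # shorter boundary overlaps are not called motifs
MIN_DONOR_SCORE = 20.0    # below this a junction side is "unclassified"


@dataclass
class Adjacency:
    """A neighbouring pair of arrays from two families on one contig."""

    array_a: SatArray
    array_b: SatArray
    gap: int
    orientation: str  # "a_left" or "b_left"

    @property
    def left(self) -> SatArray:
        return self.array_a if self.orientation == "a_left" else self.array_b

    @property
    def right(self) -> SatArray:
        return self.array_b if self.orientation == "a_left" else self.array_a


@dataclass
class JunctionRecord:
    adjacency: Adjacency
    interval: Interval
    sequence: str
    truncated: bool = False
    cluster_label: str | None = None


@dataclass
class TransitionCluster:
    label: str
    member_indices: list[int]
    consensus: str
    prevalence: float  # fraction of junctions in this cluster
    minor: bool = False

    @property
    def size(self) -> int:
        return len(self.member_indices)


@dataclass
class ChimericBreakpoint:
    breakpoint_offset: int | None
    duplicated_motif: str
    deletion_length: int
    unclassified: bool = False


@dataclass
class CassetteReport:
    """Per minor-family array: transition and inversion element presence."""

    flags: list[tuple[SatArray, bool, bool, bool]]  # (array, t1, t2, inv)
    venn: dict[str, int] = field(default_factory=dict)

    @property
    def n_arrays(self) -> int:
        return len(self.flags)

    @property
    def triple_count(self) -> int:
        return self.venn.get("T1&T2&INV", 0)

    @property
    def triple_fraction(self) -> float:
        return self.triple_count / self.n_arrays if self.n_arrays else math.nan


def find_adjacencies(arrays: Sequence[SatArray], family_a: str,
                     family_b: str, max_gap: int = 1000) -> list[Adjacency]:
    """All neighbouring (family_a, family_b) array pairs with gap <= max_gap.

    Neighbouring means no other array from the input collection lies between
    the two, regardless of its family.
    """
    fams = {a.family_id for a in arrays}
    for fam in (family_a, family_b):
        if fam not in fams:
            raise KeyError(f"no arrays of family {fam!r}")
    by_contig: dict[str, list[SatArray]] = {}
    for a in arrays:
        by_contig.setdefault(a.interval.contig_id, []).append(a)
    out: list[Adjacency] = []
    for contig in sorted(by_contig):
        ordered = sorted(by_contig[contig], key=SatArray.sort_key)
        for left, right in zip(ordered, ordered[1:]):
            pair = {left.family_id, right.family_id}
            if pair != {family_a, family_b}:
                continue
            gap = max(0, right.interval.start - left.interval.end)
            if gap > max_gap:
                continue
            if left.family_id == family_a:
                out.append(Adjacency(left, right, gap, "a_left"))
            else:
                out.append(Adjacency(right, left, gap, "b_left"))
    return out


def extract_junction(genome: Sequence[GenomeSequence], adjacency: Adjacency,
                     pad: int = 250) -> JunctionRecord:
    """Extract the '+'-strand junction window around an adjacency.

    The window runs from ``pad`` bp inside the left array's end to ``pad`` bp
    inside the right array's start, covering the whole inter-array gap.  A pad
    larger than an array (or running past the contig) is clipped and flagged.
    """
    contigs = genome_dict(genome)
    left, right = adjacency.left, adjacency.right
    seq = contigs[left.interval.contig_id].residues
    truncated = False
    left_pad = min(pad, left.length)
    right_pad = min(pad, right.length)
    if left_pad < pad or right_pad < pad:
        truncated = True
    lo = left.interval.end - left_pad
    hi = right.interval.start + right_pad
    if lo < 0 or hi > len(seq):
        truncated = True
        lo, hi = max(0, lo), min(len(seq), hi)
    iv = Interval(left.interval.contig_id, lo, hi, ".")
    return JunctionRecord(adjacency, iv, seq[lo:hi], truncated=truncated)


def classify_transitions(junctions: Sequence[str] | Sequence[JunctionRecord],
                         identity_threshold: float = 90.0
                         ) -> list[TransitionCluster]:
    """Cluster junction sequences by single-linkage global identity.

    Clusters are ranked by size and labelled TRANSc1, TRANSc2, ...; each
    carries a majority-rule consensus and its prevalence among all junctions.
    """
    if not junctions:
        raise ValueError("no junctions to classify")
    records = [j for j in junctions if isinstance(j, JunctionRecord)]
    seqs = [j.sequence if isinstance(j, JunctionRecord) else j
            for j in junctions]
    groups = align.single_linkage_clusters(seqs, identity_threshold)
    clusters: list[TransitionCluster] = []
    for rank, idxs in enumerate(groups, start=1):
        label = f"TRANSc{rank}"
        member_seqs = [seqs[i] for i in idxs]
        clusters.append(TransitionCluster(
            label=label,
            member_indices=list(idxs),
            consensus=align.majority_consensus(member_seqs),
            prevalence=len(idxs) / len(seqs),
            minor=len(idxs) < 3,
        ))
        for i in idxs:
            if records:
                records[i].cluster_label = label
    return clusters


def _tile(consensus: str, target_len: int) -> str:
    reps = max(1, math.ceil((target_len + len(consensus)) / len(consensus)))
    return consensus * reps


def _donor_orientations(consensus: str, target_len: int) -> tuple[str, str]:
    return (_tile(consensus, target_len),
            _tile(revcomp(consensus), target_len))


def _side_score(fragment: str, donors: tuple[str, str]) -> float:
    if not fragment:
        return 0.0
    return max(align.local_score(fragment, d) for d in donors)


def _side_alignment(fragment: str, donors: tuple[str, str]):
    """Best local alignment (traceback) of a fragment vs donor orientations."""
    best = None
    best_donor = None
    for donor in donors:
        aln = align.local_alignment(fragment, donor)
        if best is None or aln.score > best.score:
            best, best_donor = aln, donor
    return best, best_donor


def detect_chimeric_breakpoint(junction: str, consensus_a: str,
                               consensus_b: str,
                               coarse_step: int = 16) -> ChimericBreakpoint:
    """Characterize a two-donor junction.

    The breakpoint is the junction split maximizing the sum of the local
    alignment score of the prefix against family-a material and the suffix
    against family-b material (donors are tiled to tandem context and tried
    in both orientations; the split is located on a coarse grid and refined
    at 1-bp resolution, ties to the leftmost).  Also reported: the longest
    motif that both terminates the aligned a-donor segment and begins the
    aligned b-donor segment (a breakpoint duplication), and the largest
    deletion in the prefix relative to the a-donor.
    """
    donors_a = _donor_orientations(consensus_a, len(junction))
    donors_b = _donor_orientations(consensus_b, len(junction))

    def split_score(o: int) -> float:
        return (_side_score(junction[:o], donors_a)
                + _side_score(junction[o:], donors_b))

    n = len(junction)
    coarse = list(range(0, n + 1, coarse_step))
    if coarse[-1] != n:
        coarse.append(n)
    best_o = max(coarse, key=lambda o: (split_score(o), -o))
    lo = max(0, best_o - coarse_step)
    hi = min(n, best_o + coarse_step)
    best_o = max(range(lo, hi + 1), key=lambda o: (split_score(o), -o))

    prefix, suffix = junction[:best_o], junction[best_o:]
    if (_side_score(prefix, donors_a) < MIN_DONOR_SCORE
            or _side_score(suffix, donors_b) < MIN_DONOR_SCORE):
        return ChimericBreakpoint(None, "", 0, unclassified=True)

    aln_a, donor_a = _side_alignment(prefix, donors_a)
    aln_b, donor_b = _side_alignment(suffix, donors_b)
    aj, ad = aln_a.aligned
    bj, bd = aln_b.aligned

    a_seg = donor_a[int(ad[0][0]):int(ad[-1][1])]
    b_seg = donor_b[int(bd[0][0]):int(bd[-1][1])]
    motif = ""
    for k in range(min(20, len(a_seg), len(b_seg)),
                   MIN_DUPLICATED_MOTIF - 1, -1):
        if a_seg[-k:] == b_seg[:k]:
            motif = a_seg[-k:]
            break

    deletion = 0
    for (_, j1), (jn0, _), (_, d1), (dn0, _) in zip(aj, aj[1:], ad, ad[1:]):
        dj = int(jn0) - int(j1)
        dd = int(dn0) - int(d1)
        if dd > dj:
            deletion = max(deletion, dd - dj)
    return ChimericBreakpoint(best_o, motif, deletion)


def assign_transition_types(clusters: Sequence[TransitionCluster],
                            records: Sequence[JunctionRecord],
                            minor_family: str,
                            min_gap: int = 20) -> dict[str, str]:
    """Map junction clusters to the two prevalent transition types.

    A cluster only represents a transition *element* when its junctions
    actually occupy an inter-array gap: clusters whose median adjacency gap
    is below ``min_gap`` are plain array abutments and get no type.  Element
    clusters are typed by the side of the minor-family array their members
    sit on, following the cassette reading order major array -> entry
    transition -> minor array -> exit transition -> major array: clusters of
    predominantly minor-on-the-right junctions are TRANS_1 (entry), clusters
    of minor-on-the-left junctions are TRANS_2 (exit).  Several clusters may
    share a type (e.g. orientation variants of the same element context).
    """
    mapping: dict[str, str] = {}
    for cluster in clusters:
        members = [records[i] for i in cluster.member_indices
                   if records[i].cluster_label == cluster.label]
        if not members:
            continue
        gaps = sorted(m.adjacency.gap for m in members)
        if gaps[len(gaps) // 2] < min_gap:
            continue
        entry_votes = sum(
            1 for m in members
            if m.adjacency.right.family_id == minor_family)
        if entry_votes * 2 >= len(members):
            mapping[cluster.label] = "TRANS_1"
        else:
            mapping[cluster.label] = "TRANS_2"
    return mapping


def cassette_census(minor_arrays: Sequence[SatArray],
                    records: Sequence[JunctionRecord],
                    type_map: dict[str, str],
                    inversion_points: Sequence[InversionPoint]
                    ) -> CassetteReport:
    """Census transition/inversion element presence per minor-family array.

    For each minor array three booleans are computed: a TRANS_1-type junction
    at an edge, a TRANS_2-type junction at an edge, and at least one internal
    inversion point.  The Venn counts over the three booleans partition the
    array set exactly.
    """
    by_array: dict[int, set[str]] = {}
    for rec in records:
        if rec.cluster_label is None:
            continue
        jtype = type_map.get(rec.cluster_label)
        if jtype is None:
            continue
        for arr in (rec.adjacency.array_a, rec.adjacency.array_b):
            by_array.setdefault(id(arr), set()).add(jtype)

    flags: list[tuple[SatArray, bool, bool, bool]] = []
    venn = {key: 0 for key in
            ["none", "T1", "T2", "INV", "T1&T2", "T1&INV", "T2&INV",
             "T1&T2&INV"]}
    for arr in minor_arrays:
        types = by_array.get(id(arr), set())
        has_t1 = "TRANS_1" in types
        has_t2 = "TRANS_2" in types
        has_inv = any(
            p.contig_id == arr.interval.contig_id and
            arr.interval.start < p.position < arr.interval.end
            for p in inversion_points)
        flags.append((arr, has_t1, has_t2, has_inv))
        parts = [name for name, on in
                 (("T1", has_t1), ("T2", has_t2), ("INV", has_inv)) if on]
        venn["&".join(parts) if parts else "none"] += 1
    return CassetteReport(flags=flags, venn=venn)


def refine_edge(genome: Sequence[GenomeSequence], array: SatArray,
                family: SatFamily, k: int = 12, threshold: float = 0.5,
                side: str = "right", max_extension: int | None = None) -> int:
    """Refine an array edge by k-mer composition.

    Scanning outward from the terminal monomer in 1-bp steps, a window of
    4*k bp on the array side of each candidate position is tested; a position
    passes when at least ``threshold`` of the window's k-mers are present in
    the family consensus k-mer set (tandem context, both strands).  Against a
    sharp edge the last passing position overshoots by (1 - threshold) times
    the window k-mer count, so the returned boundary is debiased by exactly
    that amount: at threshold 1.0 it falls on the last consensus base, at 0.5
    it is an unbiased edge estimate.  The scan stops after two windows of
    consecutive failures or at ``max_extension``.
    """
    if array.monomer_count < 1:
        raise ValueError("array has no monomers")
    if side not in ("left", "right"):
        raise ValueError("side must be 'left' or 'right'")
    seq = genome_dict(genome)[array.interval.contig_id].residues
    window = 4 * k
    if max_extension is None:
        max_extension = 2 * family.monomer_length

    doubled = family.consensus * 2
    kmer_set = {doubled[i:i + k] for i in range(len(doubled) - k + 1)}
    kmer_set |= {revcomp(m) for m in kmer_set}

    def window_frac(lo: int) -> float:
        hi = lo + window
        if lo < 0 or hi > len(seq):
            return -1.0  # truncated scan: treat as failing
        kmers = [seq[i:i + k] for i in range(lo, hi - k + 1)]
        return sum(1 for m in kmers if m in kmer_set) / len(kmers)

    boundary = array.interval.end if side == "right" else array.interval.start
    best = boundary
    fails = 0
    for step in range(0, max_extension + 1):
        if side == "right":
            pos = boundary + step
            lo = pos - window
        else:
            pos = boundary - step
            lo = pos
        if window_frac(lo) >= threshold:
            best = pos
            fails = 0
        else:
            fails += 1
            if fails > 2 * window:
                break
    n_kmers = window - k + 1
    correction = int((1.0 - threshold) * n_kmers)
    return best - correction if side == "right" else best + correction


@dataclass
class FlankSimilarity:
    labels: list[str]
    matrix: np.ndarray
    truncated: list[str]


def flank_similarity(arrays: Sequence[SatArray],
                     genome: Sequence[GenomeSequence],
                     flank: int = 2000) -> FlankSimilarity:
    """All-vs-all identity of the upstream/downstream flanks of arrays.

    Each array contributes an upstream and a downstream flank row; rows whose
    flank is truncated by a contig edge are listed in ``truncated``.
    """
    if not arrays:
        raise ValueError("arrays must be non-empty")
    contigs = genome_dict(genome)
    labels, seqs, truncated = [], [], []
    for idx, arr in enumerate(sorted(arrays, key=SatArray.sort_key)):
        seq = contigs[arr.interval.contig_id].residues
        for side, lo, hi in (
                ("up", arr.interval.start - flank, arr.interval.start),
                ("down", arr.interval.end, arr.interval.end + flank)):
            label = f"{arr.family_id}_{idx}:{side}"
            clo, chi = max(0, lo), min(len(seq), hi)
            if clo != lo or chi != hi:
                truncated.append(label)
            if chi > clo:
                labels.append(label)
                seqs.append(seq[clo:chi])
    return FlankSimilarity(labels, align.identity_matrix(seqs), truncated)


def nearest_family_distance(arrays_x: Sequence[SatArray],
                            arrays_y: Sequence[SatArray]) -> pd.DataFrame:
    """Gap distance from each x-array to its nearest y-array.

    Rows with no y-array on the contig carry a missing distance ("no
    neighbor").  The table is sorted genomically.
    """
    if not arrays_x or not arrays_y:
        raise ValueError("both array collections must be non-empty")
    targets = [a.interval for a in arrays_y]
    rows = []
    for arr in sorted(arrays_x, key=SatArray.sort_key):
        res = interval_nearest(arr.interval, targets)
        rows.append({
            "contig_id": arr.interval.contig_id,
            "start": arr.interval.start,
            "end": arr.interval.end,
            "family_id": arr.family_id,
            "nearest_distance": float(res[1]) if res is not None else np.nan,
        })
    return pd.DataFrame(rows)
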