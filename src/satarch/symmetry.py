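"""Oriented subarrays, inversion points and macro-dyad symmetry.

Arrays are first built strand-agnostically; here each array is decomposed by
re-applying the gap rule per strand, giving maximal same-orientation monomer
blocks ("subarrays").  The boundary between two adjacent opposite-strand
blocks is an inversion point; an array whose blocks alternate +/- forms a
macro-dyad symmetry — a palindrome-like arrangement that can span tens of
kilobases.  The conserved sequence around each inversion point is extracted,
clustered by identity, and compared against canonical subunits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import align
from .annotate import MonomerHit, SatFamily
from .arrays import SatArray
from .core_io import Feature, GenomeSequence, Interval, genome_dict

MINOR_CLUSTER_SIZE = 3  # clusters below this are reported but marked minor


@dataclass
class Subarray:
    """A maximal same-orientation block of monomers within one array."""

    interval: Interval  # strand '+' or '-'
    monomer_count: int

    @property
    def strand(self) -> str:
        return self.interval.strand


@dataclass(frozen=True)
class InversionPoint:
    contig_id: str
    position: int  # midpoint of the gap between the flanking subarrays
    left_strand: str
    right_strand: str


@dataclass
class MacrodyadMetrics:
    array: SatArray
    n_subarrays: int
    # signed left-minus-right length difference at each inversion point
    direct_inverted_diffs: list[int]
    symmetry_span: int  # max over points of (left block bp + right block bp)


@dataclass
class InversionSite:
    point: InversionPoint
    window_sequence: str
    truncated: bool = False
    cluster_label: str | None = None
    identity_to_canonical: float | None = None


@dataclass
class SiteCluster:
    label: str
    members: list[InversionSite]
    consensus: str
    mean_pairwise_identity: float
    minor: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def decompose_subarrays(array: SatArray, family: SatFamily
                        ) -> tuple[list[Subarray], list[InversionPoint]]:
    """Split an array into oriented blocks and locate inversion points.

    Per strand, member monomers are merged under the family gap rule; the
    stranded blocks are clipped to the array span and ordered.  One
    InversionPoint is emitted at each adjacent opposite-strand boundary, at
    the midpoint of the inter-block gap (symmetric under reverse
    complementation of the contig).

    The resulting subarrays are also stored on ``array.subarrays``.
    """
    if array.monomer_count == 0:
        raise ValueError("cannot decompose an array with zero monomers")
    gap = family.monomer_length
    contig = array.interval.contig_id

    blocks: list[Subarray] = []
    for strand in "+-":
        members = [m for m in array.monomers if m.interval.strand == strand]
        members.sort(key=MonomerHit.sort_key)
        run: list[MonomerHit] = []
        for m in members:
            if run and m.interval.start - run[-1].interval.end <= gap:
                run.append(m)
            else:
                if run:
                    blocks.append(_block(contig, strand, run, array))
                run = [m]
        if run:
            blocks.append(_block(contig, strand, run, array))

    blocks.sort(key=lambda b: (b.interval.start, b.interval.end))
    # Defensive: merge same-strand neighbours so the block list alternates.
    merged: list[Subarray] = []
    for b in blocks:
        if merged and merged[-1].strand == b.strand:
            prev = merged[-1]
            merged[-1] = Subarray(
                Interval(contig, prev.interval.start,
                         max(prev.interval.end, b.interval.end), b.strand),
                prev.monomer_count + b.monomer_count)
        else:
            merged.append(b)

    points = [
        InversionPoint(
            contig_id=contig,
            position=(left.interval.end + right.interval.start) // 2,
            left_strand=left.strand,
            right_strand=right.strand,
        )
        for left, right in zip(merged, merged[1:])
    ]
    array.subarrays = merged
    return merged, points


def _block(contig: str, strand: str, run: list[MonomerHit],
           array: SatArray) -> Subarray:
    start = max(run[0].interval.start, array.interval.start)
    end = min(max(m.interval.end for m in run), array.interval.end)
    return Subarray(Interval(contig, start, end, strand), len(run))


def macrodyad_metrics(array: SatArray) -> MacrodyadMetrics:
    """Symmetry metrics of a decomposed array.

    ``direct_inverted_diffs`` holds, per inversion point, the signed length
    difference (left block minus right block); a perfectly symmetric dyad
    has diff 0.  ``symmetry_span`` is the largest flanking-pair total.
    """
    blocks = array.subarrays
    if not blocks:
        raise ValueError("array not decomposed; run decompose_subarrays first")
    diffs: list[int] = []
    span = 0
    for left, right in zip(blocks, blocks[1:]):
        diffs.append(len(left.interval) - len(right.interval))
        span = max(span, len(left.interval) + len(right.interval))
    return MacrodyadMetrics(
        array=array,
        n_subarrays=len(blocks),
        direct_inverted_diffs=diffs,
        symmetry_span=span,
    )


def extract_inversion_sites(points: Sequence[InversionPoint],
                            genome: Sequence[GenomeSequence],
                            window_radius: int = 200) -> list[InversionSite]:
    """Extract the '+'-strand window [position-r, position+r) per point.

    Windows running past a contig end are truncated and flagged.
    """
    contigs = genome_dict(genome)
    sites: list[InversionSite] = []
    for p in points:
        if p.contig_id not in contigs:
            raise KeyError(f"unknown contig {p.contig_id!r}")
        seq = contigs[p.contig_id].residues
        if not (0 <= p.position <= len(seq)):
            raise ValueError(
                f"inversion point {p.position} outside contig {p.contig_id}")
        lo = p.position - window_radius
        hi = p.position + window_radius
        truncated = lo < 0 or hi > len(seq)
        lo, hi = max(0, lo), min(len(seq), hi)
        sites.append(InversionSite(p, seq[lo:hi], truncated=truncated))
    return sites


def cluster_sites(sites: Sequence[InversionSite],
                  identity_threshold: float = 90.0) -> list[SiteCluster]:
    """Single-linkage identity clustering of inversion-site windows.

    Clusters are labelled INVc1, INVc2, ... by decreasing size; clusters with
    fewer than three members are kept but marked minor and their consensus is
    not meant for downstream statistics.
    """
    if not sites:
        raise ValueError("no sites to cluster")
    seqs = [s.window_sequence for s in sites]
    groups = align.single_linkage_clusters(seqs, identity_threshold)
    clusters: list[SiteCluster] = []
    for rank, idxs in enumerate(groups, start=1):
        label = f"INVc{rank}"
        members = [sites[i] for i in idxs]
        for m in members:
            m.cluster_label = label
        member_seqs = [m.window_sequence for m in members]
        clusters.append(SiteCluster(
            label=label,
            members=members,
            consensus=align.majority_consensus(member_seqs),
            mean_pairwise_identity=align.mean_pairwise_identity(member_seqs),
            minor=len(members) < MINOR_CLUSTER_SIZE,
        ))
    return clusters


def site_divergence(cluster_consensus: str, canonical: str) -> float:
    """Percent divergence of a cluster consensus from a canonical subunit.

    100 minus the global-alignment percent identity; gap columns count as
    differences.
    """
    return 100.0 - align.global_identity(cluster_consensus, canonical)


def points_to_features(points: Sequence[InversionPoint]) -> list[Feature]:
    return [Feature(
        Interval(p.contig_id, p.position, p.position + 1, "."),
        "inversion_point",
        {"left_strand": p.left_strand, "right_strand": p.right_strand},
    ) for p in points]


def subarrays_to_features(arrays: Sequence[SatArray]) -> list[Feature]:
    feats = []
    for a in arrays:
        for b in a.subarrays:
            feats.append(Feature(b.interval, "satellite_subarray", {
                "family_id": a.family_id,
                "monomer_count": str(b.monomer_count),
            }))
    return feats


def one_directional_vs_inverted(metrics: Sequence[MacrodyadMetrics]
                                ) -> tuple[list[int], list[int]]:
    """Array lengths split into one-directional vs inversion-bearing classes."""
    plain = [m.array.length for m in metrics if m.n_subarrays == 1]
    inverted = [m.array.length for m in metrics if m.n_subarrays >= 2]
    return plain, inverted


def diff_distribution_summary(metrics: Sequence[MacrodyadMetrics]
                              ) -> dict[str, float]:
    diffs = np.array([d for m in metrics for d in m.direct_inverted_diffs],
                     dtype=float)
    if diffs.size == 0:
        return {"n": 0, "mean": float("nan"), "sd": float("nan")}
    return {"n": int(diffs.size), "mean": float(diffs.mean()),
            "sd": float(diffs.std(ddof=1)) if diffs.size > 1 else 0.0}
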