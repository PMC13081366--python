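"""Satellite monomer annotation against a consensus library.

The search contract is: every local alignment of a consensus (either strand)
that passes the percent-identity and query-coverage filters is reported with
genomic coordinates.  The alignment engine is NCBI blastn (``-task blastn``),
run with low-complexity filtering disabled — the targets here *are*
low-complexity tandem repeats.  Filtering is applied in this module from the
raw HSP fields, so the published thresholds (identity >= 70, qcovhsp >= 70)
are the normative part, not engine internals.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .core_io import (Feature, GenomeSequence, Interval, load_sequences,
                      sort_intervals, write_fasta)

logger = logging.getLogger(__name__)

MIN_CONSENSUS_LENGTH = 20

_STRAND_RANK = {"+": 0, "-": 1}


@dataclass
class SatFamily:
    """A satellite family: consensus monomer plus optional named subunits.

    Subunits are (name, offset, length) spans within the monomer; they must
    not overlap.  ``at_fraction`` is the A+T share of the consensus.
    """

    family_id: str
    consensus: str
    subunits: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.consensus = self.consensus.upper()
        spans = sorted((off, off + ln) for _, off, ln in self.subunits)
        for (s0, e0), (s1, e1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(f"{self.family_id}: overlapping subunits")
        for s, e in spans:
            if s < 0 or e > len(self.consensus):
                raise ValueError(f"{self.family_id}: subunit outside monomer")

    @property
    def monomer_length(self) -> int:
        return len(self.consensus)

    @property
    def at_fraction(self) -> float:
        c = self.consensus
        return (c.count("A") + c.count("T")) / len(c)

    def subunit_sequence(self, name: str) -> str:
        for n, off, ln in self.subunits:
            if n == name:
                return self.consensus[off:off + ln]
        raise KeyError(name)


def load_families(path: str | Path) -> list[SatFamily]:
    """Read a consensus library FASTA; record id becomes family_id."""
    return [SatFamily(rec.contig_id, rec.residues)
            for rec in load_sequences(path)]


@dataclass
class MonomerHit:
    """One retained local alignment of a family consensus to the genome."""

    family_id: str
    interval: Interval
    percent_identity: float
    query_coverage: float
    score: float

    def sort_key(self):
        return self.interval.sort_key() + (self.family_id,)


def _resolve_blastn() -> str:
    exe = shutil.which("blastn")
    if exe is None:
        raise RuntimeError(
            "blastn executable not found on PATH; the monomer search engine "
            "requires NCBI BLAST+")
    return exe


def search_monomers(genome: Sequence[GenomeSequence],
                    families: Sequence[SatFamily],
                    min_identity: float = 70.0,
                    min_qcov: float = 70.0) -> list[MonomerHit]:
    """Find monomer copies of each family in the genome, both strands.

    Hits below ``min_identity`` percent identity or covering less than
    ``min_qcov`` percent of the consensus length are discarded.  Results are
    deterministic given the inputs.
    """
    if not families:
        raise ValueError("families must be non-empty")
    if not (0 < min_identity <= 100) or not (0 < min_qcov <= 100):
        raise ValueError("thresholds must lie in (0, 100]")
    for fam in families:
        if fam.monomer_length < MIN_CONSENSUS_LENGTH:
            raise ValueError(
                f"consensus {fam.family_id} shorter than "
                f"{MIN_CONSENSUS_LENGTH} bp: seeding unreliable")
    if not genome:
        return []

    qlen = {f.family_id: f.monomer_length for f in families}
    exe = _resolve_blastn()
    with tempfile.TemporaryDirectory(prefix="satarch_blast_") as tmp:
        tmp = Path(tmp)
        qpath, spath = tmp / "library.fa", tmp / "genome.fa"
        write_fasta([(f.family_id, f.consensus) for f in families], qpath)
        write_fasta(genome, spath)
        cmd = [
            exe, "-task", "blastn",
            "-query", str(qpath), "-subject", str(spath),
            "-outfmt", "6 qseqid sseqid pident length qstart qend sstart send bitscore",
            "-dust", "no", "-soft_masking", "false",
            "-evalue", "1e-5",
            "-perc_identity", str(min_identity),
            "-max_target_seqs", str(max(500, len(genome))),
            "-num_threads", "1",
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise RuntimeError(f"blastn failed: {proc.stderr.strip()}")
        lines = proc.stdout.splitlines()

    hits: list[MonomerHit] = []
    for line in lines:
        if not line.strip():
            continue
        (qseqid, sseqid, pident, _length, qstart, qend,
         sstart, send, bitscore) = line.split("\t")
        qstart, qend = int(qstart), int(qend)
        sstart, send = int(sstart), int(send)
        coverage = 100.0 * (qend - qstart + 1) / qlen[qseqid]
        identity = float(pident)
        if identity < min_identity or coverage < min_qcov:
            continue
        strand = "+" if sstart <= send else "-"
        lo, hi = (sstart, send) if strand == "+" else (send, sstart)
        hits.append(MonomerHit(
            family_id=qseqid,
            interval=Interval(sseqid, lo - 1, hi, strand),
            percent_identity=identity,
            query_coverage=coverage,
            score=float(bitscore),
        ))
    hits.sort(key=MonomerHit.sort_key)
    return hits


def resolve_overlaps(hits: Iterable[MonomerHit],
                     max_overlap_fraction: float = 0.1) -> list[MonomerHit]:
    """Retain best-scoring hits per genomic location.

    Greedy by descending score (ties: higher identity, then leftmost, then
    '+' strand); a hit is accepted iff its overlap with every already
    accepted hit is at most ``max_overlap_fraction`` of the shorter of the
    two.  This forbids nested and near-duplicate calls while tolerating
    micro-overlaps from alignment fuzz.
    """
    order = sorted(hits, key=lambda h: (
        -h.score, -h.percent_identity, h.interval.contig_id,
        h.interval.start, h.interval.end, _STRAND_RANK[h.interval.strand],
        h.family_id))
    accepted_by_contig: dict[str, list[MonomerHit]] = {}
    for h in order:
        contig = h.interval.contig_id
        ok = True
        for a in accepted_by_contig.get(contig, []):
            ov = h.interval.overlap(a.interval)
            if ov > max_overlap_fraction * min(len(h.interval), len(a.interval)):
                ok = False
                break
        if ok:
            accepted_by_contig.setdefault(contig, []).append(h)
    out = [h for lst in accepted_by_contig.values() for h in lst]
    out.sort(key=MonomerHit.sort_key)
    return out


@dataclass
class AnnotationSummary:
    """Per-family copy counts, bp totals and genome fractions."""

    per_family: pd.DataFrame  # index family_id; columns copy_count/total_bp/genome_fraction
    assembly_bp: int
    total_copies: int
    total_bp: int

    @property
    def total_genome_fraction(self) -> float:
        return 100.0 * self.total_bp / self.assembly_bp


def summarize_annotation(hits: Sequence[MonomerHit],
                         genome: Sequence[GenomeSequence],
                         families: Sequence[SatFamily] | None = None
                         ) -> AnnotationSummary:
    assembly_bp = sum(len(g) for g in genome)
    fam_ids = sorted({h.family_id for h in hits})
    if families is not None:
        fam_ids = sorted(set(fam_ids) | {f.family_id for f in families})
    rows = []
    for fam in fam_ids:
        fam_hits = [h for h in hits if h.family_id == fam]
        bp = sum(len(h.interval) for h in fam_hits)
        rows.append({
            "family_id": fam,
            "copy_count": len(fam_hits),
            "total_bp": bp,
            "genome_fraction": 100.0 * bp / assembly_bp if assembly_bp else 0.0,
        })
    df = pd.DataFrame(rows, columns=["family_id", "copy_count", "total_bp",
                                     "genome_fraction"]).set_index("family_id")
    return AnnotationSummary(
        per_family=df,
        assembly_bp=assembly_bp,
        total_copies=int(df["copy_count"].sum()) if len(df) else 0,
        total_bp=int(df["total_bp"].sum()) if len(df) else 0,
    )


def hits_to_features(hits: Iterable[MonomerHit]) -> list[Feature]:
    return [Feature(h.interval, "satellite_monomer", {
        "family_id": h.family_id,
        "identity": f"{h.percent_identity:.2f}",
        "qcov": f"{h.query_coverage:.2f}",
        "score": f"{h.score:.1f}",
    }) for h in hits]


def monomer_intervals(hits: Iterable[MonomerHit],
                      family_id: str | None = None) -> list[Interval]:
    ivs = [h.interval for h in hits
           if family_id is None or h.family_id == family_id]
    return sort_intervals(ivs)
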