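"""Domain primitives, coordinate conventions and annotation file IO.

All internal coordinates are 0-based half-open intervals.  GFF3 is emitted
1-based inclusive, BED stays 0-based half-open.  Sorting everywhere uses the
key (contig, start, end, strand) with '+' < '-' < '.', so outputs are
deterministic byte-for-byte.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

VALID_BASES = set("ACGTN")
_STRAND_ORDER = {"+": 0, "-": 1, ".": 2}

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GenomeSequence:
    """One contig: an identifier plus an uppercase A/C/G/T/N residue string."""

    contig_id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.contig_id:
            raise ValueError("contig_id must be non-empty")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Interval:
    """Genomic interval, 0-based half-open, strand in {+, -, .}."""

    contig_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in _STRAND_ORDER:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self):
        return (self.contig_id, self.start, self.end, _STRAND_ORDER[self.strand])

    def overlap(self, other: "Interval") -> int:
        """Overlap in bp with another interval (0 if different contigs)."""
        if self.contig_id != other.contig_id:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def gap_to(self, other: "Interval") -> int:
        """Gap in bp to another interval on the same contig; 0 if overlapping."""
        if self.contig_id != other.contig_id:
            raise ValueError("gap_to requires intervals on the same contig")
        return max(0, max(self.start, other.start) - min(self.end, other.end))


@dataclass
class Feature:
    """A located annotation: an interval, a type, and free-form attributes."""

    interval: Interval
    feature_type: str
    attributes: dict[str, str] = field(default_factory=dict)

    def sort_key(self):
        return self.interval.sort_key() + (self.feature_type,)


def sort_intervals(items: Iterable[Interval]) -> list[Interval]:
    return sorted(items, key=Interval.sort_key)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def load_sequences(path: str | Path) -> list[GenomeSequence]:
    """Read a FASTA file into GenomeSequence records, order preserved.

    Lowercase residues are uppercased; anything outside A/C/G/T/N is mapped
    to N (a warning with the substitution count is logged).  Duplicate record
    ids and empty files are hard errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    from Bio import SeqIO

    records: list[GenomeSequence] = []
    seen: set[str] = set()
    n_subst = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate contig id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        cleaned = []
        for ch in seq:
            if ch in VALID_BASES:
                cleaned.append(ch)
            else:
                cleaned.append("N")
                n_subst += 1
        records.append(GenomeSequence(rec.id, "".join(cleaned)))
    if not records:
        raise ValueError(f"{path} contains no FASTA records")
    if n_subst:
        logger.warning("%s: %d non-ACGTN residues mapped to N", path, n_subst)
    return records


def write_fasta(records: Iterable[tuple[str, str] | GenomeSequence],
                path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, GenomeSequence):
                name, seq = rec.contig_id, rec.residues
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def genome_dict(genome: Sequence[GenomeSequence]) -> dict[str, GenomeSequence]:
    return {g.contig_id: g for g in genome}


# ---------------------------------------------------------------------------
# Interval algebra
# ---------------------------------------------------------------------------

def interval_merge(items: Iterable[Interval], max_gap: int) -> list[Interval]:
    """Single-linkage merge per contig, strand ignored.

    Two intervals join iff the gap between them is <= ``max_gap``; the result
    is sorted and pairwise separated by more than ``max_gap``.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out: list[Interval] = []
    for iv in sort_intervals(items):
        if out and out[-1].contig_id == iv.contig_id and \
                iv.start - out[-1].end <= max_gap:
            last = out[-1]
            if iv.end > last.end:
                out[-1] = Interval(last.contig_id, last.start, iv.end)
        else:
            out.append(Interval(iv.contig_id, iv.start, iv.end))
    return out


def interval_subtract(items: Iterable[Interval],
                      mask: Iterable[Interval]) -> list[Interval]:
    """Remove every masked sub-segment from each item; drop empty remnants.

    Strand of each remnant is inherited from its source item.
    """
    mask_by_contig: dict[str, list[Interval]] = {}
    for m in sort_intervals(mask):
        mask_by_contig.setdefault(m.contig_id, []).append(m)
    out: list[Interval] = []
    for iv in sort_intervals(items):
        segments = [(iv.start, iv.end)]
        for m in mask_by_contig.get(iv.contig_id, []):
            if m.start >= iv.end:
                break
            if m.end <= iv.start:
                continue
            nxt: list[tuple[int, int]] = []
            for s, e in segments:
                if m.end <= s or m.start >= e:
                    nxt.append((s, e))
                    continue
                if m.start > s:
                    nxt.append((s, m.start))
                if m.end < e:
                    nxt.append((m.end, e))
            segments = nxt
        for s, e in segments:
            if e > s:
                out.append(Interval(iv.contig_id, s, e, iv.strand))
    return out


def interval_nearest(query: Interval,
                     targets: Sequence[Interval]) -> tuple[Interval, int] | None:
    """Closest target on the query's contig by gap distance (0 if overlapping).

    Ties are broken by leftmost target start.  Returns ``None`` when no target
    shares the query's contig ("no neighbor").
    """
    if not targets:
        raise ValueError("targets must be non-empty")
    best: tuple[int, int, int, Interval] | None = None
    for t in targets:
        if t.contig_id != query.contig_id:
            continue
        d = query.gap_to(t)
        key = (d, t.start, t.end)
        if best is None or key < best[:3]:
            best = (d, t.start, t.end, t)
    if best is None:
        return None
    return best[3], best[0]


def total_bp(items: Iterable[Interval]) -> int:
    return sum(len(iv) for iv in items)


# ---------------------------------------------------------------------------
# GFF3 / BED
# ---------------------------------------------------------------------------

_GFF_ESCAPE = ";=&,\t\n%"


def _gff_quote(value: str) -> str:
    return urllib.parse.quote(value, safe="".join(
        c for c in map(chr, range(33, 127)) if c not in _GFF_ESCAPE))


def write_gff3(features: Iterable[Feature], path: str | Path,
               source: str = "satarch") -> None:
    """Write features as GFF3 (coordinates converted to 1-based inclusive)."""
    feats = sorted(features, key=Feature.sort_key)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in feats:
            iv = f.interval
            attrs = ";".join(f"{_gff_quote(k)}={_gff_quote(v)}"
                             for k, v in sorted(f.attributes.items()))
            fh.write("\t".join([
                iv.contig_id, source, f.feature_type,
                str(iv.start + 1), str(iv.end), ".", iv.strand, ".",
                attrs or ".",
            ]) + "\n")


def read_gff3(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _source, ftype, start, end, _score, strand, _phase, attrs = cols
            attributes: dict[str, str] = {}
            if attrs != ".":
                for pair in attrs.split(";"):
                    if not pair:
                        continue
                    k, _, v = pair.partition("=")
                    attributes[urllib.parse.unquote(k)] = urllib.parse.unquote(v)
            feats.append(Feature(
                Interval(contig, int(start) - 1, int(end), strand),
                ftype, attributes))
    return feats


def write_bed(features: Iterable[Feature], path: str | Path,
              name_attr: str = "name") -> None:
    """Write features as BED6; the name column comes from ``name_attr``."""
    feats = sorted(features, key=Feature.sort_key)
    with open(path, "w") as fh:
        for f in feats:
            iv = f.interval
            name = f.attributes.get(name_attr, f.feature_type)
            fh.write("\t".join([
                iv.contig_id, str(iv.start), str(iv.end),
                name, "0", iv.strand,
            ]) + "\n")


def read_bed(path: str | Path) -> list[Feature]:
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            cols = line.rstrip("\n").split("\t")
            contig, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 else "."
            strand = cols[5] if len(cols) > 5 else "."
            feats.append(Feature(Interval(contig, start, end, strand),
                                 "region", {"name": name}))
    return feats
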