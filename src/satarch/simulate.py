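"""Synthetic genomes with planted satellite architecture and full ground truth.

The generator emulates the architecture the pipeline is built to recover: an
A+T-rich background; a two-subunit major satellite and a seven-subunit minor
satellite with an intra-monomer inverted block; multi-kilobase arrays built
of oriented subarrays with conserved diverged variants at inversion points;
cassettes of the minor family embedded in the major family and delimited by
two conserved transition elements (one carrying an internal deletion, one a
chimeric element with a duplicated 6-mer at its breakpoint); a third family
whose monomers alternate with (AC)n microsatellite spacers; and unlinked
(AC)n decoys in the background.  Every planted feature is emitted as ground
truth, so recovery can be scored exactly.

All randomness flows through one numpy Generator: identical spec + seed give
byte-identical genomes and truth.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .annotate import SatFamily
from .core_io import (Feature, GenomeSequence, Interval, interval_nearest,
                      interval_subtract, revcomp, write_fasta, write_gff3)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_dna(length: int, at_fraction: float,
               rng: np.random.Generator) -> str:
    """i.i.d. DNA with the stated A+T fraction (A=T, C=G)."""
    p_at = at_fraction / 2.0
    p_cg = (1.0 - at_fraction) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_cg, p_cg, p_at])
    return _BASES[codes].tobytes().decode("ascii")


def mutate_copy(consensus: str, divergence: float,
                seed: int | np.random.Generator) -> str:
    """Independent per-site substitution with the given probability.

    Substitutions are uniform over the three alternative bases; no indels.
    """
    if not (0.0 <= divergence <= 0.5):
        raise ValueError("divergence must be in [0, 0.5]")
    rng = _as_rng(seed)
    codes = _CODE[np.frombuffer(consensus.encode("ascii"), dtype=np.uint8)]
    hit = rng.random(codes.shape[0]) < divergence
    shifts = rng.integers(1, 4, size=codes.shape[0])
    mutated = np.where(hit & (codes < 4), (codes + shifts) % 4, codes)
    out = _BASES[np.minimum(mutated, 3)].tobytes().decode("ascii")
    # preserve non-ACGT characters untouched
    if (codes == 255).any():
        out = "".join(o if c != 255 else orig for o, c, orig
                      in zip(out, codes, consensus))
    return out


def mutate_fixed_positions(seq: str, n_positions: int,
                           rng: np.random.Generator) -> str:
    """Substitute exactly n distinct positions (each to a different base)."""
    positions = sorted(rng.choice(len(seq), size=n_positions, replace=False))
    chars = list(seq)
    for pos in positions:
        alternatives = [b for b in "ACGT" if b != chars[pos]]
        chars[pos] = alternatives[int(rng.integers(0, 3))]
    return "".join(chars)


# ---------------------------------------------------------------------------
# Family construction
# ---------------------------------------------------------------------------

@dataclass
class FamilyPlan:
    """Recipe for a satellite family with subunit substructure."""

    family_id: str
    n_subunits: int
    subunit_length: int
    subunit_divergence: float  # sibling subunits diverge this much from base
    at_fraction: float = 0.72
    # (dest_subunit_index, n_subunits, src_subunit_index): the destination
    # span is replaced by the reverse complement of the source span,
    # emulating an intra-monomer inverted block
    inverted_block: tuple[int, int, int] | None = None
    motif_plants: list[tuple[int, str]] = field(default_factory=list)
    prefix: str = ""
    suffix: str = ""

    @property
    def monomer_length(self) -> int:
        return self.n_subunits * self.subunit_length


def make_family(plan: FamilyPlan, seed: int | np.random.Generator) -> SatFamily:
    """Build a SatFamily from a plan.

    A base subunit is generated and sibling subunits derived from it at the
    stated divergence; the monomer is their concatenation, optionally with an
    inverted block (reverse complement of a designated subunit span) and
    planted fixed motifs.
    """
    rng = _as_rng(seed)
    ln = plan.subunit_length
    base = random_dna(ln, plan.at_fraction, rng)
    subs = [base]
    for _ in range(1, plan.n_subunits):
        subs.append(mutate_copy(base, plan.subunit_divergence, rng))
    consensus = "".join(subs)
    if plan.inverted_block is not None:
        dest, n_sub, src = plan.inverted_block
        for idx in (dest, src):
            if not (0 <= idx and idx + n_sub <= plan.n_subunits):
                raise ValueError("inverted block outside monomer")
        d0, d1 = dest * ln, (dest + n_sub) * ln
        s0, s1 = src * ln, (src + n_sub) * ln
        consensus = (consensus[:d0] + revcomp(consensus[s0:s1])
                     + consensus[d1:])
    if plan.prefix:
        consensus = plan.prefix + consensus[len(plan.prefix):]
    if plan.suffix:
        consensus = consensus[:-len(plan.suffix)] + plan.suffix
    for offset, motif in plan.motif_plants:
        if offset + len(motif) > len(consensus):
            raise ValueError("motif plant outside monomer")
        consensus = (consensus[:offset] + motif
                     + consensus[offset + len(motif):])
    names = [f"sub_{chr(ord('A') + i)}" for i in range(plan.n_subunits)]
    subunits = [(names[i], i * ln, ln) for i in range(plan.n_subunits)]
    return SatFamily(plan.family_id, consensus, subunits)


# ---------------------------------------------------------------------------
# Architecture spec
# ---------------------------------------------------------------------------

@dataclass
class ArchitectureSpec:
    """Study conditions for a planted genome (defaults are the reference
    desk-scale scenario: 5 Mb, two intermingled families plus an (AC)n
    spacer family, 40 array loci of which 20 are cassettes)."""

    genome_length: int = 5_000_000
    contig_id: str = "synth1"
    background_at: float = 0.70
    copy_divergence: float = 0.05      # per-site, per monomer copy
    element_divergence: float = 0.01   # per planted element instance

    n_major_arrays: int = 10
    n_minor_standalone: int = 4
    n_ac_arrays: int = 6
    n_cassettes: int = 20

    # cassette element presence probabilities; their product (0.59) is the
    # expected triple-element rate
    p_trans1: float = 0.90
    p_trans2: float = 0.82
    p_inversion: float = 0.80

    min_separation: int = 2_000  # background between independent loci

    # monomer-count laws (log-normal for blocks, clipped)
    major_block_log_mean: float = math.log(20.0)
    major_block_log_sigma: float = 0.5
    major_block_clip: tuple[int, int] = (3, 60)
    cassette_block_log_mean: float = math.log(8.0)
    cassette_block_log_sigma: float = 0.4
    cassette_block_clip: tuple[int, int] = (3, 20)
    subarray_count_probs: tuple[float, ...] = (0.30, 0.45, 0.15, 0.10)
    minor_copies_geom_p: float = 0.45
    minor_copies_max: int = 8
    ac_array_copies: tuple[int, int] = (12, 25)

    # (AC)n spacer/decoy unit-count laws: units = 4 + Geometric(p); spacers
    # are capped below the spacer-family monomer length so the array gap
    # rule always holds (the real system shows the same property)
    ac_spacer_geom_p: float = 0.042
    ac_spacer_max_units: int = 85
    ac_decoy_geom_p: float = 0.35
    n_ac_decoys: int = 40
    microsat_min_units: int = 5
    microsat_link_gap: int = 100

    major_plan: FamilyPlan = field(default_factory=lambda: FamilyPlan(
        "MajSat", n_subunits=2, subunit_length=170, subunit_divergence=0.20,
        motif_plants=[(274, "TTCAAT")]))
    minor_plan: FamilyPlan = field(default_factory=lambda: FamilyPlan(
        "MinSat", n_subunits=7, subunit_length=100, subunit_divergence=0.25,
        inverted_block=(4, 2, 1), motif_plants=[(52, "TTCAAT")]))
    ac_plan: FamilyPlan = field(default_factory=lambda: FamilyPlan(
        "AcSat", n_subunits=1, subunit_length=180, subunit_divergence=0.0,
        at_fraction=0.70, prefix="GG", suffix="TT"))

    # inversion variant divergences from their canonical subunits
    inv1a_divergence: float = 0.235
    inv1b_divergence: float = 0.107
    inv2_n_differences: int = 12

    def validate(self) -> None:
        for frac in (self.background_at, self.copy_divergence,
                     self.element_divergence, self.p_trans1, self.p_trans2,
                     self.p_inversion):
            if not (0.0 <= frac <= 1.0):
                raise ValueError("fractions must lie in [0, 1]")

    @property
    def triple_rate(self) -> float:
        return self.p_trans1 * self.p_trans2 * self.p_inversion


@dataclass
class GroundTruth:
    """Planted features, keyed by class, plus generator-level objects."""

    monomers: list[Feature] = field(default_factory=list)
    arrays: list[Feature] = field(default_factory=list)
    subarrays: list[Feature] = field(default_factory=list)
    inversion_points: list[Feature] = field(default_factory=list)
    transitions: list[Feature] = field(default_factory=list)
    cassettes: list[dict] = field(default_factory=list)
    microsat_runs: list[Feature] = field(default_factory=list)
    families: dict[str, SatFamily] = field(default_factory=dict)
    elements: dict[str, str] = field(default_factory=dict)
    planted_bp: int = 0

    def feature_classes(self) -> dict[str, list[Feature]]:
        return {
            "monomer": self.monomers,
            "array": self.arrays,
            "subarray": self.subarrays,
            "inversion_point": self.inversion_points,
            "transition": self.transitions,
            "microsatellite": self.microsat_runs,
        }

    def write_gff3(self, path: str | Path) -> None:
        feats = [f for lst in self.feature_classes().values() for f in lst]
        write_gff3(feats, path, source="satarch_truth")

    def write_json(self, path: str | Path) -> None:
        def feat(f: Feature) -> dict:
            return {"contig_id": f.interval.contig_id,
                    "start": f.interval.start, "end": f.interval.end,
                    "strand": f.interval.strand, "type": f.feature_type,
                    "attributes": f.attributes}
        payload = {
            "planted_bp": self.planted_bp,
            "elements": self.elements,
            "families": {k: v.consensus for k, v in self.families.items()},
            "cassettes": self.cassettes,
            "features": {cls: [feat(f) for f in lst]
                         for cls, lst in self.feature_classes().items()},
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# Locus assembly helpers
# ---------------------------------------------------------------------------

class _Locus:
    """A planted locus assembled left to right, with features recorded in
    locus-relative coordinates and shifted on placement."""

    def __init__(self, contig_id: str) -> None:
        self.contig = contig_id
        self.parts: list[str] = []
        self.offset = 0
        self.features: list[Feature] = []
        self.cassette: dict | None = None

    def add(self, seq: str) -> tuple[int, int]:
        start = self.offset
        self.parts.append(seq)
        self.offset += len(seq)
        return start, self.offset

    def feature(self, start: int, end: int, ftype: str, strand: str = ".",
                **attrs: str) -> Feature:
        f = Feature(Interval(self.contig, start, end, strand), ftype,
                    {k: str(v) for k, v in attrs.items()})
        self.features.append(f)
        return f

    @property
    def sequence(self) -> str:
        return "".join(self.parts)


def _shift(feature: Feature, offset: int) -> Feature:
    iv = feature.interval
    return Feature(Interval(iv.contig_id, iv.start + offset,
                            iv.end + offset, iv.strand),
                   feature.feature_type, dict(feature.attributes))


def _largest_remainder(n: int, probs: Sequence[float]) -> list[int]:
    """Integer allocation of n items over cells by largest remainder."""
    quotas = [n * p for p in probs]
    counts = [int(math.floor(q)) for q in quotas]
    short = n - sum(counts)
    order = sorted(range(len(probs)),
                   key=lambda i: (-(quotas[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def allocate_cassette_flags(n: int, p1: float, p2: float, p_inv: float,
                            rng: np.random.Generator
                            ) -> list[tuple[bool, bool, bool]]:
    """Element-presence flags for n cassettes with exact composition.

    The joint cell probabilities are the products of the three independent
    presence probabilities; counts are fixed by largest-remainder rounding
    (so the planted population carries exactly the stated rates, e.g. a
    round(n * p1*p2*p_inv) triple-element count) and the order shuffled.
    """
    cells = [(bool(a), bool(b), bool(c))
             for a in (1, 0) for b in (1, 0) for c in (1, 0)]
    probs = [(p1 if a else 1 - p1) * (p2 if b else 1 - p2)
             * (p_inv if c else 1 - p_inv) for a, b, c in cells]
    counts = _largest_remainder(n, probs)
    flags = [cell for cell, cnt in zip(cells, counts) for _ in range(cnt)]
    return [flags[i] for i in rng.permutation(len(flags))]


# ---------------------------------------------------------------------------
# Main generator
# ---------------------------------------------------------------------------

def plant_architecture(spec: ArchitectureSpec, seed: int
                       ) -> tuple[list[GenomeSequence], GroundTruth]:
    """Generate a genome with the planted architecture and its ground truth."""
    spec.validate()
    rng = np.random.default_rng(seed)
    truth = GroundTruth()

    major = make_family(spec.major_plan, rng)
    minor = make_family(spec.minor_plan, rng)
    acfam = make_family(spec.ac_plan, rng)
    truth.families = {f.family_id: f for f in (major, minor, acfam)}

    # conserved elements, derived once per run
    mad2 = major.consensus[major.monomer_length // 2:]
    inv1a = mutate_copy(mad2, spec.inv1a_divergence, rng)
    inv1b = mutate_copy(mad2, spec.inv1b_divergence, rng)
    sub_fg = minor.consensus[5 * spec.minor_plan.subunit_length:]
    inv2 = mutate_fixed_positions(sub_fg, spec.inv2_n_differences, rng)
    # TRANS_1: 389 bp of major-satellite material with a 60 bp internal
    # deletion.  The donor window starts mid-monomer (offset 97) so that the
    # element's two segments occupy overlapping monomer phases: no single
    # colinear alignment of the consensus can reach the coverage filter
    # there, which keeps the element itself out of the monomer annotation.
    donor = (major.consensus * 2)[97:546]
    trans1 = donor[:200] + donor[260:]
    # TRANS_2: 124 bp chimera; the minor part ends with TTCAAT and the major
    # part begins with it (the motif sits at the truncation point of both
    # donors), and each part continues its neighbour's tandem register.
    trans2 = minor.consensus[:58] + major.consensus[274:]
    truth.elements = {"INV_1a": inv1a, "INV_1b": inv1b, "INV_2": inv2,
                      "TRANS_1": trans1, "TRANS_2": trans2}

    def copy_of(fam: SatFamily, strand: str) -> str:
        c = mutate_copy(fam.consensus, spec.copy_divergence, rng)
        return c if strand == "+" else revcomp(c)

    def element_of(canonical: str) -> str:
        return mutate_copy(canonical, spec.element_divergence, rng)

    def block(locus: _Locus, fam: SatFamily, strand: str, n: int
              ) -> tuple[int, int]:
        b0 = locus.offset
        for _ in range(n):
            s, e = locus.add(copy_of(fam, strand))
            locus.feature(s, e, "monomer", strand, family_id=fam.family_id)
        locus.feature(b0, locus.offset, "subarray", strand,
                      family_id=fam.family_id, monomer_count=n)
        return b0, locus.offset

    def lognormal_count(mean: float, sigma: float,
                        clip: tuple[int, int]) -> int:
        n = int(round(rng.lognormal(mean, sigma)))
        return int(np.clip(n, clip[0], clip[1]))

    def inversion_variant(locus: _Locus, fam: SatFamily, canonical_name: str
                          ) -> None:
        canonical = truth.elements[canonical_name]
        s, e = locus.add(element_of(canonical))
        locus.feature(s, e, "inversion_variant", ".",
                      family_id=fam.family_id, variant=canonical_name)
        locus.feature((s + e) // 2, (s + e) // 2 + 1, "inversion_point", ".",
                      family_id=fam.family_id, variant=canonical_name)

    def array_feature(locus: _Locus, fam: SatFamily, start: int, end: int,
                      n_monomers: int) -> Feature:
        return locus.feature(start, end, "array", ".",
                             family_id=fam.family_id,
                             monomer_count=n_monomers)

    # ---- locus builders ---------------------------------------------------

    def major_array_locus() -> _Locus:
        locus = _Locus(spec.contig_id)
        n_blocks = 1 + int(rng.choice(len(spec.subarray_count_probs),
                                      p=spec.subarray_count_probs))
        strand = "+" if rng.random() < 0.5 else "-"
        a0 = locus.offset
        total = 0
        for b in range(n_blocks):
            if b > 0:
                name = "INV_1a" if rng.random() < 0.4 else "INV_1b"
                inversion_variant(locus, major, name)
            n = lognormal_count(spec.major_block_log_mean,
                                spec.major_block_log_sigma,
                                spec.major_block_clip)
            block(locus, major, strand, n)
            total += n
            strand = "-" if strand == "+" else "+"
        array_feature(locus, major, a0, locus.offset, total)
        return locus

    def minor_copies() -> int:
        n = 2 + int(rng.geometric(spec.minor_copies_geom_p)) - 1
        return min(n, spec.minor_copies_max)

    def minor_array_body(locus: _Locus, has_inv: bool,
                         entry_strand: str, exit_strand: str
                         ) -> tuple[int, int, int]:
        """Plant a minor array; returns (start, end, n_monomers)."""
        a0 = locus.offset
        n = minor_copies()
        if has_inv:
            n = max(n, 2)
            n_entry = 1 + int(rng.integers(0, n - 1))
            block(locus, minor, entry_strand, n_entry)
            inversion_variant(locus, minor, "INV_2")
            block(locus, minor, exit_strand, n - n_entry)
        else:
            block(locus, minor, exit_strand, n)
        return a0, locus.offset, n

    def minor_standalone_locus(has_inv: bool) -> _Locus:
        locus = _Locus(spec.contig_id)
        strand = "+" if rng.random() < 0.5 else "-"
        other = "-" if strand == "+" else "+"
        a0, a1, n = minor_array_body(locus, has_inv, strand, other)
        array_feature(locus, minor, a0, a1, n)
        locus.cassette = {"start": a0, "end": a1,
                          "has_trans1": False, "has_trans2": False,
                          "has_inversion": has_inv}
        return locus

    def cassette_locus(has_t1: bool, has_t2: bool, has_inv: bool) -> _Locus:
        locus = _Locus(spec.contig_id)
        n_left = lognormal_count(spec.cassette_block_log_mean,
                                 spec.cassette_block_log_sigma,
                                 spec.cassette_block_clip)
        b0, b1 = block(locus, major, "+", n_left)
        array_feature(locus, major, b0, b1, n_left)
        if has_t1:
            s, e = locus.add(element_of(trans1))
            locus.feature(s, e, "transition", ".", element="TRANS_1")
        # entry block is '-' when an internal inversion is present, so the
        # exit block (and the TRANS_2 junction) always reads '+'
        a0, a1, n = minor_array_body(locus, has_inv, "-", "+")
        array_feature(locus, minor, a0, a1, n)
        if has_t2:
            s, e = locus.add(element_of(trans2))
            locus.feature(s, e, "transition", ".", element="TRANS_2")
        n_right = lognormal_count(spec.cassette_block_log_mean,
                                  spec.cassette_block_log_sigma,
                                  spec.cassette_block_clip)
        b0, b1 = block(locus, major, "+", n_right)
        array_feature(locus, major, b0, b1, n_right)
        locus.cassette = {"start": a0, "end": a1,
                          "has_trans1": has_t1, "has_trans2": has_t2,
                          "has_inversion": has_inv}
        return locus

    def ac_array_locus() -> _Locus:
        locus = _Locus(spec.contig_id)
        n = int(rng.integers(spec.ac_array_copies[0],
                             spec.ac_array_copies[1] + 1))
        a0 = locus.offset
        for i in range(n):
            if i > 0:
                units = min(4 + int(rng.geometric(spec.ac_spacer_geom_p)),
                            spec.ac_spacer_max_units)
                locus.add("AC" * units)
            s, e = locus.add(copy_of(acfam, "+"))
            locus.feature(s, e, "monomer", "+", family_id=acfam.family_id)
        array_feature(locus, acfam, a0, locus.offset, n)
        return locus

    def decoy_locus() -> _Locus:
        locus = _Locus(spec.contig_id)
        units = 4 + int(rng.geometric(spec.ac_decoy_geom_p))
        locus.add("AC" * units)
        return locus

    # ---- assemble the locus list (order shuffled) -------------------------

    loci: list[_Locus] = []
    for _ in range(spec.n_major_arrays):
        loci.append(major_array_locus())
    standalone_inv = allocate_cassette_flags(
        spec.n_minor_standalone, 0.0, 0.0, spec.p_inversion, rng)
    for _, _, has_inv in standalone_inv:
        loci.append(minor_standalone_locus(has_inv))
    for flags in allocate_cassette_flags(spec.n_cassettes, spec.p_trans1,
                                         spec.p_trans2, spec.p_inversion, rng):
        loci.append(cassette_locus(*flags))
    for _ in range(spec.n_ac_arrays):
        loci.append(ac_array_locus())
    for _ in range(spec.n_ac_decoys):
        loci.append(decoy_locus())
    order = rng.permutation(len(loci))
    loci = [loci[int(i)] for i in order]

    # ---- place loci with background gaps ----------------------------------

    planted_bp = sum(len(l.sequence) for l in loci)
    n_gaps = len(loci) + 1
    background_bp = spec.genome_length - planted_bp
    if background_bp < n_gaps * spec.min_separation:
        raise ValueError(
            f"infeasible packing: {planted_bp} planted bp + minimum "
            f"separation exceeds genome_length {spec.genome_length}")
    extra = background_bp - n_gaps * spec.min_separation
    gap_extra = rng.multinomial(extra, [1.0 / n_gaps] * n_gaps)
    gaps = [spec.min_separation + int(g) for g in gap_extra]

    parts: list[str] = []
    pos = 0
    for gap_len, locus in zip(gaps, loci):
        parts.append(random_dna(gap_len, spec.background_at, rng))
        pos += gap_len
        parts.append(locus.sequence)
        for f in locus.features:
            shifted = _shift(f, pos)
            {
                "monomer": truth.monomers,
                "array": truth.arrays,
                "subarray": truth.subarrays,
                "inversion_point": truth.inversion_points,
                "inversion_variant": truth.inversion_points,  # see below
                "transition": truth.transitions,
            }[f.feature_type].append(shifted)
        if locus.cassette is not None:
            truth.cassettes.append({
                **locus.cassette,
                "start": locus.cassette["start"] + pos,
                "end": locus.cassette["end"] + pos,
            })
        pos += len(locus.sequence)
    parts.append(random_dna(gaps[-1], spec.background_at, rng))

    # keep only true zero-width points in inversion_points; variants move to
    # their own list inside transitions-like bookkeeping via attributes
    points = [f for f in truth.inversion_points
              if f.feature_type == "inversion_point"]
    variants = [f for f in truth.inversion_points
                if f.feature_type == "inversion_variant"]
    truth.inversion_points = points
    truth.transitions.extend(variants)

    genome = [GenomeSequence(spec.contig_id, "".join(parts))]
    truth.planted_bp = planted_bp

    truth.microsat_runs = _truth_microsat_runs(genome, truth, spec)
    return genome, truth


_AC_RUN = re.compile(r"(?:AC)+A?|(?:CA)+C?")


def _truth_microsat_runs(genome: Sequence[GenomeSequence], truth: GroundTruth,
                         spec: ArchitectureSpec) -> list[Feature]:
    """Scan the finished genome for (AC)n runs and label linkage.

    Scanning the final sequence (rather than echoing planted spacer
    coordinates) makes the truth exact even when background sequence extends
    a planted run or contains spontaneous runs.  Runs are trimmed against the
    planted spacer-family monomers and labelled linked when within the
    linkage gap of one, mirroring the analysis definition.
    """
    ac_monomers = [f.interval for f in truth.monomers
                   if f.attributes.get("family_id") == spec.ac_plan.family_id]
    out: list[Feature] = []
    for contig in genome:
        for m in _AC_RUN.finditer(contig.residues):
            units = (m.end() - m.start()) // 2
            if units < spec.microsat_min_units:
                continue
            run_iv = Interval(contig.contig_id, m.start(),
                              m.start() + 2 * units, "+")
            for rem in interval_subtract([run_iv], ac_monomers):
                rem_units = len(rem) // 2
                if rem_units < 1:
                    continue
                linked = False
                distance = None
                if ac_monomers:
                    res = interval_nearest(rem, ac_monomers)
                    if res is not None and res[1] <= spec.microsat_link_gap:
                        linked = True
                        distance = res[1]
                attrs = {"motif": "AC", "units": str(rem_units),
                         "class": "linked" if linked else "unlinked"}
                if linked:
                    attrs["linked_family"] = spec.ac_plan.family_id
                    attrs["link_distance"] = str(distance)
                out.append(Feature(rem, "microsatellite", attrs))
    return out


def write_outputs(genome: Sequence[GenomeSequence], truth: GroundTruth,
                  out_dir: str | Path) -> dict[str, Path]:
    """Write genome FASTA, consensus library FASTA, truth GFF3 and JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": out_dir / "genome.fa",
        "library": out_dir / "library.fa",
        "truth_gff": out_dir / "truth.gff3",
        "truth_json": out_dir / "truth.json",
    }
    write_fasta(genome, paths["genome"])
    write_fasta([(f.family_id, f.consensus)
                 for f in truth.families.values()], paths["library"])
    truth.write_gff3(paths["truth_gff"])
    truth.write_json(paths["truth_json"])
    return paths


# ---------------------------------------------------------------------------
# Truth comparison
# ---------------------------------------------------------------------------

@dataclass
class TruthComparison:
    recall: float
    precision: float
    n_truth: int
    n_predicted: int
    start_errors: list[int]   # predicted minus truth, matched truth features
    end_errors: list[int]

    @property
    def mean_boundary_error(self) -> float:
        errs = [abs(e) for e in self.start_errors + self.end_errors]
        return float(np.mean(errs)) if errs else 0.0

    @property
    def max_boundary_error(self) -> int:
        errs = [abs(e) for e in self.start_errors + self.end_errors]
        return max(errs) if errs else 0


def truth_compare(predicted: Sequence[Interval | Feature],
                  truth_features: Sequence[Interval | Feature],
                  reciprocal_overlap: float = 0.5) -> TruthComparison:
    """Score predictions against truth by reciprocal-overlap matching.

    A feature on either side counts as matched when some feature on the
    other side overlaps it by at least ``reciprocal_overlap`` of BOTH
    lengths.  Recall is the matched fraction of truth, precision the matched
    fraction of predictions; boundary errors are computed per matched truth
    feature against its best-overlapping prediction.
    """
    def _iv(x) -> Interval:
        return x.interval if isinstance(x, Feature) else x

    pred = [_iv(p) for p in predicted]
    tru = [_iv(t) for t in truth_features]

    def reciprocal(a: Interval, b: Interval) -> bool:
        ov = a.overlap(b)
        return (ov >= reciprocal_overlap * len(a)
                and ov >= reciprocal_overlap * len(b))

    matched_truth = 0
    start_errors: list[int] = []
    end_errors: list[int] = []
    for t in tru:
        best = None
        for p in pred:
            if reciprocal(t, p):
                ov = t.overlap(p)
                if best is None or ov > best[0]:
                    best = (ov, p)
        if best is not None:
            matched_truth += 1
            start_errors.append(best[1].start - t.start)
            end_errors.append(best[1].end - t.end)
    matched_pred = sum(1 for p in pred if any(reciprocal(t, p) for t in tru))
    return TruthComparison(
        recall=matched_truth / len(tru) if tru else 1.0,
        precision=matched_pred / len(pred) if pred else 1.0,
        n_truth=len(tru),
        n_predicted=len(pred),
        start_errors=start_errors,
        end_errors=end_errors,
    )
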