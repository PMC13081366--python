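"""One-shot pipeline driver: annotate -> arrays -> symmetry -> junctions ->
microsat (-> compare), with all artifacts written to an output directory and
listed in a content-hashed MANIFEST."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import arrays as arr
from . import comparative as comp
from . import junctions as jx
from . import microsat as ms
from . import symmetry as sym
from .core_io import Feature, GenomeSequence, load_sequences, write_gff3, write_bed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    genome: str = ""
    library: str = ""
    out_dir: str = "satarch_out"
    seed: int = 0

    # annotation
    min_identity: float = 70.0
    min_qcov: float = 70.0
    max_overlap_fraction: float = 0.1
    min_tandem: int = 5

    # symmetry
    window_radius: int = 200
    site_identity_threshold: float = 90.0

    # junctions (major/minor default to the two most abundant families)
    major_family: str = "auto"
    minor_family: str = "auto"
    adjacency_max_gap: int = 1000
    junction_pad: int = 250
    junction_identity_threshold: float = 90.0
    transition_min_gap: int = 20

    # microsatellites
    microsat_motif: str = "AC"
    microsat_min_units: int = 5
    microsat_link_gap: int = 100
    microsat_link_family: str = "auto"

    # comparative (optional second genome)
    compare_genome: str = ""
    kmer_k: int = 16
    kmer_max_distance: int = 3

    stages: list[str] = field(default_factory=lambda: [
        "annotate", "arrays", "symmetry", "junctions", "microsat"])

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update(overrides)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class PipelineResult:
    config: PipelineConfig
    genome: list[GenomeSequence]
    families: list[ann.SatFamily]
    hits: list[ann.MonomerHit] = field(default_factory=list)
    summary: ann.AnnotationSummary | None = None
    arrays: list[arr.SatArray] = field(default_factory=list)
    satellite_status: dict[str, bool] = field(default_factory=dict)
    array_stats: dict[str, arr.ArrayStats] = field(default_factory=dict)
    inversion_points: list[sym.InversionPoint] = field(default_factory=list)
    macrodyad: list[sym.MacrodyadMetrics] = field(default_factory=list)
    sites: list[sym.InversionSite] = field(default_factory=list)
    site_clusters: list[sym.SiteCluster] = field(default_factory=list)
    adjacencies: list[jx.Adjacency] = field(default_factory=list)
    junction_records: list[jx.JunctionRecord] = field(default_factory=list)
    transition_clusters: list[jx.TransitionCluster] = field(default_factory=list)
    transition_types: dict[str, str] = field(default_factory=dict)
    cassette_report: jx.CassetteReport | None = None
    microsat_runs: list[ms.MicrosatRun] = field(default_factory=list)
    linkage: ms.LinkageStats | None = None
    scan_regions: list[comp.ScanRegion] = field(default_factory=list)
    manifest: dict[str, str] = field(default_factory=dict)

    def arrays_of(self, family_id: str) -> list[arr.SatArray]:
        return [a for a in self.arrays if a.family_id == family_id]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _pick_major_minor(result: PipelineResult) -> tuple[str, str]:
    per = result.summary.per_family.sort_values(
        ["total_bp", "family_id"], ascending=[False, True])
    fams = list(per.index)
    if len(fams) < 2:
        raise ValueError("junction analysis needs at least two families")
    return fams[0], fams[1]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the configured stages and write all artifacts.

    Outputs: GFF3 for monomers/arrays/subarrays/inversion points, BED for
    microsatellite runs, TSV statistics tables, JSON reports, a copy of the
    effective configuration and a MANIFEST with a sha256 per output file.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "run_config.yaml")

    genome = load_sequences(config.genome)
    families = ann.load_families(config.library)
    result = PipelineResult(config, genome, families)
    fam_by_id = {f.family_id: f for f in families}
    outputs: list[Path] = [out / "run_config.yaml"]

    def write_tsv(df: pd.DataFrame, name: str, index: bool = True) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=index)
        outputs.append(path)

    def write_json_file(payload: Any, name: str) -> None:
        path = out / name
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        outputs.append(path)

    if "annotate" in config.stages:
        raw = ann.search_monomers(genome, families, config.min_identity,
                                  config.min_qcov)
        result.hits = ann.resolve_overlaps(raw, config.max_overlap_fraction)
        result.summary = ann.summarize_annotation(result.hits, genome, families)
        path = out / "monomers.gff3"
        write_gff3(ann.hits_to_features(result.hits), path)
        outputs.append(path)
        write_tsv(result.summary.per_family, "annotation_summary.tsv")

    if "arrays" in config.stages and result.hits:
        result.arrays = arr.build_arrays(result.hits, families)
        result.satellite_status = {
            f.family_id: arr.classify_satellite(f.family_id, result.arrays,
                                                config.min_tandem)
            for f in families}
        result.array_stats = arr.array_stats(result.arrays)
        path = out / "arrays.gff3"
        write_gff3(arr.arrays_to_features(result.arrays), path)
        outputs.append(path)
        stats_df = pd.DataFrame([
            {"family_id": s.family_id, "n_arrays": s.n_arrays,
             "median_length": s.median_length, "max_length": s.max_length,
             "is_satellite": result.satellite_status.get(s.family_id, False)}
            for s in result.array_stats.values()]).set_index("family_id")
        write_tsv(stats_df, "array_stats.tsv")

    if "symmetry" in config.stages and result.arrays:
        for a in result.arrays:
            _, points = sym.decompose_subarrays(a, fam_by_id[a.family_id])
            result.inversion_points.extend(points)
            result.macrodyad.append(sym.macrodyad_metrics(a))
        result.sites = sym.extract_inversion_sites(
            result.inversion_points, genome, config.window_radius)
        if result.sites:
            result.site_clusters = sym.cluster_sites(
                result.sites, config.site_identity_threshold)
        path = out / "subarrays.gff3"
        write_gff3(sym.subarrays_to_features(result.arrays), path)
        outputs.append(path)
        path = out / "inversion_points.gff3"
        write_gff3(sym.points_to_features(result.inversion_points), path)
        outputs.append(path)
        write_json_file({
            "n_inversion_points": len(result.inversion_points),
            "clusters": [{
                "label": c.label, "size": c.size, "minor": c.minor,
                "mean_pairwise_identity": c.mean_pairwise_identity,
                "consensus": c.consensus} for c in result.site_clusters],
            "diff_summary": sym.diff_distribution_summary(result.macrodyad),
        }, "symmetry_report.json")

    if "junctions" in config.stages and result.arrays:
        major, minor = config.major_family, config.minor_family
        if major == "auto" or minor == "auto":
            major, minor = _pick_major_minor(result)
        try:
            result.adjacencies = jx.find_adjacencies(
                result.arrays, major, minor, config.adjacency_max_gap)
        except KeyError:
            result.adjacencies = []
        if result.adjacencies:
            result.junction_records = [
                jx.extract_junction(genome, adj, config.junction_pad)
                for adj in result.adjacencies]
            result.transition_clusters = jx.classify_transitions(
                result.junction_records, config.junction_identity_threshold)
            result.transition_types = jx.assign_transition_types(
                result.transition_clusters, result.junction_records, minor,
                min_gap=config.transition_min_gap)
            minor_arrays = result.arrays_of(minor)
            result.cassette_report = jx.cassette_census(
                minor_arrays, result.junction_records,
                result.transition_types, result.inversion_points)
            write_json_file({
                "major_family": major, "minor_family": minor,
                "n_adjacencies": len(result.adjacencies),
                "clusters": [{
                    "label": c.label, "size": c.size,
                    "prevalence": c.prevalence,
                    "type": result.transition_types.get(c.label, "none"),
                } for c in result.transition_clusters],
                "venn": result.cassette_report.venn,
                "n_minor_arrays": result.cassette_report.n_arrays,
                "triple_fraction": result.cassette_report.triple_fraction,
            }, "cassette_report.json")

    if "microsat" in config.stages:
        runs = ms.find_dinuc_runs(genome, config.microsat_motif,
                                  config.microsat_min_units)
        link_family = config.microsat_link_family
        if link_family == "auto" and result.hits:
            # family whose monomers lie nearest to the most runs
            counts: dict[str, int] = {}
            for fam in fam_by_id:
                linked = ms.link_runs(runs, result.hits, fam,
                                      config.microsat_link_gap)
                counts[fam] = sum(1 for r in linked if r.linked_family)
            link_family = sorted(counts.items(),
                                 key=lambda kv: (-kv[1], kv[0]))[0][0]
        if link_family != "auto":
            result.microsat_runs = ms.link_runs(
                runs, result.hits, link_family, config.microsat_link_gap)
        else:
            result.microsat_runs = runs
        result.linkage = ms.linkage_stats(result.microsat_runs)
        path = out / "microsat_runs.bed"
        write_bed(ms.runs_to_features(result.microsat_runs), path,
                  name_attr="class")
        outputs.append(path)
        write_tsv(result.linkage.table, "microsat_stats.tsv")

    if "compare" in config.stages and config.compare_genome:
        target = load_sequences(config.compare_genome)
        all_hits: list[comp.ScanHit] = []
        for fam in families:
            kset = comp.kmerize(fam.consensus, config.kmer_k)
            all_hits.extend(comp.approx_scan(target, kset,
                                             config.kmer_max_distance))
        result.scan_regions = comp.merge_hits(all_hits,
                                              max_gap=config.kmer_k)
        df = pd.DataFrame([{
            "contig_id": r.interval.contig_id, "start": r.interval.start,
            "end": r.interval.end, "n_hits": r.n_hits,
            "min_edit_distance": r.min_edit_distance}
            for r in result.scan_regions])
        write_tsv(df, "scan_regions.tsv", index=False)

    manifest = {str(p.relative_to(out)): _sha256(p) for p in outputs}
    (out / "MANIFEST.tsv").write_text(
        "".join(f"{name}\t{digest}\n"
                for name, digest in sorted(manifest.items())))
    result.manifest = manifest
    return result
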