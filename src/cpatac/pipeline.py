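"""End-to-end orchestration: config, stage sequencing, manifests.

A run executes insertions → accessibility → footprints → FPD/bias →
selection → NUPT in order, writing every artifact plus a manifest
(inputs, parameters, seed, version) so that re-running the same config
reproduces identical outputs.  A single global seed is fanned out to
per-stage seeds by a fixed derivation rule, so stages can be rerun in
isolation.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__, accessibility, io, nupt, selection
from .footprinting import (
    FootprintCallParams,
    bias_correct,
    detect_footprints,
    fpd_correlation,
)

logger = logging.getLogger(__name__)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    mix = np.random.SeedSequence([int(global_seed), zlib.crc32(stage.encode())])
    return int(mix.generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    genome_fasta: str
    annotation_gff: str
    atac: str  # SAM/BAM alignments or a .bedgraph insertion track
    outdir: str
    operons_tsv: str | None = None
    gdna: str | None = None
    rna_coverage: str | None = None
    expression_tsv: str | None = None
    gerp_tsv: str | None = None
    nupt_sites: str | None = None
    nupt_alignments: str | None = None
    bin_size: int = 100
    min_mapq: int = 0
    footprint: FootprintCallParams = field(default_factory=FootprintCallParams)
    alignment: selection.AlignmentParams = field(default_factory=selection.AlignmentParams)
    differential_alpha: float = 0.05
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        missing = {"genome_fasta", "annotation_gff", "atac", "outdir"} - set(raw)
        if missing:
            raise ValueError(f"missing required config fields: {sorted(missing)}")
        if "footprint" in raw:
            raw["footprint"] = FootprintCallParams(**raw["footprint"])
        if "alignment" in raw:
            raw["alignment"] = selection.AlignmentParams(**raw["alignment"])
        return cls(**raw)

    def manifest(self) -> dict:
        out = dataclasses.asdict(self)
        out["version"] = __version__
        return out


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns a summary dict (also written as JSON)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {}

    def _stage(name):
        logger.info("pipeline stage: %s", name)

    try:
        _stage("inputs")
        genome = io.read_genome(config.genome_fasta)
        annotation = io.read_annotation(config.annotation_gff,
                                        operon_table=config.operons_tsv,
                                        genome_length=genome.length)

        _stage("insertions")
        if str(config.atac).endswith((".bedgraph", ".bg")):
            track = io.read_track(config.atac, genome.length)
        else:
            track = io.extract_insertions(config.atac, genome, min_mapq=config.min_mapq)
        io.write_track(track, outdir / "insertions.bedgraph")
        summary["total_insertions"] = track.total

        _stage("accessibility")
        bins = accessibility.bin_track(track, config.bin_size)
        np.savetxt(outdir / "bins.tsv", bins.counts, fmt="%g")
        genic, intergenic = annotation.partition(
            genome.length, use_operons=bool(annotation.operons))
        mwu = accessibility.compare_region_classes(track, genic, intergenic)
        summary["genic_vs_intergenic"] = mwu
        if config.rna_coverage:
            rna = io.read_track(config.rna_coverage, genome.length)
            rna_bins = accessibility.bin_track(rna, config.bin_size)
            ct = accessibility.quantile_crosstab(rna_bins.counts, bins)
            np.savetxt(outdir / "quantile_crosstab.tsv", ct.proportions, fmt="%.6f")
            summary["crosstab_top_cell"] = float(ct.proportions[-1, -1])

        _stage("footprints")
        fps = detect_footprints(track, config.footprint,
                                seed=stage_seed(config.seed, "footprints"))
        from .footprinting import write_footprints_bed
        write_footprints_bed(fps, genome.name, outdir / "footprints.bed")
        summary["n_footprints"] = len(fps)

        _stage("bias")
        if config.gdna:
            gdna = (io.read_track(config.gdna, genome.length)
                    if str(config.gdna).endswith((".bedgraph", ".bg"))
                    else io.extract_insertions(config.gdna, genome, config.min_mapq))
            corrected = bias_correct(track, gdna)
            io.write_track(corrected, outdir / "corrected.bedgraph")
            if len(fps) >= 2:
                summary["fpd_correlation"] = fpd_correlation(fps, track, corrected)
        else:
            logger.warning("no gDNA control supplied; bias stage skipped")

        _stage("selection")
        site_classes = selection.classify_degenerate_sites(genome, annotation)
        summary["site_class_counts"] = site_classes.summary()
        t_bp = selection.overlap_contingency(fps.intervals(), "basepair", genome.length,
                                             annotation=annotation)
        t_site = selection.overlap_contingency(fps.intervals(), "site", genome.length,
                                               site_classes=site_classes)
        for name, tab in (("basepair", t_bp), ("site", t_site)):
            res = selection.fisher_exact(tab)
            tab.to_frame().to_csv(outdir / f"contingency_{name}.tsv", sep="\t")
            summary[f"fisher_{name}"] = {"odds_ratio": res.odds_ratio, "p": res.p_floored}
        if config.gerp_tsv:
            scores = io.read_conservation_scores(config.gerp_tsv, genome.length)
            covered = selection.coverage_mask(fps.intervals(), genome.length)
            gerp = selection.gerp_class_test(scores, covered, ~covered)
            gerp.to_csv(outdir / "gerp_classes.tsv", sep="\t", index=False)

        _stage("nupt")
        if config.nupt_sites and config.nupt_alignments:
            sites = io.read_variant_sites(config.nupt_sites)
            counts = nupt.count_alleles(config.nupt_alignments, genome, sites)
            counts.to_csv(outdir / "nupt_counts.tsv", sep="\t", index=False)
            summary["nupt_ratio"] = nupt.nupt_ratio(counts)
    except Exception as exc:  # annotate failures with the stage
        raise RuntimeError(f"pipeline failed: {exc}") from exc

    manifest = {"config": config.manifest(), "summary": _jsonable(summary)}
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=float)
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def make_demo(outdir: str | Path, seed: int = 7, depth: int | None = None) -> dict:
    """One-command synthetic dataset plus an executed pipeline run."""
    from . import simulate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = simulate.SimParams()
    genome, annotation = simulate.simulate_genome(params, seed=stage_seed(seed, "genome"))
    truth = simulate.simulate_truth(genome, annotation, params,
                                    seed=stage_seed(seed, "truth"))
    depth = depth or params.depth
    atac = simulate.simulate_atac(truth, depth, seed=stage_seed(seed, "atac"))
    gdna = simulate.simulate_gdna(truth, depth, seed=stage_seed(seed, "gdna"))
    rna, expression = simulate.simulate_rnaseq_coverage(truth, depth // 5,
                                                        seed=stage_seed(seed, "rna"))

    io.write_genome(genome, outdir / "genome.fasta")
    io.write_gff3(annotation, genome, outdir / "annotation.gff3")
    io.write_operons(annotation.operons, outdir / "operons.tsv")
    io.write_track(atac, outdir / "atac.bedgraph")
    io.write_track(gdna, outdir / "gdna.bedgraph")
    io.write_track(rna, outdir / "rna.bedgraph")
    io.write_expression(expression, outdir / "expression.tsv")
    truth_df = [{"start": fp.interval.start, "end": fp.interval.end,
                 "protection": fp.protection, "tag": fp.tag} for fp in truth.footprints]
    with open(outdir / "truth_footprints.tsv", "w") as fh:
        fh.write("start\tend\tprotection\ttag\n")
        for row in truth_df:
            fh.write(f"{row['start']}\t{row['end']}\t{row['protection']:.4f}\t{row['tag']}\n")

    config = RunConfig(
        genome_fasta=str(outdir / "genome.fasta"),
        annotation_gff=str(outdir / "annotation.gff3"),
        operons_tsv=str(outdir / "operons.tsv"),
        atac=str(outdir / "atac.bedgraph"),
        gdna=str(outdir / "gdna.bedgraph"),
        rna_coverage=str(outdir / "rna.bedgraph"),
        outdir=str(outdir / "report"),
        seed=seed,
    )
    with open(outdir / "run.yaml", "w") as fh:
        cfg = {k: v for k, v in dataclasses.asdict(config).items()
               if not isinstance(v, dict) and v is not None}
        yaml.safe_dump(cfg, fh)
    return run_pipeline(config)
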