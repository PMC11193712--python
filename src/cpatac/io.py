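"""Reading and writing the standard formats the pipeline touches.

FASTA (genome), GFF3 (annotation), SAM/BAM (alignments), bedGraph
(per-base tracks) and small TSV tables (operons, expression,
conservation scores, diagnostic variant sites).  Alignments are turned
into per-base Tn5 insertion tracks with the canonical ATAC shift
(+4 bp on the forward strand, −5 bp from the last aligned base on the
reverse strand), wrapped onto the circular coordinate system.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO

from .core import (
    AnnotationSet,
    CircularGenome,
    FormatError,
    FragmentSet,
    Gene,
    GenomicInterval,
    InsertionTrack,
    Operon,
    functional_class_for,
)

logger = logging.getLogger(__name__)

TN5_FORWARD_SHIFT = 4
TN5_REVERSE_SHIFT = 5


# ---------------------------------------------------------------------------
# FASTA

def read_genome(path: str | Path) -> CircularGenome:
    """Read a single-record FASTA as a circular genome.

    Multi-record files are accepted with a warning; the first record is
    used, matching the single-molecule nature of cpDNA references.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA records in {path}")
    if len(records) > 1:
        logger.warning("%s contains %d records; using the first (%s)",
                       path, len(records), records[0].id)
    rec = records[0]
    return CircularGenome(name=rec.id, sequence=str(rec.seq).upper())


def write_genome(genome: CircularGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{genome.name}\n")
        for i in range(0, genome.length, width):
            fh.write(genome.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 + operon table

def read_annotation(
    path: str | Path,
    operon_table: str | Path | None = None,
    genome_length: int | None = None,
    class_map=None,
) -> AnnotationSet:
    """Parse gene/CDS/rRNA/tRNA features from GFF3 (1-based inclusive).

    Coordinates are converted to 0-based half-open.  The functional
    class is assigned from gene-name prefixes (psa/psb/pet/ndh →
    photosystem; rrn/trn → ribosomal/RNA; rpo → polymerase).
    """
    genes: dict[str, dict] = {}
    children: list[tuple[str, str, GenomicInterval]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            _, _, ftype, start_s, end_s, _, strand, _, attrs_s = cols
            start1, end1 = int(start_s), int(end_s)
            if end1 < start1:
                raise FormatError(f"{path}:{lineno}: end < start")
            if genome_length is not None and end1 > genome_length:
                raise FormatError(f"{path}:{lineno}: coordinates beyond genome length")
            attrs = dict(
                kv.split("=", 1) for kv in attrs_s.split(";") if "=" in kv
            )
            iv = GenomicInterval(start1 - 1, end1, strand=strand if strand in "+-" else ".")
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene feature without ID")
                name = attrs.get("Name", gid)
                genes[gid] = {"id": gid, "name": name, "interval": iv, "children": []}
            elif ftype in ("CDS", "rRNA", "tRNA"):
                parent = attrs.get("Parent", attrs.get("ID", ""))
                children.append((parent, ftype, iv))

    for parent, ftype, iv in children:
        if parent in genes:
            genes[parent]["children"].append((ftype, iv))

    out: list[Gene] = []
    for g in genes.values():
        child_types = {t for t, _ in g["children"]}
        if "CDS" in child_types:
            ftype = "CDS"
        elif "rRNA" in child_types:
            ftype = "rRNA"
        elif "tRNA" in child_types:
            ftype = "tRNA"
        else:
            ftype = "other"
        cds_parts = tuple(
            sorted((iv for t, iv in g["children"] if t == "CDS"), key=lambda iv: iv.start)
        )
        out.append(
            Gene(
                id=g["id"],
                interval=g["interval"],
                feature_type=ftype,
                functional_class=functional_class_for(g["name"], class_map),
                cds_parts=cds_parts,
            )
        )
    out.sort(key=lambda g: g.interval.start)
    ann = AnnotationSet(genes=out, genome_length=genome_length)
    if operon_table is not None:
        ann.operons = read_operons(operon_table, ann)
    return ann


def write_gff3(annotation: AnnotationSet, genome: CircularGenome, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.name} 1 {genome.length}\n")
        for g in annotation.genes:
            iv = g.interval
            fh.write(
                f"{genome.name}\tcpatac\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.id};Name={g.id}\n"
            )
            child = g.feature_type if g.feature_type in ("CDS", "rRNA", "tRNA") else None
            if child:
                for part in g.cds_intervals() if g.feature_type == "CDS" else (iv,):
                    frame = "0" if child == "CDS" else "."
                    fh.write(
                        f"{genome.name}\tcpatac\t{child}\t{part.start + 1}\t{part.end}\t.\t"
                        f"{iv.strand}\t{frame}\tID={g.id}.{child};Parent={g.id}\n"
                    )


def read_operons(path: str | Path, annotation: AnnotationSet) -> list[Operon]:
    """Operon TSV: `operon_id<TAB>gene1,gene2,...`; interval = union span."""
    operons = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            op_id, members_s = line.split("\t")[:2]
            members = tuple(members_s.split(","))
            ivs = [annotation.gene(m).interval for m in members]
            strand = ivs[0].strand if len({iv.strand for iv in ivs}) == 1 else "."
            operons.append(
                Operon(
                    id=op_id,
                    interval=GenomicInterval(
                        min(iv.start for iv in ivs), max(iv.end for iv in ivs), strand=strand
                    ),
                    members=members,
                )
            )
    return operons


def write_operons(operons: list[Operon], path: str | Path) -> None:
    with open(path, "w") as fh:
        for op in operons:
            fh.write(f"{op.id}\t{','.join(op.members)}\n")


# ---------------------------------------------------------------------------
# Alignments → insertions / fragments

def extract_insertions(
    path: str | Path, genome: CircularGenome, min_mapq: int = 0
) -> InsertionTrack:
    """One Tn5 insertion per accepted alignment record.

    Forward read at 0-based leftmost position s → insertion at s+4;
    reverse read whose last aligned base is e−1 → insertion at e−1−5.
    Positions wrap modulo the genome length.  Secondary/supplementary
    and duplicate-flagged records are skipped; records below
    ``min_mapq`` are skipped and counted in the log.
    """
    counts = np.zeros(genome.length, dtype=float)
    skipped_mapq = 0
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate:
                continue
            if read.reference_name != genome.name:
                raise FormatError(
                    f"alignment reference {read.reference_name!r} does not match "
                    f"genome {genome.name!r}"
                )
            if read.mapping_quality < min_mapq:
                skipped_mapq += 1
                continue
            if read.is_reverse:
                pos = (read.reference_end - 1 - TN5_REVERSE_SHIFT) % genome.length
            else:
                pos = (read.reference_start + TN5_FORWARD_SHIFT) % genome.length
            counts[pos] += 1
    if skipped_mapq:
        logger.info("extract_insertions: skipped %d records below MAPQ %d",
                    skipped_mapq, min_mapq)
    return InsertionTrack(genome_name=genome.name, counts=counts, label=Path(path).stem)


def extract_fragments(path: str | Path) -> FragmentSet:
    """Template intervals of properly paired alignments (one per pair)."""
    frags: list[tuple[int, int]] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if not read.is_proper_pair:
                continue
            tlen = read.template_length
            if tlen > 0:  # count each pair once, from the leftmost mate
                frags.append((read.reference_start, read.reference_start + tlen))
    if not frags:
        logger.warning("extract_fragments: no properly paired records in %s", path)
    return FragmentSet(frags)


# ---------------------------------------------------------------------------
# bedGraph tracks

def write_track(track: InsertionTrack, path: str | Path) -> None:
    """Run-length encode a track as bedGraph (zero runs omitted)."""
    counts = track.counts
    change = np.flatnonzero(np.diff(counts)) + 1
    bounds = np.concatenate([[0], change, [counts.size]])
    with open(path, "w") as fh:
        for a, b in zip(bounds[:-1], bounds[1:]):
            v = counts[a]
            if v == 0:
                continue
            v_s = str(int(v)) if float(v).is_integer() else repr(float(v))
            fh.write(f"{track.genome_name}\t{a}\t{b}\t{v_s}\n")


def read_track(path: str | Path, genome_length: int, label: str = "") -> InsertionTrack:
    """Read a bedGraph track; overlap or negative values are format errors."""
    counts = np.zeros(genome_length, dtype=float)
    intervals: list[tuple[int, int]] = []
    name = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            chrom, a_s, b_s, v_s = line.split("\t")[:4]
            name = name or chrom
            a, b, v = int(a_s), int(b_s), float(v_s)
            if v < 0:
                raise FormatError(f"{path}:{lineno}: negative value")
            if b <= a or b > genome_length:
                raise FormatError(f"{path}:{lineno}: bad interval [{a},{b})")
            intervals.append((a, b))
            counts[a:b] = v
    intervals.sort()
    for (a1, b1), (a2, b2) in zip(intervals, intervals[1:]):
        if a2 < b1:
            raise FormatError(f"overlapping bedGraph intervals in {path}")
    return InsertionTrack(genome_name=name or "genome", counts=counts, label=label or Path(path).stem)


# ---------------------------------------------------------------------------
# Small TSV tables

def write_expression(expression: pd.Series, path: str | Path) -> None:
    expression.rename_axis("gene_id").rename("tpm").to_csv(path, sep="\t")


def read_expression(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0]


def read_conservation_scores(path: str | Path, genome_length: int) -> np.ndarray:
    """Per-site score TSV (`pos<TAB>score`, 0-based); unscored sites NaN."""
    df = pd.read_csv(path, sep="\t", names=["pos", "score"], comment="#")
    scores = np.full(genome_length, np.nan)
    scores[df["pos"].to_numpy()] = df["score"].to_numpy()
    return scores


def write_conservation_scores(scores: np.ndarray, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pos in np.flatnonzero(~np.isnan(scores)):
            fh.write(f"{pos}\t{scores[pos]:g}\n")


def read_variant_sites(path: str | Path) -> pd.DataFrame:
    """Diagnostic-site TSV: pos (0-based), ref, alt."""
    df = pd.read_csv(path, sep="\t")
    expected = {"pos", "ref", "alt"}
    if not expected.issubset(df.columns):
        df = pd.read_csv(path, sep="\t", names=["pos", "ref", "alt"], comment="#")
    bad = df[(df["ref"] == df["alt"]) | ~df["ref"].isin(list("ACGT")) | ~df["alt"].isin(list("ACGT"))]
    if len(bad):
        raise FormatError(f"invalid variant sites in {path}: rows {bad.index.tolist()}")
    return df[["pos", "ref", "alt"]]


def write_variant_sites(sites: pd.DataFrame, path: str | Path) -> None:
    sites[["pos", "ref", "alt"]].to_csv(path, sep="\t", index=False)
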