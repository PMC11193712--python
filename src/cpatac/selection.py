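"""Degeneracy classes, overlap contingency tests, cross-species mapping.

Coding sites are classified by degeneracy under the plastid/bacterial
codon table (table 11): a fourfold degenerate site (4DS) is a third
codon position where every substitution is synonymous, a proxy for weak
selective constraint.  Footprint distribution preferences are tested
with Fisher's exact test on 2x2 overlap tables (odds ratio as the
cross-product ratio).  Footprints are mapped across species by local
alignment of the 50-bp window centered on each footprint under
blastn-like scoring (+2 match, -3 mismatch, -5 gap open, -2 extend):
a best hit with score > 85 and aligned length > 45 is "conserved", and
"shared" if the mapped interval overlaps a footprint in the target
species by >= 1 bp.  Per-site conservation (GERP) scores are split
into Low (< 0), Middle ([0, 0.42)) and High (>= 0.42, the observed
maximum) classes, compared between covered and background sites with a
two-proportion Z test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Data import CodonTable
from scipy import stats

from .core import AnnotationSet, CircularGenome, GenomicInterval, revcomp

logger = logging.getLogger(__name__)

# site classes
NONCDS, OTHERCDS, NONDEG, FOURFOLD = 0, 1, 2, 3
SITE_CLASS_NAMES = {NONCDS: "nonCDS", OTHERCDS: "otherCDS",
                    NONDEG: "nonDeg", FOURFOLD: "4DS"}

P_FLOOR = 2.2e-16  # R-style reporting floor


@dataclass
class SiteClassTrack:
    classes: np.ndarray  # int8 per-base codes
    codon_table: int = 11

    def count(self, code: int) -> int:
        return int(np.sum(self.classes == code))

    def summary(self) -> dict[str, int]:
        return {name: self.count(code) for code, name in SITE_CLASS_NAMES.items()}


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def _fourfold_prefixes(table_id: int) -> set[str]:
    """Two-base codon prefixes whose four completions encode one amino acid."""
    codons = _codon_map(table_id)
    out = set()
    for b1 in "ACGT":
        for b2 in "ACGT":
            aas = {codons[b1 + b2 + b3] for b3 in "ACGT"}
            if len(aas) == 1 and "*" not in aas:
                out.add(b1 + b2)
    return out


def classify_degenerate_sites(
    genome: CircularGenome, annotation: AnnotationSet, codon_table: int = 11
) -> SiteClassTrack:
    """Per-base degeneracy classes from annotated CDS.

    Minus-strand CDS are reverse-complemented before codon reading; CDS
    lengths not divisible by 3 are logged and their trailing partial
    codon skipped.  A site contained in several CDS is 4DS only if it
    is 4DS in every one of them (conservative, logged implicitly by the
    per-base AND).
    """
    L = genome.length
    fourfold_prefixes = _fourfold_prefixes(codon_table)
    in_cds = np.zeros(L, dtype=bool)
    third_any = np.zeros(L, dtype=bool)
    bad = np.zeros(L, dtype=bool)  # some containing CDS vetoes 4DS status

    for gene in annotation.genes:
        if gene.feature_type != "CDS":
            continue
        parts = sorted(gene.cds_intervals(), key=lambda iv: iv.start)
        for part in parts:
            if not part.wraps and part.end > L:
                raise ValueError(f"CDS of {gene.id} outside genome")
        coords = np.concatenate([p.positions(L) for p in parts])
        seq = "".join(genome.sequence[i] for i in coords)
        if gene.interval.strand == "-":
            seq = revcomp(seq)
            coords = coords[::-1]
        n_codons, rem = divmod(len(seq), 3)
        if rem:
            logger.warning("CDS %s length %d not divisible by 3; trailing %d bp skipped",
                           gene.id, len(seq), rem)
        used = coords[: n_codons * 3]
        in_cds[used] = True
        for k in range(n_codons):
            prefix = seq[3 * k : 3 * k + 2]
            third = used[3 * k + 2]
            third_any[third] = True
            if prefix not in fourfold_prefixes:
                bad[third] = True
            bad[used[3 * k]] = True
            bad[used[3 * k + 1]] = True

    classes = np.full(L, NONCDS, dtype=np.int8)
    classes[in_cds] = OTHERCDS
    classes[in_cds & third_any & bad] = NONDEG
    classes[in_cds & third_any & ~bad] = FOURFOLD
    return SiteClassTrack(classes=classes, codon_table=codon_table)


# ---------------------------------------------------------------------------
# contingency tables and Fisher's exact test

@dataclass
class ContingencyTable:
    table: np.ndarray  # 2x2 integer counts, columns (non-overlap, overlap)
    row_labels: tuple[str, str]
    col_labels: tuple[str, str] = ("non_overlap", "overlap")

    def __post_init__(self) -> None:
        self.table = np.asarray(self.table, dtype=np.int64)
        if self.table.shape != (2, 2) or np.any(self.table < 0):
            raise ValueError("contingency table must be 2x2 with non-negative counts")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.table, index=list(self.row_labels),
                            columns=list(self.col_labels))


@dataclass(frozen=True)
class FisherResult:
    odds_ratio: float
    p: float
    p_floored: float


def coverage_mask(intervals: list[GenomicInterval], genome_length: int) -> np.ndarray:
    mask = np.zeros(genome_length, dtype=bool)
    for iv in intervals:
        mask[iv.positions(genome_length)] = True
    return mask


def overlap_contingency(
    footprints: list[GenomicInterval],
    mode: str,
    genome_length: int,
    annotation: AnnotationSet | None = None,
    site_classes: SiteClassTrack | None = None,
    use_operons: bool = True,
) -> ContingencyTable:
    """Count footprint overlap against a two-class universe.

    ``basepair`` mode counts every genomic base by genic/intergenic
    (operon boundaries when available) x footprint coverage; ``site``
    mode counts only third-codon sites by 4DS/non-4DS x coverage.
    """
    covered = coverage_mask(footprints, genome_length)
    if mode == "basepair":
        if annotation is None:
            raise ValueError("basepair mode needs an annotation")
        genic = annotation.genic_mask(genome_length, use_operons=use_operons)
        rows = [genic, ~genic]
        labels = ("genic", "intergenic")
    elif mode == "site":
        if site_classes is None:
            raise ValueError("site mode needs site classes")
        rows = [site_classes.classes == FOURFOLD, site_classes.classes == NONDEG]
        labels = ("4DS", "non-4DS")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    table = np.array([[np.sum(r & ~covered), np.sum(r & covered)] for r in rows])
    return ContingencyTable(table=table, row_labels=labels)


def fisher_exact(table: ContingencyTable | np.ndarray, floor: float = P_FLOOR) -> FisherResult:
    """Cross-product odds ratio and two-sided exact p.

    OR = (a*d)/(b*c), oriented so OR > 1 means the second row class is
    enriched for overlap; undefined (NaN) when any cell is zero.  The
    reported p is floored at 2.2e-16, mirroring R-style output.
    """
    t = table.table if isinstance(table, ContingencyTable) else np.asarray(table, dtype=np.int64)
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    odds = (a * d) / (b * c) if min(a, b, c, d) > 0 else float("nan")
    p = float(stats.fisher_exact(t, alternative="two-sided").pvalue)
    return FisherResult(odds_ratio=odds, p=p, p_floored=max(p, floor))


# ---------------------------------------------------------------------------
# cross-species footprint mapping

@dataclass
class AlignmentParams:
    """blastn-like local alignment scoring and acceptance thresholds."""

    window: int = 50
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_score: float = 85.0
    min_length: int = 45

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner(mode="local")
        al.match_score = self.match
        al.mismatch_score = self.mismatch
        al.open_gap_score = self.gap_open
        al.extend_gap_score = self.gap_extend
        return al


def _footprint_intervals(footprints) -> list[GenomicInterval]:
    if hasattr(footprints, "intervals"):
        return footprints.intervals()
    return [fp.interval if hasattr(fp, "interval") else fp for fp in footprints]


def _candidate_locations(window: str, text: str, max_extra: int = 1):
    """edlib seed hits: locations within ``max_extra`` of the best distance."""
    best = edlib.align(window, text, mode="HW", task="locations", k=-1)
    locs = list(best["locations"] or [])
    if best["editDistance"] >= 0 and max_extra > 0:
        wider = edlib.align(window, text, mode="HW", task="locations",
                            k=best["editDistance"] + max_extra)
        locs = list(wider["locations"] or locs)
    return best["editDistance"], locs[:8]


def footprint_conservation(
    query_genome: CircularGenome,
    query_footprints,
    target_genome: CircularGenome,
    target_footprints,
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Map each query footprint onto the target genome and categorize it.

    For the 50-bp window centered on each footprint, the best local
    alignment against the target genome and its reverse complement is
    found (edlib locates candidate loci, Smith-Waterman under the
    configured scoring decides).  Categories: conserved+shared,
    conserved+unshared, not conserved.
    """
    params = params or AlignmentParams()
    half = params.window // 2
    if target_genome.length < params.window or query_genome.length < params.window:
        raise ValueError("genome shorter than alignment window")
    Lt = target_genome.length
    ext = params.window + 10
    fwd_text = target_genome.sequence + target_genome.sequence[:ext]
    rev = revcomp(target_genome.sequence)
    rev_text = rev + rev[:ext]
    covered = coverage_mask(_footprint_intervals(target_footprints), Lt)
    aligner = params.aligner()

    rows = []
    for q_iv in _footprint_intervals(query_footprints):
        center = (q_iv.start + q_iv.length // 2) % query_genome.length
        window = query_genome.subseq(center - half, center - half + params.window)
        candidates = []  # (score, length, positions, strand)
        for strand, text in (("+", fwd_text), ("-", rev_text)):
            dist, locs = _candidate_locations(window, text)
            if dist < 0:
                continue
            for ls, le in locs:
                if ls is None:  # edlib may omit start positions
                    ls = max(0, le - params.window + 1)
                lo = max(0, ls - 20)
                hi = min(len(text), le + 21)
                alns = aligner.align(text[lo:hi], window)
                if len(alns) == 0:
                    continue
                aln = alns[0]
                blocks = aln.aligned[0]
                if len(blocks) == 0:
                    continue
                c0, c1 = int(blocks[0][0]) + lo, int(blocks[-1][1]) + lo
                if strand == "+":
                    positions = np.arange(c0, c1) % Lt
                else:
                    positions = (Lt - 1 - (np.arange(c0, c1) % Lt)) % Lt
                candidates.append((float(aln.score), int(aln.length), positions, strand))
        if not candidates:
            rows.append({"q_start": q_iv.start, "q_end": q_iv.end,
                         "category": "not conserved", "score": float("nan"),
                         "aligned_length": 0, "t_start": -1, "t_end": -1, "strand": "."})
            continue
        best_score = max(c[0] for c in candidates)
        tied = [c for c in candidates if c[0] == best_score]
        score, alen, positions, strand = tied[0]
        accepted = best_score > params.min_score and alen > params.min_length
        if not accepted:
            category = "not conserved"
        elif any(covered[c[2]].any() for c in tied):
            category = "conserved+shared"
        else:
            category = "conserved+unshared"
        t_start = int(positions.min())
        t_end = int(positions.max()) + 1
        rows.append({"q_start": q_iv.start, "q_end": q_iv.end, "category": category,
                     "score": score, "aligned_length": alen,
                     "t_start": t_start, "t_end": t_end, "strand": strand})
    return pd.DataFrame(rows)


def conservation_fractions(mapping: pd.DataFrame) -> dict[str, float]:
    """Category fractions as reported in cross-species comparisons."""
    n = len(mapping)
    if n == 0:
        return {}
    return {cat: float((mapping["category"] == cat).mean())
            for cat in ("conserved+shared", "conserved+unshared", "not conserved")}


def multiway_conserved(
    reference_genome: CircularGenome,
    reference_footprints,
    others: list[tuple[CircularGenome, object]],
    params: AlignmentParams | None = None,
) -> pd.DataFrame:
    """Reference footprints conserved and shared in every other genome.

    Each reference footprint is mapped pairwise against every other
    genome; the returned frame flags footprints whose category is
    conserved+shared in all of them (>= 1 bp overlap intersection on
    reference coordinates).
    """
    if len(others) < 1:
        raise ValueError("need at least one non-reference genome")
    ref_ivs = _footprint_intervals(reference_footprints)
    keep = np.ones(len(ref_ivs), dtype=bool)
    for genome, fps in others:
        mapping = footprint_conservation(reference_genome, ref_ivs, genome, fps, params)
        keep &= (mapping["category"] == "conserved+shared").to_numpy()
    return pd.DataFrame({
        "start": [iv.start for iv in ref_ivs],
        "end": [iv.end for iv in ref_ivs],
        "conserved_in_all": keep,
    })


# ---------------------------------------------------------------------------
# conservation-score classes

@dataclass
class ConservationTrack:
    """Per-base conservation scores with Low/Middle/High class thresholds."""

    scores: np.ndarray
    low_below: float = 0.0
    high_at: float = 0.42  # the observed maximum defines the High boundary

    def classify(self) -> np.ndarray:
        """0=Low (<0), 1=Middle [0, 0.42), 2=High (>= 0.42); -1 unscored."""
        cls = np.full(self.scores.size, -1, dtype=np.int8)
        scored = ~np.isnan(self.scores)
        cls[scored & (self.scores < self.low_below)] = 0
        cls[scored & (self.scores >= self.low_below) & (self.scores < self.high_at)] = 1
        cls[scored & (self.scores >= self.high_at)] = 2
        return cls


def gerp_class_test(
    conservation: ConservationTrack | np.ndarray,
    covered: np.ndarray,
    background: np.ndarray,
) -> pd.DataFrame:
    """Per-class proportions among covered vs background sites + Z test.

    Z = (p1 - p2) / sqrt(p̂ (1-p̂) (1/n1 + 1/n2)) with the pooled
    proportion p̂; two-sided p.
    """
    track = conservation if isinstance(conservation, ConservationTrack) \
        else ConservationTrack(np.asarray(conservation, dtype=float))
    cls = track.classify()
    cov_cls = cls[covered & (cls >= 0)]
    bg_cls = cls[background & (cls >= 0)]
    if cov_cls.size == 0:
        raise ValueError("empty covered site set")
    if bg_cls.size == 0:
        raise ValueError("empty background site set")
    rows = []
    for code, name in enumerate(("Low", "Middle", "High")):
        x1, n1 = int(np.sum(cov_cls == code)), cov_cls.size
        x2, n2 = int(np.sum(bg_cls == code)), bg_cls.size
        p1, p2 = x1 / n1, x2 / n2
        pooled = (x1 + x2) / (n1 + n2)
        denom = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
        z = 0.0 if denom == 0 else (p1 - p2) / denom
        p = 2 * stats.norm.sf(abs(z))
        rows.append({"class": name, "prop_covered": p1, "prop_background": p2,
                     "z": z, "p": float(p)})
    return pd.DataFrame(rows)
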