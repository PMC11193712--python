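"""Synthetic chloroplast ATAC-seq data with known ground truth.

The generator emulates the statistical structure the analysis assumes:
a ~130 kb circular quadripartite genome (IRB an exact reverse
complement of IRA), non-overlapping genes partly grouped into operons,
log-normal gene expression coupled to genic accessibility,
sequence-dependent Tn5 insertion bias (a seeded 9-mer weight model,
Tn5's recognition footprint), protein-protected footprints whose
effective protection can vary by tissue, nucleosome-free fragment
sizes, a diverged sister genome sharing a subset of footprints, and
NUPT-derived contaminating reads carrying diagnostic variants.

Per-base accessibility weights are smoothed with a circular Gaussian
kernel before protection is applied: measured ATAC profiles transition
gradually at gene boundaries, and an unsmoothed step profile would
plant sharp genic/intergenic edges indistinguishable from footprints.
Footprint protection itself stays sharp.

All generators are bit-reproducible given (params, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    AnnotationSet,
    CircularGenome,
    FragmentSet,
    Gene,
    GenomicInterval,
    InsertionTrack,
    Operon,
    functional_class_for,
    revcomp,
)

_BASES = np.array(list("ACGT"))
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

# name prefixes by feature type; CDS prefixes drawn with the given weights
_CDS_PREFIXES = ["psa", "psb", "pet", "ndh", "rpo", "rps", "rpl", "mat", "ycf"]
_CDS_WEIGHTS = [0.10, 0.14, 0.06, 0.10, 0.08, 0.22, 0.20, 0.04, 0.06]


@dataclass
class SimParams:
    """Tunable knobs of the generator; defaults are the study conditions.

    Lengths are in bp, depth in total insertions, rates per base.
    """

    genome_length: int = 130_000
    lsc_length: int = 80_000
    ira_length: int = 21_000
    ssc_length: int = 8_000

    n_genes: int = 80
    cds_length_range: tuple[int, int] = (300, 1500)
    trna_length_range: tuple[int, int] = (60, 90)
    rrna_length_range: tuple[int, int] = (1200, 2900)
    feature_type_probs: tuple[float, float, float] = (0.7, 0.2, 0.1)  # CDS, tRNA, rRNA
    min_gene_gap: int = 60
    operon_fraction: float = 0.5
    operon_size_range: tuple[int, int] = (2, 5)

    n_footprints: int = 500
    footprint_length_range: tuple[int, int] = (15, 40)
    protection_range: tuple[float, float] = (0.9, 1.0)
    intergenic_enrichment: float = 1.25
    tissue_tag_probs: dict = field(
        default_factory=lambda: {"constitutive": 0.6, "leaf": 0.2, "root": 0.2}
    )
    off_tissue_protection: float = 0.3  # protection multiplier outside the tagged tissue

    expression_meanlog: float = 2.0
    expression_sdlog: float = 1.0
    coupling: float = 0.3  # genic accessibility ∝ expression^coupling
    intergenic_accessibility: float = 0.6
    accessibility_smoothing_bp: float = 50.0

    bias_kmer: int = 9
    bias_log_sd: float = 0.25  # ~2.7-fold spread between extreme 9-mers

    depth: int = 1_300_000  # 10 insertions/bp
    fragment_min: int = 40
    fragment_scale: float = 80.0  # exponential tail, no nucleosome periodicity

    divergence: float = 0.02
    footprint_divergence_factor: float = 0.5  # footprint bases mutate at this × divergence
    retention: float = 0.8  # probability a footprint is kept in the sister genome

    nupt_fraction: float = 0.02
    nupt_segment_length: int = 5_000
    nupt_variant_density: float = 0.01
    nupt_read_length: int = 50

    def validate(self) -> None:
        if self.lsc_length + 2 * self.ira_length + self.ssc_length != self.genome_length:
            raise ValueError("segment lengths must sum to genome_length (IRB mirrors IRA)")
        for frac in (self.operon_fraction, self.retention, self.nupt_fraction,
                     self.nupt_variant_density, self.divergence,
                     self.footprint_divergence_factor, self.off_tissue_protection):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"fraction/rate {frac} outside [0, 1]")
        lo, hi = self.protection_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("protection_range must lie within [0, 1]")
        if self.intergenic_enrichment <= 0 or self.depth <= 0:
            raise ValueError("intergenic_enrichment and depth must be positive")
        if abs(sum(self.tissue_tag_probs.values()) - 1.0) > 1e-9:
            raise ValueError("tissue_tag_probs must sum to 1")


@dataclass(frozen=True)
class PlantedFootprint:
    interval: GenomicInterval
    protection: float
    tag: str  # tissue-specificity: constitutive / leaf / root
    mirror_of: int | None = None  # index of the primary copy for IR mirrors


@dataclass
class TruthSet:
    """Ground truth behind one synthetic dataset."""

    genome: CircularGenome
    annotation: AnnotationSet
    footprints: list[PlantedFootprint]
    expression: pd.Series  # per-gene TPM-like values
    accessibility_weight: np.ndarray  # per-base, > 0
    bias_weight: np.ndarray  # per-base Tn5 sequence preference, > 0
    seed: int
    params: SimParams
    bias_table: np.ndarray | None = None

    def protection_profile(self, tissue: str = "leaf") -> np.ndarray:
        """Per-base protection in [0, 1] for one tissue."""
        prof = np.zeros(self.genome.length)
        for fp in self.footprints:
            factor = 1.0 if fp.tag in ("constitutive", tissue) else self.params.off_tissue_protection
            prof[fp.interval.positions(self.genome.length)] = fp.protection * factor
        return prof

    def insertion_probability(self, tissue: str = "leaf") -> np.ndarray:
        w = self.accessibility_weight * self.bias_weight * (1.0 - self.protection_profile(tissue))
        total = w.sum()
        if total <= 0:
            raise ValueError("degenerate insertion probabilities")
        return w / total

    def effective_protection(self, tissue: str = "leaf") -> np.ndarray:
        """Per-footprint protection realized in one tissue."""
        return np.array([
            fp.protection * (1.0 if fp.tag in ("constitutive", tissue)
                             else self.params.off_tissue_protection)
            for fp in self.footprints])

    def footprint_mask(self) -> np.ndarray:
        mask = np.zeros(self.genome.length, dtype=bool)
        for fp in self.footprints:
            mask[fp.interval.positions(self.genome.length)] = True
        return mask


# ---------------------------------------------------------------------------
# genome + annotation

def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=n)])


def simulate_genome(
    params: SimParams | None = None, seed: int = 0
) -> tuple[CircularGenome, AnnotationSet]:
    """Random quadripartite circular genome with non-overlapping genes."""
    params = params or SimParams()
    params.validate()
    rng = np.random.default_rng(seed)
    L = params.genome_length

    lsc = _random_sequence(rng, params.lsc_length)
    ira = _random_sequence(rng, params.ira_length)
    ssc = _random_sequence(rng, params.ssc_length)
    sequence = lsc + ira + ssc + revcomp(ira)
    s0, s1 = params.lsc_length, params.lsc_length + params.ira_length
    s2 = s1 + params.ssc_length
    segments = {
        "LSC": GenomicInterval(0, s0),
        "IRA": GenomicInterval(s0, s1),
        "SSC": GenomicInterval(s1, s2),
        "IRB": GenomicInterval(s2, L),
    }
    genome = CircularGenome(name=f"cp_sim{seed}", sequence=sequence, segments=segments)

    # feature types and lengths
    types = rng.choice(["CDS", "tRNA", "rRNA"], size=params.n_genes,
                       p=list(params.feature_type_probs))
    lengths = np.empty(params.n_genes, dtype=int)
    for i, t in enumerate(types):
        lo, hi = {"CDS": params.cds_length_range, "tRNA": params.trna_length_range,
                  "rRNA": params.rrna_length_range}[t]
        n = int(rng.integers(lo, hi + 1))
        if t == "CDS":
            n -= n % 3
        lengths[i] = n

    spare = L - int(lengths.sum()) - params.n_genes * params.min_gene_gap
    if spare < 0:
        raise ValueError("gene demand exceeds genome capacity")
    extra = rng.multinomial(spare, np.full(params.n_genes, 1.0 / params.n_genes))
    gaps = params.min_gene_gap + extra

    # group genes into operons (consecutive, same strand)
    groups: list[list[int]] = []
    i = 0
    while i < params.n_genes:
        if rng.random() < params.operon_fraction and params.operon_fraction > 0:
            size = int(rng.integers(params.operon_size_range[0],
                                    params.operon_size_range[1] + 1))
            groups.append(list(range(i, min(i + size, params.n_genes))))
            i += size
        else:
            groups.append([i])
            i += 1

    genes: list[Gene] = []
    pos = int(gaps[0])
    names_seen: set[str] = set()
    strands = {}
    for group in groups:
        strand = "+" if rng.random() < 0.5 else "-"
        for gi in group:
            strands[gi] = strand
    for gi in range(params.n_genes):
        t = types[gi]
        if t == "tRNA":
            prefix = "trn"
        elif t == "rRNA":
            prefix = "rrn"
        else:
            prefix = _CDS_PREFIXES[rng.choice(len(_CDS_PREFIXES), p=_CDS_WEIGHTS)]
        name = f"{prefix}{chr(ord('A') + gi % 26)}{gi:02d}"
        assert name not in names_seen
        names_seen.add(name)
        iv = GenomicInterval(pos, pos + int(lengths[gi]), strand=strands[gi])
        genes.append(Gene(id=name, interval=iv, feature_type=t,
                          functional_class=functional_class_for(name)))
        pos = iv.end + int(gaps[(gi + 1) % params.n_genes])

    operons = []
    for k, group in enumerate(g for g in groups if len(g) > 1):
        members = tuple(genes[gi].id for gi in group)
        ivs = [genes[gi].interval for gi in group]
        operons.append(Operon(
            id=f"operon{k:02d}",
            interval=GenomicInterval(min(iv.start for iv in ivs),
                                     max(iv.end for iv in ivs),
                                     strand=ivs[0].strand),
            members=members,
        ))
    annotation = AnnotationSet(genes=genes, operons=operons, genome_length=L)
    return genome, annotation


# ---------------------------------------------------------------------------
# truth (expression, accessibility, bias, footprints)

def gaussian_smooth_circular(values: np.ndarray, sigma: float) -> np.ndarray:
    """Circular Gaussian smoothing (kernel truncated at 4 sigma)."""
    if sigma <= 0:
        return values.copy()
    radius = int(np.ceil(4 * sigma))
    x = np.arange(-radius, radius + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    padded = np.concatenate([values[-radius:], values, values[:radius]])
    return np.convolve(padded, kernel, mode="same")[radius:-radius]


def kmer_codes(sequence: str, k: int) -> np.ndarray:
    """Base-4 code of the k-mer centered on each position (circular)."""
    digits = np.frombuffer(sequence.encode(), dtype=np.uint8)
    lut = np.zeros(256, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    digits = lut[digits]
    half = k // 2
    codes = np.zeros(digits.size, dtype=np.int64)
    for j in range(k):
        codes = codes * 4 + np.roll(digits, half - j)
    return codes


def simulate_truth(
    genome: CircularGenome,
    annotation: AnnotationSet,
    params: SimParams | None = None,
    seed: int = 0,
) -> TruthSet:
    """Plant expression, accessibility weights, Tn5 bias and footprints."""
    params = params or SimParams()
    params.validate()
    rng = np.random.default_rng(seed)
    L = genome.length

    expression = pd.Series(
        rng.lognormal(params.expression_meanlog, params.expression_sdlog,
                      size=len(annotation.genes)),
        index=[g.id for g in annotation.genes],
        name="tpm",
    )

    # genic accessibility ∝ expression^coupling relative to the geometric mean
    acc = np.full(L, params.intergenic_accessibility)
    gmean = float(np.exp(np.log(expression).mean()))
    for g in annotation.genes:
        acc[g.interval.positions(L)] = (expression[g.id] / gmean) ** params.coupling
    acc = gaussian_smooth_circular(acc, params.accessibility_smoothing_bp)

    # Tn5 sequence bias from a seeded k-mer table applied to the actual sequence
    bias_table = rng.normal(0.0, params.bias_log_sd, size=4 ** params.bias_kmer)
    bias = np.exp(bias_table[kmer_codes(genome.sequence, params.bias_kmer)])

    # plant footprints: intergenic bases enriched by the stated factor
    genic = annotation.genic_mask(L)
    weights = np.where(genic, 1.0, params.intergenic_enrichment)
    weights = weights / weights.sum()
    occupied = np.zeros(L, dtype=bool)
    tags = list(params.tissue_tag_probs)
    tag_p = [params.tissue_tag_probs[t] for t in tags]

    # inverted repeats are identical sequence: a protein-bound element in
    # one copy is present and bound in the other, so footprints landing
    # fully inside IRA/IRB are planted symmetrically in both copies
    def _ir_mirror(start: int, end: int) -> tuple[int, int] | None:
        if genome.segments is None:
            return None
        for this, other in (("IRA", "IRB"), ("IRB", "IRA")):
            if this in genome.segments and other in genome.segments:
                a = genome.segments[this]
                b = genome.segments[other]
                if a.start <= start and end <= a.end:
                    return b.start + (a.end - end), b.start + (a.end - start)
        return None

    footprints: list[PlantedFootprint] = []
    n_primary = 0
    tries = 0
    while n_primary < params.n_footprints:
        tries += 1
        if tries > 200 * params.n_footprints:
            raise RuntimeError("could not place footprints without overlap")
        flen = int(rng.integers(params.footprint_length_range[0],
                                params.footprint_length_range[1] + 1))
        center = int(rng.choice(L, p=weights))
        start = (center - flen // 2) % L
        spans = [(start, start + flen)]
        mirror = _ir_mirror(start, start + flen) if start + flen <= L else None
        if mirror is not None:
            spans.append(mirror)
        idx = [np.arange(s, e) % L for s, e in spans]
        if any(occupied[ix].any() for ix in idx):
            continue
        for ix in idx:
            occupied[ix] = True
        protection = float(rng.uniform(*params.protection_range))
        tag = str(rng.choice(tags, p=tag_p))
        primary_index = len(footprints)
        footprints.append(PlantedFootprint(
            interval=GenomicInterval(start, start + flen, wraps=start + flen > L),
            protection=protection, tag=tag))
        n_primary += 1
        if mirror is not None:
            footprints.append(PlantedFootprint(
                interval=GenomicInterval(*mirror), protection=protection,
                tag=tag, mirror_of=primary_index))

    return TruthSet(genome=genome, annotation=annotation, footprints=footprints,
                    expression=expression, accessibility_weight=acc, bias_weight=bias,
                    seed=seed, params=params, bias_table=bias_table)


# ---------------------------------------------------------------------------
# sequencing-derived tracks

def simulate_atac(
    truth: TruthSet,
    depth: int | None = None,
    seed: int = 0,
    tissue: str = "leaf",
    with_fragments: bool = False,
    sam_path: str | Path | None = None,
):
    """Draw ``depth`` i.i.d. insertions from the planted per-base law.

    Optionally also draws nucleosome-free fragment sizes (single
    exponential tail) and emits a SAM file in which the +4/−5 shift is
    pre-inverted, so that ``extract_insertions`` recovers exactly the
    sampled positions.
    """
    depth = int(depth or truth.params.depth)
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    p = truth.insertion_probability(tissue)
    counts = rng.multinomial(depth, p).astype(float)
    track = InsertionTrack(genome_name=truth.genome.name, counts=counts,
                           label=f"atac_{tissue}_seed{seed}")
    if sam_path is not None:
        _emit_sam(truth.genome, counts.astype(int), sam_path, rng)
    if with_fragments:
        frags = simulate_fragments(truth.params, depth // 2, seed=seed + 1,
                                   genome_length=truth.genome.length)
        return track, frags
    return track


def simulate_fragments(
    params: SimParams,
    n: int,
    seed: int = 0,
    genome_length: int | None = None,
    nucleosome_period: float | None = None,
) -> FragmentSet:
    """Fragment sizes: minimum + exponential tail (no periodicity).

    ``nucleosome_period`` adds an artificial periodic ladder, used only
    to exercise the periodicity check on a positive control.
    """
    rng = np.random.default_rng(seed)
    L = genome_length or params.genome_length
    lengths = params.fragment_min + rng.exponential(params.fragment_scale, size=n)
    if nucleosome_period is not None:
        ladder = nucleosome_period * rng.integers(1, 4, size=n)
        ladder = ladder + rng.normal(0, 10, size=n)
        pick = rng.random(n) < 0.6
        lengths = np.where(pick, np.maximum(params.fragment_min, ladder), lengths)
    lengths = np.maximum(1, np.round(lengths)).astype(int)
    starts = rng.integers(0, L, size=n)
    return FragmentSet([(int(s), int(s + l)) for s, l in zip(starts, lengths)])


def _emit_sam(genome: CircularGenome, counts: np.ndarray, path: str | Path,
              rng: np.random.Generator, read_length: int = 36) -> None:
    """Write single-end SAM whose shifted starts recover ``counts``."""
    from .io import TN5_FORWARD_SHIFT, TN5_REVERSE_SHIFT

    L = genome.length
    positions = np.repeat(np.arange(L), counts)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        fh.write(f"@SQ\tSN:{genome.name}\tLN:{L}\n")
        for i, pos in enumerate(positions):
            # reads cannot wrap the origin in SAM, so shorten them at the edges
            fwd_start = pos - TN5_FORWARD_SHIFT
            rev_end = pos + TN5_REVERSE_SHIFT + 1
            fwd_len = min(read_length, L - fwd_start) if fwd_start >= 0 else 0
            rev_len = min(read_length, rev_end) if rev_end <= L else 0
            if fwd_len >= 1 and (rev_len < 1 or rng.random() < 0.5):
                start, rlen, flag = fwd_start, fwd_len, 0
            elif rev_len >= 1:
                start, rlen, flag = rev_end - rev_len, rev_len, 16
            else:  # unreachable on genomes longer than the shift offsets
                continue
            seq = genome.sequence[start : start + rlen]
            if flag == 16:
                seq = revcomp(seq)
            fh.write(f"r{i}\t{flag}\t{genome.name}\t{start + 1}\t60\t"
                     f"{rlen}M\t*\t0\t0\t{seq}\t*\n")


def simulate_gdna(truth: TruthSet, depth: int | None = None, seed: int = 0) -> InsertionTrack:
    """Naked-DNA control: insertion probability ∝ sequence bias only."""
    depth = int(depth or truth.params.depth)
    rng = np.random.default_rng(seed)
    p = truth.bias_weight / truth.bias_weight.sum()
    counts = rng.multinomial(depth, p).astype(float)
    return InsertionTrack(genome_name=truth.genome.name, counts=counts,
                          label=f"gdna_seed{seed}")


def simulate_rnaseq_coverage(
    truth: TruthSet, depth: int | None = None, seed: int = 0, background: float = 0.01
) -> tuple[InsertionTrack, pd.Series]:
    """Per-base RNA coverage ∝ gene expression, plus a uniform background."""
    depth = int(depth or truth.params.depth)
    rng = np.random.default_rng(seed)
    L = truth.genome.length
    rate = np.zeros(L)
    for g in truth.annotation.genes:
        rate[g.interval.positions(L)] = truth.expression[g.id]
    if rate.sum() > 0:
        rate = rate / rate.sum() * (1.0 - background)
    p = rate + background / L
    p /= p.sum()
    counts = rng.multinomial(depth, p).astype(float)
    track = InsertionTrack(genome_name=truth.genome.name, counts=counts,
                           label=f"rna_seed{seed}")
    return track, truth.expression.copy()


# ---------------------------------------------------------------------------
# sister genome / divergence

def simulate_divergence(
    truth: TruthSet, seed: int = 0, params: SimParams | None = None
) -> tuple[CircularGenome, TruthSet, pd.DataFrame]:
    """Diverged sister genome plus a per-footprint conservation truth map.

    Point substitutions land at rate ``divergence`` outside footprints
    and ``divergence × footprint_divergence_factor`` inside them (no
    indels, so homologous coordinates are preserved).  Each footprint is
    retained in the sister truth with probability ``retention``.  The
    map records, per footprint, the realized mismatch count of its
    50-bp window and the true category: a gap-free 50-mer with m
    mismatches scores 100−5m under +2/−3 scoring, so the window is
    sequence-conserved iff m ≤ 2.
    """
    params = params or truth.params
    rng = np.random.default_rng(seed)
    L = truth.genome.length
    fp_mask = truth.footprint_mask()
    rate = np.where(fp_mask, params.divergence * params.footprint_divergence_factor,
                    params.divergence)
    mutate = rng.random(L) < rate
    seq = np.array(list(truth.genome.sequence))
    for pos in np.flatnonzero(mutate):
        alternatives = [b for b in "ACGT" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(0, 3)]
    sister_genome = CircularGenome(name=truth.genome.name + "_sister",
                                   sequence="".join(seq),
                                   segments=truth.genome.segments)

    # IR mirror copies are retained jointly with their primary (the two
    # copies are one sequence element under concerted evolution)
    retained = np.zeros(len(truth.footprints), dtype=bool)
    for i, fp in enumerate(truth.footprints):
        if fp.mirror_of is None:
            retained[i] = rng.random() < params.retention
        else:
            retained[i] = retained[fp.mirror_of]
    sister_fps = [fp for fp, keep in zip(truth.footprints, retained) if keep]
    bias = (np.exp(truth.bias_table[kmer_codes(sister_genome.sequence, params.bias_kmer)])
            if truth.bias_table is not None else truth.bias_weight.copy())
    sister_truth = TruthSet(
        genome=sister_genome, annotation=truth.annotation, footprints=sister_fps,
        expression=truth.expression.copy(), accessibility_weight=truth.accessibility_weight.copy(),
        bias_weight=bias, seed=seed, params=params, bias_table=truth.bias_table,
    )

    rows = []
    for fp, keep in zip(truth.footprints, retained):
        center = (fp.interval.start + fp.interval.length // 2) % L
        idx = np.arange(center - 25, center + 25) % L
        m = int(sum(truth.genome.sequence[i] != sister_genome.sequence[i] for i in idx))
        if m > 2:
            category = "not conserved"
        elif keep:
            category = "conserved+shared"
        else:
            category = "conserved+unshared"
        rows.append({"start": fp.interval.start, "end": fp.interval.end,
                     "retained": bool(keep), "window_mismatches": m,
                     "true_category": category})
    return sister_genome, sister_truth, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# NUPT contamination

@dataclass
class NuptSimulation:
    segment: GenomicInterval
    sites: pd.DataFrame  # pos, ref, alt
    fraction: float
    n_reads: int
    sam_path: Path | None


def simulate_nupt(
    truth: TruthSet,
    seed: int = 0,
    params: SimParams | None = None,
    n_reads: int = 20_000,
    fraction: float | None = None,
    sam_path: str | Path | None = None,
) -> NuptSimulation:
    """Reads over one cpDNA segment, a fraction of which carry NUPT alleles.

    A NUPT copy of the segment differs from cpDNA at diagnostic sites
    (density ``nupt_variant_density``); a read drawn from the NUPT copy
    carries the alt allele at every site it covers, so the expected alt
    fraction at in-segment sites equals the read fraction exactly.
    """
    params = params or truth.params
    f = params.nupt_fraction if fraction is None else fraction
    rng = np.random.default_rng(seed)
    L = truth.genome.length
    seg_len = min(params.nupt_segment_length, L - params.nupt_read_length - 1)
    seg_start = int(rng.integers(0, L - seg_len))
    segment = GenomicInterval(seg_start, seg_start + seg_len)

    site_pos = seg_start + np.flatnonzero(rng.random(seg_len) < params.nupt_variant_density)
    refs = [truth.genome.sequence[p] for p in site_pos]
    alts = []
    for r in refs:
        choices = [b for b in "ACGT" if b != r]
        alts.append(choices[rng.integers(0, 3)])
    sites = pd.DataFrame({"pos": site_pos.astype(int), "ref": refs, "alt": alts})
    alt_at = dict(zip(sites["pos"], sites["alt"]))

    rlen = params.nupt_read_length
    out_path = Path(sam_path) if sam_path is not None else None
    if out_path is not None:
        starts = rng.integers(seg_start, seg_start + seg_len - rlen + 1, size=n_reads)
        from_nupt = rng.random(n_reads) < f
        with open(out_path, "w") as fh:
            fh.write("@HD\tVN:1.6\tSO:unsorted\n")
            fh.write(f"@SQ\tSN:{truth.genome.name}\tLN:{L}\n")
            for i, (s, nupt) in enumerate(zip(starts, from_nupt)):
                seq = list(truth.genome.sequence[s : s + rlen])
                if nupt:
                    for off in range(rlen):
                        alt = alt_at.get(s + off)
                        if alt is not None:
                            seq[off] = alt
                fh.write(f"n{i}\t0\t{truth.genome.name}\t{s + 1}\t60\t{rlen}M\t*\t0\t0\t"
                         f"{''.join(seq)}\t*\n")
    return NuptSimulation(segment=segment, sites=sites, fraction=f,
                          n_reads=n_reads, sam_path=out_path)
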