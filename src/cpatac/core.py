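"""Core domain types for circular-genome accessibility analysis.

The chloroplast genome is a circular molecule of ~130 kb with a
quadripartite structure (LSC, SSC and two inverted repeats).  Everything
downstream — insertion tracks, footprints, meta-profile windows — must
therefore tolerate intervals that cross the origin.  Coordinates are
0-based half-open internally; GFF3 (1-based inclusive) and bedGraph/BED
(0-based half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

VALID_STRANDS = ("+", "-", ".")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval on a circular genome.

    An interval that crosses the origin is stored with ``end > length``
    (``wraps=True``); its occupied positions are taken modulo the genome
    length.  ``length`` of the interval is always ``end - start``.
    """

    start: int
    end: int
    strand: str = "."
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")
        if self.end <= self.start:
            raise ValueError(f"empty interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def positions(self, genome_length: int) -> np.ndarray:
        """All occupied positions, wrapped modulo the genome length."""
        return np.arange(self.start, self.end) % genome_length

    def overlaps(self, other: "GenomicInterval", genome_length: int | None = None) -> bool:
        """True iff the two intervals share at least one base."""
        if genome_length is None or not (self.wraps or other.wraps):
            return self.start < other.end and other.start < self.end
        mine = set(self.positions(genome_length).tolist())
        return bool(mine.intersection(other.positions(genome_length).tolist()))


@dataclass(frozen=True)
class CircularGenome:
    """A circular DNA sequence with optional quadripartite segment labels."""

    name: str
    sequence: str
    segments: dict[str, GenomicInterval] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError("empty genome sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise FormatError(f"non-DNA characters in sequence: {sorted(bad)}")
        if self.segments:
            ivs = sorted(self.segments.values(), key=lambda iv: iv.start)
            covered = sum(iv.length for iv in ivs)
            if covered != len(self.sequence):
                raise ValueError("segments must tile the genome exactly")
            for a, b in zip(ivs, ivs[1:]):
                if a.end > b.start:
                    raise ValueError("segments must not overlap")

    @property
    def length(self) -> int:
        return len(self.sequence)

    def subseq(self, start: int, end: int) -> str:
        """Sequence of [start, end), wrapping the origin as needed."""
        n = end - start
        if n < 0:
            raise ValueError("end before start")
        L = self.length
        start %= L
        if start + n <= L:
            return self.sequence[start : start + n]
        return (self.sequence[start:] + self.sequence)[:n]


@dataclass(frozen=True)
class Gene:
    id: str
    interval: GenomicInterval
    feature_type: str = "CDS"  # CDS, rRNA, tRNA, other
    functional_class: str = "other"  # photosystem, ribosomal/RNA, polymerase, other
    cds_parts: tuple[GenomicInterval, ...] = ()

    def cds_intervals(self) -> tuple[GenomicInterval, ...]:
        if self.cds_parts:
            return self.cds_parts
        return (self.interval,)


@dataclass(frozen=True)
class Operon:
    id: str
    interval: GenomicInterval
    members: tuple[str, ...]


DEFAULT_CLASS_MAP = {
    ("psa", "psb", "pet", "ndh"): "photosystem",
    ("rrn", "trn"): "ribosomal/RNA",
    ("rpo",): "polymerase",
}


def functional_class_for(name: str, class_map=None) -> str:
    """Assign a functional class from gene-name prefixes."""
    lowered = name.lower()
    for prefixes, cls in (class_map or DEFAULT_CLASS_MAP).items():
        if lowered.startswith(tuple(prefixes)):
            return cls
    return "other"


@dataclass
class AnnotationSet:
    """Genes and operons on one circular genome."""

    genes: list[Gene]
    operons: list[Operon] = field(default_factory=list)
    genome_length: int | None = None

    def __post_init__(self) -> None:
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids must be unique")
        known = set(ids)
        for op in self.operons:
            missing = set(op.members) - known
            if missing:
                raise ValueError(f"operon {op.id} references unknown genes {sorted(missing)}")

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def genic_mask(self, genome_length: int, use_operons: bool = False) -> np.ndarray:
        """Boolean per-base mask; True = genic.

        When ``use_operons`` is set the partition follows operon
        boundaries (polycistronic units), otherwise gene boundaries.
        """
        mask = np.zeros(genome_length, dtype=bool)
        units = self.operons if (use_operons and self.operons) else self.genes
        for u in units:
            mask[u.interval.positions(genome_length)] = True
        return mask

    def partition(
        self, genome_length: int, use_operons: bool = False
    ) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
        """(genic, intergenic) interval lists covering the genome exactly once.

        Runs are reported in linear coordinates; a run touching both the
        first and last base is joined across the origin into one wrapped
        interval, respecting circularity.
        """
        mask = self.genic_mask(genome_length, use_operons=use_operons)
        out: dict[bool, list[GenomicInterval]] = {True: [], False: []}
        L = genome_length
        # run-length encode
        change = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
        bounds = np.concatenate([[0], change, [L]])
        runs = [(int(a), int(b), bool(mask[a])) for a, b in zip(bounds[:-1], bounds[1:])]
        if len(runs) > 1 and runs[0][2] == runs[-1][2]:
            # join across origin
            a0, b0, v = runs[0]
            a1, b1, _ = runs.pop()
            runs[0] = (a1, b0 + L, v)
        for a, b, v in runs:
            out[v].append(GenomicInterval(a % L if b > L else a, b, wraps=b > L))
        return out[True], out[False]


@dataclass
class InsertionTrack:
    """Per-base Tn5 insertion counts on one circular genome.

    Raw ATAC and naked-gDNA control tracks are integer counts; tracks
    produced by bias correction may hold non-integer values.
    """

    genome_name: str
    counts: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1 or self.counts.size == 0:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0):
            raise ValueError("insertion counts must be non-negative")

    @property
    def length(self) -> int:
        return int(self.counts.size)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def window_sum(self, start: int, length: int) -> float:
        """Sum of counts over [start, start+length), wrapping the origin."""
        L = self.length
        if length > L:
            raise ValueError("window longer than genome")
        start %= L
        if start + length <= L:
            return float(self.counts[start : start + length].sum())
        head = self.counts[start:].sum()
        return float(head + self.counts[: start + length - L].sum())

    def copy_with(self, counts: np.ndarray, label: str | None = None) -> "InsertionTrack":
        return dataclasses.replace(
            self, counts=np.asarray(counts), label=self.label if label is None else label
        )


@dataclass
class FragmentSet:
    """Template intervals of properly paired alignments."""

    fragments: list[tuple[int, int]]

    def __post_init__(self) -> None:
        for s, e in self.fragments:
            if e <= s:
                raise ValueError(f"fragment end {e} <= start {s}")

    @property
    def lengths(self) -> np.ndarray:
        return np.array([e - s for s, e in self.fragments], dtype=int)

    def __len__(self) -> int:
        return len(self.fragments)


def circular_window(
    track: InsertionTrack, center: int, halfwidth: int, strand: str = "+"
) -> np.ndarray:
    """Counts in [center-halfwidth, center+halfwidth], wrapped circularly.

    For a minus-strand anchor the window is reversed so that profiles
    read 5'→3' relative to the anchor.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    L = track.length
    width = 2 * halfwidth + 1
    if width > L:
        raise ValueError("window exceeds genome length")
    idx = (np.arange(center - halfwidth, center + halfwidth + 1)) % L
    values = track.counts[idx]
    if strand == "-":
        values = values[::-1]
    return values


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]
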