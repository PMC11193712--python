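"""NUPT contamination estimation by diagnostic-allele counting.

Nuclear plastid DNAs (NUPTs) are cpDNA-derived segments integrated in
the nuclear genome; reads originating from them carry the nuclear
("alt") allele at sites where the two copies differ.  Analogous to
allele-specific expression counting, the contaminating read fraction
is estimated as the summed alt-allele coverage over all diagnostic
sites divided by the summed biallelic (ref + alt) coverage.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .core import CircularGenome, FormatError


def count_alleles(
    alignments: str | Path,
    genome: CircularGenome,
    sites: pd.DataFrame,
    min_baseq: int = 0,
) -> pd.DataFrame:
    """Tally read bases at diagnostic sites into ref/alt/other coverage.

    ``sites`` columns: pos (0-based), ref, alt.  Deletions spanning a
    site are skipped; bases below ``min_baseq`` are ignored when quality
    strings are present.  A site whose ref allele disagrees with the
    genome sequence is an error.
    """
    sites = sites.reset_index(drop=True)
    for _, row in sites.iterrows():
        if genome.sequence[int(row["pos"])] != row["ref"]:
            raise FormatError(
                f"site {int(row['pos'])}: ref allele {row['ref']} disagrees with genome "
                f"base {genome.sequence[int(row['pos'])]}"
            )
    lookup = {int(row["pos"]): i for i, row in sites.iterrows()}
    refs = sites["ref"].to_numpy()
    alts = sites["alt"].to_numpy()
    counts = np.zeros((len(sites), 3), dtype=np.int64)  # ref, alt, other

    with pysam.AlignmentFile(str(alignments), check_sq=False) as af:
        for read in af.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.query_sequence is None:
                continue
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                i = lookup.get(rpos)
                if i is None:
                    continue
                if quals is not None and quals[qpos] < min_baseq:
                    continue
                base = read.query_sequence[qpos]
                if base == refs[i]:
                    counts[i, 0] += 1
                elif base == alts[i]:
                    counts[i, 1] += 1
                else:
                    counts[i, 2] += 1

    out = sites.copy()
    out["ref_count"] = counts[:, 0]
    out["alt_count"] = counts[:, 1]
    out["other_count"] = counts[:, 2]
    return out


def nupt_ratio(counts: pd.DataFrame) -> float:
    """Σ alt / Σ (ref + alt) over all diagnostic sites.

    Third ("other") alleles are sequencing errors and are excluded from
    the denominator, matching ASE counting conventions.
    """
    if len(counts) == 0:
        raise ValueError("no diagnostic sites: NUPT ratio undefined")
    alt = int(counts["alt_count"].sum())
    total = int(counts["ref_count"].sum()) + alt
    if total == 0:
        raise ValueError("zero total allele coverage: NUPT ratio undefined")
    return alt / total
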