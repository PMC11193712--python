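# cpatac

DNA-accessibility analysis of circular chloroplast genomes (cpDNA)
from ATAC-seq Tn5 insertion data — for researchers studying organelle
transcriptional regulation who have cpDNA-mapped ATAC-seq (and
optionally naked-DNA control, RNA-seq and conservation-score) data, or
who want a fully synthetic, ground-truthed test bed for organelle
footprinting methods.

The chloroplast genome is a ~130-kb circular molecule with a
quadripartite structure (LSC, SSC and two inverted repeats) and no
nucleosomes; its accessibility landscape reflects protein occupancy of
the plastid nucleoid.  `cpatac` quantifies Tn5 insertions on the
circular coordinate system, relates accessibility to annotation and
gene expression, calls protein-binding footprints, scores their depth,
corrects Tn5 sequence bias, tests the selective constraints on
footprint placement, maps footprints across species, and estimates
nuclear-plastid-DNA (NUPT) read contamination.

## The statistics at the core

**Insertion shift.** A forward-strand read at 0-based position *s*
contributes one Tn5 insertion at *s* + 4; a reverse-strand read with
last aligned base *e* − 1 contributes at *e* − 1 − 5.

**Footprint score.** For a candidate interval of length
*L* ∈ [11, 26] with *S* = 35 bp shoulders, *f* insertions inside, *s*
in the shoulders, *n* = *f* + *s* and *p*₀ = *L*/(*L* + 2*S*):

    score = log10 P(X ≤ f),   X ~ Binomial(n, p0)

calibrated at FDR 0.01 against permuted-and-rotated copies of the
observed track.

**Footprint depth.** With FPI insertions inside a footprint of length
*L* and FKI in the 50 bp flanking each side:

    FPD = (FKI/100 − FPI/L) / (FKI/100 + FPI/L)  ∈ [−1, 1]

**Bias correction.** Against a naked-DNA tagmentation control:
Corrected*ᵢ* = Raw*ᵢ* / (gDNA*ᵢ* + 1).

**Selection tests.** Footprint overlap with genic/intergenic bases and
with fourfold-degenerate vs non-degenerate third-codon sites is tested
by Fisher's exact test (odds ratio = cross-product, p floored at
2.2e−16); cross-species conservation requires the 50-bp window around
a footprint to align into the sister genome with score > 85 and
aligned length > 45 under +2/−3/−5/−2 scoring.

**NUPT ratio.** Σ alt / Σ (ref + alt) over diagnostic variant sites.

## Worked example

Every capability has a narrative script under `examples/`; they run on
synthetic data and need no downloads.  Calling footprints on a default
synthetic dataset (`python examples/03_footprints_and_fpd.py`) prints:

```
called 504 footprints at FDR 0.01 (score threshold -29.2 log10 units)
planted footprints with protection >= 0.9 in leaf: 530, recovered: 502 (95%)
calls not overlapping any planted footprint: 0
FPD of called footprints: median 0.90 (FPD = (FKI/100 - FPI/L)/(FKI/100 + FPI/L); 1 = fully protected, 0 = indistinguishable from flanks)
```

The generator planted 500 footprints (plus inverted-repeat mirror
copies) with protection ≥ 0.9 on a 130-kb genome at 10 insertions/bp;
the caller recovers 95% of those protected in the assayed tissue with
no spurious calls, and their depth scores sit near full protection.
The other examples cover accessibility-vs-expression association
(`02`), Tn5 bias correction (`04`), degeneracy/conservation selection
tests (`05`) and NUPT contamination (`06`).

A thin CLI wraps the same library:

```bash
cpatac demo --outdir demo/ --seed 7        # simulate + full pipeline
cpatac insertions --bam in.sam --fasta cp.fa --out track.bedgraph
cpatac footprints --track track.bedgraph --fasta cp.fa --fdr 0.01 --seed 7 --out fp.bed
cpatac nupt --bam in.sam --fasta cp.fa --sites sites.tsv
```

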