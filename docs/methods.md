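# Methods

`cpatac` analyses DNA accessibility of circular chloroplast genomes
(cpDNA) from ATAC-seq Tn5 insertion data.  This note records the models
implemented, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical and design
choices made where more than one reasonable option existed.

## Coordinates and circularity

All coordinates are 0-based half-open internally; GFF3 (1-based
inclusive) and bedGraph/BED (0-based half-open) are converted at the
I/O boundary.  cpDNA is circular, so every window, footprint flank and
meta-profile may cross the origin: intervals that wrap are stored with
`end > genome length` and their occupied positions taken modulo the
length.  Reads mapping ambiguously between the two inverted repeats
keep their aligner-assigned primary placement; no re-assignment is
attempted (the MAPQ filter defaults to 0, i.e., multi-mapped primary
records are kept, configurable via `--min-mapq`).

## Insertion quantification

Each accepted alignment contributes one Tn5 insertion at the canonical
ATAC-shifted cut site: forward-strand reads at 0-based leftmost
position s insert at s+4; reverse-strand reads with last aligned base
e−1 insert at e−1−5 ("−5 from the read end" — stated explicitly because
end conventions differ between tools).  Secondary, supplementary and
duplicate-flagged records are skipped.  Accessibility is quantified as
insertions per 100-bp bin; the trailing short bin is kept so binning
conserves totals.  Replicate agreement is the Pearson correlation of
log2(CPM+1)-transformed bins.

## Footprint model

A footprint is a short interval whose insertion count is binomially
improbable relative to its local flanks.  For a candidate of length
L ∈ [11, 26] with S = 35 bp shoulders, f insertions inside, s in the
shoulders, n = f + s and p0 = L/(L+2S), the score is
log10 P(X ≤ f), X ~ Binomial(n, p0), computed in log space.  Where
scipy's log-CDF underflows (depths beyond ~10³ per window), the lower
tail is rebuilt from log-pmf terms over an 80-term window below f,
whose geometric decay makes the truncation exact to double precision.
Counts are rounded to integers before scoring since bias-corrected
tracks can be fractional.

Significance is calibrated empirically: each of 100 shuffles permutes
the per-base count vector and applies a random circular rotation
(a rotation alone leaves the multiset of window scores unchanged, so
the permutation carries the null; the rotation is kept as a stated part
of the shuffle), the best genome-wide score of each shuffle is
recorded, and the calling threshold is the α-quantile (α = 0.01) of
those best scores.  This is family-wise calibration against a null
that preserves the marginal count distribution — including its
overdispersion from accessibility and sequence-bias heterogeneity —
on the circular genome.  For speed, only the 64 most depleted windows
per length per shuffle (by normal-approximation z-score) are scored
exactly; the binomial score is monotone enough in z that the minimum
always lies among them.  Candidates below threshold with at least 10
shoulder insertions are accepted greedily by ascending score with
(score, start, length) tie-breaking; later candidates overlapping an
accepted one are discarded, so called footprints never overlap.

Footprint depth is FPD = (FKI/100 − FPI/L)/(FKI/100 + FPI/L), with FPI
the insertions inside the footprint and FKI the insertions in the
50 bp flanking each side (100 bp total); FPD ∈ [−1, 1], 1 meaning full
protection, and it is undefined (NaN, deliberately distinct from 0)
when footprint and flanks are both empty.  Tn5 sequence bias is
corrected per base as Corrected_i = Raw_i/(gDNA_i + 1) against a
naked-DNA tagmentation control — the pseudocount form exactly as
published practice writes it, so a zero control leaves the track
unchanged.  Downstream analyses run on raw-track footprints; the
correction is reported (FPD correlation before/after), not applied,
because naked DNA retains base modifications and correction can remove
genuine signal.

Tissue differences in FPD are tested per footprint with a two-sided
Welch t-test across replicates (≥ 2 per tissue), flagged at p < 0.05
with no multiplicity correction by default; a Benjamini–Hochberg option
exists but is off, matching the reporting convention of the analyses
this package reproduces.  Footprints from different samples are merged
by single linkage at ≥ 1 bp overlap (half-open intervals sharing no
base do not merge), recording per-sample presence for
"all tissues" / "one tissue" queries.

## Selection and conservation

Coding sites are classified under the plastid/bacterial codon table
(NCBI table 11).  A third-codon position is a fourfold degenerate site
(4DS) iff all four substitutions encode the same amino acid; sites in
several overlapping CDS are 4DS only if 4DS in every one of them
(conservative).  Minus-strand CDS are reverse-complemented before codon
reading; lengths not divisible by 3 are logged and the trailing partial
codon skipped.

Overlap preferences are tested on 2×2 tables (rows: genic/intergenic
by operon boundaries when provided, else gene boundaries; or 4DS vs
non-4DS third-codon sites; columns: non-overlap/overlap with
footprints).  The odds ratio is the cross-product (a·d)/(b·c) — at the
cell sizes involved it agrees with the conditional MLE to two decimals
and is exactly reproducible — and the two-sided p comes from the exact
hypergeometric test (scipy), reported with a 2.2e−16 floor mirroring
R-style output.

Cross-species mapping extracts the 50-bp window centered on each
footprint and locally aligns it against the target genome and its
reverse complement under blastn-like scoring (+2 match, −3 mismatch,
−5 gap open, −2 extend), so a perfect 50-mer scores 100 and the
acceptance thresholds (score > 85 AND aligned length > 45) tolerate at
most two mismatches in an ungapped alignment.  "Score" is the raw
alignment score, not a bit score — the threshold arithmetic only makes
sense on that scale — and the parameters are exposed in
`AlignmentParams`.  Candidate loci are found with edlib (infix mode,
best edit distance + 1), then scored exactly by Smith–Waterman
(Biopython `PairwiseAligner`) in a window around each candidate;
because the two inverted repeats can tie, all tied-best loci are kept
and a footprint counts as "shared" if any of them overlaps a target
footprint by ≥ 1 bp.  Categories: conserved+shared,
conserved+unshared, not conserved.  Multi-genome intersection maps the
reference footprints against every other genome and intersects the
conserved+shared flags on reference coordinates.

Per-site conservation scores are split into Low (< 0),
Middle ([0, 0.42)) and High (≥ 0.42; the observed maximum defines the
boundary, and ≥ rather than == is used so floating-point
representations of the maximum are not silently dropped).  Covered vs
background proportions per class are compared with the pooled
two-proportion Z test, two-sided.

## NUPT contamination

Nuclear copies of cpDNA segments (NUPTs) contaminate cpDNA-mapped
reads.  At diagnostic sites where the nuclear copy carries an alternate
allele, read bases are tallied into ref/alt/other and the contaminated
read fraction estimated as Σ alt / Σ (ref + alt) over all sites.
Third alleles are sequencing errors and are excluded from the
denominator (ASE counting convention; the estimator is unbiased for the
planted fraction under this choice, which is configurable in effect by
recomputing from the returned per-site counts).  Site discovery itself
is out of scope: diagnostic sites are an input or are simulated.

## The synthetic-data generator

The generator is first-class, tested code; its defaults are the study
conditions every property suite runs under.

* **Genome** — 130 kb circular, quadripartite: LSC 80 kb, IRA 21 kb,
  SSC 8 kb, IRB = exact reverse complement of IRA.  80 non-overlapping
  genes (70% CDS, 20% tRNA, 10% rRNA) with name-prefix functional
  classes (psa/psb/pet/ndh → photosystem, rrn/trn → ribosomal/RNA,
  rpo → polymerase); about half the genes grouped into consecutive
  same-strand operons of 2–5 genes.
* **Expression and accessibility** — per-gene expression is log-normal
  (meanlog 2, sdlog 1, TPM-like).  Genic accessibility weight is
  (expression/geometric mean)^0.3; intergenic baseline 0.6.  The
  coupling exponent and baseline are set so that at the default depth
  of 10 insertions/bp every non-footprint base keeps a local rate of
  roughly 7–15/bp while the genic > intergenic contrast stays decisive,
  which is the regime the recovery properties are stated for.  Weights
  are smoothed with a circular Gaussian (σ = 50 bp) before protection
  is applied: measured ATAC profiles transition gradually at gene
  boundaries, and an unsmoothed step would plant sharp edges
  indistinguishable from footprints.  Footprint protection itself stays
  sharp.
* **Tn5 bias** — per-base weight exp(w(9-mer)) from a seeded table of
  4⁹ independent Normal(0, 0.25) log-weights applied to the centered
  9-mer (Tn5's recognition footprint); the 0.25 log-sd gives a
  ~2.7-fold spread between extreme 9-mers, enough to make bias
  correction non-trivial without dominating the signal.
* **Footprints** — 500 primaries of 15–40 bp, protection uniform in
  [0.9, 1.0], placed without overlap with intergenic centers favored
  1.25 : 1.  A footprint falling fully inside an inverted repeat is
  planted symmetrically in both copies (IRs are identical sequence, so
  a bound element exists in both) and the mirror shares protection,
  tissue tag and — under divergence — retention with its primary.
  Tissue dynamics: 60% of footprints are constitutive, 20% leaf- and
  20% root-tagged; outside its tissue a tagged footprint keeps only
  0.3 of its protection, emulating tissue-variable binding.
* **Sequencing** — insertions are i.i.d. multinomial draws from the
  per-base law accessibility × bias × (1 − protection); no dependence
  between the two insertion events of one fragment (adequate for every
  statistic used downstream).  Optional SAM emission pre-inverts the
  +4/−5 shift (shortening reads at the origin, since SAM reads cannot
  wrap) so that `extract_insertions` recovers the sampled positions
  exactly.  Fragment sizes are minimum 40 bp plus an exponential tail
  (scale 80 bp) — no nucleosome periodicity; an optional 190-bp ladder
  mode provides the positive control for the periodicity check.
* **Divergence** — point substitutions at rate 0.02 outside footprints
  and 0.01 inside (half rate, emulating constraint); no indels, so
  homologous coordinates are preserved.  Footprints are retained in the
  sister truth with probability 0.8.  The truth map records each
  window's realized mismatch count m; with gap-free divergence the
  window is sequence-conserved iff m ≤ 2 (score 100 − 5m > 85), so the
  planted category is exact.
* **NUPT** — one 5-kb segment with diagnostic sites at density 0.01/bp;
  2% of reads over the segment originate from the NUPT copy and carry
  alt alleles at every covered site, making the expected alt fraction
  equal the read fraction exactly.

What the generator does **not** emulate: base-call errors and quality
strings, PCR duplicates, fragment-pair dependence, mappability
variation between the IR copies (insertions are drawn per base, not
re-mapped), duplicated gene annotations inside the IRs, indel
divergence, and concerted evolution of the IRs after divergence.
Passing property suites therefore demonstrate the statistical
machinery is correct under the assumed sampling laws, not that the
pipeline is robust to alignment artifacts of real libraries.

## Study sizes and measured properties

The recovery study runs ten independent 130-kb datasets at the default
conditions plus ten matched control datasets with protection forced
to 0 (same genome, annotation, expression and bias; these sizes keep
the full suite's runtime proportionate while the binomial counting
errors on every asserted fraction stay well below the asserted
margins).  Recovery is measured over planted footprints whose
protection *in the assayed tissue* is ≥ 0.9 — a root-tagged footprint
assayed in leaf carries protection ~0.27 and is not part of the stated
recovery condition.  The false-discovery proportion pools false calls
in the recovery runs with all calls in the control scans (every control
call is false by construction) over the total real-data call count — an
empirical-FDR construction; an FDP computed inside a single control
scan alone is degenerate (0 or 1).  FPD monotonicity is the Spearman
correlation between planted effective protection and measured FPD,
pooled over the study.  Retention recovery conditions on sequence
conservation: shared/(shared + unshared) estimates the retention
probability directly, whereas the raw shared fraction equals
retention × P(window has ≤ 2 substitutions) and would be attenuated by
~4 points at the default divergence.

## Known limitations

* The footprint caller is a re-specified combined-strand binomial
  variant of the Wellington scheme, validated against planted truth,
  not against any external caller's output; strand-split scoring is not
  implemented because Tn5 cut data is used unstranded throughout.
* Family-wise calibration against the permutation null is conservative
  when the track is strongly overdispersed; detection power at local
  depths below ~5 insertions/bp drops accordingly.
* Footprint merging treats intervals linearly; two footprints merging
  only across the origin would not be joined (calls themselves may wrap).
* The Smith–Waterman gap convention (open −5 applied to the first gap
  base, extend −2 thereafter) differs from BLAST's open+extend-per-base
  by one extension per gap; irrelevant at the gap-free acceptance
  boundary, and the parameters are configurable.
* `run_pipeline` executes the single-sample workflow; multi-tissue
  merging and differential FPD are library calls (`merge_footprints`,
  `differential_fpd`) and CLI subcommands, not pipeline stages.
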