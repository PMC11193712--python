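"""Test the selective constraints on footprint placement.

Classifies every coding site by degeneracy (fourfold degenerate sites,
4DS, tolerate any substitution), tests footprint overlap preferences
with Fisher's exact test, and maps footprints onto a diverged sister
genome to measure conservation.
"""

from cpatac import selection as sel, simulate as sim
from cpatac.footprinting import detect_footprints

params = sim.SimParams()
genome, annotation = sim.simulate_genome(params, seed=7)
truth = sim.simulate_truth(genome, annotation, params, seed=8)
atac = sim.simulate_atac(truth, seed=9)
fps = detect_footprints(atac, seed=10)

classes = sel.classify_degenerate_sites(genome, annotation)
print("site classes:", classes.summary())

tab = sel.overlap_contingency(fps.intervals(), "basepair", genome.length,
                              annotation=annotation)
res = sel.fisher_exact(tab)
print(f"genic/intergenic footprint coverage: OR={res.odds_ratio:.2f}, "
      f"p={res.p_floored:.2e} (OR > 1 would mean intergenic enrichment; "
      f"non-overlap placement and IR mirroring flatten the planted "
      f"per-center enrichment at the base-pair level)")

tab4 = sel.overlap_contingency(fps.intervals(), "site", genome.length,
                               site_classes=classes)
res4 = sel.fisher_exact(tab4)
print(f"4DS vs non-4DS overlap: OR={res4.odds_ratio:.2f}, p={res4.p_floored:.2e}")

sister_genome, sister_truth, _ = sim.simulate_divergence(truth, seed=11)
sister_atac = sim.simulate_atac(sister_truth, seed=12)
sister_fps = detect_footprints(sister_atac, seed=13)
mapping = sel.footprint_conservation(genome, fps, sister_genome, sister_fps)
for cat, frac in sel.conservation_fractions(mapping).items():
    print(f"  {cat}: {frac:.1%}")
# conserved = the 50-bp window aligns into the sister genome with score
# > 85 and > 45 aligned bp (+2/-3/-5/-2 scoring); shared additionally
# requires >= 1 bp overlap with a footprint called there.
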