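"""Correct Tn5 sequence bias with a naked-DNA (gDNA) control.

Corrected_i = Raw_i / (gDNA_i + 1) per base; footprint depth is then
recomputed on the corrected track and correlated with the raw-track
depth, showing how much of the footprint signal survives correction.
"""

from cpatac import simulate as sim
from cpatac.footprinting import bias_correct, detect_footprints, fpd_correlation

params = sim.SimParams()
genome, annotation = sim.simulate_genome(params, seed=7)
truth = sim.simulate_truth(genome, annotation, params, seed=8)
atac = sim.simulate_atac(truth, seed=9)
gdna = sim.simulate_gdna(truth, seed=10)

corrected = bias_correct(atac, gdna)
print(f"raw track total {atac.total:,.0f}; corrected track total "
      f"{corrected.total:,.1f} (division by gDNA+1 shrinks biased sites "
      f"toward 1)")

fps = detect_footprints(atac, seed=11)
r = fpd_correlation(fps, atac, corrected)
print(f"FPD correlation before vs after correction over {len(fps)} "
      f"footprints: r = {r:.3f}")
# A high correlation means the planted 9-mer insertion bias inflates or
# deflates footprint depths only mildly: calls driven by true protection
# keep their ranking once sequence preference is divided out.
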