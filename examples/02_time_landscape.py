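"""Contrast every TIME marker between EMT-high and EMT-low samples.

Builds the unified marker table (17 immune cells, 17 checkpoints, 17
cytokines, 8 signatures) for one synthetic cohort and computes the
median-difference landscape with KS, ANOVA and Spearman statistics.
"""

from emtime import (assemble_time_table, build_landscape, compute_emt_score,
                    default_signatures, landscape_frame, score_signatures,
                    stratify_by_emt)
from emtime.simulate import SimulationConfig, generate_cohort

bundle = generate_cohort(SimulationConfig(cohort_id="DEMO", n_samples=400, seed=11))
scores = compute_emt_score(bundle.expression)
groups = stratify_by_emt(scores)

sigs = score_signatures(bundle.expression, default_signatures())
table = assemble_time_table(bundle.enrichment, bundle.expression, sig_scores=sigs)
frame = landscape_frame(build_landscape(table, groups, scores))

print(f"{len(frame)} markers contrasted "
      f"(n_high={frame.n_high.iloc[0]}, n_low={frame.n_low.iloc[0]})")
cols = ["category", "delta_median", "ks_p", "ks_band", "corr_rho"]
print("\nstrongest EMT-high enrichment (delta median = median(high) - median(low)):")
print(frame.nlargest(5, "delta_median")[cols].round(4))
print("\nplanted null markers stay flat:")
print(frame.loc[["IL4", "IL5", "IFNA1"], cols].round(4))
# Markers coupled to the planted axis (Macrophages, TGFB1, SIGLEC7, ...)
# show positive delta medians with *** KS bands; uncoupled cytokines do not.
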