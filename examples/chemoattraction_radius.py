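"""Recover a known chemoattraction radius from synthetic neurons.

Builds a small cohort of synthetic neurons, places axonal spots whose
density is doubled within 5 µm of each neuron surface, and runs the full
enrichment analysis: per-µm distance bins, a per-neuron Monte Carlo CSR
null, Šidák-corrected per-bin tests and the radius estimate.  The printed
radius should come back close to the 5 µm used by the generator, and the
normalized percentages should sit well above 100% inside that range.
"""

import numpy as np

import spotsurf as ss
from spotsurf.pipeline import build_cohort, cohort_profiles

geom = ss.AcquisitionGeometry((30, 96, 96), (0.4, 0.4, 0.4))
kernel = ss.ChemoattractionKernel(radius_um=5.0, amplitude=1.0, profile="flat")

cohort = build_cohort(geom, n_neurons=12, n_spots=800, n_sims=500,
                      bin_edges=ss.FINE_BINS_UM, seed=7,
                      n_branches=2, branch_length_um=8.0, soma_radius_um=3.0)
profiles = cohort_profiles(cohort, kernel, seed=8)
summary = ss.summarize_cohort(profiles)

print(summary.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3g}"))
print(f"\nestimated chemoattraction radius: {summary.radius_um:g} µm "
      f"(generator used {kernel.radius_um:g} µm)")
print(f"interaction p (observed vs null × distance): "
      f"{summary.anova['p_interaction']:.2g}")
print("\nEach row is one distance bin: 'mean_pct' is the spot count as a % of")
print("the random-placement expectation (100 = no chemoattraction); the radius")
print("is the extent of the contiguous significantly-enriched run from 0 µm.")
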