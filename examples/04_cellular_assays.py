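"""Count-based endpoints: progenitor colonies, senescence, densities, images.

Shows the unit summaries (CFU per 10^5 PBMC, percent SA-beta-gal-positive
with an exact binomial interval, cells per mm^2) and the image-intensity
quantification: Otsu threshold, background subtraction, mean of the stained
area.
"""

import numpy as np

from bbbassay import (
    EffectModel,
    cell_density,
    cep_rate,
    quantify_intensity,
    senescence_fraction,
    simulate_count_assays,
    summarize_counts_table,
)

print("CEP rate:", cep_rate(12, 6e5), "CFU per 10^5 PBMC")
pct, (lo, hi) = senescence_fraction(120, 400)
print(f"senescence: {pct:.1f}%  (95% CI {lo:.1f}-{hi:.1f})")
print("density:", cell_density(50, 0.25), "cells/mm^2")

# synthetic two-level image: background 10, stained quarter at 110
img = np.full((128, 128), 10.0)
img.flat[: 128 * 128 // 4] = 110.0
print("image intensity (background-subtracted):", quantify_intensity(img))

# simulated senescence dose response at day 5 (19 coverslips per group)
study = simulate_count_assays(EffectModel(), seed=5)
sen = summarize_counts_table(study.counts_table.query("assay == 'senescence'"))
means = sen.groupby("dose_gy")["value"].mean()
for dose, m in means.items():
    print(f"  {dose:>4.1f} Gy: {m:.1f}% positive "
          f"({100 * (m / means[0.0] - 1):+.0f}% vs sham)")
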