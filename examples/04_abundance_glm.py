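"""Clade abundance vs environmental metadata with NB GLMs.

Simulates a clade × sample count matrix where half the clades respond to
temperature (log-scale effect 0.5) and half do not, scales by library
size (median of ratios), fits one NB GLM per clade with AIC-optimised
dispersion, and screens for significant associations with BH correction
(variable p < 0.1, coefficient p < 0.05).
"""

import numpy as np
import pandas as pd

from poseidonia import abundance, simulate

# responders are a minority, as the median-of-ratios scaling assumes:
# when most clades track the covariate, size factors absorb the signal
n_samples, effect = 120, 0.5
rng = np.random.default_rng(2)
covars = pd.DataFrame({"temperature": rng.normal(0, 1, n_samples)})
coefs = {f"responder{i}": [effect] for i in range(2)}
coefs |= {f"null{i}": [0.0] for i in range(18)}
sim = simulate.simulate_counts(
    simulate.CountSimSpec(
        n_samples=n_samples, n_clades=20, coefficients=coefs,
        dispersion_alpha=0.4, covariates=covars, seed=9,
    )
)

factors, _ = abundance.scale_by_library_size(sim.counts)
dataset = abundance.AbundanceDataset(sim.counts, sim.metadata, size_factors=factors)

fits = [abundance.fit_nb_glm(dataset, clade, "temperature") for clade in sim.counts.index]
for fit in fits:
    print(
        f"{fit.clade:<12s} beta={fit.params['temperature']:+.3f} "
        f"alpha={fit.alpha:.3f} p={fit.block_p:.2e}"
    )

screen = abundance.significance_screen(fits)
print("\nsignificant after BH (variable p<0.1, coefficient p<0.05):")
print(screen[["clade", "estimate", "p_adj", "sign"]].to_string(index=False))
# The planted responders survive the screen with positive sign and
# estimates near the planted 0.5. With only 20 clades the estimated size
# factors carry noise that can let an occasional weak negative null
# through; the effect shrinks as the clade panel grows (the real reference
# set has ~200 dereplicated genomes).
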