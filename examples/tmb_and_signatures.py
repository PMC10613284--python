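"""TMB, the cohort TMB-high threshold, and SBS96 signature refitting.

Simulates a cohort TMB distribution, derives the median + 2*IQR cutoff,
then decomposes a 500-mutation spectrum drawn from three signatures of a
synthetic catalog by nonnegative least squares.
"""
import numpy as np
import pandas as pd

from hemeascn.io import SBS96_CHANNELS
from hemeascn.tmb import (classify_tmb_high, refit_signatures,
                          tmb_high_threshold)

rng = np.random.default_rng(7)

# --- cohort TMB thresholding -------------------------------------------
cohort = np.round(rng.lognormal(mean=1.2, sigma=0.9, size=200), 1)
threshold = tmb_high_threshold(cohort)
n_high = sum(classify_tmb_high(t, threshold) for t in cohort)
print(f"cohort of {len(cohort)}: median {np.median(cohort):.1f} mut/Mb, "
      f"TMB-high threshold {threshold:.1f} mut/Mb, {n_high} samples above")

# --- signature refit ----------------------------------------------------
k = 6
catalog = {}
for j in range(k):
    alpha = np.full(96, 0.08)
    alpha[rng.choice(96, 8, replace=False)] = 4.0
    catalog[f"SBS_sim{j + 1}"] = rng.dirichlet(alpha)
P = pd.DataFrame(catalog, index=SBS96_CHANNELS)

true_w = {"SBS_sim1": 0.6, "SBS_sim4": 0.3, "SBS_sim6": 0.1}
probs = sum(w * P[s] for s, w in true_w.items())
spectrum = pd.Series(rng.multinomial(500, probs / probs.sum()),
                     index=SBS96_CHANNELS)
fit = refit_signatures(spectrum, P)
print(f"\nrefit of a 500-mutation spectrum (truth {true_w}):")
for sig, frac in fit.fractions[fit.fractions > 0].round(3).items():
    print(f"  {sig}: {frac}")
print(f"dominant: {fit.dominant}")
# Fractions are the nonnegative least-squares attribution of the spectrum
# to catalog signatures, after pruning contributions below 5%.
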