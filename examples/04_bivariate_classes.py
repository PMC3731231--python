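"""Classify an eQTL as stable or differential across two cell types.

Fits the five bivariate models (stable, A-not-B, B-not-A, A-and-B,
A-opposite-B) for a planted cell-type-A-specific eQTL and a planted stable
eQTL, and prints the integrated Bayes factor for each.
"""

import numpy as np

from eqtlcre.bivariate import fit_five_models

rng = np.random.default_rng(3)
n = 300
g = rng.binomial(2, 0.4, n).astype(float)

# cell-type-A-specific eQTL: effect in A, none in B
yA = 0.6 * g + rng.standard_normal(n)
yB = rng.standard_normal(n)
r = fit_five_models(yA, yB, g, g)
print("planted A-not-B eQTL:")
for m, bf in r.log10_bf.items():
    print(f"  log10 BF[{m:>12s}] = {bf:7.2f}")
print(f"  iBF = {r.ibf:.2f} -> best model {r.best_model} "
      f"(differential={r.differential})")

# stable eQTL: same effect in both cell types
yB2 = 0.6 * g + rng.standard_normal(n)
r2 = fit_five_models(yA, yB2, g, g)
print(f"planted stable eQTL: iBF = {r2.ibf:.2f} -> best model "
      f"{r2.best_model} (differential={r2.differential})")
# A positive iBF means the evidence for some differential configuration
# exceeds the evidence for one shared effect; the stable eQTL lands at a
# clearly negative iBF.
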