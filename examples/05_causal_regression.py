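"""Estimate the causal effect of positive trans interactions on stability.

Design-scenario records are regressed on standardized community features
with a fractional (logit-link) model.  The covariates are chosen by the
backdoor criterion on the package's causal diagram: for the exposure
"total positive trans strength" the minimal adjustment set is the pair of
species richnesses, which confound the exposure through the number of
possible cross-patch links.
"""

import itertools

import numpy as np
import pandas as pd

from chainstab import (
    MigrationParams,
    adjustment_set,
    default_diagram,
    fit_stability_logit,
)
from chainstab.reproduce import design_structured

diagram = default_diagram()
adj = sorted(adjustment_set(diagram, "total_pos_trans", "stability"))
print(f"backdoor adjustment set for total_pos_trans: {adj}")

print("sampling design-scenario records (a minute or two)...")
result = design_structured(seed=4, targets=10, upstream=30)
df = pd.DataFrame(result["records"])
print(f"{result['n_survivors']} surviving meta-communities, {len(df)} records")

features = ["total_pos_trans"] + adj + ["rho", "mu"]
fit = fit_stability_logit(df, features)
print("\nstandardized fractional-logit coefficients on stability:")
for name in ["total_pos_trans", "rho", "mu"] + adj:
    print(f"  {name:16s} {fit.params[name]:+.3f}  (p = {fit.pvalues[name]:.2g})")
print("\npositive trans interactions and rho stabilize the downstream")
print("community; mu's coefficient is negative but small at this sample size.")
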