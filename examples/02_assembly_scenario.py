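"""Assemble a meta-community by sequential invasion and watch stability grow.

One species per cycle invades the system (patch chosen by the migration
parameters rho and mu); the dynamics then run for 300 t units.  Stability
tends to increase as assembly proceeds, and downstream compositions persist
for progressively longer runs of cycles (longevity).
"""

import numpy as np

from chainstab import (
    EnsembleConfig,
    MigrationParams,
    longevity,
    run_assembly,
    sample_pool,
)

rng = np.random.default_rng(1)
pool = sample_pool(EnsembleConfig(), rng)
records = run_assembly(pool, MigrationParams(rho=0.5, mu=0.5), cycles=60, rng=rng)

print("cycle  patch  richness(up/down)  q0")
for r in records[::10]:
    print(f"{r.cycle:5d}  {r.patch:5s}  {r.features['richness_up']:2d} / "
          f"{r.features['richness_down']:2d}            {r.q0:.3f}")

early = np.median([r.q0 for r in records[:20]])
late = np.median([r.q0 for r in records[-20:]])
print(f"\nmedian q0, cycles 1-20:  {early:.3f}")
print(f"median q0, cycles 41-60: {late:.3f}")
print("stability climbs as weakly persisting species are weeded out.")

runs = longevity(records)
print(f"\ndownstream composition persisted for runs of {runs} cycles")
print("(longevities partition the 60 cycles; long runs = stable epochs)")
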