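"""Migration model: who invades which patch, and how often.

One species invades the meta-community at each cycle boundary.  Three routes
exist: pool -> upstream (weight ``rho``), pool -> downstream (weight
``1 - rho``) and upstream -> downstream (weight ``mu`` per species currently
present upstream).  Normalizing over the N pool species gives, with
``S = sum_k delta(x_k1)`` the upstream richness and ``D = N + mu * S``:

    p_i1 = rho / D
    p_i2 = ((1 - rho) + mu * delta(x_i1)) / D

``delta`` is the presence indicator (1 if abundance > 0), i.e. all upstream
residents are equally likely to seed the downstream patch regardless of
abundance.  The probabilities always sum to one across the 2N
(species, patch) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MigrationParams", "MigrationProbabilities", "presence_indicator", "migration_probabilities"]


@dataclass(frozen=True)
class MigrationParams:
    """rho: pool->upstream vs downstream split in [0, 1]; mu >= 0 scales
    upstream->downstream migration against migration from the pool."""

    rho: float
    mu: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must be in [0, 1], got {self.rho}")
        if self.mu < 0.0:
            raise ValueError(f"mu must be nonnegative, got {self.mu}")


@dataclass(frozen=True)
class MigrationProbabilities:
    """Per-species invasion probabilities; p1 upstream, p2 downstream."""

    p1: np.ndarray
    p2: np.ndarray

    @property
    def total(self) -> float:
        return float(self.p1.sum() + self.p2.sum())


def presence_indicator(x: float) -> int:
    """1 if the abundance is strictly positive, else 0 (negative numerical
    dust counts as absent)."""
    if not np.isfinite(x):
        raise ValueError("abundance must be finite")
    return 1 if x > 0 else 0


def migration_probabilities(
    params: MigrationParams, x1: np.ndarray
) -> MigrationProbabilities:
    """Invasion probabilities for every (species, patch) pair.

    ``x1`` should already have the extinction threshold applied, so that
    "present upstream" means above threshold.
    """
    x1 = np.asarray(x1, dtype=float)
    n = x1.shape[0]
    if n == 0:
        raise ValueError("empty species pool")
    delta = (x1 > 0).astype(float)
    D = n + params.mu * delta.sum()
    p1 = np.full(n, params.rho / D)
    p2 = ((1.0 - params.rho) + params.mu * delta) / D
    return MigrationProbabilities(p1=p1, p2=p2)
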