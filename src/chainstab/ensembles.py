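"""Random pools and feasible, locally stable communities.

Pools follow the classic random-matrix ensemble: self-interactions are -1
and every off-diagonal entry is i.i.d. N(0, sd^2) with sd = 0.25 by default.
Growth rates in both patches are i.i.d. Uniform(0.1, 1) — positive, so every
species persists in mono-culture with equilibrium abundance x* = r.

Design targets and upstream communities are random species subsets that can
coexist on their own in the relevant patch.  A subset passes when the linear
equilibrium ``A_sub x* = -r_sub`` is strictly positive (feasibility), the
community Jacobian ``diag(x*) A_sub`` is Hurwitz-stable, and one cycle of
integration started at x* keeps every member above the extinction threshold
with an endpoint close to x*.  Subsets are rejection-sampled; richer subsets
fail more often, which is why target richness is capped well below the pool
size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dynamics import CYCLE_DURATION, EXTINCTION_THRESHOLD, step_cycle
from .pool import MetaCommunityState, SpeciesPool

__all__ = [
    "EnsembleConfig",
    "sample_pool",
    "subset_equilibrium",
    "generate_design_target",
    "generate_upstream_community",
]


@dataclass(frozen=True)
class EnsembleConfig:
    """Parameters of the random pool ensemble."""

    N: int = 25
    interaction_sd: float = 0.25
    growth_low: float = 0.1
    growth_high: float = 1.0
    richness_range: tuple = (1, 10)

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if self.interaction_sd <= 0:
            raise ValueError("interaction_sd must be positive")
        if not self.growth_low < self.growth_high:
            raise ValueError("growth_low must be below growth_high")
        lo, hi = self.richness_range
        if not (1 <= lo <= hi <= self.N):
            raise ValueError("richness_range must lie within 1..N")


def sample_pool(config: EnsembleConfig, rng: np.random.Generator) -> SpeciesPool:
    """Draw one pool: A ~ (diag -1, off-diag N(0, sd^2)), r ~ U(low, high)."""
    n = config.N
    A = rng.normal(0.0, config.interaction_sd, size=(n, n))
    np.fill_diagonal(A, -1.0)
    r1 = rng.uniform(config.growth_low, config.growth_high, size=n)
    r2 = rng.uniform(config.growth_low, config.growth_high, size=n)
    return SpeciesPool(r1=r1, r2=r2, A=A)


def subset_equilibrium(pool: SpeciesPool, members: np.ndarray, patch: str):
    """Analytic equilibrium of an isolated subset in one patch.

    Solves ``A_sub x* = -r_sub``.  Returns ``(x_star, feasible, stable)``
    where feasible means x* is strictly positive and stable means all
    eigenvalues of ``diag(x*) A_sub`` have negative real parts.
    """
    members = np.asarray(members, dtype=int)
    r = (pool.r1 if patch == "up" else pool.r2)[members]
    A = pool.A[np.ix_(members, members)]
    try:
        x_star = np.linalg.solve(A, -r)
    except np.linalg.LinAlgError:
        return None, False, False
    feasible = bool(np.all(x_star > 0))
    if not feasible:
        return x_star, False, False
    J = x_star[:, None] * A
    stable = bool(np.all(np.linalg.eigvals(J).real < 0))
    return x_star, feasible, stable


def _persists(pool, members, x_star, patch) -> bool:
    """Numeric check: one cycle from x* keeps all members alive near x*."""
    n = pool.N
    state = MetaCommunityState.empty(n)
    if patch == "up":
        state.x1[members] = x_star
    else:
        state.x2[members] = x_star
    post, ok = step_cycle(state, pool)
    x_end = (post.x1 if patch == "up" else post.x2)[members]
    return ok and np.all(x_end > EXTINCTION_THRESHOLD) and np.max(np.abs(x_end - x_star)) < 1e-3


def _sample_community(
    pool: SpeciesPool,
    richness: int,
    patch: str,
    rng: np.random.Generator,
    max_tries: int = 10_000,
    verify: bool = True,
):
    if richness == 0:
        return np.array([], dtype=int), np.array([])
    if not 1 <= richness <= pool.N:
        raise ValueError(f"richness {richness} out of range 1..{pool.N}")
    for _ in range(max_tries):
        members = np.sort(rng.choice(pool.N, size=richness, replace=False))
        x_star, feasible, stable = subset_equilibrium(pool, members, patch)
        if not (feasible and stable):
            continue
        if verify and not _persists(pool, members, x_star, patch):
            continue
        return members, x_star
    raise RuntimeError(
        f"no feasible locally stable {patch} community of richness {richness} "
        f"found in {max_tries} draws"
    )


def generate_design_target(
    pool: SpeciesPool, richness: int, rng: np.random.Generator, max_tries: int = 10_000
):
    """A downstream target community: members plus equilibrium abundances."""
    return _sample_community(pool, richness, "down", rng, max_tries)


def generate_upstream_community(
    pool: SpeciesPool, richness: int, rng: np.random.Generator, max_tries: int = 10_000
):
    """A self-coexistent upstream community (richness 0 = explicit
    no-upstream control), accepted by the same rejection contract as
    design targets."""
    return _sample_community(pool, richness, "up", rng, max_tries)


def random_upstream_community(
    pool: SpeciesPool, richness: int, rng: np.random.Generator
):
    """An *unscreened* random upstream community for the design scenario.

    A uniformly random subset of the given richness, each member initialized
    at its mono-culture equilibrium (x = r1).  No coexistence screening is
    applied: whether the community persists is decided by the design
    scenario's joint relaxation, whose extinction filter discards
    meta-communities losing species in either patch.  This is what makes
    rich random meta-communities rare in the design scenario.
    """
    if richness == 0:
        return np.array([], dtype=int), np.array([])
    if not 1 <= richness <= pool.N:
        raise ValueError(f"richness {richness} out of range 1..{pool.N}")
    members = np.sort(rng.choice(pool.N, size=richness, replace=False))
    return members, pool.r1[members].copy()
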