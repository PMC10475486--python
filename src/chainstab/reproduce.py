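"""Scaled reproduction drivers for the headline experiments.

Each driver regenerates its inputs from a master seed, runs the relevant
scenario end to end and returns the summary statistic(s) together with the
number of measurements behind them.  ``scale='full'`` uses the original
ensemble sizes (60 replicates, 250 cycles, 200 upstream communities, a
5x5 migration grid); ``scale='desk'`` uses reduced sampling sizes chosen to
run on a single CPU in minutes while keeping the medians and correlations
statistically meaningful.  The study conditions themselves — pool size 25,
interaction SD 0.25, growth rates U(0.1, 1), richness 1..10, inoculum 0.01,
300-t cycles — are identical at both scales.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .ensembles import (
    EnsembleConfig,
    generate_design_target,
    random_upstream_community,
    sample_pool,
)
from .interventions import build_pseudo_system, run_pseudo_experiment
from .migration import MigrationParams, migration_probabilities
from .pool import MetaCommunityState
from .scenarios import filter_unchanged, run_assembly, run_design
from .stability import stability

__all__ = ["REPRODUCIBLE_SECTIONS", "reproduce", "available_sections"]

FULL_GRID = [
    MigrationParams(rho, mu)
    for rho in (0.0, 0.25, 0.5, 0.75, 1.0)
    for mu in (0.0, 0.25, 0.5, 0.75, 1.0)
]
#: desk-scale grid for assembly runs: the full rho marginal is kept (pooled
#: medians are dominated by the rho mix, in particular the fraction of
#: rho = 0 cells where the upstream patch stays empty), while the weaker
#: mu axis is thinned.  Contains the special corners (1, 0) and rho = 0.
DESK_GRID = [
    MigrationParams(rho, mu)
    for rho in (0.0, 0.25, 0.5, 0.75, 1.0)
    for mu in (0.0, 0.5, 1.0)
]

_CONFIG = EnsembleConfig()  # N=25, sd=0.25, U(0.1, 1) growth, richness 1..10


def _spawn(seed: int, n: int):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _rand_richness(rng, config=_CONFIG):
    lo, hi = config.richness_range
    return int(rng.integers(lo, hi + 1))


# ---------------------------------------------------------------------------
# unstructured (single patch) experiments
# ---------------------------------------------------------------------------


def design_unstructured(seed: int, n_communities: int = 60) -> dict:
    """Median stability of randomly generated locally stable communities in
    a single patch (no upstream community; all invaders arrive directly)."""
    rngs = _spawn(seed, n_communities)
    params = MigrationParams(0.0, 0.0)
    values = []
    for rng in rngs:
        pool = sample_pool(_CONFIG, rng)
        members, x_star = generate_design_target(pool, _rand_richness(rng), rng)
        state = MetaCommunityState.empty(pool.N)
        state.x2[members] = x_star
        values.append(stability(state, pool, params).q0)
    return {"value": float(np.median(values)), "n": len(values), "values": values}


def assembly_unstructured(seed: int, replicates: int = 8, cycles: int = 250) -> dict:
    """Median stability across post-invasion cycles of single-patch assembly
    runs (unchanged-abundance cycles removed)."""
    rngs = _spawn(seed, replicates)
    params = MigrationParams(0.0, 0.0)
    q = []
    for rep, rng in enumerate(rngs):
        pool = sample_pool(_CONFIG, rng)
        records = run_assembly(
            pool, params, cycles, rng, replicate=rep, compute_feature_vectors=False
        )
        q.extend(r.q0 for r in filter_unchanged(records) if r.valid)
    return {"value": float(np.median(q)), "n": len(q), "values": q}


# ---------------------------------------------------------------------------
# structured (two patch) experiments
# ---------------------------------------------------------------------------


def assembly_structured(
    seed: int, replicates: int = 2, cycles: int = 250, grid=None
) -> dict:
    """Two-patch assembly pooled over the migration grid.

    Returns the pooled median stability, the Spearman correlation between
    stability and cycle index, and the median total positive trans strength,
    all over unchanged-filtered records.  One pool per replicate is shared
    across the grid, mirroring how parameter sets reuse species pools.
    """
    grid = DESK_GRID if grid is None else grid
    rngs = _spawn(seed, replicates)
    kept = []
    for rep, rep_rng in enumerate(rngs):
        pool = sample_pool(_CONFIG, rep_rng)
        run_rngs = _spawn(int(rep_rng.integers(2**31)), len(grid))
        for params, rng in zip(grid, run_rngs):
            records = run_assembly(pool, params, cycles, rng, replicate=rep)
            kept.extend(r for r in filter_unchanged(records) if r.valid)
    q = [r.q0 for r in kept]
    t = [r.cycle for r in kept]
    trans = [r.features["total_pos_trans"] for r in kept]
    rho_t, _ = spearmanr(q, t)
    return {
        "median_q0": float(np.median(q)),
        "spearman_time": float(rho_t),
        "median_total_pos_trans": float(np.median(trans)),
        "n": len(q),
        "records": kept,
    }


def design_structured(
    seed: int, targets: int = 30, upstream: int = 50, grid=None
) -> dict:
    """Random target communities exposed to random upstream communities.

    Each target gets a fresh pool; its upstream communities are unscreened
    random subsets of the same pool (members start at their mono-culture
    equilibria), so meta-communities losing any species in either patch
    during the joint relaxation are discarded — the dominant data-reduction
    step of this scenario.  Trial outcomes are computed once per survivor
    and re-weighted over the grid (exact, since outcomes do not depend on
    rho or mu).
    """
    grid = FULL_GRID if grid is None else grid
    rngs = _spawn(seed, targets)
    records = []
    survivors = 0
    attempts = 0
    for rng in rngs:
        pool = sample_pool(_CONFIG, rng)
        t_members, t_eq = generate_design_target(pool, _rand_richness(rng), rng)
        for _ in range(upstream):
            u_members, u_eq = random_upstream_community(
                pool, _rand_richness(rng), rng
            )
            attempts += 1
            recs = run_design(pool, t_members, t_eq, u_members, u_eq, grid)
            recs = [r for r in recs if r["valid"]]
            if recs:
                survivors += 1
                records.extend(recs)

    q_all = np.array([r["q0"] for r in records])
    rho_arr = np.array([r["rho"] for r in records])
    mu_arr = np.array([r["mu"] for r in records])
    q_rho0 = q_all[rho_arr == 0.0]
    q_10 = q_all[(rho_arr == 1.0) & (mu_arr == 0.0)]
    # the trans feature does not depend on (rho, mu): one value per survivor
    trans = np.array(
        [r["total_pos_trans"] for r in records if r["rho"] == 0.0 and r["mu"] == 0.0]
    )
    return {
        "median_q0": float(np.median(q_all)),
        "median_q0_rho0": float(np.median(q_rho0)),
        "median_q0_rho1_mu0": float(np.median(q_10)),
        "median_total_pos_trans": float(np.median(trans)),
        "n": len(q_all),
        "n_survivors": survivors,
        "n_attempts": attempts,
        "records": records,
    }


# ---------------------------------------------------------------------------
# pseudo-spatial experiment
# ---------------------------------------------------------------------------


def pseudo_positive(seed: int, per_m: int = 30, m_values=(0.1, 0.3, 0.6, 0.9)) -> dict:
    """Spearman correlation between the summed positive species-0->resident
    strength and the paired stability difference, over positive-m systems.

    Systems whose initial {species 0} + residents community does not coexist
    are redrawn at generation time; systems whose residents cannot coexist
    after species 0 is removed are discarded, matching the paired design.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])
    systems = []
    from .interventions import _coexists  # generation-time coexistence guard

    for m in m_values:
        kept = 0
        guard = 0
        while kept < per_m and guard < 100 * per_m:
            guard += 1
            sys_ = build_pseudo_system(m, rng)
            members = np.sort(np.concatenate([[0], sys_.residents]))
            if _coexists(sys_.pool, members) is not None:
                systems.append(sys_)
                kept += 1
        if kept < per_m:
            raise RuntimeError(f"could not generate {per_m} coexisting systems for m={m}")
    result = run_pseudo_experiment(systems)
    return {
        "value": result["spearman_rho"],
        "n": len(result["records"]),
        "records": result["records"],
    }


# ---------------------------------------------------------------------------
# section registry
# ---------------------------------------------------------------------------


def _sections(seed: int, scale: str) -> dict:
    desk = scale == "desk"
    return {
        "design-median": lambda: design_unstructured(seed, 60),
        "assembly-median": lambda: assembly_unstructured(
            seed, *(8, 250) if desk else (60, 250)
        ),
        "structured-assembly": lambda: assembly_structured(
            seed, *(2, 250) if desk else (60, 250), grid=DESK_GRID if desk else FULL_GRID
        ),
        "structured-design": lambda: design_structured(
            seed, *(30, 50) if desk else (60, 200), grid=FULL_GRID
        ),
        "pseudo-positive": lambda: pseudo_positive(seed, 30),
        "probabilities-sum": lambda: _probability_normalization(seed),
    }


def _probability_normalization(seed: int) -> dict:
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(100):
        n = int(rng.integers(1, 40))
        params = MigrationParams(rng.uniform(), rng.uniform(0, 5))
        x1 = rng.uniform(0, 2, n) * (rng.uniform(size=n) < 0.5)
        probs = migration_probabilities(params, x1)
        worst = max(worst, abs(probs.total - 1.0))
    return {"value": worst, "n": 100}


REPRODUCIBLE_SECTIONS = (
    "design-median",
    "assembly-median",
    "structured-assembly",
    "structured-design",
    "pseudo-positive",
    "probabilities-sum",
)


def available_sections() -> tuple:
    return REPRODUCIBLE_SECTIONS


def reproduce(section: str, seed: int = 0, scale: str = "desk") -> dict:
    """Run one reproduction section and return its summary statistics."""
    table = _sections(seed, scale)
    if section not in table:
        raise KeyError(
            f"unknown section {section!r}; available: {sorted(table)}"
        )
    return table[section]()
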