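"""The downstream stability statistic: 2N deterministic invasion trials.

Stability of the downstream community at cycle T is the probability q0 that
its species composition (presence/absence pattern) is identical one cycle
later, after a single invasion event.  Because the dynamics are
deterministic, q0 only requires 2N trial integrations — each pool species
invading each patch once — combined with the migration probabilities:

    q0 = sum_i p_i1 * Sp(i)  +  sum_i p_i2 * Ri(i)

*Resistance to invasion* Ri(i) is 1 iff species i invading the downstream
patch leaves the downstream presence/absence pattern unchanged (it neither
establishes nor drives a resident extinct).  *Structural persistence* Sp(i)
is 1 iff species i invading the upstream patch drives no downstream resident
extinct; upstream compositional change is deliberately ignored, since only
its knock-on effect on downstream realized growth rates matters.

Both trial outcomes depend only on the state and the pool, not on
(rho, mu); the migration parameters enter purely as weights.  This module
therefore exposes the raw trial outcomes separately so one set of 2N
integrations can be re-weighted across a whole (rho, mu) grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import CYCLE_DURATION, EXTINCTION_THRESHOLD, INOCULUM, step_cycle
from .migration import MigrationParams, MigrationProbabilities, migration_probabilities
from .pool import MetaCommunityState, SpeciesPool

__all__ = ["TrialOutcomes", "StabilityReport", "invasion_trial", "run_all_trials", "combine_trials", "stability"]

#: sentinel for a trial that was skipped because its migration weight is zero
NOT_EVALUATED = -1


@dataclass
class TrialOutcomes:
    """Raw outcomes of the 2N invasion trials (independent of rho, mu).

    Entries are 1/0, or -1 for trials that were not evaluated (only possible
    when a zero-weight patch was skipped).  ``valid`` is False if any
    evaluated trial hit an integrator failure.
    """

    Ri: np.ndarray
    Sp: np.ndarray
    valid: bool = True


@dataclass
class StabilityReport:
    """q0 and its decomposition for one state under one (rho, mu)."""

    Ri: np.ndarray
    Sp: np.ndarray
    probs: MigrationProbabilities
    q0: float
    resistance_component: float
    persistence_component: float
    valid: bool = True


def invasion_trial(
    state: MetaCommunityState,
    pool: SpeciesPool,
    invader: int,
    patch: str,
    duration: float = CYCLE_DURATION,
    threshold: float = EXTINCTION_THRESHOLD,
    inoculum: float = INOCULUM,
):
    """Run one deterministic invasion trial from a copy of ``state``.

    The invader is added at abundance ``inoculum`` in the target patch (if it
    is already present there, the inoculum is added on top — presence of the
    invader itself then cannot change).  Returns ``(outcome, post_state,
    converged)`` where outcome is Ri for ``patch='down'`` and Sp for
    ``patch='up'``.
    """
    if not 0 <= invader < pool.N:
        raise ValueError(f"invader index {invader} out of range")
    if patch not in ("up", "down"):
        raise ValueError("patch must be 'up' or 'down'")
    pre_down = state.x2 > 0
    trial = state.copy()
    if patch == "up":
        trial.x1[invader] += inoculum
    else:
        trial.x2[invader] += inoculum
    post, ok = step_cycle(trial, pool, duration=duration, threshold=threshold)
    post_down = post.x2 > 0
    if patch == "down":
        outcome = int(np.array_equal(post_down, pre_down))
    else:
        # structural persistence: no downstream resident lost
        outcome = int(np.all(post_down[pre_down]))
    return outcome, post, ok


def run_all_trials(
    state: MetaCommunityState,
    pool: SpeciesPool,
    duration: float = CYCLE_DURATION,
    threshold: float = EXTINCTION_THRESHOLD,
    patches: str = "both",
) -> TrialOutcomes:
    """All 2N invasion trials for one state.

    ``patches`` may restrict evaluation to ``'up'`` or ``'down'`` (the other
    side is filled with the NOT_EVALUATED sentinel); use this only when the
    corresponding migration weights are exactly zero.
    """
    n = pool.N
    Ri = np.full(n, NOT_EVALUATED, dtype=int)
    Sp = np.full(n, NOT_EVALUATED, dtype=int)
    valid = True
    if patches in ("both", "down"):
        for i in range(n):
            Ri[i], _, ok = invasion_trial(state, pool, i, "down", duration, threshold)
            valid &= ok
    if patches in ("both", "up"):
        for i in range(n):
            Sp[i], _, ok = invasion_trial(state, pool, i, "up", duration, threshold)
            valid &= ok
    return TrialOutcomes(Ri=Ri, Sp=Sp, valid=valid)


def combine_trials(
    trials: TrialOutcomes, probs: MigrationProbabilities
) -> StabilityReport:
    """Weight trial outcomes by migration probabilities to obtain q0."""
    Ri = trials.Ri
    Sp = trials.Sp
    if np.any((Ri == NOT_EVALUATED) & (probs.p2 > 0)):
        raise ValueError("downstream trials missing for nonzero p2 weights")
    if np.any((Sp == NOT_EVALUATED) & (probs.p1 > 0)):
        raise ValueError("upstream trials missing for nonzero p1 weights")
    res = float(np.sum(probs.p2 * np.where(Ri == NOT_EVALUATED, 0, Ri)))
    per = float(np.sum(probs.p1 * np.where(Sp == NOT_EVALUATED, 0, Sp)))
    return StabilityReport(
        Ri=Ri,
        Sp=Sp,
        probs=probs,
        q0=res + per,
        resistance_component=res,
        persistence_component=per,
        valid=trials.valid,
    )


def stability(
    state: MetaCommunityState,
    pool: SpeciesPool,
    params: MigrationParams,
    duration: float = CYCLE_DURATION,
    threshold: float = EXTINCTION_THRESHOLD,
    skip_unweighted: bool = True,
) -> StabilityReport:
    """Downstream stability q0 of ``state`` under migration ``params``.

    Fully deterministic: repeated calls with identical inputs agree exactly.
    With ``skip_unweighted`` (default) trials whose migration weight is zero
    for these parameters are not integrated; this never changes q0.
    """
    probs = migration_probabilities(params, state.x1)
    if skip_unweighted:
        if np.all(probs.p1 == 0):
            patches = "down"
        elif np.all(probs.p2 == 0):
            patches = "up"
        else:
            patches = "both"
    else:
        patches = "both"
    trials = run_all_trials(state, pool, duration, threshold, patches=patches)
    return combine_trials(trials, probs)
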