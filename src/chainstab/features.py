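"""Community features: realized interaction strengths, in-degrees, richness.

All features are computed on *realized* interactions only — both endpoint
species must be present in the relevant patch(es).  Within a patch, the
total positive (negative) strength is the sum of |a_ik| over off-diagonal
pairs of present species with a_ik > 0 (< 0); the mean divides by the number
of such links.  The *trans* features run from present upstream species k to
present downstream species i.  Degrees are in-degrees of nonzero
off-diagonal realized links, averaged over the present species of the
receiving patch (for trans: over downstream richness).  Abundances are never
weighted in, and self-interactions never contribute.

Empty classes (no links of a sign, or an empty patch) yield 0 rather than
NaN so downstream regressions need no imputation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .migration import MigrationParams
from .pool import MetaCommunityState, SpeciesPool

__all__ = ["FeatureVector", "compute_features", "FEATURE_NAMES"]

FEATURE_NAMES = [
    "total_pos_up", "mean_pos_up", "total_neg_up", "mean_neg_up",
    "mean_degree_up", "richness_up",
    "total_pos_down", "mean_pos_down", "total_neg_down", "mean_neg_down",
    "mean_degree_down", "richness_down",
    "total_pos_trans", "mean_pos_trans", "total_neg_trans", "mean_neg_trans",
    "mean_degree_trans",
    "rho", "mu",
]


@dataclass
class FeatureVector:
    total_pos_up: float
    mean_pos_up: float
    total_neg_up: float
    mean_neg_up: float
    mean_degree_up: float
    richness_up: int
    total_pos_down: float
    mean_pos_down: float
    total_neg_down: float
    mean_neg_down: float
    mean_degree_down: float
    richness_down: int
    total_pos_trans: float
    mean_pos_trans: float
    total_neg_trans: float
    mean_neg_trans: float
    mean_degree_trans: float
    rho: float
    mu: float

    def as_dict(self) -> dict:
        return asdict(self)


def _strengths(block: np.ndarray):
    """(total_pos, mean_pos, total_neg, mean_neg, n_links) of a realized
    off-diagonal block (diagonal already removed by the caller)."""
    pos = block[block > 0]
    neg = block[block < 0]
    tp = float(pos.sum())
    tn = float(np.abs(neg).sum())
    mp = tp / pos.size if pos.size else 0.0
    mn = tn / neg.size if neg.size else 0.0
    return tp, mp, tn, mn, pos.size + neg.size


def compute_features(
    state: MetaCommunityState, pool: SpeciesPool, params: MigrationParams
) -> FeatureVector:
    """Feature vector of one (thresholded) meta-community state."""
    up = np.flatnonzero(state.x1 > 0)
    down = np.flatnonzero(state.x2 > 0)

    def within(members):
        block = pool.A[np.ix_(members, members)].copy()
        np.fill_diagonal(block, 0.0)
        tp, mp, tn, mn, nlinks = _strengths(block)
        deg = nlinks / members.size if members.size else 0.0
        return tp, mp, tn, mn, deg

    tp_u, mp_u, tn_u, mn_u, deg_u = within(up)
    tp_d, mp_d, tn_d, mn_d, deg_d = within(down)

    # trans: effect of present upstream species k on present downstream i;
    # A[down, up] needs no diagonal masking unless a species is present in
    # both patches, in which case its self-interaction is not a trans link.
    trans = pool.A[np.ix_(down, up)].copy()
    both = np.intersect1d(down, up)
    for s in both:
        trans[np.searchsorted(down, s), np.searchsorted(up, s)] = 0.0
    tp_t, mp_t, tn_t, mn_t, nlinks_t = _strengths(trans)
    deg_t = nlinks_t / down.size if down.size else 0.0

    return FeatureVector(
        total_pos_up=tp_u, mean_pos_up=mp_u, total_neg_up=tn_u, mean_neg_up=mn_u,
        mean_degree_up=deg_u, richness_up=int(up.size),
        total_pos_down=tp_d, mean_pos_down=mp_d, total_neg_down=tn_d, mean_neg_down=mn_d,
        mean_degree_down=deg_d, richness_down=int(down.size),
        total_pos_trans=tp_t, mean_pos_trans=mp_t, total_neg_trans=tn_t, mean_neg_trans=mn_t,
        mean_degree_trans=deg_t,
        rho=params.rho, mu=params.mu,
    )
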