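"""Statistical layer: standardization, fractional logistic regression,
and nonparametric tests with rank-based effect sizes.

Stability values are probabilities in [0, 1], not Bernoulli outcomes, so
the regression is a *fractional* logit: a binomial GLM with logit link fit
to the fractional response, with robust (sandwich) standard errors.
Features are standardized to mean 0 / SD 1 (population SD) so coefficient
magnitudes are comparable.

Effect sizes are the rank-based pair: Cliff's delta for two independent
samples and the rank-biserial correlation for paired (signed-rank)
comparisons, both in [-1, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "standardize",
    "RegressionResult",
    "fit_stability_logit",
    "cliffs_delta",
    "cliffs_delta_label",
    "rank_biserial",
    "nonparametric_tests",
]


def standardize(table: pd.DataFrame) -> pd.DataFrame:
    """Center and scale every numeric column to mean 0, SD 1.

    The population SD (divisor n) is used.  Constant columns carry no
    information and are dropped with a warning.
    """
    out = {}
    dropped = []
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0 or not np.isfinite(sd):
            dropped.append(col)
            continue
        out[col] = (x - x.mean()) / sd
    if dropped:
        warnings.warn(f"dropping constant columns from standardization: {dropped}")
    return pd.DataFrame(out, index=table.index)


@dataclass
class RegressionResult:
    """Coefficients of a fractional-logit fit on standardized features."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    n: int

    def coef(self, name: str) -> float:
        return float(self.params[name])


def fit_stability_logit(
    records: pd.DataFrame,
    features: list,
    response: str = "q0",
) -> RegressionResult:
    """Fractional logistic regression of stability on standardized features.

    ``records[response]`` must lie in [0, 1].  Features are standardized
    internally; constant features are dropped.  Robust HC1 standard errors
    are reported since the response is a probability, not a Bernoulli draw.
    Raises ``ValueError`` on a singular design, naming the columns.
    """
    y = records[response].to_numpy(dtype=float)
    if np.any((y < 0) | (y > 1)):
        raise ValueError(f"{response} must lie in [0, 1]")
    X = standardize(records[list(features)])
    design = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(design.to_numpy())
    if rank < design.shape[1]:
        raise ValueError(
            f"singular design matrix (rank {rank} < {design.shape[1]}); "
            f"columns: {list(design.columns)}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # fractional response is intentional
        model = sm.GLM(y, design, family=sm.families.Binomial())
        fit = model.fit(cov_type="HC1")
    return RegressionResult(
        params=fit.params, bse=fit.bse, pvalues=fit.pvalues, n=len(y)
    )


def cliffs_delta(a, b) -> float:
    """Cliff's delta: (#{a_i > b_j} - #{a_i < b_j}) / (n_a n_b) in [-1, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    diff = a[:, None] - b[None, :]
    return float((np.sign(diff)).sum() / (a.size * b.size))


def cliffs_delta_label(delta: float) -> str:
    """Conventional magnitude label (negligible/small/medium/large);
    advisory only."""
    d = abs(delta)
    if d < 0.11:
        return "negligible"
    if d < 0.28:
        return "small"
    if d < 0.43:
        return "medium"
    return "large"


def rank_biserial(differences) -> float:
    """Rank-biserial correlation of paired differences, matched to the
    Wilcoxon signed-rank convention (zeros dropped, ties mid-ranked).

    Returns NaN if every difference is zero.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        return float("nan")
    ranks = sps.rankdata(np.abs(d))
    r_pos = ranks[d > 0].sum()
    r_neg = ranks[d < 0].sum()
    return float((r_pos - r_neg) / (r_pos + r_neg))


def nonparametric_tests(a, b=None, mode: str = "rank_sum", alternative: str = "two-sided") -> dict:
    """Wilcoxon rank-sum / signed-rank tests and Spearman correlation.

    * ``rank_sum``: independent samples ``a`` vs ``b``; effect size is
      Cliff's delta.
    * ``signed_rank``: paired; pass differences as ``a`` (or ``a`` and ``b``
      to difference them); effect size is the rank-biserial correlation.
    * ``spearman``: correlation between paired vectors ``a`` and ``b``.

    ``alternative`` follows scipy ('two-sided', 'greater', 'less').
    """
    a = np.asarray(a, dtype=float)
    if mode == "rank_sum":
        if b is None:
            raise ValueError("rank_sum requires two samples")
        b = np.asarray(b, dtype=float)
        if a.size < 1 or b.size < 1:
            raise ValueError("both samples must be nonempty")
        stat, p = sps.mannwhitneyu(a, b, alternative=alternative)
        return {"statistic": float(stat), "p": float(p), "effect_size": cliffs_delta(a, b)}
    if mode == "signed_rank":
        d = a if b is None else a - np.asarray(b, dtype=float)
        if np.all(d == 0):
            raise ValueError("all paired differences are zero")
        _, p = sps.wilcoxon(d, alternative=alternative)
        # report the positive-rank sum W+ regardless of sidedness (scipy's
        # two-sided statistic is min(W+, W-))
        nz = d[d != 0]
        ranks = sps.rankdata(np.abs(nz))
        w_plus = float(ranks[nz > 0].sum())
        return {"statistic": w_plus, "p": float(p), "effect_size": rank_biserial(d)}
    if mode == "spearman":
        if b is None:
            raise ValueError("spearman requires two vectors")
        b = np.asarray(b, dtype=float)
        if a.size < 3:
            raise ValueError("spearman requires at least 3 pairs")
        rho, p = sps.spearmanr(a, b, alternative=alternative)
        return {"statistic": float(rho), "p": float(p), "effect_size": float(rho)}
    raise ValueError(f"unknown mode {mode!r}")
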