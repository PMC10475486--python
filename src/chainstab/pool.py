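"""Core containers: the species pool and the two-patch community state.

A *migration pool* is a fixed set of ``N`` candidate species.  Each species
carries two intrinsic growth rates (one per patch, since the upstream and
downstream environments may differ) and a shared interaction matrix ``A``
whose entry ``A[i, k]`` is the net per-abundance effect of species ``k`` on
species ``i``.  Interactions are scaled so that every self-interaction is
exactly -1, which puts every mono-culture equilibrium at ``x* = r``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SpeciesPool", "MetaCommunityState", "Trajectory"]


@dataclass(frozen=True)
class SpeciesPool:
    """A migration pool of N species shared by the two patches.

    Parameters
    ----------
    r1, r2 : ndarray, shape (N,)
        Intrinsic growth rates in the upstream (1) and downstream (2) patch.
    A : ndarray, shape (N, N)
        Interaction matrix; ``A[i, k]`` is the effect of species ``k`` on
        species ``i``.  The diagonal must be exactly -1.
    """

    r1: np.ndarray
    r2: np.ndarray
    A: np.ndarray

    def __post_init__(self) -> None:
        r1 = np.asarray(self.r1, dtype=float)
        r2 = np.asarray(self.r2, dtype=float)
        A = np.asarray(self.A, dtype=float)
        object.__setattr__(self, "r1", r1)
        object.__setattr__(self, "r2", r2)
        object.__setattr__(self, "A", A)
        n = r1.shape[0]
        if n < 1:
            raise ValueError("pool must contain at least one species")
        if r2.shape != (n,) or A.shape != (n, n):
            raise ValueError(
                f"inconsistent pool dimensions: r1 {r1.shape}, r2 {r2.shape}, A {A.shape}"
            )
        if not (np.isfinite(r1).all() and np.isfinite(r2).all() and np.isfinite(A).all()):
            raise ValueError("pool parameters must be finite")
        if not np.all(np.diag(A) == -1.0):
            raise ValueError("diagonal of the interaction matrix must be exactly -1")

    @property
    def N(self) -> int:
        return self.r1.shape[0]

    # -- serialization ----------------------------------------------------
    def to_csv(self, path) -> None:
        """Write the pool as a flat CSV: ``species, r1, r2, a_0..a_{N-1}``."""
        cols = {"species": np.arange(self.N), "r1": self.r1, "r2": self.r2}
        for k in range(self.N):
            cols[f"a_{k}"] = self.A[:, k]
        pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "SpeciesPool":
        df = pd.read_csv(path)
        n = len(df)
        A = df[[f"a_{k}" for k in range(n)]].to_numpy(dtype=float)
        return cls(df["r1"].to_numpy(float), df["r2"].to_numpy(float), A)


@dataclass
class MetaCommunityState:
    """Abundances in both patches at a cycle boundary.

    Species with abundance exactly 0 are absent; absence is absorbing under
    the deterministic dynamics (new species only enter via migration).
    """

    x1: np.ndarray
    x2: np.ndarray
    cycle: int = 0

    def __post_init__(self) -> None:
        self.x1 = np.asarray(self.x1, dtype=float).copy()
        self.x2 = np.asarray(self.x2, dtype=float).copy()
        if self.x1.shape != self.x2.shape:
            raise ValueError("x1 and x2 must have the same length")
        if np.any(self.x1 < 0) or np.any(self.x2 < 0):
            raise ValueError("abundances must be nonnegative")

    @property
    def N(self) -> int:
        return self.x1.shape[0]

    def copy(self) -> "MetaCommunityState":
        return MetaCommunityState(self.x1.copy(), self.x2.copy(), self.cycle)

    def presence_downstream(self) -> np.ndarray:
        return self.x2 > 0

    def presence_upstream(self) -> np.ndarray:
        return self.x1 > 0

    @classmethod
    def empty(cls, n: int) -> "MetaCommunityState":
        return cls(np.zeros(n), np.zeros(n), 0)


@dataclass
class Trajectory:
    """Solution of one within-cycle integration.

    ``times`` is strictly increasing and spans ``[0, duration]``; ``states``
    holds one :class:`MetaCommunityState` snapshot per time point.
    """

    times: np.ndarray
    states: list
    converged: bool = True

    @property
    def final(self) -> MetaCommunityState:
        return self.states[-1]

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: ``cycle, t, patch, species, abundance``."""
        rows = []
        for t, st in zip(self.times, self.states):
            for patch, x in ((1, st.x1), (2, st.x2)):
                for i, xi in enumerate(x):
                    rows.append((st.cycle, t, patch, i, xi))
        return pd.DataFrame(rows, columns=["cycle", "t", "patch", "species", "abundance"])
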