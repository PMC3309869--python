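"""Seeded permutation engine, add-one p-values, and null diagnostics.

All permutation tests in this package share one convention: the outcome vector
is permuted among subjects, the statistic is recomputed on each permuted
outcome, and the p-value is the add-one proportion

    p = (1 + #{b : T_b >= T_obs}) / (B + 1),

which is never zero and is exactly valid under exchangeability (ties count as
greater-or-equal).  The permutation stream is generated by a counter-based
Philox generator so that identical (n, B, seed) always reproduce the same
stream, bit for bit, across runs and platforms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PermutationPlan", "perm_pvalue", "add_one_pvalue", "pvalue_ecdf",
           "EcdfSummary"]


@dataclass
class PermutationPlan:
    """A reproducible stream of B permutations of n subject indices."""

    n: int
    B: int
    seed: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("need n >= 2 subjects")
        if self.B < 1:
            raise ValueError("need B >= 1 permutations")
        self._indices = None

    def indices(self) -> np.ndarray:
        """The (B, n) array of permutation index rows (cached)."""
        if self._indices is None:
            rng = np.random.Generator(np.random.Philox(self.seed))
            idx = np.tile(np.arange(self.n), (self.B, 1))
            self._indices = rng.permuted(idx, axis=1)
        return self._indices

    @classmethod
    def exhaustive(cls, n: int) -> "PermutationPlan":
        """The complete group of all n! permutations (tiny n only), in
        lexicographic order — the exact-enumeration reference."""
        import math
        from itertools import permutations
        if n > 8:
            raise ValueError("exhaustive enumeration is for tiny n only")
        plan = cls(n=n, B=math.factorial(n), seed=0)
        plan._indices = np.array(list(permutations(range(n))), dtype=np.intp)
        return plan

    def __iter__(self):
        return iter(self.indices())


def add_one_pvalue(observed: float, null_stats: np.ndarray) -> float:
    """(1 + #{T_b >= T_obs}) / (B + 1), ties counted as exceedances."""
    null_stats = np.asarray(null_stats, dtype=float)
    return (1.0 + np.count_nonzero(null_stats >= observed)) / (null_stats.size + 1.0)


def perm_pvalue(stat_fn, y, plan: PermutationPlan):
    """Permutation p-value of ``stat_fn`` under outcome permutation.

    ``stat_fn`` maps an outcome vector to a scalar statistic and must be
    deterministic.  Returns ``(p_value, null_stats)`` with the B recomputed
    statistics retained for diagnostics.  Vectorised fast paths elsewhere in
    the package consume the same :meth:`PermutationPlan.indices` stream, so
    their p-values agree exactly with this reference loop.
    """
    y = np.asarray(y, dtype=float)
    observed = float(stat_fn(y))
    null_stats = np.empty(plan.B)
    for b, idx in enumerate(plan.indices()):
        try:
            null_stats[b] = stat_fn(y[idx])
        except Exception as exc:  # noqa: BLE001 - reraise with context
            raise RuntimeError(f"statistic failed on permutation {b}") from exc
    return add_one_pvalue(observed, null_stats), null_stats


@dataclass
class EcdfSummary:
    """Empirical CDF of permutation p-values plus the point mass at the top.

    The restricted likelihood-ratio test has a point mass of exactly-zero
    statistics under the null, so its p-values pile up at the maximum
    attainable value while the rest are uniform; ``mass_at_max`` quantifies
    that pile-up.
    """

    grid: np.ndarray
    cdf: np.ndarray
    mass_at_max: float
    n: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"p": self.grid, "ecdf": self.cdf})

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.step(self.grid, self.cdf, where="post", **kwargs)
        ax.set_xlabel("p-value")
        ax.set_ylabel("ECDF")
        return ax


def pvalue_ecdf(pvalues, grid_size: int = 200) -> EcdfSummary:
    """Summarise a collection of p-values in (0, 1] as an ECDF on a fixed grid."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value collection")
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    grid = np.linspace(0.0, 1.0, grid_size + 1)
    cdf = np.searchsorted(np.sort(p), grid, side="right") / p.size
    mass_at_max = float(np.mean(p == p.max()))
    return EcdfSummary(grid=grid, cdf=cdf, mass_at_max=mass_at_max, n=p.size)
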