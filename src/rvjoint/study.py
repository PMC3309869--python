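"""Scenario driver: empirical type I error and power over the simulation grid.

One scenario = (trait type, effect setting, rho, number of neutral variants).
For each of R replicates the driver simulates a dataset, runs the requested
tests sharing a single permutation stream per replicate (B outcome
permutations for the five permutation tests; the analytic mixture tail for
SKAT), and records the rejection of each test at each nominal alpha.  The
result is the long-format grid behind the study's type I error tables and
power figures.

Reproducibility: per-replicate seeds derive from the chain
SeedSequence([master_seed, scenario_index, replicate_index, attempt]) —
every scenario and replicate is independently re-runnable, and the serial
loop's results are independent of execution order.  Degenerate draws (a
constant super variant, or a single-class binary outcome) are redrawn with
the attempt counter bumped, counted in the result.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import binomial_tests as bt
from . import gaussian_tests as gt
from .core import BINARY, CONTINUOUS, GenotypeMatrix, PhenotypeVector, super_variant
from .permutation import PermutationPlan, add_one_pvalue
from .quadform import skat_stat
from .results import METHODS, TestResult
from .simulator import SimulationConfig, simulate_dataset

logger = logging.getLogger(__name__)

__all__ = ["StudyResult", "run_scenario", "emit_tables", "run_region_tests",
           "replicate_pvalues"]

_MAX_REDRAWS = 10


@dataclass
class StudyResult:
    """Long-format empirical rejection-rate grid."""

    frame: pd.DataFrame
    n_redraws: int = 0

    def __post_init__(self):
        required = {"trait_type", "setting", "rho", "n_neutral", "alpha",
                    "method", "replicates", "rejections"}
        missing = required - set(self.frame.columns)
        if missing:
            raise ValueError(f"result frame missing columns: {sorted(missing)}")
        f = self.frame
        f["rejection_rate"] = f["rejections"] / f["replicates"]
        f["mc_stderr"] = np.sqrt(f["rejection_rate"] * (1 - f["rejection_rate"])
                                 / f["replicates"])

    def rate(self, method: str, alpha: float, **keys) -> float:
        f = self.frame
        mask = (f["method"] == method) & np.isclose(f["alpha"], alpha)
        for col, val in keys.items():
            mask &= (f[col] == val) if isinstance(val, str) else np.isclose(f[col], val)
        sel = f[mask]
        if len(sel) != 1:
            raise KeyError(f"expected one record, found {len(sel)}")
        return float(sel["rejection_rate"].iloc[0])

    def to_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StudyResult":
        # keep_default_na: the "null" effect setting is a label, not a NaN
        frame = pd.read_csv(path, sep="\t", keep_default_na=False,
                            na_values=[""])
        return cls(frame.drop(columns=["rejection_rate", "mc_stderr"],
                              errors="ignore"))


def _dispatch(method: str, Y: np.ndarray, G: GenotypeMatrix,
              trait_type: str) -> np.ndarray:
    """Observed + permuted statistics for one method on a shared outcome block."""
    s = super_variant(G)
    if method == "sum":
        return gt._batch_sum_stats(Y, s)
    if method == "ssu":
        return gt._batch_ssu_stats(Y, G)
    if method == "score_joint":
        if trait_type == BINARY:
            return bt._batch_score_joint_binary(Y, G)[0]
        return gt._batch_score_joint_stats(Y, G, s)[0]
    if method == "lrt_joint":
        if trait_type == BINARY:
            return bt._batch_glmm_lrt_stats(Y, G, with_burden=True)
        return gt._batch_lrt_joint_stats(Y, G, s)
    if method == "rlrt":
        if trait_type == BINARY:
            return bt._batch_glmm_lrt_stats(Y, G, with_burden=False)
        return gt._batch_rlrt_stats(Y, G)
    raise ValueError(f"unknown permutation method {method!r}")


def replicate_pvalues(G: GenotypeMatrix, y: PhenotypeVector, methods,
                      plan: PermutationPlan) -> dict:
    """p-values of the requested methods on one dataset, sharing one
    permutation stream (SKAT's p-value is analytic and ignores the stream)."""
    for method in methods:
        if method not in METHODS:
            raise ValueError(f"unknown method {method!r}")
    pvals = {}
    perm_methods = [m for m in methods if m != "skat"]
    if perm_methods:
        Y = gt._perm_outcomes(y.values, plan)
        for method in perm_methods:
            stats = _dispatch(method, Y, G, y.trait_type)
            pvals[method] = add_one_pvalue(stats[0], stats[1:])
    if "skat" in methods:
        pvals["skat"] = skat_stat(y, G).p_value
    return pvals


def _replicate_seeds(master_seed: int, scenario_index: int, rep: int,
                     attempt: int) -> tuple:
    ss = np.random.SeedSequence([master_seed, scenario_index, rep, attempt])
    data_seed, perm_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    return data_seed, perm_seed


def _valid_dataset(G: GenotypeMatrix, y: PhenotypeVector) -> bool:
    s = super_variant(G)
    if s.max() == s.min():
        return False
    if y.trait_type == BINARY and (y.values.min() == y.values.max()):
        return False
    return True


def run_scenario(cfg: SimulationConfig, methods, R: int, B: int, alphas,
                 seed: int, scenario_index: int = 0) -> StudyResult:
    """Empirical rejection rates of ``methods`` over R simulated replicates.

    Deterministic given ``seed``; replicates use derived sub-seeds so the
    serial loop could be distributed without changing any number.  A scenario
    aborts if more than 5% of replicates fail outright (after redraws).
    """
    if R < 1:
        raise ValueError("need R >= 1 replicates")
    methods = list(methods)
    if not methods:
        raise ValueError("need at least one method")
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}")
    alphas = list(alphas)
    rejections = {(m, a): 0 for m in methods for a in alphas}
    n_redraws = n_failures = 0
    for rep in range(R):
        pvals = None
        for attempt in range(_MAX_REDRAWS):
            data_seed, perm_seed = _replicate_seeds(seed, scenario_index, rep, attempt)
            rng = np.random.Generator(np.random.Philox(data_seed))
            G, y, _ = simulate_dataset(cfg, rng)
            if not _valid_dataset(G, y):
                n_redraws += 1
                continue
            try:
                plan = PermutationPlan(cfg.n, B, perm_seed)
                pvals = replicate_pvalues(G, y, methods, plan)
                break
            except (ValueError, RuntimeError) as exc:
                logger.warning("replicate %d attempt %d failed: %s", rep, attempt, exc)
                n_redraws += 1
        if pvals is None:
            n_failures += 1
            if n_failures > 0.05 * R:
                raise RuntimeError("more than 5% of replicates failed; aborting scenario")
            continue
        for m in methods:
            for a in alphas:
                rejections[(m, a)] += pvals[m] <= a
    completed = R - n_failures
    records = [{"trait_type": cfg.trait_type, "setting": str(cfg.setting),
                "rho": cfg.rho, "n_neutral": cfg.n_neutral, "alpha": a,
                "method": m, "replicates": completed,
                "rejections": rejections[(m, a)]}
               for m in methods for a in alphas]
    return StudyResult(pd.DataFrame.from_records(records), n_redraws=n_redraws)


def combine(results) -> StudyResult:
    """Concatenate scenario results into one grid."""
    results = list(results)
    frame = pd.concat([r.frame for r in results], ignore_index=True)
    frame = frame.drop(columns=["rejection_rate", "mc_stderr"])
    return StudyResult(frame, n_redraws=sum(r.n_redraws for r in results))


def emit_tables(res: StudyResult, path) -> list:
    """Write the long-format grid plus one wide table per (trait, alpha).

    Wide tables have (n_neutral, rho) rows and one column per method — the
    printed type-I-error table layout.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    written = []
    long_path = path / "study_long.tsv"
    res.to_tsv(long_path)
    written.append(long_path)
    f = res.frame
    for (trait, alpha), grp in f.groupby(["trait_type", "alpha"]):
        wide = grp.pivot_table(index=["n_neutral", "rho"], columns="method",
                               values="rejection_rate")
        out = path / f"rates_{trait}_alpha{alpha:g}.tsv"
        wide.to_csv(out, sep="\t")
        written.append(out)
    return written


def run_region_tests(G: GenotypeMatrix, y: PhenotypeVector, methods,
                     B: int, seed: int) -> list:
    """Run the requested tests on one observed region (the CLI entry point)."""
    plan = PermutationPlan(y.n, B, seed)
    out = []
    Y = None
    for m in methods:
        if m == "skat":
            out.append(skat_stat(y, G))
        else:
            if Y is None:
                Y = gt._perm_outcomes(y.values, plan)
            stats = _dispatch(m, Y, G, y.trait_type)
            out.append(TestResult(method=m, statistic=float(stats[0]),
                                  p_value=add_one_pvalue(stats[0], stats[1:]),
                                  n_permutations=B, seed=seed))
    return out
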