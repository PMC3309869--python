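"""Shared result containers for the six association tests."""
from __future__ import annotations

from dataclasses import dataclass, field

METHODS = ("sum", "ssu", "score_joint", "lrt_joint", "rlrt", "skat")


@dataclass
class TestResult:
    """One test's statistic plus its (possibly permutation) p-value.

    ``statistic`` is >= 0 for every method (the burden test is reported in
    squared, chi-square form).  ``p_value`` is None before calibration;
    permutation p-values use the add-one rule so they lie in (0, 1].
    ``n_permutations`` is 0 for the analytic SKAT p-value.
    """

    method: str
    statistic: float
    p_value: float | None = None
    n_permutations: int = 0
    seed: int | None = None
    components: object | None = None
    extras: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}")
        if not (self.statistic >= 0):
            raise ValueError("statistic must be >= 0")
        if self.p_value is not None and not (0 < self.p_value <= 1):
            raise ValueError("p-value must lie in (0, 1]")
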