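"""Two-sample permutation test on per-spine curvature summaries.

Two populations of spines (e.g. wild-type vs compound-heterozygous
mutants) are compared through one scalar summary per spine — by default
the arc-length-weighted mean curvature.  The null distribution of the
group difference is built by re-assigning the pooled summaries to
groups of the original sizes: exhaustively when the number of distinct
assignments is small (it is C(10, 5) = 252 for the common 5-vs-5
design), otherwise by seeded Monte-Carlo sampling with the standard
add-one correction so the reported p-value is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Callable, Literal, Sequence

import numpy as np

from .errors import UsageError, ValidationError

__all__ = ["PermutationTestResult", "permutation_test", "EXHAUSTIVE_LIMIT"]

#: exhaustive enumeration is used when the number of distinct label
#: assignments does not exceed this
EXHAUSTIVE_LIMIT = 20_000

_STATISTICS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "mean_difference": lambda g, axis: np.mean(g, axis=axis),
    "median_difference": lambda g, axis: np.median(g, axis=axis),
}


@dataclass
class PermutationTestResult:
    statistic_name: str
    observed: float
    n_permutations: int
    mode: Literal["exhaustive", "monte_carlo"]
    p_value: float
    alternative: Literal["two_sided", "greater", "less"]
    seed: int | None = None  # monte_carlo only

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError("p_value must lie in (0, 1]")


def _count_extreme(
    null: np.ndarray, observed: float, alternative: str
) -> int:
    if alternative == "two_sided":
        return int(np.sum(np.abs(null) >= abs(observed)))
    if alternative == "greater":
        return int(np.sum(null >= observed))
    if alternative == "less":
        return int(np.sum(null <= observed))
    raise UsageError(f"unknown alternative {alternative!r}")


def permutation_test(
    group_a: Sequence[float],
    group_b: Sequence[float],
    statistic: Literal["mean_difference", "median_difference"] = "mean_difference",
    alternative: Literal["two_sided", "greater", "less"] = "two_sided",
    n_permutations: int = 10_000,
    seed: int = 0,
    mode: Literal["auto", "exhaustive", "monte_carlo"] = "auto",
) -> PermutationTestResult:
    """Permutation test of stat(A) - stat(B) between two groups.

    Exhaustive mode enumerates every assignment of the pooled values to
    groups of the original sizes and reports the exact p-value
    ``#{T* as-or-more-extreme} / n_assignments`` (inclusive >=, so the
    identity assignment always counts).  Monte-Carlo mode draws
    ``n_permutations`` seeded random assignments and reports
    ``(1 + #extreme) / (n_permutations + 1)``.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("group values must be finite")
    if statistic not in _STATISTICS:
        raise UsageError(f"unknown statistic {statistic!r}")
    stat = _STATISTICS[statistic]
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = float(stat(a, 0) - stat(b, 0))

    n_assignments = comb(n, na)
    if mode not in ("auto", "exhaustive", "monte_carlo"):
        raise UsageError(f"unknown mode {mode!r}")
    if mode == "exhaustive" and n_assignments > EXHAUSTIVE_LIMIT:
        raise UsageError(
            f"{n_assignments} assignments exceed the exhaustive limit "
            f"({EXHAUSTIVE_LIMIT}); use monte_carlo"
        )
    if mode != "monte_carlo" and n_assignments <= EXHAUSTIVE_LIMIT:
        idx = np.fromiter(
            (i for c in combinations(range(n), na) for i in c), dtype=np.intp
        ).reshape(n_assignments, na)
        mask = np.zeros((n_assignments, n), dtype=bool)
        mask[np.arange(n_assignments)[:, None], idx] = True
        av = pooled[idx]
        bv = np.broadcast_to(pooled, mask.shape)[~mask].reshape(n_assignments, n - na)
        null = stat(av, 1) - stat(bv, 1)
        extreme = _count_extreme(null, observed, alternative)
        return PermutationTestResult(
            statistic_name=statistic,
            observed=observed,
            n_permutations=n_assignments,
            mode="exhaustive",
            p_value=extreme / n_assignments,
            alternative=alternative,
        )

    if n_permutations < 100:
        raise UsageError("Monte-Carlo mode needs n_permutations >= 100")
    rng = np.random.default_rng(seed)
    # one random assignment per row: argsort of iid uniforms is a uniform
    # random permutation of the pooled indices
    order = np.argsort(rng.random((n_permutations, n)), axis=1)
    av = pooled[order[:, :na]]
    bv = pooled[order[:, na:]]
    null = stat(av, 1) - stat(bv, 1)
    extreme = _count_extreme(null, observed, alternative)
    return PermutationTestResult(
        statistic_name=statistic,
        observed=observed,
        n_permutations=n_permutations,
        mode="monte_carlo",
        p_value=(1 + extreme) / (n_permutations + 1),
        alternative=alternative,
        seed=seed,
    )
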