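"""Group comparisons for methylation ratios and other per-sample scalars.

Provides the classical one-way ANOVA with Tukey's HSD post-hoc test, and a
two-group permutation test on the mean difference as a distribution-free
alternative better suited to n≈10 ratio comparisons.  The permutation p-value
uses the add-one estimator p = (1 + #{|Δ_perm| >= |Δ_obs|}) / (n_perm + 1),
which is never exactly zero and is valid under the permutation null.
"""

from __future__ import annotations

import enum
import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DegenerateDataError, UsageError

__all__ = [
    "Method",
    "GroupComparison",
    "one_way_anova",
    "tukey_hsd",
    "permutation_test",
    "arcsine_sqrt",
]


class Method(enum.Enum):
    ANOVA = "anova"
    TUKEY = "tukey"
    PERMUTATION = "permutation"


@dataclass(frozen=True)
class GroupComparison:
    """Result of one comparison: the statistic, its p-value, and context."""

    statistic: float
    p_value: float
    method: Method
    group_labels: tuple[str, ...]
    n_per_group: tuple[int, ...]
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise UsageError(f"p-value {self.p_value} outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def as_dict(self) -> dict:
        return {
            "comparison": " vs ".join(self.group_labels),
            "method": self.method.value,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "significant_at_alpha": self.significant,
            "alpha": self.alpha,
        }


def _check_groups(groups: Sequence[Sequence[float]], min_groups: int = 2) -> list[np.ndarray]:
    if len(groups) < min_groups:
        raise UsageError(f"need at least {min_groups} groups")
    arrays = []
    for k, g in enumerate(groups):
        a = np.asarray(g, dtype=float)
        if a.size < 2:
            raise UsageError(f"group {k} has fewer than 2 observations")
        if not np.all(np.isfinite(a)):
            raise UsageError(f"group {k} contains non-finite values")
        arrays.append(a)
    return arrays


def arcsine_sqrt(x: Sequence[float]) -> np.ndarray:
    """Variance-stabilising transform for proportions: asin(sqrt(x))."""
    a = np.asarray(x, dtype=float)
    if np.any(a < 0) or np.any(a > 1):
        raise UsageError("arcsine_sqrt requires values in [0, 1]")
    return np.arcsin(np.sqrt(a))


def one_way_anova(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> GroupComparison:
    """Classical one-way ANOVA F test across k groups."""
    arrays = _check_groups(groups)
    pooled = np.concatenate(arrays)
    grand = pooled.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ss_between == 0.0 and ss_within == 0.0:
        raise DegenerateDataError("all observations identical; F undefined")
    f_stat, p = sps.f_oneway(*arrays)
    if ss_between == 0.0:
        # identical group means: scipy returns 0/…, make the limit explicit
        f_stat, p = 0.0, 1.0
    labels = tuple(labels) if labels else tuple(f"group{k + 1}" for k in range(len(arrays)))
    return GroupComparison(
        statistic=float(f_stat),
        p_value=float(p),
        method=Method.ANOVA,
        group_labels=labels,
        n_per_group=tuple(a.size for a in arrays),
        alpha=alpha,
    )


def tukey_hsd(
    groups: Sequence[Sequence[float]],
    labels: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> list[GroupComparison]:
    """Tukey's HSD pairwise comparisons (studentized-range adjusted).

    For two groups the adjustment is vacuous; defer to :func:`one_way_anova`.
    """
    arrays = _check_groups(groups, min_groups=3)
    if all(((a - a.mean()) ** 2).sum() == 0.0 for a in arrays) and all(
        a.mean() == arrays[0].mean() for a in arrays
    ):
        raise DegenerateDataError("all observations identical; q undefined")
    labels = tuple(labels) if labels else tuple(f"group{k + 1}" for k in range(len(arrays)))
    res = sps.tukey_hsd(*arrays)
    out = []
    for i, j in itertools.combinations(range(len(arrays)), 2):
        out.append(
            GroupComparison(
                statistic=float(res.statistic[i, j]),
                p_value=float(min(1.0, res.pvalue[i, j])),
                method=Method.TUKEY,
                group_labels=(labels[i], labels[j]),
                n_per_group=(arrays[i].size, arrays[j].size),
                alpha=alpha,
            )
        )
    return out


def permutation_test(
    a: Sequence[float],
    b: Sequence[float],
    n_perm: int = 9999,
    seed: int | None = None,
    labels: tuple[str, str] = ("a", "b"),
    alpha: float = 0.05,
    exact: bool | None = None,
) -> GroupComparison:
    """Two-sided permutation test on the difference of group means.

    Monte Carlo: p = (1 + #{|Δ_perm| >= |Δ_obs|}) / (n_perm + 1), with group
    labels permuted uniformly at random; seeded and reproducible.  When the
    number of distinct splits is at most ``n_perm`` (or ``exact=True``) all
    splits are enumerated and the exact p-value is returned without the
    add-one correction.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise UsageError("both groups must be non-empty")
    if n_perm < 99:
        raise UsageError("n_perm must be >= 99")
    # Work with the sorted pool and always resample the smaller group: the
    # procedure is then symmetric in the two labels, so swapping a and b (at
    # the same seed) gives an identical p-value.
    pooled = np.sort(np.concatenate([x, y]))
    n_sel, n_rest = min(x.size, y.size), max(x.size, y.size)
    observed = x.mean() - y.mean()
    total = pooled.sum()
    n_splits = math.comb(pooled.size, n_sel)
    if exact is None:
        exact = n_splits <= n_perm
    if exact:
        sum_sel = np.fromiter(
            (sum(c) for c in itertools.combinations(pooled, n_sel)),
            dtype=float,
            count=n_splits,
        )
        deltas = sum_sel / n_sel - (total - sum_sel) / n_rest
        p = np.sum(np.abs(deltas) >= abs(observed) - 1e-12) / n_splits
    else:
        rng = np.random.default_rng(seed)
        # vectorised label shuffles: argsort of uniforms gives random permutations
        u = rng.random((n_perm, pooled.size))
        idx = np.argsort(u, axis=1)
        # mean difference via totals avoids allocating the complement slice
        sum_sel = pooled[idx[:, :n_sel]].sum(axis=1)
        deltas = sum_sel / n_sel - (total - sum_sel) / n_rest
        exceed = int(np.sum(np.abs(deltas) >= abs(observed) - 1e-12))
        p = (1 + exceed) / (n_perm + 1)
    return GroupComparison(
        statistic=float(observed),
        p_value=float(p),
        method=Method.PERMUTATION,
        group_labels=labels,
        n_per_group=(x.size, y.size),
        alpha=alpha,
    )
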