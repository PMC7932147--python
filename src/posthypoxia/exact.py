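"""Exact small-sample two-group inference.

This module implements the inferential core of the screening pipeline:

* :func:`exact_perm_test` — a fully enumerated two-sample permutation test.
  All ``C(n1+n2, n_trt)`` reassignments of the group labels are evaluated and
  the p-value is returned as an exact rational ``k/N`` (the observed
  assignment is always counted, so ``p > 0``).
* :func:`min_attainable_p` — the floor of that p-value, i.e. the smallest
  value any dataset of the given group sizes can attain.  With five animals
  per group and a two-sided test the floor is ``2/252``, rendered ``0.008``.
* :func:`is_complete_separation` — the "no overlap between groups" criterion.
  For a rank-sum statistic (any group sizes) and for a mean-difference
  statistic with equal group sizes, attaining the two-sided floor is
  equivalent to complete separation on tie-free data; the screen uses the
  separation flag directly as its primary-hit criterion.
* :func:`mann_whitney_exact` — exact Mann-Whitney U (scipy's exact null for
  tie-free samples up to a combined n of 20; midrank permutation enumeration
  when ties are present; normal approximation with tie correction otherwise).
* :func:`bh_adjust` — Benjamini-Hochberg step-up FDR control.

Two-sided p-values are defined symmetrically: an assignment is "as or more
extreme" when its statistic is at least as far from the statistic's exact
null expectation as the observed one.  For the mean difference the null
expectation is 0; for the rank sum it is ``n_trt (N+1)/2``.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "DEFAULT_MAX_SPLITS",
    "PermutationResult",
    "SeparationResult",
    "MannWhitneyResult",
    "BHResult",
    "EnumerationCapError",
    "min_attainable_p",
    "exact_perm_test",
    "is_complete_separation",
    "mann_whitney_exact",
    "bh_adjust",
    "render_p",
]

logger = logging.getLogger(__name__)

#: Default cap on the number of enumerated label assignments.
DEFAULT_MAX_SPLITS = 10_000_000

_STATISTICS = ("mean_diff", "rank_sum")
_SIDES = ("one", "two")


class EnumerationCapError(ValueError):
    """Raised when full enumeration would exceed the configured cap."""


def render_p(p: float | Fraction) -> str:
    """Three-decimal rendering used in printed tables (2/252 -> ``'0.008'``)."""
    return f"{float(p):.3f}"


def _as_values(name: str, values: Sequence[float]) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-d sequence of values")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


def min_attainable_p(
    n1: int, n2: int, sided: str = "two", statistic: str = "mean_diff"
) -> Fraction:
    """Smallest exact permutation p-value attainable at the given group sizes.

    One-sided tests can attain ``1/C(n1+n2, n1)``.  Two-sided tests with equal
    group sizes attain ``2/C(2n, n)`` because the mirror assignment is exactly
    as extreme.  With unequal sizes the two statistics differ: the rank-sum
    null is symmetric about its expectation for any sizes, so the mirror
    assignment always ties and the floor stays ``2/C``; for a mean-difference
    statistic the mirror's magnitude generically differs and a single
    assignment can be uniquely extreme, giving ``1/C``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    if sided not in _SIDES:
        raise ValueError(f"sided must be one of {_SIDES}")
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    n_splits = math.comb(n1 + n2, n1)
    if sided == "one":
        return Fraction(1, n_splits)
    if n1 == n2 or statistic == "rank_sum":
        return Fraction(2, n_splits)
    return Fraction(1, n_splits)


@dataclass(frozen=True)
class PermutationResult:
    """Exact permutation p-value with its enumeration bookkeeping."""

    p: Fraction
    n_extreme: int
    n_splits: int
    observed: float
    statistic: str
    sided: str

    @property
    def pvalue(self) -> float:
        return float(self.p)

    @property
    def rendered(self) -> str:
        return render_p(self.p)

    def __float__(self) -> float:
        return float(self.p)


def _iter_subset_sums(values: np.ndarray, k: int, chunk: int = 131_072):
    """Yield subset sums over all k-of-N index combinations, in chunks."""
    n = values.size
    combos = itertools.combinations(range(n), k)
    while True:
        block = list(itertools.islice(combos, chunk))
        if not block:
            return
        idx = np.asarray(block, dtype=np.intp)
        yield values[idx].sum(axis=1)


def exact_perm_test(
    ctrl: Sequence[float],
    trt: Sequence[float],
    statistic: str = "mean_diff",
    sided: str = "two",
    max_splits: int = DEFAULT_MAX_SPLITS,
) -> PermutationResult:
    """Fully enumerated two-sample permutation test.

    Both the mean-difference and the rank-sum statistic are monotone in the
    treated-group subset sum (of raw values resp. midranks), so extremeness is
    evaluated on subset sums, which keeps the enumeration exact and fast.

    Parameters
    ----------
    ctrl, trt
        The two groups of observed values (control and treated).
    statistic
        ``"mean_diff"`` (difference of group means, the default) or
        ``"rank_sum"`` (Wilcoxon rank sum of the treated group, midranks).
    sided
        ``"two"`` (symmetric around the null expectation) or ``"one"``
        (treated larger).
    max_splits
        Refuse to enumerate more than this many assignments.  Monte-Carlo
        approximation is deliberately not provided; reduce the group sizes or
        raise the cap instead.

    Returns
    -------
    PermutationResult
        ``p`` is the exact rational ``n_extreme / n_splits``; the observed
        assignment is always counted, so ``p >= 1/n_splits``.
    """
    c = _as_values("ctrl", ctrl)
    t = _as_values("trt", trt)
    if statistic not in _STATISTICS:
        raise ValueError(f"statistic must be one of {_STATISTICS}")
    if sided not in _SIDES:
        raise ValueError(f"sided must be one of {_SIDES}")

    n_c, n_t = c.size, t.size
    n = n_c + n_t
    n_splits = math.comb(n, n_t)
    if n_splits > max_splits:
        raise EnumerationCapError(
            f"full enumeration needs {n_splits} assignments, above the cap of "
            f"{max_splits}; Monte-Carlo approximation is out of scope — reduce "
            f"group sizes or raise max_splits"
        )

    pooled = np.concatenate([c, t])
    vals = stats.rankdata(pooled) if statistic == "rank_sum" else pooled
    center = n_t * vals.mean()  # exact null expectation of the subset sum
    obs_sum = float(vals[n_c:].sum())
    obs_dev = obs_sum - center
    # subset sums of ranks/values are exact up to fp roundoff; tolerate it
    tol = 1e-9 * max(1.0, float(np.abs(vals).sum()))

    if statistic == "mean_diff":
        observed = float(t.mean() - c.mean())
    else:
        observed = obs_sum

    n_extreme = 0
    for sums in _iter_subset_sums(vals, n_t):
        if sided == "two":
            n_extreme += int(np.count_nonzero(np.abs(sums - center) >= abs(obs_dev) - tol))
        else:
            n_extreme += int(np.count_nonzero(sums >= obs_sum - tol))

    return PermutationResult(
        p=Fraction(n_extreme, n_splits),
        n_extreme=n_extreme,
        n_splits=n_splits,
        observed=observed,
        statistic=statistic,
        sided=sided,
    )


@dataclass(frozen=True)
class SeparationResult:
    """Complete-separation flag with the direction of the treated group."""

    separated: bool
    direction: str | None  # "up", "down", or None

    def __bool__(self) -> bool:
        return self.separated


def is_complete_separation(
    ctrl: Sequence[float], trt: Sequence[float]
) -> SeparationResult:
    """No-overlap criterion between two groups.

    Returns ``(True, "up")`` when every treated value exceeds every control
    value, ``(True, "down")`` for the mirror case, and ``(False, None)``
    otherwise.  Cross-group ties break separation (conservative).
    """
    c = _as_values("ctrl", ctrl)
    t = _as_values("trt", trt)
    if t.min() > c.max():
        return SeparationResult(True, "up")
    if t.max() < c.min():
        return SeparationResult(True, "down")
    return SeparationResult(False, None)


@dataclass(frozen=True)
class MannWhitneyResult:
    u: float
    p: float
    method: str


def mann_whitney_exact(
    x: Sequence[float],
    y: Sequence[float],
    max_splits: int = DEFAULT_MAX_SPLITS,
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test with an exact small-sample null.

    Tie-free samples with combined n <= 20 use the exact U null distribution.
    Tied samples small enough to enumerate use the exact midrank permutation
    p-value (the exact distribution of U over relabelings of the tied data).
    Anything larger falls back to the normal approximation with tie
    correction.  The chosen method is recorded on the result and logged.
    """
    xa = _as_values("x", x)
    ya = _as_values("y", y)
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    n = pooled.size

    if not has_ties and n <= 20:
        res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method="exact")
        method = "exact"
        u, p = float(res.statistic), float(res.pvalue)
    elif math.comb(n, xa.size) <= max_splits:
        # exact permutation over midranks; U is computed from the rank sum
        perm = exact_perm_test(ya, xa, statistic="rank_sum", sided="two",
                               max_splits=max_splits)
        w_x = perm.observed
        u = float(w_x - xa.size * (xa.size + 1) / 2.0)
        p = float(perm.p)
        method = "exact-midrank-permutation"
    else:
        res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method="asymptotic")
        method = "asymptotic"
        u, p = float(res.statistic), float(res.pvalue)

    logger.debug("mann_whitney_exact: n=(%d,%d) ties=%s method=%s p=%.6g",
                 xa.size, ya.size, has_ties, method, p)
    return MannWhitneyResult(u=u, p=min(p, 1.0), method=method)


@dataclass(frozen=True)
class BHResult:
    """Benjamini-Hochberg decisions and monotone adjusted p-values."""

    significant: np.ndarray  # bool, in input order
    adjusted: np.ndarray  # float, in input order
    q: float


def bh_adjust(pvals: Sequence[float], q: float = 0.1) -> BHResult:
    """Benjamini-Hochberg step-up procedure at target FDR ``q``.

    Flags the hypotheses rejected at level ``q`` and returns the usual
    monotone adjusted p-values; ``m`` is the number of p-values supplied (the
    screen applies this within one tissue across the full panel).
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-d sequence")
    if not (0.0 < q < 1.0):
        raise ValueError("q must lie in (0, 1)")
    if np.any(~np.isfinite(p)) or np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    reject, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return BHResult(significant=reject, adjusted=adjusted, q=q)
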