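"""Retinal layer-thickness derivations and group statistics.

Covers the structural side of the study: OCT layer thicknesses per eye
(total retinal thickness TRT, ganglion cell complex GCC, the derived
INL-to-RPE layer ``TRT - GCC``, photoreceptor IS/OS), group summaries as
mean +/- SEM, paired baseline-vs-posthypoxia t-tests, one-way ANOVA with
Tukey(-Kramer) post-hoc comparisons (also reconstructable from printed
mean/SEM/n summaries), two-way ANOVA for per-layer cell counts, and Pearson
correlation.  The statistical unit is the eye for OCT and the animal for
histology; the unit is always an explicit column, never inferred.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "PairedTResult",
    "AnovaResult",
    "derive_inl_to_rpe",
    "group_summary",
    "group_delta",
    "paired_t",
    "anova_tukey",
    "anova_tukey_from_summary",
    "two_way_anova",
    "pearson_corr",
    "validate_oct_table",
    "RetinalThicknessStudy",
    "RetinalThicknessResults",
    "OCT_LAYERS",
]

OCT_LAYERS = ("TRT", "GCC", "INL_to_RPE", "ISOS")


# ---------------------------------------------------------------------------
# layer derivation and summaries


def derive_inl_to_rpe(trt: float, gcc: float) -> float:
    """Derived inner-nuclear-layer-to-RPE thickness: ``TRT - GCC`` (μm).

    Requires ``0 < GCC < TRT``; the three layers then conserve
    ``GCC + INL_to_RPE = TRT`` exactly.
    """
    trt_a = np.asarray(trt, dtype=float)
    gcc_a = np.asarray(gcc, dtype=float)
    if np.any(gcc_a <= 0) or np.any(gcc_a >= trt_a):
        raise ValueError("requires 0 < GCC < TRT for every measurement")
    out = trt_a - gcc_a
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GroupSummary:
    """(mean, SEM, n) reporting triple; SEM uses the n-1 sample SD."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.sem < 0:
            raise ValueError("SEM must be >= 0")

    @property
    def sd(self) -> float:
        return self.sem * math.sqrt(self.n)


def group_summary(values: Sequence[float]) -> GroupSummary:
    """Mean, SEM (sample SD / sqrt(n)) and n of a list of raw values."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("values must be non-empty")
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return GroupSummary(mean=float(arr.mean()), sem=sd / math.sqrt(arr.size), n=int(arr.size))


def group_delta(a: GroupSummary, b: GroupSummary) -> tuple[float, float]:
    """Difference of group means ``b - a`` and its percent change vs ``a``."""
    if a.mean == 0:
        raise ValueError("reference group mean is zero; percent change undefined")
    delta = b.mean - a.mean
    return delta, 100.0 * delta / a.mean


# ---------------------------------------------------------------------------
# paired and group tests


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_diff: float
    df: int
    degenerate: bool = False
    note: str = ""


def paired_t(
    pre: Sequence[float],
    post: Sequence[float],
    pairing: Sequence | None = None,
) -> PairedTResult:
    """Classical paired t-test on ``post - pre`` differences.

    ``pairing`` (e.g. eye IDs) aligns the two lists; both must then contain
    exactly the same IDs.  Positive mean difference means post > pre.
    Zero-variance nonzero differences are reported as degenerate with the
    direction preserved (p set to 0).
    """
    pre_a = np.asarray(pre, dtype=float)
    post_a = np.asarray(post, dtype=float)
    if pre_a.size != post_a.size or pre_a.size < 2:
        raise ValueError("pre and post must have equal length >= 2")
    if pairing is not None:
        ids_pre = list(pairing)
        if len(ids_pre) != pre_a.size:
            raise ValueError("pairing must have one ID per observation")
        if len(set(ids_pre)) != len(ids_pre):
            raise ValueError("pairing IDs must be unique")

    d = post_a - pre_a
    mean_d = float(d.mean())
    df = d.size - 1
    if float(d.std(ddof=1)) == 0.0:
        if mean_d == 0.0:
            return PairedTResult(t=0.0, p=1.0, mean_diff=0.0, df=df)
        return PairedTResult(
            t=math.copysign(math.inf, mean_d), p=0.0, mean_diff=mean_d, df=df,
            degenerate=True,
            note="degenerate: zero variance, direction reported",
        )
    res = stats.ttest_rel(post_a, pre_a)
    return PairedTResult(t=float(res.statistic), p=float(res.pvalue),
                         mean_diff=mean_d, df=df)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    tukey: pd.DataFrame  # columns: group_a, group_b, diff, p
    degenerate: bool = False


def _tukey_table(
    means: np.ndarray, ns: np.ndarray, msw: float, labels: list[str]
) -> pd.DataFrame:
    """Tukey-Kramer pairwise p-values via the studentized range distribution."""
    k = len(means)
    df_w = int(ns.sum() - k)
    rows = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[j] - means[i]
        if msw == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            se = math.sqrt(msw / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
            q = abs(diff) / se
            p = float(stats.studentized_range.sf(q, k, df_w))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "diff": float(diff), "p": p})
    return pd.DataFrame(rows)


def _anova_from_moments(
    means: np.ndarray, sds: np.ndarray, ns: np.ndarray, labels: list[str]
) -> AnovaResult:
    k = len(means)
    n_tot = int(ns.sum())
    grand = float(np.sum(ns * means) / n_tot)
    msb = float(np.sum(ns * (means - grand) ** 2) / (k - 1))
    df_w = n_tot - k
    msw = float(np.sum((ns - 1) * sds**2) / df_w)
    if msw == 0.0:
        if msb == 0.0:
            # all data identical: no variation anywhere
            return AnovaResult(F=0.0, p=1.0,
                               tukey=_tukey_table(means, ns, 0.0, labels),
                               degenerate=True)
        return AnovaResult(F=math.inf, p=0.0,
                           tukey=_tukey_table(means, ns, 0.0, labels),
                           degenerate=True)
    F = msb / msw
    p = float(stats.f.sf(F, k - 1, df_w))
    return AnovaResult(F=F, p=p, tukey=_tukey_table(means, ns, msw, labels))


def anova_tukey(
    groups: Sequence[Sequence[float]], labels: Sequence[str] | None = None
) -> AnovaResult:
    """One-way ANOVA with Tukey HSD post-hoc comparisons on raw values.

    Unequal group sizes use the Tukey-Kramer generalization.  Identical
    groups give F = 0 and all pairwise p = 1; zero within-group variance with
    distinct means is reported as degenerate (F = inf).
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs n >= 2")
    labels = list(labels) if labels is not None else [f"group{i+1}" for i in range(len(arrays))]
    means = np.array([a.mean() for a in arrays])
    sds = np.array([a.std(ddof=1) for a in arrays])
    ns = np.array([a.size for a in arrays])
    result = _anova_from_moments(means, sds, ns, labels)

    # cross-check the omnibus F against scipy on the non-degenerate path
    if not result.degenerate:
        f_ref = stats.f_oneway(*arrays)
        assert np.isclose(result.F, f_ref.statistic, rtol=1e-6, atol=1e-12)
    return result


def anova_tukey_from_summary(
    summaries: Sequence[GroupSummary], labels: Sequence[str] | None = None
) -> AnovaResult:
    """One-way ANOVA + Tukey reconstructed from (mean, SEM, n) summaries.

    Group SDs are recovered from the SEMs, pooled into the within-group mean
    square, and the test proceeds exactly as :func:`anova_tukey`; built from
    the summaries of raw groups it reproduces the raw-data result.
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 group summaries")
    if any(s.n < 2 for s in summaries):
        raise ValueError("each summary needs n >= 2")
    labels = list(labels) if labels is not None else [f"group{i+1}" for i in range(len(summaries))]
    means = np.array([s.mean for s in summaries], dtype=float)
    sds = np.array([s.sd for s in summaries], dtype=float)
    ns = np.array([s.n for s in summaries], dtype=int)
    return _anova_from_moments(means, sds, ns, labels)


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
) -> pd.DataFrame:
    """Two-way ANOVA with interaction, type-II sums of squares.

    The layout must be complete (every factor-level combination observed).
    Returns the statsmodels ANOVA table with an extra boolean attribute-free
    ``degenerate`` column flagging rows whose F is undefined (e.g. all-zero
    counts); such F values are reported as 0.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (response, factor_a, factor_b):
        if col not in table.columns:
            raise ValueError(f"column {col!r} missing from table")
    counts = table.groupby([factor_a, factor_b], observed=True).size()
    levels_a = table[factor_a].nunique()
    levels_b = table[factor_b].nunique()
    if len(counts) < levels_a * levels_b:
        raise ValueError("incomplete two-factor layout: empty cells present")

    data = table.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    with np.errstate(invalid="ignore", divide="ignore"):
        anova = sm.stats.anova_lm(model, typ=2)
    degenerate = ~np.isfinite(anova["F"])
    anova["F"] = anova["F"].where(~degenerate, 0.0)
    anova["PR(>F)"] = anova["PR(>F)"].where(~degenerate, 1.0)
    anova["degenerate"] = degenerate
    return anova


def pearson_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson r with its two-sided t-based p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size or xa.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if xa.std() == 0 or ya.std() == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    r, p = stats.pearsonr(xa, ya)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# OCT table handling and the thickness study object


def validate_oct_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a per-eye OCT thickness table and (re)derive INL-to-RPE.

    Expected columns: ``animal``, ``eye``, ``group``, ``timepoint``
    (``baseline`` or ``posthypoxia``), ``TRT``, ``GCC``, ``ISOS`` in μm.
    ``INL_to_RPE`` is always recomputed as ``TRT - GCC``.
    """
    required = ["animal", "eye", "group", "timepoint", "TRT", "GCC", "ISOS"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"OCT table is missing columns {missing}")
    out = df.copy()
    out["INL_to_RPE"] = derive_inl_to_rpe(
        out["TRT"].to_numpy(float), out["GCC"].to_numpy(float)
    )
    return out


class RetinalThicknessStudy:
    """Paired baseline/posthypoxia OCT thickness study per group.

    ``fit()`` produces, per group and layer: baseline and posthypoxia group
    summaries (mean, SEM, n of eyes), the paired t-test across eyes, the
    between-group delta and percent change, and a cross-group Tukey
    comparison of posthypoxia values per layer.
    """

    def __init__(self, table: pd.DataFrame, layers: Sequence[str] = OCT_LAYERS) -> None:
        self.table = validate_oct_table(table)
        self.layers = list(layers)

    def fit(self) -> "RetinalThicknessResults":
        df = self.table
        groups = [g for g in df["group"].unique()]
        rows = []
        for grp in groups:
            sub = df[df["group"] == grp]
            base = sub[sub["timepoint"] == "baseline"].set_index("eye")
            post = sub[sub["timepoint"] == "posthypoxia"].set_index("eye")
            common = base.index.intersection(post.index)
            for layer in self.layers:
                s_base = group_summary(base.loc[common, layer])
                s_post = group_summary(post.loc[common, layer])
                pt = paired_t(base.loc[common, layer], post.loc[common, layer],
                              pairing=list(common))
                delta, pct = group_delta(s_base, s_post)
                rows.append({
                    "group": grp, "layer": layer,
                    "baseline_mean": s_base.mean, "baseline_sem": s_base.sem,
                    "post_mean": s_post.mean, "post_sem": s_post.sem,
                    "n": s_base.n, "paired_t": pt.t, "paired_p": pt.p,
                    "delta": delta, "pct_change": pct,
                })
        layer_table = pd.DataFrame(rows)

        tukey = {}
        post = df[df["timepoint"] == "posthypoxia"]
        if post["group"].nunique() >= 2:
            for layer in self.layers:
                grouped = [post.loc[post["group"] == g, layer].to_numpy(float)
                           for g in groups]
                if all(len(g) >= 2 for g in grouped):
                    tukey[layer] = anova_tukey(grouped, labels=groups)
        return RetinalThicknessResults(self, layer_table, tukey)


class RetinalThicknessResults:
    def __init__(self, model: RetinalThicknessStudy,
                 layer_table: pd.DataFrame, tukey: dict[str, AnovaResult]) -> None:
        self.model = model
        self.layer_table = layer_table
        self.tukey = tukey

    def summary(self) -> str:
        """Printed-table-shaped report: Mean, SEM, n, paired p, Δ, %change."""
        lines = [
            f"{'group':<9}{'layer':<12}{'base':>7}{'SEM':>6}{'post':>8}{'SEM':>6}"
            f"{'n':>4}{'paired p':>10}{'Δ':>7}{'%chg':>7}"
        ]
        for _, r in self.layer_table.iterrows():
            lines.append(
                f"{r['group']:<9}{r['layer']:<12}{r['baseline_mean']:>7.1f}"
                f"{r['baseline_sem']:>6.1f}{r['post_mean']:>8.1f}{r['post_sem']:>6.1f}"
                f"{int(r['n']):>4}{r['paired_p']:>10.4f}{r['delta']:>7.1f}"
                f"{r['pct_change']:>7.1f}"
            )
        for layer, res in self.tukey.items():
            pairs = "; ".join(
                f"{t.group_a} vs {t.group_b}: p={t.p:.4f}"
                for t in res.tukey.itertuples()
            )
            lines.append(f"Tukey (posthypoxia {layer}): F={res.F:.3f} p={res.p:.4f} | {pairs}")
        return "\n".join(lines)
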