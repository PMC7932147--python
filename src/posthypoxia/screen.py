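"""Panel-wide screening model: exact permutation screen with FDR follow-up.

:class:`ImmuneScreen` is the modelling object for one tissue and one treated
group.  ``fit()`` runs, per analyte: ratio-to-control, the fully enumerated
permutation test, the complete-separation flag, the exact Mann-Whitney test
and Benjamini-Hochberg FDR control across the panel.  The resulting
:class:`ImmuneScreenResults` carries the per-analyte table, the primary hit
set (complete separation, i.e. the smallest attainable permutation p-value)
and the secondary hit set (BH-significant Mann-Whitney analytes that are not
primary hits), plus a printable ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .exact import (
    DEFAULT_MAX_SPLITS,
    bh_adjust,
    exact_perm_test,
    is_complete_separation,
    mann_whitney_exact,
    min_attainable_p,
    render_p,
)
from .preprocess import NormalizedMatrix

__all__ = ["ScreenResult", "ImmuneScreen", "ImmuneScreenResults", "run_screen", "venn_partition"]


@dataclass(frozen=True)
class ScreenResult:
    """Per-analyte screening record."""

    analyte: str
    tissue: str
    ratio: float
    perm_p: Fraction
    min_p: Fraction
    separation: bool
    direction: str | None
    mw_u: float
    mw_p: float
    mw_method: str
    bh_adjusted: float
    bh_significant: bool


class ImmuneScreen:
    """Exact two-group screen of a normalized sample x analyte matrix.

    Parameters
    ----------
    matrix
        Normalized matrix with ``group`` metadata containing both ``group``
        and ``control`` samples.
    group
        Treated group label to compare against control.
    statistic, sided
        Permutation-test statistic (``"mean_diff"`` default, or
        ``"rank_sum"``) and sidedness (``"two"`` default).
    q
        Target false discovery rate of the BH follow-up screen (default 0.1).
    """

    def __init__(
        self,
        matrix: NormalizedMatrix,
        group: str,
        control: str = "control",
        statistic: str = "mean_diff",
        sided: str = "two",
        q: float = 0.1,
        max_splits: int = DEFAULT_MAX_SPLITS,
    ) -> None:
        self.matrix = matrix
        self.group = group
        self.control = control
        self.statistic = statistic
        self.sided = sided
        self.q = q
        self.max_splits = max_splits
        for g in (group, control):
            if not (matrix.meta["group"] == g).any():
                raise ValueError(f"group {g!r} has no samples in the matrix")

    @classmethod
    def from_dataframe(
        cls,
        values: pd.DataFrame,
        groups: Sequence[str] | pd.Series,
        group: str,
        tissue: str = "plasma",
        **kwargs,
    ) -> "ImmuneScreen":
        """Build a screen directly from a sample x analyte DataFrame."""
        meta = pd.DataFrame(
            {"group": list(groups), "tissue": tissue}, index=values.index
        )
        matrix = NormalizedMatrix(values=values, meta=meta, normalized=True)
        return cls(matrix, group=group, **kwargs)

    def fit(self) -> "ImmuneScreenResults":
        m = self.matrix
        tissue = str(m.meta["tissue"].iloc[0]) if "tissue" in m.meta else ""
        ctrl_mask = (m.meta["group"] == self.control).to_numpy()
        trt_mask = (m.meta["group"] == self.group).to_numpy()
        values = m.values.to_numpy(dtype=float)

        n1, n2 = int(ctrl_mask.sum()), int(trt_mask.sum())
        floor = min_attainable_p(n1, n2, self.sided, self.statistic)

        records: list[dict] = []
        for j, analyte in enumerate(m.analytes):
            ctrl = values[ctrl_mask, j]
            trt = values[trt_mask, j]
            ratio = float(trt.mean() / ctrl.mean())
            perm = exact_perm_test(ctrl, trt, self.statistic, self.sided,
                                   max_splits=self.max_splits)
            sep = is_complete_separation(ctrl, trt)
            mw = mann_whitney_exact(trt, ctrl, max_splits=self.max_splits)
            records.append({
                "analyte": analyte,
                "tissue": tissue,
                "ratio": ratio,
                "perm_p": perm.p,
                "min_p": floor,
                "separation": sep.separated,
                "direction": sep.direction,
                "mw_u": mw.u,
                "mw_p": mw.p,
                "mw_method": mw.method,
            })

        bh = bh_adjust([r["mw_p"] for r in records], q=self.q)
        results = [
            ScreenResult(
                bh_adjusted=float(bh.adjusted[i]),
                bh_significant=bool(bh.significant[i]),
                **records[i],
            )
            for i in range(len(records))
        ]
        return ImmuneScreenResults(model=self, results=results)


class ImmuneScreenResults:
    """Fitted screen: per-analyte records, hit sets and a summary table."""

    def __init__(self, model: ImmuneScreen, results: list[ScreenResult]) -> None:
        self.model = model
        self.results = results

    @property
    def table(self) -> pd.DataFrame:
        df = pd.DataFrame([r.__dict__ for r in self.results])
        df["perm_p_float"] = df["perm_p"].map(float)
        return df

    @property
    def primary_hits(self) -> set[str]:
        """Analytes with complete separation (permutation p at its floor)."""
        return {r.analyte for r in self.results if r.separation}

    @property
    def secondary_hits(self) -> set[str]:
        """BH-significant Mann-Whitney analytes that are not primary hits."""
        return {
            r.analyte
            for r in self.results
            if r.bh_significant and not r.separation
        }

    def hit_table(self) -> pd.DataFrame:
        """Primary hits sorted by descending ratio (printed-table layout)."""
        df = self.table
        hits = df[df["separation"]].sort_values(
            ["ratio", "analyte"], ascending=[False, True]
        )
        return hits[["analyte", "ratio", "perm_p_float"]].reset_index(drop=True)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"Immune screen: {m.group} vs {m.control} "
            f"({self.results[0].tissue}, statistic={m.statistic}, "
            f"sided={m.sided}, q={m.q})",
            f"analytes tested: {len(self.results)}; attainable floor "
            f"p = {self.results[0].min_p} ({render_p(self.results[0].min_p)})",
            "",
            f"{'analyte':<12}{'ratio':>8}  {'perm p':>7}  {'sep':>4}  "
            f"{'MW p':>8}  {'BH':>3}",
        ]
        order = sorted(self.results, key=lambda r: (-r.ratio, r.analyte))
        for r in order:
            if not (r.separation or r.bh_significant):
                continue
            lines.append(
                f"{r.analyte:<12}{r.ratio:>8.3f}  {render_p(r.perm_p):>7}  "
                f"{'yes' if r.separation else 'no':>4}  {r.mw_p:>8.4f}  "
                f"{'*' if r.bh_significant else '':>3}"
            )
        lines.append("")
        lines.append(
            f"primary hits (complete separation): {len(self.primary_hits)}; "
            f"secondary hits (BH-only): {len(self.secondary_hits)}"
        )
        return "\n".join(lines)


def run_screen(
    matrix: NormalizedMatrix,
    group: str,
    statistic: str = "mean_diff",
    sided: str = "two",
    q: float = 0.1,
    max_splits: int = DEFAULT_MAX_SPLITS,
) -> ImmuneScreenResults:
    """Functional entry point: screen ``group`` vs control in ``matrix``."""
    return ImmuneScreen(
        matrix, group=group, statistic=statistic, sided=sided, q=q,
        max_splits=max_splits,
    ).fit()


def venn_partition(
    hits_a: set[str] | Sequence[str], hits_b: set[str] | Sequence[str]
) -> tuple[set[str], set[str], set[str]]:
    """Disjoint partition (only_a, shared, only_b); the union is preserved."""
    a, b = set(hits_a), set(hits_b)
    return a - b, a & b, b - a
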