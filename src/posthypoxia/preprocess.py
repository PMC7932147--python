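"""Duplicate averaging, control-bead normalization and ratio-to-control.

The preprocessing chain mirrors how bead-assay readouts are prepared before
screening: technical duplicate wells are averaged per sample, each sample's
analyte vector is rescaled by its Chex #4 internal-control bead relative to
the plate median (removing per-well multiplicative drift while keeping the
original MFI scale), and group effects are expressed as the ratio of group
mean to control mean per analyte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .plate import CHEX_COLUMNS, LuminexPlate

__all__ = ["NormalizedMatrix", "average_duplicates", "chex_normalize", "ratio_to_control"]

logger = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Sample x analyte MFI matrix with metadata, one row per sample.

    ``values`` is indexed by sample ID with one column per analyte; ``meta``
    carries ``group`` and ``tissue`` per sample; ``chex`` carries the
    (duplicate-averaged) control-bead MFIs.  ``normalized`` records whether
    Chex normalization has been applied.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    chex: pd.DataFrame | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if len(self.values) == 0:
            raise ValueError("matrix has no samples")
        if not self.values.index.is_unique:
            raise ValueError("one row per sample required; duplicate sample IDs found")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)) or not np.all(arr > 0):
            raise ValueError("matrix values must be finite and positive")
        if not self.meta.index.equals(self.values.index):
            raise ValueError("meta index must match values index")

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def groups(self) -> pd.Series:
        return self.meta["group"]

    def group_values(self, group: str, analyte: str) -> np.ndarray:
        mask = self.meta["group"] == group
        if not mask.any():
            raise ValueError(f"no samples in group {group!r}")
        return self.values.loc[mask, analyte].to_numpy(dtype=float)


def average_duplicates(plate: LuminexPlate) -> NormalizedMatrix:
    """Arithmetic mean over duplicate wells, per sample, analytes and Chex alike.

    Samples may carry one or two wells; more than two is an error.
    """
    counts = plate.data.groupby("sample").size()
    bad = counts[counts > 2]
    if len(bad):
        raise ValueError(f"samples with more than 2 wells: {list(bad.index)}")

    num_cols = plate.analytes + list(CHEX_COLUMNS)
    averaged = plate.data.groupby("sample", sort=False)[num_cols].mean()
    meta = (
        plate.data.groupby("sample", sort=False)[["group", "tissue"]]
        .first()
        .loc[averaged.index]
    )
    return NormalizedMatrix(
        values=averaged[plate.analytes],
        meta=meta,
        chex=averaged[list(CHEX_COLUMNS)],
        normalized=False,
    )


def chex_normalize(matrix: NormalizedMatrix, chex_bead: str = "CHEX4") -> NormalizedMatrix:
    """Divide each sample by its Chex #4 value relative to the plate median.

    The scaling factor for sample *i* is ``chex4_i / median(chex4)``, so a
    well-level multiplicative drift that affects analyte and control beads
    alike cancels exactly, while the plate-median rescaling keeps values on
    the original MFI scale.  Requires a positive Chex value for every sample.
    """
    if matrix.chex is None or chex_bead not in matrix.chex.columns:
        raise ValueError(f"control bead {chex_bead!r} not present; cannot normalize")
    chex = matrix.chex[chex_bead].to_numpy(dtype=float)
    if not np.all(np.isfinite(chex)) or not np.all(chex > 0):
        raise ValueError(f"{chex_bead} values must be finite and positive for every sample")
    factor = chex / np.median(chex)
    logger.info("chex_normalize: bead=%s median=%.4g factor range [%.4g, %.4g]",
                chex_bead, float(np.median(chex)), factor.min(), factor.max())
    values = matrix.values.div(factor, axis=0)
    chex_scaled = matrix.chex.div(factor, axis=0)
    return replace(matrix, values=values, chex=chex_scaled, normalized=True)


def ratio_to_control(
    matrix: NormalizedMatrix, group: str, control: str = "control"
) -> pd.Series:
    """Per-analyte ratio of group mean MFI to control mean MFI.

    Arithmetic means of (normalized) MFI are used in both numerator and
    denominator; a group identical to control therefore gives exactly 1.
    """
    for g in (group, control):
        if not (matrix.meta["group"] == g).any():
            raise ValueError(f"group {g!r} has no samples")
    grp_mean = matrix.values[matrix.meta["group"] == group].mean(axis=0)
    ctl_mean = matrix.values[matrix.meta["group"] == control].mean(axis=0)
    if (ctl_mean == 0).any():
        raise ValueError("control mean is zero for at least one analyte")
    ratio = grp_mean / ctl_mean
    ratio.name = f"ratio_{group}_vs_{control}"
    return ratio
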