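"""Tab-separated reading and writing of plates, matrices and screen tables.

All files are plain TSV with a mandatory header row and ``.`` as the decimal
mark, matching exported instrument tables.  Duplicate-averaged supplementary
style tables (one row per sample, no duplicate wells, optionally no control
bead columns) are first-class inputs: each row is treated as a
single-duplicate well and absent control beads are filled with a constant so
normalization is the identity.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import AnalytePanel, DEFAULT_PANEL
from .plate import CHEX_COLUMNS, META_COLUMNS, LuminexPlate

__all__ = [
    "read_plate",
    "write_plate",
    "write_matrix",
    "write_screen_results",
    "read_screen_results",
]

logger = logging.getLogger(__name__)

_SCREEN_COLUMNS = [
    "analyte", "tissue", "ratio", "perm_p", "perm_p_rational", "min_p",
    "separation", "direction", "mw_u", "mw_p", "bh_adjusted", "bh_significant",
]


def read_plate(
    path: str | Path,
    panel: AnalytePanel = DEFAULT_PANEL,
    column_map: Mapping[str, str] | None = None,
    averaged: bool = False,
    tissue: str | None = None,
) -> LuminexPlate:
    """Read a well-level (or duplicate-averaged) plate table.

    Parameters
    ----------
    path
        TSV file with one header row.  Required metadata columns: ``sample``
        and ``group`` (plus ``tissue`` and ``duplicate`` unless supplied via
        ``tissue=`` / ``averaged=True``).  Analyte columns are resolved
        through the panel's alias table; any unresolvable non-metadata column
        is an error naming the column.
    column_map
        Optional renaming applied before interpretation (supports arbitrary
        supplementary-table layouts).
    averaged
        Treat the file as duplicate-averaged: each row becomes a
        single-duplicate well, and missing control-bead columns are filled
        with 1.0 (normalization then degenerates to the identity).
    tissue
        Tissue label to use when the file carries no ``tissue`` column.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if column_map:
        df = df.rename(columns=dict(column_map))

    if "sample" not in df.columns or "group" not in df.columns:
        raise ValueError(f"{path}: required columns 'sample' and 'group' missing")
    if "tissue" not in df.columns:
        if tissue is None:
            raise ValueError(f"{path}: no 'tissue' column and no tissue= given")
        df["tissue"] = tissue
    if "duplicate" not in df.columns:
        if not averaged:
            raise ValueError(
                f"{path}: no 'duplicate' column; pass averaged=True for "
                "duplicate-averaged tables"
            )
        df["duplicate"] = 1

    # resolve analyte columns through the panel aliases
    rename: dict[str, str] = {}
    for col in df.columns:
        if col in META_COLUMNS or col in CHEX_COLUMNS:
            continue
        try:
            rename[col] = panel.resolve(col)
        except KeyError:
            raise ValueError(f"{path}: unknown analyte column {col!r}") from None
    df = df.rename(columns=rename)

    missing = [a for a in panel.names if a not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing analyte columns {missing}")

    for bead in CHEX_COLUMNS:
        if bead not in df.columns:
            if not averaged:
                raise ValueError(f"{path}: missing control-bead column {bead!r}")
            df[bead] = 1.0

    numeric = list(panel.names) + list(CHEX_COLUMNS)
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[df[numeric].isna().any(axis=1) | (df[numeric] <= 0).any(axis=1)]
    if len(bad):
        # +2: header row plus 1-based numbering, as a user sees the file
        rows = [int(i) + 2 for i in bad]
        raise ValueError(f"{path}: non-positive or unparseable MFI at file rows {rows}")

    ordered = df[list(META_COLUMNS) + numeric]
    plate = LuminexPlate(data=ordered.reset_index(drop=True), panel=panel)
    logger.info("read_plate: %s -> %d wells, tissue=%s", path, plate.n_wells, plate.tissue)
    return plate


def write_plate(plate: LuminexPlate, path: str | Path) -> None:
    """Write a plate as TSV (header + one row per well)."""
    path = Path(path)
    plate.data.to_csv(path, sep="\t", index=False)
    logger.info("write_plate: %d wells -> %s", plate.n_wells, path)


def write_matrix(values: pd.DataFrame, meta: pd.DataFrame, path: str | Path) -> None:
    """Write a sample x analyte matrix with its metadata columns first."""
    out = pd.concat([meta, values], axis=1)
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def write_screen_results(results: Sequence, path: str | Path) -> None:
    """Write screen results as a TSV in printed-table layout.

    Rows are sorted by descending ratio within tissue; ties in ratio fall
    back to analyte name so the order is stable.  Exact permutation p-values
    are written both as 3-decimal renderings and as rationals ``k/N``.
    """
    rows = list(results)
    if not rows:
        raise ValueError("no screen results to write")
    records = []
    for r in rows:
        records.append({
            "analyte": r.analyte,
            "tissue": r.tissue,
            "ratio": r.ratio,
            "perm_p": f"{float(r.perm_p):.3f}",
            "perm_p_rational": f"{r.perm_p.numerator}/{r.perm_p.denominator}",
            "min_p": f"{r.min_p.numerator}/{r.min_p.denominator}",
            "separation": r.separation,
            "direction": r.direction if r.direction is not None else "",
            "mw_u": r.mw_u,
            "mw_p": r.mw_p,
            "bh_adjusted": r.bh_adjusted,
            "bh_significant": r.bh_significant,
        })
    df = pd.DataFrame.from_records(records, columns=_SCREEN_COLUMNS)
    df = df.sort_values(
        ["tissue", "ratio", "analyte"], ascending=[True, False, True]
    ).reset_index(drop=True)
    df.to_csv(Path(path), sep="\t", index=False, float_format="%.6g")
    logger.info("write_screen_results: %d rows -> %s", len(df), path)


def read_screen_results(path: str | Path) -> pd.DataFrame:
    """Read back a screen-results TSV (numeric columns parsed)."""
    df = pd.read_csv(Path(path), sep="\t")
    missing = [c for c in _SCREEN_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing screen columns {missing}")
    df["separation"] = df["separation"].astype(bool)
    df["bh_significant"] = df["bh_significant"].astype(bool)
    return df
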