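"""Well-level container for multiplex bead-assay plates.

A :class:`LuminexPlate` holds one row per well: sample identity, experimental
group, tissue, duplicate index, the analyte mean-fluorescence-intensity (MFI)
vector and the four internal-control (Chex) bead MFIs used for quality control
and normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import AnalytePanel, DEFAULT_PANEL

__all__ = [
    "LuminexPlate",
    "META_COLUMNS",
    "CHEX_COLUMNS",
    "GROUPS",
    "TISSUES",
]

META_COLUMNS = ("sample", "group", "tissue", "duplicate")
CHEX_COLUMNS = ("CHEX1", "CHEX2", "CHEX3", "CHEX4")
GROUPS = ("control", "post1h", "post18h")
TISSUES = ("plasma", "retina")


@dataclass
class LuminexPlate:
    """Validated well-level MFI table for one tissue.

    ``data`` must contain the metadata columns ``sample``, ``group``,
    ``tissue``, ``duplicate``, one column per panel analyte and the four
    ``CHEX1``..``CHEX4`` control-bead columns.
    """

    data: pd.DataFrame
    panel: AnalytePanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def analytes(self) -> list[str]:
        return list(self.panel.names)

    @property
    def tissue(self) -> str:
        return str(self.data["tissue"].iloc[0])

    @property
    def n_wells(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> list[str]:
        return list(dict.fromkeys(self.data["sample"]))

    def validate(self) -> None:
        df = self.data
        missing = [c for c in META_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate is missing metadata columns {missing}")
        missing = [c for c in self.panel.names if c not in df.columns]
        if missing:
            raise ValueError(f"plate is missing analyte columns {missing}")
        missing = [c for c in CHEX_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate is missing control-bead columns {missing}")
        if len(df) == 0:
            raise ValueError("plate contains no wells")

        bad_groups = sorted(set(df["group"]) - set(GROUPS))
        if bad_groups:
            raise ValueError(f"unknown group labels {bad_groups}; expected {GROUPS}")
        tissues = sorted(set(df["tissue"]))
        if len(tissues) != 1:
            raise ValueError(f"all wells on a plate must share one tissue, got {tissues}")
        if tissues[0] not in TISSUES:
            raise ValueError(f"unknown tissue {tissues[0]!r}; expected one of {TISSUES}")
        if not df["duplicate"].isin((1, 2)).all():
            raise ValueError("duplicate index must be 1 or 2")

        dup = df.duplicated(subset=["sample", "duplicate"])
        if dup.any():
            rows = list(df.index[dup])
            raise ValueError(f"duplicate (sample, duplicate) pairs at rows {rows}")

        numeric = df[list(self.panel.names) + list(CHEX_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(numeric)):
            bad = df.index[~np.isfinite(numeric).all(axis=1)].tolist()
            raise ValueError(f"non-finite MFI values at rows {bad}")
        if not np.all(numeric > 0):
            bad = df.index[(numeric <= 0).any(axis=1)].tolist()
            raise ValueError(f"non-positive MFI values at rows {bad}")

    # -- convenience -------------------------------------------------------

    def mfi(self) -> pd.DataFrame:
        """Analyte MFI block, indexed like ``data``."""
        return self.data[list(self.panel.names)]

    def chex(self) -> pd.DataFrame:
        """Control-bead MFI block."""
        return self.data[list(CHEX_COLUMNS)]

    def equals(self, other: "LuminexPlate", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Structural and numeric equality, optionally within a tolerance."""
        if self.panel.names != other.panel.names:
            return False
        a, b = self.data.reset_index(drop=True), other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        meta_cols = list(META_COLUMNS)
        if not a[meta_cols].equals(b[meta_cols]):
            return False
        num_cols = list(self.panel.names) + list(CHEX_COLUMNS)
        return bool(
            np.allclose(a[num_cols].to_numpy(float), b[num_cols].to_numpy(float),
                        rtol=rtol, atol=atol)
        )
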