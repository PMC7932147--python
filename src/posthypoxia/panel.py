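"""Analyte panel metadata for the mouse 39-plex bead assay.

The default panel covers the 39 cytokines, chemokines and growth factors of a
mouse ProcartaPlex-style multiplex kit.  Canonical names follow the compact
instrument-export style (``GMCSF.CSF2``, ``IL15.IL15R``); aliases map common
display spellings (``GM-CSF``, ``IL-1β``-free ASCII forms, CCL/CXCL synonyms)
onto the canonical names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["AnalytePanel", "DEFAULT_PANEL", "DEFAULT_ANALYTES"]

#: Canonical names of the default 39-plex panel.
DEFAULT_ANALYTES: tuple[str, ...] = (
    "IL1A", "IL6", "LIF", "RANTES", "MCP1", "IFNA", "GROA", "IL9",
    "MCSF.CSF1", "IL13", "IL31", "IL15.IL15R", "MIP1A", "IL3", "IL4",
    "GMCSF.CSF2", "IFNG", "MIP1B", "GCSF.CSF3", "IL12P70", "MIP2", "IL2",
    "IL27", "IL5", "IL17A", "TNFA", "IL18", "TGFB", "IP10", "VEGF", "IL23",
    "IL22", "IL1B", "IL28", "IL10", "MCP3", "ENA78", "EOTAXIN", "BNGF",
)

_DEFAULT_ALIASES: dict[str, str] = {
    "GMCSF": "GMCSF.CSF2",
    "CSF2": "GMCSF.CSF2",
    "GCSF": "GCSF.CSF3",
    "CSF3": "GCSF.CSF3",
    "MCSF": "MCSF.CSF1",
    "CSF1": "MCSF.CSF1",
    "IL15": "IL15.IL15R",
    "IL15R": "IL15.IL15R",
    "CCL2": "MCP1",
    "CCL3": "MIP1A",
    "CCL4": "MIP1B",
    "CCL5": "RANTES",
    "CCL7": "MCP3",
    "CCL11": "EOTAXIN",
    "CXCL1": "GROA",
    "CXCL2": "MIP2",
    "CXCL5": "ENA78",
    "CXCL10": "IP10",
    "TNF": "TNFA",
    "NGF": "BNGF",
}


def _normalize(name: str) -> str:
    """Canonicalizing key: case, hyphens, underscores and spaces are cosmetic."""
    return name.strip().upper().replace("-", "").replace("_", "").replace(" ", "")


@dataclass(frozen=True)
class AnalytePanel:
    """Ordered analyte identifiers plus display-name aliases.

    Parameters
    ----------
    names
        Ordered, unique, non-empty canonical analyte names.
    aliases
        Mapping from alternative display names to canonical names.  Lookup is
        insensitive to case, hyphens, underscores and spaces.  When omitted,
        the default kit aliases are used for the default panel and no aliases
        for a custom one.
    """

    names: tuple[str, ...] = DEFAULT_ANALYTES
    aliases: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.aliases is None:
            default = _DEFAULT_ALIASES if tuple(self.names) == DEFAULT_ANALYTES else {}
            object.__setattr__(self, "aliases", dict(default))
        if not self.names:
            raise ValueError("panel must contain at least one analyte name")
        if any(not n or not isinstance(n, str) for n in self.names):
            raise ValueError("analyte names must be non-empty strings")
        if len(set(self.names)) != len(self.names):
            raise ValueError("analyte names must be unique")
        lookup: dict[str, str] = {}
        for name in self.names:
            lookup[_normalize(name)] = name
        for alias, target in self.aliases.items():
            if target not in self.names:
                raise ValueError(f"alias {alias!r} points to unknown analyte {target!r}")
            key = _normalize(alias)
            if key in lookup and lookup[key] != target:
                raise ValueError(f"alias {alias!r} is ambiguous")
            lookup[key] = target
        object.__setattr__(self, "_lookup", lookup)

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return _normalize(name) in self._lookup  # type: ignore[attr-defined]

    def resolve(self, name: str) -> str:
        """Return the canonical name for ``name``; raise KeyError if unknown."""
        try:
            return self._lookup[_normalize(name)]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"unknown analyte {name!r}") from None


#: Panel instance for the default 39-plex kit.
DEFAULT_PANEL = AnalytePanel()
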