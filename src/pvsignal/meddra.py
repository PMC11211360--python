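"""Preferred-term to system-organ-class mapping.

A miniature PT->SOC table ships with the package (``data/pt_soc.csv``).  It
covers the terms emitted by the synthetic generator and the common
esketamine-related terms; it is *not* the licensed MedDRA dictionary.  PTs
absent from the mapping resolve to the sentinel SOC ``"Unmapped"``.
"""

from __future__ import annotations

import csv
from importlib import resources
from typing import Mapping, Optional

UNMAPPED_SOC = "Unmapped"


def _norm_pt(pt: str) -> str:
    # case-insensitive lookup; unify dash variants and runs of whitespace
    return " ".join(pt.replace("–", "-").replace("—", "-").split()).casefold()


class PtSocMapping:
    """Lookup table from MedDRA preferred term to system organ class."""

    def __init__(self, pairs: Mapping[str, str]):
        self._table = {_norm_pt(pt): soc for pt, soc in pairs.items()}

    def __len__(self) -> int:
        return len(self._table)

    def __contains__(self, pt: str) -> bool:
        return _norm_pt(pt) in self._table

    def soc_for(self, pt: str) -> str:
        return self._table.get(_norm_pt(pt), UNMAPPED_SOC)

    def socs(self) -> set[str]:
        return set(self._table.values())

    @classmethod
    def from_csv(cls, path) -> "PtSocMapping":
        """Read a two-column (pt, soc) CSV with a header row."""
        with open(path, newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or not {"pt", "soc"} <= set(
                reader.fieldnames
            ):
                raise ValueError(f"{path}: expected columns 'pt' and 'soc'")
            return cls({row["pt"]: row["soc"] for row in reader})


_default: Optional[PtSocMapping] = None


def default_mapping() -> PtSocMapping:
    """The bundled miniature PT->SOC mapping (cached)."""
    global _default
    if _default is None:
        ref = resources.files("pvsignal.data").joinpath("pt_soc.csv")
        with resources.as_file(ref) as path:
            _default = PtSocMapping.from_csv(path)
    return _default


def map_pt_to_soc(pt: str, mapping: Optional[PtSocMapping] = None) -> str:
    """SOC for ``pt`` under ``mapping`` (default: the bundled table).

    Unknown PTs return ``"Unmapped"``; this is never an error.
    """
    if mapping is None:
        mapping = default_mapping()
    return mapping.soc_for(pt)
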