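"""Preferred-term to System Organ Class mapping.

Adverse-event terms in spontaneous reports are coded to MedDRA preferred
terms (PTs); each PT is aggregated to a single primary System Organ Class
(SOC) for organ-level tabulation.  MedDRA itself is licensed and not
redistributed; the dictionary is pluggable and a small toy dictionary
covering common haematology/oncology terms ships with the package for
testing and demonstration.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

_WS_RE = re.compile(r"\s+")

#: Sentinel returned for PTs absent from the dictionary.
UNMAPPED = "UNMAPPED"


def normalize_term(raw: str) -> str:
    """Canonical PT spelling: trimmed, whitespace collapsed, uppercased."""
    out = _WS_RE.sub(" ", str(raw)).strip().upper()
    if not out:
        raise ValueError("term is empty after normalization")
    return out


@dataclass
class TermDictionary:
    """PT -> (PT code, SOC name, SOC code) with a single primary SOC per PT."""

    entries: dict[str, tuple[str, str, str]] = field(default_factory=dict)
    version: str = "toy"

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pt: str) -> bool:
        return pt in self.entries

    def soc_of(self, pt: str) -> tuple[str, str]:
        """SOC (name, code) for a normalized PT; UNMAPPED sentinel if unknown."""
        entry = self.entries.get(pt)
        if entry is None:
            return (UNMAPPED, UNMAPPED)
        return (entry[1], entry[2])

    def socs(self) -> set[str]:
        return {soc for (_, soc, _) in self.entries.values()}

    def pts_in_soc(self, soc_name: str) -> set[str]:
        return {pt for pt, (_, s, _) in self.entries.items() if s == soc_name}


def load_dictionary(source, version: str = "toy") -> TermDictionary:
    """Load a 4-column (pt_name, pt_code, soc_name, soc_code) dictionary.

    Comma- or tab-separated with a header row.  Duplicate PT rows mapping to
    the same SOC collapse silently; a PT mapped to two different SOCs is an
    error (single primary-SOC convention).
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text(encoding="utf-8")
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    if df.shape[1] < 4:
        raise ValueError("dictionary needs 4 columns: pt_name, pt_code, soc_name, soc_code")
    df.columns = ["pt_name", "pt_code", "soc_name", "soc_code"] + list(df.columns[4:])

    entries: dict[str, tuple[str, str, str]] = {}
    for row in df.itertuples(index=False):
        pt = normalize_term(row.pt_name)
        entry = (str(row.pt_code).strip(), str(row.soc_name).strip(), str(row.soc_code).strip())
        prev = entries.get(pt)
        if prev is not None and prev[1] != entry[1]:
            raise ValueError(f"PT {pt!r} maps to conflicting SOCs: {prev[1]!r} vs {entry[1]!r}")
        entries[pt] = entry
    return TermDictionary(entries=entries, version=version)


def toy_dictionary() -> TermDictionary:
    """The bundled toy dictionary (~50 haematology/oncology PTs)."""
    text = resources.files("pvsignal.data").joinpath("toy_meddra.csv").read_text("utf-8")
    return load_dictionary(text, version="toy-0.1")
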