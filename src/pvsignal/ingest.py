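"""Reading and cleaning FAERS-style quarterly ASCII tables.

FAERS distributes quarterly extracts as dollar-delimited text files with a
single header row (DEMO, DRUG, REAC, THER, OUTC).  This module parses that
dialect, applies the FDA case-deduplication protocol (per CASEID keep the
report with the latest FDA receipt date, ties broken by the highest
PRIMARYID), selects reports where the drug of interest is the primary
suspect, and assembles the event universe — the unique
(report, preferred term) pairs that all disproportionality counting is
based on.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable

import pandas as pd

from .meddra import normalize_term

logger = logging.getLogger("pvsignal")

DELIMITER = "$"

#: Canonical column schemas for the five quarterly tables.
TABLE_SCHEMAS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid", "caseid", "fda_dt", "event_dt", "sex",
        "age", "age_cod", "occp_cod", "occr_country", "quarter",
    ],
    "DRUG": ["primaryid", "drug_seq", "role_cod", "drugname", "start_dt"],
    "REAC": ["primaryid", "pt"],
    "THER": ["primaryid", "dsg_drug_seq", "start_dt"],
    "OUTC": ["primaryid", "outc_cod"],
}

#: Drug role codes: primary suspect, secondary suspect, concomitant, interacting.
ROLE_CODES = ("PS", "SS", "C", "I")

#: Serious-outcome codes (death, life-threatening, hospitalization, disability,
#: congenital anomaly, required intervention, other serious).
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")

#: Names under which the default target drug is marketed.
DEFAULT_LEXICON = frozenset({"AZACITIDINE", "VIDAZA", "ONUREG"})

_PUNCT_RE = re.compile(r"[^\w\s]")
_WS_RE = re.compile(r"\s+")


class ParseError(ValueError):
    """A malformed row in a delimited quarterly table."""


# ---------------------------------------------------------------------------
# Date handling.  FAERS dates are 8-digit YYYYMMDD strings but event and
# therapy dates are frequently partial (YYYYMM, YYYY) or absent.  Partial
# dates keep their year for descriptive tabulations but are unusable for
# day-level arithmetic.
# ---------------------------------------------------------------------------

def parse_full_date(raw) -> date | None:
    """Parse an 8-digit YYYYMMDD string; return None for partial/missing."""
    s = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw).strip()
    if len(s) != 8 or not s.isdigit():
        return None
    try:
        return date(int(s[:4]), int(s[4:6]), int(s[6:8]))
    except ValueError:
        return None


def date_year(raw) -> int | None:
    """Extract the year from a full or partial (YYYYMM / YYYY) date string."""
    s = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw).strip()
    if len(s) in (4, 6, 8) and s.isdigit():
        year = int(s[:4])
        if 1900 <= year <= 2100:
            return year
    return None


def normalize_drug_name(name: str) -> str:
    """Uppercase, strip punctuation, collapse whitespace."""
    cleaned = _PUNCT_RE.sub(" ", str(name))
    return _WS_RE.sub(" ", cleaned).strip().upper()


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def parse_table(
    source,
    schema: list[str] | None = None,
    *,
    strict: bool = True,
) -> pd.DataFrame:
    """Parse one dollar-delimited quarterly table into a DataFrame.

    Parameters
    ----------
    source
        A path, or a text stream / string containing the table.
    schema
        Expected column names, in order (e.g. ``TABLE_SCHEMAS["DEMO"]``).
        When given, the header must start with these names; extra trailing
        header columns are preserved as opaque extras.
    strict
        If True, a data row whose field count does not match the header
        raises :class:`ParseError` naming the line number.  If False the
        row is skipped and counted in a log message.

    Notes
    -----
    A trailing delimiter on data rows (a FAERS quirk) is tolerated: one
    trailing empty field beyond the header width is dropped.
    """
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()

    lines = text.splitlines()
    if not lines or not lines[0].strip():
        raise ParseError("input has no header row")

    header = [h.strip().lower() for h in lines[0].split(DELIMITER)]
    if schema is not None:
        if header[: len(schema)] != list(schema):
            raise ParseError(
                f"header {header!r} does not begin with expected schema {schema!r}"
            )
    width = len(header)

    rows: list[list[str]] = []
    skipped = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split(DELIMITER)
        if len(fields) == width + 1 and fields[-1] == "":
            fields = fields[:-1]  # tolerate trailing delimiter
        if len(fields) != width:
            if strict:
                raise ParseError(
                    f"line {lineno}: expected {width} fields, got {len(fields)}"
                )
            skipped += 1
            continue
        rows.append([f.strip() for f in fields])

    if skipped:
        logger.warning("parse_table: skipped %d malformed row(s)", skipped)

    return pd.DataFrame(rows, columns=header, dtype=str)


def read_quarter_dir(directory, table: str, *, strict: bool = True) -> pd.DataFrame:
    """Concatenate all ``<TABLE>*.txt`` files under *directory*.

    Quarter files are concatenated before deduplication because duplicate
    case submissions straddle quarters.
    """
    directory = Path(directory)
    paths = sorted(directory.glob(f"{table}*.txt")) + sorted(directory.glob(f"{table.lower()}*.txt"))
    if not paths:
        raise FileNotFoundError(f"no {table} files found under {directory}")
    frames = [parse_table(p, TABLE_SCHEMAS.get(table), strict=strict) for p in paths]
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------

def deduplicate(reports: pd.DataFrame) -> pd.DataFrame:
    """Collapse repeat submissions of the same case to a single report.

    For each CASEID the report with the latest FDA receipt date is kept;
    when receipt dates tie, the report with the highest PRIMARYID wins.
    Output is sorted by caseid, one row per case.
    """
    if reports.empty:
        return reports.copy()
    df = reports.copy()
    fda = df["fda_dt"].map(parse_full_date)
    bad = fda.isna()
    if bad.any():
        first = df.loc[bad].iloc[0]
        raise ValueError(
            f"unparseable fda_dt {first['fda_dt']!r} for primaryid {first['primaryid']}"
        )
    df["_fda"] = fda
    df["_pid"] = df["primaryid"].astype("int64")
    df = df.sort_values(["caseid", "_fda", "_pid"], kind="mergesort")
    kept = df.groupby("caseid", sort=True).tail(1)
    kept = kept.sort_values("caseid", kind="mergesort").drop(columns=["_fda", "_pid"])
    return kept.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Target-drug selection and the event universe
# ---------------------------------------------------------------------------

def load_lexicon(path) -> frozenset[str]:
    """Read a drug-name lexicon file (one name per line, UTF-8)."""
    names = {
        normalize_drug_name(line)
        for line in Path(path).read_text(encoding="utf-8").splitlines()
        if line.strip()
    }
    if not names:
        raise ValueError(f"lexicon file {path} contains no names")
    return frozenset(names)


def select_target_reports(
    drugs: pd.DataFrame, lexicon: Iterable[str] = DEFAULT_LEXICON
) -> set[str]:
    """Report ids with >=1 primary-suspect drug row matching the lexicon."""
    lex = frozenset(lexicon)
    if not lex:
        raise ValueError("lexicon is empty")
    if drugs.empty:
        return set()
    ps = drugs[drugs["role_cod"] == "PS"]
    hit = ps["drugname"].map(normalize_drug_name).isin(lex)
    return set(ps.loc[hit, "primaryid"])


@dataclass
class EventUniverse:
    """Deduplicated reports joined to unique (report, PT) adverse events.

    ``events`` has columns primaryid, pt (normalized), is_target; ``reports``
    is the deduplicated DEMO frame restricted to reports contributing events
    or not (full dedup set).  ``n_target_events`` is the a+b margin of every
    2x2 table built from this universe.
    """

    reports: pd.DataFrame
    events: pd.DataFrame
    target_report_ids: set[str] = field(default_factory=set)
    n_dropped_orphan: int = 0

    @property
    def n_reports(self) -> int:
        return len(self.reports)

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_target_events(self) -> int:
        return int(self.events["is_target"].sum()) if len(self.events) else 0

    @property
    def n_other_events(self) -> int:
        return self.n_events - self.n_target_events


def assemble_event_universe(
    reports: pd.DataFrame,
    drugs: pd.DataFrame,
    reactions: pd.DataFrame,
    lexicon: Iterable[str] = DEFAULT_LEXICON,
) -> EventUniverse:
    """Build the event universe from deduplicated reports.

    Events are the unique (primaryid, normalized PT) pairs among reactions
    whose report survived deduplication; duplicate PT mentions within one
    report collapse to one event.  Reactions referencing unknown report ids
    (e.g. reports lacking a DEMO row) are dropped and counted.
    """
    known = set(reports["primaryid"]) if len(reports) else set()
    if reactions.empty:
        ev = pd.DataFrame(columns=["primaryid", "pt", "is_target"])
        return EventUniverse(reports=reports, events=ev)

    reac = reactions.copy()
    keep = reac["primaryid"].isin(known)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("assemble_event_universe: dropped %d orphan reaction(s)", dropped)
    reac = reac[keep]
    reac["pt"] = reac["pt"].map(normalize_term)
    events = (
        reac[["primaryid", "pt"]]
        .drop_duplicates()
        .sort_values(["primaryid", "pt"], kind="mergesort")
        .reset_index(drop=True)
    )
    targets = select_target_reports(drugs, lexicon) & known
    events["is_target"] = events["primaryid"].isin(targets)
    return EventUniverse(
        reports=reports,
        events=events,
        target_report_ids=targets,
        n_dropped_orphan=dropped,
    )
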