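"""Time-to-onset analysis.

The onset of an adverse event is the calendar-day difference between the
earliest therapy start of the suspect drug and the event date.  Reports
with unreported, partial, or inconsistent (event before start) dates are
excluded, with exclusions tallied by reason.  Durations are summarized by
mean/median/IQR, a fixed set of clinically conventional bins, and the
empirical cumulative incidence curve.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import (
    DEFAULT_LEXICON,
    EventUniverse,
    normalize_drug_name,
    parse_full_date,
)

#: Upper edges of the duration bins (days); the last bin is open-ended.
DEFAULT_BIN_EDGES = (30, 60, 90, 120, 180)

EXCLUSION_REASONS = ("missing start", "missing event date", "partial date", "negative duration")


def onset_days(start_raw, event_raw) -> int | None:
    """Calendar days from therapy start to event; None if either date is
    partial/missing; negative values are returned for the caller to flag."""
    start = parse_full_date(start_raw)
    event = parse_full_date(event_raw)
    if start is None or event is None:
        return None
    return (event - start).days


def _is_partial(raw) -> bool:
    s = "" if raw is None or (isinstance(raw, float) and pd.isna(raw)) else str(raw).strip()
    return s.isdigit() and len(s) in (4, 6)


def collect_valid_onsets(
    universe: EventUniverse,
    therapies: pd.DataFrame,
    drugs: pd.DataFrame,
    lexicon=DEFAULT_LEXICON,
) -> tuple[list[int], Counter]:
    """One duration per target report: event date minus the earliest
    target-drug therapy start.  Returns (durations, exclusion tally)."""
    lex = frozenset(lexicon)
    target_ids = universe.target_report_ids

    # therapy rows attached to a target-drug row of the same report
    d = drugs.copy()
    d["_is_target"] = d["drugname"].map(normalize_drug_name).isin(lex)
    target_drug_keys = set(
        zip(d.loc[d["_is_target"], "primaryid"], d.loc[d["_is_target"], "drug_seq"])
    )
    mask = pd.Series(
        [k in target_drug_keys
         for k in zip(therapies["primaryid"], therapies["dsg_drug_seq"])],
        index=therapies.index, dtype=bool,
    )
    ther = therapies[mask]
    starts_by_report: dict[str, list] = {}
    for pid, start in zip(ther["primaryid"], ther["start_dt"]):
        starts_by_report.setdefault(pid, []).append(start)

    event_dt = dict(zip(universe.reports["primaryid"], universe.reports["event_dt"]))

    durations: list[int] = []
    excluded: Counter = Counter()
    for pid in sorted(target_ids):
        raw_starts = starts_by_report.get(pid, [])
        parsed = [(parse_full_date(s), s) for s in raw_starts]
        full_starts = sorted(d0 for d0, _ in parsed if d0 is not None)
        ev_raw = event_dt.get(pid)
        ev = parse_full_date(ev_raw)
        if not raw_starts:
            excluded["missing start"] += 1
            continue
        if not full_starts:
            # start present but not day-resolved
            reason = "partial date" if any(_is_partial(s) for _, s in parsed) else "missing start"
            excluded[reason] += 1
            continue
        if ev is None:
            excluded["partial date" if _is_partial(ev_raw) else "missing event date"] += 1
            continue
        delta = (ev - full_starts[0]).days
        if delta < 0:
            excluded["negative duration"] += 1
            continue
        durations.append(delta)
    return durations, excluded


@dataclass
class OnsetSummary:
    n: int
    excluded: Counter
    mean: float
    median: float
    q1: float
    q3: float
    bins: pd.DataFrame  # columns: bin, count, proportion

    @property
    def n_excluded(self) -> int:
        return sum(self.excluded.values())


def _bin_labels(edges) -> list[str]:
    labels = [f"[0,{edges[0]}]"]
    labels += [f"({lo},{hi}]" for lo, hi in zip(edges[:-1], edges[1:])]
    labels.append(f"({edges[-1]},inf)")
    return labels


def summarize_onsets(
    durations,
    excluded: Counter | None = None,
    bin_edges=DEFAULT_BIN_EDGES,
) -> OnsetSummary:
    """Mean/median/quartiles (linear interpolation between order statistics)
    and the binned distribution of onset durations."""
    x = np.asarray(sorted(durations), dtype=float)
    if x.size == 0:
        raise ValueError("no durations to summarize")
    q1, med, q3 = np.percentile(x, [25, 50, 75])  # linear interpolation

    edges = list(bin_edges)
    counts = []
    prev = -np.inf
    # first bin is closed [0, e0]; subsequent (lo, hi]
    counts.append(int(((x >= 0) & (x <= edges[0])).sum()))
    for lo, hi in zip(edges[:-1], edges[1:]):
        counts.append(int(((x > lo) & (x <= hi)).sum()))
    counts.append(int((x > edges[-1]).sum()))
    bins = pd.DataFrame({
        "bin": _bin_labels(edges),
        "count": counts,
        "proportion": [c / x.size for c in counts],
    })
    return OnsetSummary(
        n=int(x.size),
        excluded=excluded or Counter(),
        mean=float(x.mean()),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        bins=bins,
    )


def cumulative_curve(durations) -> pd.DataFrame:
    """Empirical CDF step points: (day, cumulative proportion), ending at 1."""
    x = np.asarray(sorted(durations), dtype=float)
    if x.size == 0:
        raise ValueError("no durations for a cumulative curve")
    days, counts = np.unique(x, return_counts=True)
    cum = np.cumsum(counts) / x.size
    return pd.DataFrame({"day": days, "cumulative_proportion": cum})
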