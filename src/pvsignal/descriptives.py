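"""Cohort descriptives: demographics, reporting sources, seriousness, trend.

Summaries are computed over deduplicated reports.  Percentages are always
100*count/total rounded to two decimals, so recomputing a percentage from
its count reproduces the reported value exactly.  Outcome percentages can
exceed 100% in aggregate because one report may carry several outcome
codes.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .ingest import OUTCOME_CODES, date_year

AGE_BANDS = ("<18", "18-44", "45-64", ">=65", "Not specified")
SEX_CATEGORIES = ("F", "M", "UNK")
REPORTER_CATEGORIES = ("MD", "PH", "OT", "HP", "CN", "LW", "UNK")

#: Conversion of FAERS age units to years.
_AGE_UNIT_YEARS = {"YR": 1.0, "DEC": 10.0, "MON": 1 / 12.0, "WK": 7 / 365.25,
                   "DY": 1 / 365.25, "HR": 1 / (24 * 365.25)}


def pct(count: float, total: float) -> float:
    """Percentage rounded to 2 decimals, the convention of all report tables."""
    if total == 0:
        return 0.0
    return round(100.0 * count / total, 2)


def age_in_years(value, unit) -> float | None:
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    factor = _AGE_UNIT_YEARS.get(str(unit).strip().upper())
    if factor is None:
        return None
    return v * factor


def age_band(years: float | None) -> str:
    if years is None or pd.isna(years):
        return "Not specified"
    if years < 18:
        return "<18"
    if years < 45:
        return "18-44"
    if years < 65:
        return "45-64"
    return ">=65"


@dataclass
class CohortSummary:
    total_reports: int
    sex: dict[str, tuple[int, float]]
    age: dict[str, tuple[int, float]]
    reporter: dict[str, tuple[int, float]]
    countries: list[tuple[str, int, float]]      # ranked, top-k
    serious: tuple[int, float]
    non_serious: tuple[int, float]
    outcomes: dict[str, tuple[int, float]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (block, category, count, percentage) table."""
        rows = [("Total", "Reports", self.total_reports, "")]
        for block, mapping in (("Sex", self.sex), ("Age", self.age),
                               ("Reporter", self.reporter)):
            rows += [(block, k, n, p) for k, (n, p) in mapping.items()]
        rows += [("Country", k, n, p) for k, n, p in self.countries]
        rows.append(("Severity", "Serious", *self.serious))
        rows.append(("Severity", "Non-serious", *self.non_serious))
        rows += [("Outcome", k, n, p) for k, (n, p) in self.outcomes.items()]
        return pd.DataFrame(rows, columns=["block", "category", "count", "percentage"])


def summarize_cohort(
    reports: pd.DataFrame,
    outcomes: pd.DataFrame | None = None,
    top_countries: int = 5,
) -> CohortSummary:
    """Demographic and clinical summary of a deduplicated report cohort.

    A report's reporter category is its first-listed occupation code; age
    is converted to years before banding; a report is "serious" when it has
    at least one outcome code.
    """
    total = len(reports)

    sex_counts = {k: 0 for k in SEX_CATEGORIES}
    for s in reports["sex"].fillna(""):
        key = s.strip().upper() if s.strip().upper() in ("F", "M") else "UNK"
        sex_counts[key] += 1
    sex = {k: (n, pct(n, total)) for k, n in sex_counts.items()}

    bands = {k: 0 for k in AGE_BANDS}
    for _, row in reports.iterrows():
        bands[age_band(age_in_years(row.get("age"), row.get("age_cod")))] += 1
    age = {k: (n, pct(n, total)) for k, n in bands.items()}

    rep_counts = {k: 0 for k in REPORTER_CATEGORIES}
    for r in reports["occp_cod"].fillna(""):
        first = r.split(",")[0].strip().upper()
        rep_counts[first if first in REPORTER_CATEGORIES else "UNK"] += 1
    reporter = {k: (n, pct(n, total)) for k, n in rep_counts.items()}

    ctry = (
        reports["occr_country"].fillna("").str.strip().replace("", "Not specified")
    )
    counts = ctry.value_counts()
    # ties broken alphabetically for a deterministic ranking
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top_countries]
    countries = [(name, int(n), pct(n, total)) for name, n in ranked]

    if outcomes is None or outcomes.empty:
        outc = pd.DataFrame(columns=["primaryid", "outc_cod"])
    else:
        outc = outcomes[outcomes["primaryid"].isin(set(reports["primaryid"]))]
    n_serious = outc["primaryid"].nunique()
    serious = (n_serious, pct(n_serious, total))
    non_serious = (total - n_serious, pct(total - n_serious, total))

    outcome_map = outcome_distribution(outc, total)

    return CohortSummary(
        total_reports=total, sex=sex, age=age, reporter=reporter,
        countries=countries, serious=serious, non_serious=non_serious,
        outcomes=outcome_map,
    )


def outcome_distribution(outcomes: pd.DataFrame, total_reports: int) -> dict[str, tuple[int, float]]:
    """Per-outcome-code report counts; multi-outcome reports count in each row."""
    if total_reports <= 0:
        raise ValueError("total_reports must be positive")
    result = {code: (0, 0.0) for code in OUTCOME_CODES}
    if outcomes is None or outcomes.empty:
        return result
    dedup = outcomes[["primaryid", "outc_cod"]].drop_duplicates()
    for code, n in dedup["outc_cod"].value_counts().items():
        code = str(code).strip().upper()
        if code not in result:
            raise ValueError(f"unknown outcome code {code!r}")
        result[code] = (int(n), pct(n, total_reports))
    return result


def yearly_counts(reports: pd.DataFrame) -> pd.Series:
    """Report counts by FDA-receipt year, ascending; .attrs['peak'] = max year."""
    if reports.empty:
        s = pd.Series(dtype="int64", name="reports")
        s.attrs["peak_year"] = None
        return s
    years = reports["fda_dt"].map(date_year)
    s = years.value_counts().sort_index().astype("int64")
    s.name = "reports"
    s.index.name = "year"
    s.attrs["peak_year"] = int(s.idxmax())
    return s
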