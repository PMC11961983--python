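"""2x2 disproportionality contingency tables.

For a drug-event pair the table counts adverse events (unique
report x preferred-term pairs), not reports:

                 term      other terms   total
    target drug   a            b          a+b
    other drugs   c            d          c+d

All four signal estimators operate on this table.  The module also
back-solves the unobserved c/d margin from a published (a, a+b, PRR, chi2)
row, which lets printed summary statistics be turned back into a full table
for verification.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .ingest import EventUniverse
from .meddra import TermDictionary, normalize_term


@dataclass(frozen=True)
class ContingencyTable:
    """Cells a, b, c, d; real-valued cells arise only from back-solving."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative cell in table {self}")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0

    @classmethod
    def from_margins(cls, a: float, target_total: float, term_total: float, n: float) -> "ContingencyTable":
        """Reconstruct b, c, d from (a, a+b, a+c, N) aggregated counts.

        This is the form in which external databases (e.g. WHO-VigiAccess
        style aggregates) publish counts.
        """
        return cls(a=a, b=target_total - a, c=term_total - a,
                   d=n - target_total - term_total + a)


def pearson_chi2(t: ContingencyTable) -> float:
    """Pearson chi-square, no continuity correction."""
    n = t.n
    if n == 0:
        return 0.0
    row1, row2 = t.a + t.b, t.c + t.d
    col1, col2 = t.a + t.c, t.b + t.d
    if 0 in (row1, row2, col1, col2):
        return 0.0
    chi2 = 0.0
    for obs, r, c in ((t.a, row1, col1), (t.b, row1, col2),
                      (t.c, row2, col1), (t.d, row2, col2)):
        exp = r * c / n
        chi2 += (obs - exp) ** 2 / exp
    return chi2


def build_table(
    universe: EventUniverse,
    term: str,
    level: str = "PT",
    dictionary: TermDictionary | None = None,
) -> ContingencyTable:
    """Count the 2x2 table for *term* at PT or SOC level.

    At SOC level each event's PT is mapped through the dictionary and the
    event counts toward the SOC it maps to (UNMAPPED PTs form their own
    pseudo-SOC so that SOC counts still partition the event total).
    """
    events = universe.events
    n_target = universe.n_target_events
    n_other = universe.n_other_events

    if level.upper() == "PT":
        term_n = normalize_term(term)
        mask = events["pt"] == term_n
    elif level.upper() == "SOC":
        if dictionary is None or len(dictionary) == 0:
            raise ValueError("SOC-level tables require a loaded term dictionary")
        socs = events["pt"].map(lambda p: dictionary.soc_of(p)[0])
        mask = socs == term
    else:
        raise ValueError(f"level must be PT or SOC, got {level!r}")

    a = int((mask & events["is_target"]).sum())
    c = int((mask & ~events["is_target"]).sum())
    return ContingencyTable(a=a, b=n_target - a, c=c, d=n_other - c)


def solve_margins(
    a: float,
    row_total: float,
    prr: float,
    chi2: float,
    *,
    scale_bounds: tuple[float, float] = (1e3, 1e10),
    rel_tol: float = 1e-9,
) -> ContingencyTable:
    """Recover (c, d) from a published (a, a+b, PRR, chi2) row.

    The PRR fixes the background event rate c/(c+d) = [a/(a+b)]/PRR; the
    chi-square statistic then pins the background size c+d, which is found
    by bisection on the log scale (chi2 is monotone increasing in c+d for
    fixed rates).  Returns a real-valued table.
    """
    if not (0 < a < row_total):
        raise ValueError("need 0 < a < row_total")
    if prr <= 0 or chi2 <= 0:
        raise ValueError("need prr > 0 and chi2 > 0")
    if math.isclose(prr, 1.0):
        raise ValueError("unidentifiable: PRR = 1 gives chi2 = 0 at every scale")

    p_target = a / row_total
    p_background = p_target / prr
    if p_background >= 1:
        raise ValueError("implied background rate >= 1; inputs inconsistent")
    b = row_total - a

    def chi2_at(m: float) -> float:
        c = p_background * m
        return pearson_chi2(ContingencyTable(a=a, b=b, c=c, d=m - c))

    lo, hi = (math.log10(s) for s in scale_bounds)
    f_lo = chi2_at(10.0 ** lo) - chi2
    f_hi = chi2_at(10.0 ** hi) - chi2
    if f_lo * f_hi > 0:
        raise ValueError(
            f"no bracketing sign change for chi2={chi2} in scale bounds {scale_bounds}"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if (chi2_at(10.0 ** mid) - chi2) * f_lo > 0:
            lo = mid
        else:
            hi = mid
        if abs(chi2_at(10.0 ** (0.5 * (lo + hi))) - chi2) <= rel_tol * chi2:
            break
    m = 10.0 ** (0.5 * (lo + hi))
    c = p_background * m
    return ContingencyTable(a=a, b=b, c=c, d=m - c)
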