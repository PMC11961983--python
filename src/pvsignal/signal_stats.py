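"""Disproportionality estimators and the combined significance rule.

Four estimators are computed from each 2x2 table, each with 95% bounds:

* ROR, reporting odds ratio: ad/(bc), Wald interval on the log scale with
  SE = sqrt(1/a + 1/b + 1/c + 1/d).
* PRR, proportional reporting ratio: [a/(a+b)] / [c/(c+d)], log-scale Wald
  interval with SE = sqrt(1/a - 1/(a+b) + 1/c - 1/(c+d)), paired with the
  uncorrected Pearson chi-square.
* IC, BCPNN information component: log2 of the observed/expected reporting
  ratio, with either a delta-method ("se") interval or the closed-form
  Bayesian posterior approximation ("bcpnn-bayes").
* EBGM: here the observed/expected reporting ratio a*N/((a+c)(a+b)) with a
  log-scale Wald interval.  Note this is the unshrunk ratio, not a fitted
  gamma-Poisson shrinkage estimate; IC and EBGM therefore satisfy
  IC = log2(EBGM) identically.

A drug-event pair is flagged significant only when it has at least
``min_a`` reports AND all four estimator criteria hold simultaneously:
ROR lower bound > 1; PRR >= 2 with chi2 >= 4; IC025 > 0; EBGM05 > 2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .contingency import ContingencyTable, pearson_chi2
from .ingest import EventUniverse
from .meddra import TermDictionary

Z95 = 1.959963984540054  # two-sided 95% normal quantile
_LN2 = math.log(2.0)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with 95% bounds on the estimator's natural scale."""

    point: float
    lower: float
    upper: float

    @property
    def defined(self) -> bool:
        return not (math.isnan(self.point) or math.isnan(self.lower) or math.isnan(self.upper))


_UNDEFINED = Estimate(math.nan, math.nan, math.nan)


@dataclass(frozen=True)
class Thresholds:
    """Signal criteria; defaults are the conventional published cut-offs."""

    min_a: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ror_lower_min: float = 1.0
    ic025_min: float = 0.0
    ebgm05_min: float = 2.0


@dataclass(frozen=True)
class SignalResult:
    table: ContingencyTable
    ror: Estimate
    prr: Estimate
    chi2: float
    ic: Estimate
    ebgm: Estimate
    count_pass: bool
    ror_pass: bool
    prr_pass: bool
    ic_pass: bool
    ebgm_pass: bool

    @property
    def significant(self) -> bool:
        return (self.count_pass and self.ror_pass and self.prr_pass
                and self.ic_pass and self.ebgm_pass)


def _log_wald(point: float, se: float) -> Estimate:
    return Estimate(
        point=point,
        lower=math.exp(math.log(point) - Z95 * se),
        upper=math.exp(math.log(point) + Z95 * se),
    )


def ror_estimate(t: ContingencyTable) -> Estimate:
    """Reporting odds ratio ad/(bc) with a log-scale Wald 95% CI."""
    if t.has_zero_cell:
        return _UNDEFINED
    point = (t.a * t.d) / (t.b * t.c)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return _log_wald(point, se)


def prr_estimate(t: ContingencyTable) -> tuple[Estimate, float]:
    """Proportional reporting ratio with its chi-square companion statistic."""
    chi2 = pearson_chi2(t)
    if t.a == 0 or t.c == 0 or (t.a + t.b) == 0 or (t.c + t.d) == 0:
        return _UNDEFINED, chi2
    point = (t.a / (t.a + t.b)) / (t.c / (t.c + t.d))
    se_sq = 1 / t.a - 1 / (t.a + t.b) + 1 / t.c - 1 / (t.c + t.d)
    return _log_wald(point, math.sqrt(max(se_sq, 0.0))), chi2


def _obs_over_exp(t: ContingencyTable) -> float:
    return t.a * t.n / ((t.a + t.c) * (t.a + t.b))


def ic_estimate(t: ContingencyTable, method: str = "se") -> Estimate:
    """Information component: log2 of the observed/expected reporting ratio.

    method "se": delta-method bounds point +/- 1.96*sqrt(1/a+1/b+1/c+1/d)/ln2.
    method "bcpnn-bayes": the closed-form normal approximation to the BCPNN
    posterior (Bate et al. 1998), with priors alpha1 = beta1 = 1,
    alpha = beta = 2, gamma11 = 1 and gamma tied to the margins so that the
    prior IC expectation is 0.  Bounds are E(IC) +/- 1.96*sqrt(V(IC)); this
    shrinks hard for small a, which is why tabulated IC025 values for rare
    terms sit far below the delta-method bound.
    """
    if t.a == 0:
        return _UNDEFINED
    point = math.log2(_obs_over_exp(t))

    if method == "se":
        if t.has_zero_cell:
            return _UNDEFINED
        se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d) / _LN2
        return Estimate(point=point, lower=point - Z95 * se, upper=point + Z95 * se)

    if method == "bcpnn-bayes":
        a, n = t.a, t.n
        row = t.a + t.b   # all target-drug events
        col = t.a + t.c   # all events with this term
        alpha1 = beta1 = 1.0
        alpha = beta = 2.0
        g11 = 1.0
        gamma = g11 * (n + alpha) * (n + beta) / ((row + alpha1) * (col + beta1))
        e_ic = math.log2(
            (a + g11) * (n + alpha) * (n + beta)
            / ((n + gamma) * (row + alpha1) * (col + beta1))
        )
        v_ic = (
            (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
            + (n - row + alpha - alpha1) / ((row + alpha1) * (1 + n + alpha))
            + (n - col + beta - beta1) / ((col + beta1) * (1 + n + beta))
        ) / (_LN2 ** 2)
        sd = math.sqrt(v_ic)
        return Estimate(point=point, lower=e_ic - Z95 * sd, upper=e_ic + Z95 * sd)

    raise ValueError(f"unknown IC interval method {method!r}")


def ebgm_estimate(t: ContingencyTable) -> Estimate:
    """Observed/expected reporting ratio a*N/((a+c)(a+b)), log-Wald CI."""
    if t.a == 0:
        return _UNDEFINED
    if t.has_zero_cell:
        return _UNDEFINED
    point = _obs_over_exp(t)
    se = math.sqrt(1 / t.a + 1 / t.b + 1 / t.c + 1 / t.d)
    return _log_wald(point, se)


def evaluate_signal(
    t: ContingencyTable,
    thresholds: Thresholds = Thresholds(),
    ic_method: str = "se",
) -> SignalResult:
    """Apply all four estimator criteria plus the minimum-count rule.

    Undefined estimates (zero cells) fail their criterion.
    """
    ror = ror_estimate(t)
    prr, chi2 = prr_estimate(t)
    ic = ic_estimate(t, method=ic_method)
    ebgm = ebgm_estimate(t)
    th = thresholds
    return SignalResult(
        table=t,
        ror=ror, prr=prr, chi2=chi2, ic=ic, ebgm=ebgm,
        count_pass=t.a >= th.min_a,
        ror_pass=ror.defined and ror.lower > th.ror_lower_min,
        prr_pass=prr.defined and prr.point >= th.prr_min and chi2 >= th.chi2_min,
        ic_pass=ic.defined and ic.lower > th.ic025_min,
        ebgm_pass=ebgm.defined and ebgm.lower > th.ebgm05_min,
    )


def compute_signal_table(
    universe: EventUniverse,
    level: str = "PT",
    dictionary: TermDictionary | None = None,
    thresholds: Thresholds = Thresholds(),
    ic_method: str = "se",
) -> pd.DataFrame:
    """Signal results for every term with >=1 target event at the given level.

    Returns one row per term with the full column set used by the report
    writer, sorted by target event count (descending), ties by term.
    """
    events = universe.events
    if level.upper() == "SOC":
        if dictionary is None:
            raise ValueError("SOC-level results require a term dictionary")
        labels = events["pt"].map(lambda p: dictionary.soc_of(p)[0])
    else:
        labels = events["pt"]

    terms = sorted(labels[events["is_target"]].unique())
    rows = []
    for term in terms:
        mask = labels == term
        a = int((mask & events["is_target"]).sum())
        c = int((mask & ~events["is_target"]).sum())
        t = ContingencyTable(a=a, b=universe.n_target_events - a,
                             c=c, d=universe.n_other_events - c)
        r = evaluate_signal(t, thresholds, ic_method=ic_method)
        rows.append({
            "level": level.upper(),
            "term": term,
            "case_number": a,
            "b": t.b, "c": t.c, "d": t.d,
            "ror": r.ror.point, "ror_l": r.ror.lower, "ror_u": r.ror.upper,
            "prr": r.prr.point, "prr_l": r.prr.lower, "prr_u": r.prr.upper,
            "chi_square": r.chi2,
            "ic": r.ic.point, "ic025": r.ic.lower,
            "ebgm": r.ebgm.point, "ebgm05": r.ebgm.lower,
            "count_pass": r.count_pass,
            "ror_pass": r.ror_pass,
            "prr_pass": r.prr_pass,
            "ic_pass": r.ic_pass,
            "ebgm_pass": r.ebgm_pass,
            "significant": r.significant,
        })
    df = pd.DataFrame(rows)
    if len(df):
        df = df.sort_values(["case_number", "term"], ascending=[False, True],
                            kind="mergesort").reset_index(drop=True)
    return df
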