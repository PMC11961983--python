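"""Synthetic spontaneous-reporting database generator.

Emits DEMO/DRUG/REAC/THER/OUTC quarterly tables in the same dollar-delimited
dialect the ingest module reads, together with a ground-truth ledger, so the
whole pipeline is testable without an external database download.

What is emulated, with defaults calibrated to a real haematology-drug
cohort: duplicate case submissions across quarters; multiple preferred
terms per report (zero-truncated Poisson, mean ~2.76 events/report); a
target drug whose reports are enriched for chosen PTs against a background
drug universe; partially missing or partial (month/year-only) dates;
demographic category mixes; and log-normal onset times (median 36 days,
sigma of log 1.8, i.e. Q3/Q1 ~ 126/11).

All randomness flows from one seed through named SeedSequence substreams,
so individual components are reproducible in isolation and identical seeds
produce byte-identical output files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .meddra import normalize_term

_EPOCH = date(2004, 1, 1)
_LAST = date(2024, 9, 30)
_SPAN_DAYS = (_LAST - _EPOCH).days

#: default background PT catalog: (PT, SOC, relative mention weight)
DEFAULT_PT_CATALOG: tuple[tuple[str, str, float], ...] = (
    ("FEBRILE NEUTROPENIA", "Blood and lymphatic system disorders", 0.8),
    ("NEUTROPENIA", "Blood and lymphatic system disorders", 1.0),
    ("THROMBOCYTOPENIA", "Blood and lymphatic system disorders", 1.0),
    ("ANAEMIA", "Blood and lymphatic system disorders", 1.2),
    ("PANCYTOPENIA", "Blood and lymphatic system disorders", 0.5),
    ("PNEUMONIA", "Infections and infestations", 1.5),
    ("SEPSIS", "Infections and infestations", 0.8),
    ("SEPTIC SHOCK", "Infections and infestations", 0.4),
    ("INFECTION", "Infections and infestations", 0.8),
    ("URINARY TRACT INFECTION", "Infections and infestations", 0.8),
    ("ACUTE MYELOID LEUKAEMIA", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 0.3),
    ("MYELODYSPLASTIC SYNDROME", "Neoplasms benign, malignant and unspecified (incl cysts and polyps)", 0.2),
    ("DEATH", "General disorders and administration site conditions", 1.5),
    ("PYREXIA", "General disorders and administration site conditions", 1.5),
    ("FATIGUE", "General disorders and administration site conditions", 2.0),
    ("NAUSEA", "Gastrointestinal disorders", 2.0),
    ("VOMITING", "Gastrointestinal disorders", 1.5),
    ("DIARRHOEA", "Gastrointestinal disorders", 1.5),
    ("PLATELET COUNT DECREASED", "Investigations", 0.8),
    ("CARDIAC FAILURE", "Cardiac disorders", 0.6),
)

#: relative enrichment of target-report mention weights for chosen PTs
DEFAULT_RISK_MULTIPLIERS: dict[str, float] = {
    "FEBRILE NEUTROPENIA": 20.0,
    "NEUTROPENIA": 8.0,
    "THROMBOCYTOPENIA": 8.0,
    "ACUTE MYELOID LEUKAEMIA": 40.0,
    "PNEUMONIA": 5.0,
    "SEPSIS": 8.0,
}

TARGET_DRUG_NAMES = ("AZACITIDINE", "Vidaza", "azacitidine.")

BACKGROUND_DRUGS = tuple(
    f"BACKGROUND DRUG {i:02d}" for i in range(1, 31)
)

# demographic mixes (proportions of reports) of the reference cohort
SEX_MIX = {"F": 0.3253, "M": 0.5353, "UNK": 0.1394}
AGE_BAND_MIX = {"<18": 0.0164, "18-44": 0.0318, "45-64": 0.1479,
                ">=65": 0.5536, "NA": 0.2503}
REPORTER_MIX = {"CN": 0.0803, "MD": 0.3769, "PH": 0.2439, "UNK": 0.0287,
                "LW": 0.0001, "HP": 0.2701}
COUNTRY_MIX = {"US": 0.2640, "JP": 0.1228, "FR": 0.0766, "ES": 0.0659,
               "DE": 0.0605, "OTHER": 0.4102}
SERIOUS_RATE = 0.9578
# marginal outcome-code rates among all reports (multi-outcome allowed)
OUTCOME_MIX = {"OT": 0.4534, "HO": 0.4406, "DE": 0.4087, "LT": 0.1084,
               "DS": 0.0180, "RI": 0.0018, "CA": 0.0003}


def ztp_lambda(mean: float) -> float:
    """Rate of a zero-truncated Poisson with the given mean (bisection)."""
    if mean <= 1:
        raise ValueError("zero-truncated Poisson mean must exceed 1")
    lo, hi = 1e-9, mean
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mid / (1.0 - math.exp(-mid)) < mean:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def lognormal_sigma_from_iqr(q1: float, q3: float) -> float:
    """Sigma of the log for a log-normal with the given quartiles."""
    z75 = 0.6744897501960817
    return math.log(q3 / q1) / (2 * z75)


@dataclass(frozen=True)
class GeneratorConfig:
    """Full parameterization of the synthetic reporting database."""

    n_reports: int = 2000
    target_share: float = 0.15
    pt_catalog: tuple = DEFAULT_PT_CATALOG
    risk_multipliers: dict = field(default_factory=lambda: dict(DEFAULT_RISK_MULTIPLIERS))
    events_per_report_mean: float = 44295 / 16056   # ~2.76
    duplicate_rate: float = 0.05
    missing_event_dt_rate: float = 0.30
    partial_event_dt_rate: float = 0.10
    missing_start_rate: float = 0.20
    partial_start_rate: float = 0.08
    negative_onset_rate: float = 0.02
    onset_median_days: float = 36.0
    onset_sigma: float = 1.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_reports < 1:
            raise ValueError("invalid config field: n_reports must be >= 1")
        if not 0 <= self.target_share <= 1:
            raise ValueError("invalid config field: target_share must be in [0,1]")
        if not 0 <= self.duplicate_rate < 1:
            raise ValueError("invalid config field: duplicate_rate must be in [0,1)")
        for name in ("missing_event_dt_rate", "partial_event_dt_rate",
                     "missing_start_rate", "partial_start_rate",
                     "negative_onset_rate"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"invalid config field: {name} must be in [0,1]")
        if any(m <= 0 for m in self.risk_multipliers.values()):
            raise ValueError("invalid config field: risk_multipliers must be > 0")
        if self.events_per_report_mean <= 1:
            raise ValueError("invalid config field: events_per_report_mean must exceed 1")
        if self.onset_median_days <= 0:
            raise ValueError("invalid config field: onset_median_days must be > 0")
        if self.onset_sigma <= 0:
            raise ValueError("invalid config field: onset_sigma must be > 0")


def _substreams(seed: int, names: tuple[str, ...]) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


_STREAMS = ("assign", "demo", "drug", "reac", "ther", "outc", "onset", "dup")


def sample_onsets(n: int, seed: int, median_days: float = 36.0,
                  sigma: float = 1.8) -> np.ndarray:
    """Draw n integer onset durations (days, >=0) from the log-normal model.

    The model is parameterized by its median (mu = ln median) and the sigma
    of the log; durations are rounded to whole days.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    draws = rng.lognormal(mean=math.log(median_days), sigma=sigma, size=n)
    return np.maximum(np.rint(draws), 0).astype(int)


def _sample_ztp(rng: np.random.Generator, lam: float, n: int) -> np.ndarray:
    out = rng.poisson(lam, size=n)
    zero = out == 0
    while zero.any():
        out[zero] = rng.poisson(lam, size=int(zero.sum()))
        zero = out == 0
    return out


def _date_str(d: date) -> str:
    return d.strftime("%Y%m%d")


def _categorical(rng, mapping: dict[str, float], n: int) -> np.ndarray:
    keys = list(mapping)
    p = np.array([mapping[k] for k in keys], dtype=float)
    p = p / p.sum()
    return rng.choice(keys, size=n, p=p)


@dataclass
class SyntheticDatabase:
    tables: dict[str, pd.DataFrame]
    ledger: dict

    def write(self, directory) -> None:
        """Write the quarterly ASCII files plus the ledger CSVs."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(directory / f"{name}.txt", sep="$", index=False)
        self.ledger["pt_counts"].to_csv(directory / "ledger_pt_counts.csv", index=False)
        self.ledger["duplicates"].to_csv(directory / "ledger_duplicates.csv", index=False)


def generate_database(config: GeneratorConfig = GeneratorConfig(),
                      seed: int | None = None,
                      outdir=None) -> SyntheticDatabase:
    """Generate the five quarterly tables plus a ground-truth ledger.

    The ledger records, per PT, the true unique (report, PT) event counts
    for target and background reports (computed from the emitted reaction
    rows before duplicate injection), the injected duplicate pairs with
    their designated dedup survivor, and the onset model parameters.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rngs = _substreams(seed, _STREAMS)

    n = config.n_reports
    caseids = np.arange(1, n + 1)
    primaryids = caseids * 10
    is_target = rngs["assign"].random(n) < config.target_share

    # --- DEMO ---------------------------------------------------------
    rng = rngs["demo"]
    fda_offsets = rng.integers(0, _SPAN_DAYS + 1, size=n)
    fda_dates = [_EPOCH + timedelta(days=int(o)) for o in fda_offsets]
    sex = _categorical(rng, SEX_MIX, n)
    bands = _categorical(rng, AGE_BAND_MIX, n)
    lo_hi = {"<18": (1, 17), "18-44": (18, 44), "45-64": (45, 64), ">=65": (65, 90)}
    ages, age_cods = [], []
    for band in bands:
        if band == "NA":
            ages.append("")
            age_cods.append("")
        else:
            lo, hi = lo_hi[band]
            ages.append(str(int(rng.integers(lo, hi + 1))))
            age_cods.append("YR")
    reporter = _categorical(rng, REPORTER_MIX, n)
    reporter = np.where(reporter == "UNK", "", reporter)
    country = _categorical(rng, COUNTRY_MIX, n)

    # --- therapy starts and onsets -------------------------------------
    rng_on = rngs["onset"]
    start_back = rng_on.integers(30, 720, size=n)  # start precedes receipt
    start_dates = [f - timedelta(days=int(b)) for f, b in zip(fda_dates, start_back)]
    onsets = np.maximum(
        np.rint(rng_on.lognormal(math.log(config.onset_median_days),
                                 config.onset_sigma, size=n)), 0
    ).astype(int)
    event_dates = [s + timedelta(days=int(o)) for s, o in zip(start_dates, onsets)]
    negative = rng_on.random(n) < config.negative_onset_rate
    for i in np.flatnonzero(negative):
        event_dates[i] = start_dates[i] - timedelta(days=int(rng_on.integers(1, 31)))

    u = rng_on.random(n)
    event_strs = []
    for i in range(n):
        if u[i] < config.missing_event_dt_rate:
            event_strs.append("")
        elif u[i] < config.missing_event_dt_rate + config.partial_event_dt_rate:
            event_strs.append(event_dates[i].strftime("%Y%m"))
        else:
            event_strs.append(_date_str(event_dates[i]))

    def quarter_label(d: date) -> str:
        return f"{d.year}Q{(d.month - 1) // 3 + 1}"

    demo = pd.DataFrame({
        "primaryid": primaryids.astype(str),
        "caseid": caseids.astype(str),
        "fda_dt": [_date_str(d) for d in fda_dates],
        "event_dt": event_strs,
        "sex": sex,
        "age": ages,
        "age_cod": age_cods,
        "occp_cod": reporter,
        "occr_country": country,
        "quarter": [quarter_label(d) for d in fda_dates],
    })

    # --- DRUG and THER --------------------------------------------------
    rng_d = rngs["drug"]
    rng_t = rngs["ther"]
    drug_rows, ther_rows = [], []
    v = rng_t.random(n)
    for i in range(n):
        pid = str(primaryids[i])
        if is_target[i]:
            name = TARGET_DRUG_NAMES[int(rng_d.integers(0, len(TARGET_DRUG_NAMES)))]
        else:
            name = BACKGROUND_DRUGS[int(rng_d.integers(0, len(BACKGROUND_DRUGS)))]
        drug_rows.append((pid, "1", "PS", name, ""))
        for j in range(int(rng_d.integers(0, 3))):  # concomitants
            conc = BACKGROUND_DRUGS[int(rng_d.integers(0, len(BACKGROUND_DRUGS)))]
            drug_rows.append((pid, str(2 + j), "C", conc, ""))
        if v[i] < config.missing_start_rate:
            continue  # no therapy row at all
        if v[i] < config.missing_start_rate + config.partial_start_rate:
            ther_rows.append((pid, "1", start_dates[i].strftime("%Y%m")))
        else:
            ther_rows.append((pid, "1", _date_str(start_dates[i])))
    drug = pd.DataFrame(drug_rows,
                        columns=["primaryid", "drug_seq", "role_cod", "drugname", "start_dt"])
    ther = pd.DataFrame(ther_rows, columns=["primaryid", "dsg_drug_seq", "start_dt"])

    # --- REAC -----------------------------------------------------------
    rng_r = rngs["reac"]
    pts = [normalize_term(p) for p, _, _ in config.pt_catalog]
    w_bg = np.array([w for _, _, w in config.pt_catalog], dtype=float)
    w_tg = w_bg * np.array([config.risk_multipliers.get(p, 1.0) for p in pts])
    p_bg = w_bg / w_bg.sum()
    p_tg = w_tg / w_tg.sum()
    lam = ztp_lambda(config.events_per_report_mean)
    k = _sample_ztp(rng_r, lam, n)
    reac_rows = []
    for i in range(n):
        p = p_tg if is_target[i] else p_bg
        for idx in rng_r.choice(len(pts), size=int(k[i]), p=p):
            reac_rows.append((str(primaryids[i]), pts[idx]))
    reac = pd.DataFrame(reac_rows, columns=["primaryid", "pt"])

    # --- OUTC -----------------------------------------------------------
    rng_o = rngs["outc"]
    serious = rng_o.random(n) < SERIOUS_RATE
    outc_rows = []
    codes = list(OUTCOME_MIX)
    cond = np.array([OUTCOME_MIX[c] for c in codes]) / SERIOUS_RATE
    for i in np.flatnonzero(serious):
        hits = [c for c, pr in zip(codes, cond) if rng_o.random() < pr]
        if not hits:
            hits = ["OT"]
        for c in hits:
            outc_rows.append((str(primaryids[i]), c))
    outc = pd.DataFrame(outc_rows, columns=["primaryid", "outc_cod"])

    # --- ground-truth event counts (unique pairs, pre-duplication) ------
    soc_of = {normalize_term(p): s for p, s, _ in config.pt_catalog}
    uniq = reac.drop_duplicates()
    tgt_ids = set(demo.loc[is_target, "primaryid"])
    uniq_t = uniq[uniq["primaryid"].isin(tgt_ids)]
    uniq_b = uniq[~uniq["primaryid"].isin(tgt_ids)]
    pt_counts = pd.DataFrame({
        "pt": pts,
        "soc": [soc_of[p] for p in pts],
        "target_events": [int((uniq_t["pt"] == p).sum()) for p in pts],
        "other_events": [int((uniq_b["pt"] == p).sum()) for p in pts],
    })

    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "THER": ther, "OUTC": outc}
    tables, duplicates = inject_duplicates(tables, config.duplicate_rate, rngs["dup"])

    ledger = {
        "n_reports": n,
        "n_target_reports": int(is_target.sum()),
        "pt_counts": pt_counts,
        "duplicates": duplicates,
        "onset_model": {"median_days": config.onset_median_days,
                        "sigma": config.onset_sigma},
        "row_counts": {name: len(df) for name, df in tables.items()},
    }
    db = SyntheticDatabase(tables=tables, ledger=ledger)
    if outdir is not None:
        db.write(outdir)
    return db


def inject_duplicates(tables: dict[str, pd.DataFrame], rate: float,
                      rng_or_seed) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Re-emit a fraction of cases as duplicate submissions.

    Each selected case is copied with a new, higher primaryid and a
    later-or-equal FDA receipt date (its DRUG/REAC/THER/OUTC rows are copied
    under the new primaryid), so the copy is always the dedup survivor.
    Returns the augmented tables and a ledger of (caseid, original, duplicate,
    survivor) rows.
    """
    if not 0 <= rate < 1:
        raise ValueError("duplicate rate must be in [0, 1)")
    rng = (rng_or_seed if isinstance(rng_or_seed, np.random.Generator)
           else np.random.default_rng(np.random.SeedSequence(rng_or_seed)))
    demo = tables["DEMO"]
    if rate == 0 or demo.empty:
        return tables, pd.DataFrame(
            columns=["caseid", "original_primaryid", "duplicate_primaryid", "survivor"])

    pick = rng.random(len(demo)) < rate
    dup_demo_rows = []
    pairs = []
    extra = {name: [] for name in ("DRUG", "REAC", "THER", "OUTC")}
    for _, row in demo[pick].iterrows():
        old_pid = row["primaryid"]
        new_pid = str(int(old_pid) + 1 + int(rng.integers(0, 9)))
        new_row = row.copy()
        new_row["primaryid"] = new_pid
        shift = int(rng.integers(0, 60))
        d = date(int(row["fda_dt"][:4]), int(row["fda_dt"][4:6]), int(row["fda_dt"][6:8]))
        new_row["fda_dt"] = (d + timedelta(days=shift)).strftime("%Y%m%d")
        dup_demo_rows.append(new_row)
        pairs.append((row["caseid"], old_pid, new_pid, new_pid))
        for name in extra:
            sub = tables[name][tables[name]["primaryid"] == old_pid].copy()
            sub["primaryid"] = new_pid
            extra[name].append(sub)

    out = dict(tables)
    out["DEMO"] = pd.concat([demo, pd.DataFrame(dup_demo_rows)], ignore_index=True)
    for name, frames in extra.items():
        if frames:
            out[name] = pd.concat([tables[name], *frames], ignore_index=True)
    dup_ledger = pd.DataFrame(
        pairs, columns=["caseid", "original_primaryid", "duplicate_primaryid", "survivor"])
    return out, dup_ledger


# ---------------------------------------------------------------------------
# Exact expectations implied by a configuration (used for parameter-recovery
# checks).  Because duplicate PT mentions within a report collapse to one
# event, the event-level relative reporting rate differs from the raw mention
# multiplier; these helpers compute the implied event-level truth in closed
# form via the zero-truncated Poisson generating function.
# ---------------------------------------------------------------------------

def _presence_probs(p: np.ndarray, lam: float) -> np.ndarray:
    """P(PT appears at least once in a report), K ~ ZTP(lam), mentions iid p."""
    denom = math.expm1(lam)
    return 1.0 - np.expm1(lam * (1.0 - p)) / denom


def expected_ebgm(config: GeneratorConfig, pt: str) -> float:
    """The EBGM (observed/expected ratio) implied by the configuration."""
    pts = [normalize_term(p) for p, _, _ in config.pt_catalog]
    i = pts.index(normalize_term(pt))
    w_bg = np.array([w for _, _, w in config.pt_catalog], dtype=float)
    w_tg = w_bg * np.array([config.risk_multipliers.get(p, 1.0) for p in pts])
    lam = ztp_lambda(config.events_per_report_mean)
    q_t = _presence_probs(w_tg / w_tg.sum(), lam)
    q_b = _presence_probs(w_bg / w_bg.sum(), lam)
    s = config.target_share
    events_t = s * q_t.sum()          # expected target events per report drawn
    events_b = (1 - s) * q_b.sum()
    a = s * q_t[i]
    col = a + (1 - s) * q_b[i]
    return (a / events_t) / (col / (events_t + events_b))
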