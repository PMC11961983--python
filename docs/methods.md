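# Methods

## Data model and counting convention

The pipeline operates on FAERS-style quarterly extracts: DEMO (one row per
report version), DRUG (one row per drug per report, with role codes PS/SS/
C/I), REAC (one row per reported preferred term), THER (therapy episodes
keyed to drug rows), OUTC (serious-outcome codes). Quarters are concatenated
before any cleaning because duplicate case submissions straddle quarters.

**Deduplication.** A case (CASEID) may be submitted repeatedly as follow-up
versions. Per FDA convention the survivor is the version with the latest
FDA receipt date, ties broken by the highest PRIMARYID. The rule is a pure
lexicographic maximum on (FDA_DT, PRIMARYID) within CASEID, which makes it
idempotent and order-independent; both properties are tested.

**Counting unit.** All disproportionality counts are *adverse events* —
unique (deduplicated report, normalized PT) pairs — not reports. Duplicate
mentions of a PT within one report collapse to a single event. This is the
convention under which an organ-class breakdown of the analysed cohort
partitions the event total exactly, and it makes the a+b margin of every
2×2 table equal to the target drug's total event count.

**Target selection.** A report belongs to the target drug iff at least one
of its drug rows has role PS and a normalized drug name (uppercased,
punctuation stripped, whitespace collapsed) contained in a configurable
lexicon. Matching is exact on the normalized form — no fuzzy matching —
trading recall for reproducibility.

**Exclusions.** Reports lacking a DEMO row cannot carry demographics or
dates and are excluded from the universe entirely; reactions pointing at
such reports are dropped and counted in the run log. Partial dates (YYYY,
YYYYMM) keep their year for descriptive tabulations but are treated as
missing wherever day-level arithmetic is needed.

## Estimators

For a table (a, b, c, d) with N = a+b+c+d:

* **ROR** ad/bc; 95% CI exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). Undefined
  (and failing its criterion) when any cell is 0.
* **PRR** [a/(a+b)]/[c/(c+d)]; CI on the log scale with
  SE² = 1/a − 1/(a+b) + 1/c − 1/(c+d); companion statistic is the Pearson
  χ² **without** continuity correction. The uncorrected form is adopted
  because back-solving a published summary row with it reproduces that
  row's other printed statistics to their printed rounding, which the
  corrected form does not.
* **IC** log₂(aN/((a+b)(a+c))), the base-2 log of the observed/expected
  reporting ratio. Two interval methods are provided:
  * `se` (default): delta-method, point ± 1.96·√(1/a+1/b+1/c+1/d)/ln 2.
    This reproduces tabulated IC025 values for large-count rows.
  * `bcpnn-bayes`: the closed-form normal approximation to the BCPNN
    posterior (Bate et al. 1998), priors α₁ = β₁ = 1, α = β = 2, γ₁₁ = 1,
    γ tied to the margins so the prior IC expectation is 0. For small a
    this bound shrinks hard toward 0 (e.g. a = 3 with a point IC near 9
    gets an IC025 well under 2), which matches how rare-term rows are
    tabulated in practice.
* **EBGM** aN/((a+b)(a+c)) with a log-scale Wald interval. This is the
  *unshrunk* observed/expected ratio, implemented exactly as published
  analyses of this style print it; it is **not** a fitted gamma-Poisson
  (MGPS) shrinkage estimate, and consequently IC = log₂ EBGM holds
  identically — an identity the tests assert on random tables and that
  published IC/EBGM pairs satisfy at 2 decimals.

**Signal rule.** significant ⇔ a ≥ 3 ∧ ROR lower bound > 1 ∧ (PRR ≥ 2 ∧
χ² ≥ 4) ∧ IC025 > 0 ∧ EBGM05 > 2. All five thresholds are configurable.
Zero cells yield undefined estimates which fail their criterion; no
Haldane/continuity corrections are applied to counts, since the a ≥ 3 rule
already excludes the emptiest tables.

**Margin back-solving.** Published tables print (a, a+b, PRR, χ²) but not
the background margin. `solve_margins` fixes the background event rate
c/(c+d) = [a/(a+b)]/PRR and finds the background size c+d by bisection on
log₁₀(c+d) ∈ [3, 10], since χ² is monotone increasing in the background
size at fixed rates; iteration stops at |χ²−target| ≤ 10⁻⁹ relative (the
contract only requires 10⁻³). PRR = 1 leaves the scale unidentifiable
(χ² ≡ 0) and is rejected, as is a χ² outside the bracketable range — χ²
saturates as c+d → ∞ at the one-sample limit, so an overstated χ² is
detectable. Back-solved tables are real-valued; the estimators accept them
unchanged.

## Descriptives

Percentages are always round(100·n/total, 2), so any reported percentage is
exactly recomputable from its count. Age is converted to years (MON/12,
DY/365.25, …) before banding into <18, 18–44, 45–64, ≥65, unspecified. A
report's reporter category is its first-listed occupation code. A report is
*serious* iff it has ≥ 1 OUTC code; a report with k outcome codes counts in
all k outcome rows, so outcome percentages may sum past 100%. Country
ranking ties break alphabetically; yearly counts key on FDA receipt year.

## Time-to-onset

Duration = event date − earliest day-resolved therapy start among the
report's target-drug therapy rows (earliest-start is deterministic and
conservative when several episodes exist). One duration per target report.
Exclusions are tallied by reason: missing start (no therapy row), partial
date (month/year-only start or event date), missing event date, negative
duration. Day-0 (same-day) onsets are valid. Quartiles use linear
interpolation between order statistics; the binned distribution uses
[0,30], (30,60], (60,90], (90,120], (120,180], (180,∞) — the 30-day and
180-day landmarks are the clinically reported ones, the interior edges a
package choice. The cumulative incidence curve is the empirical CDF,
ending at exactly 1.

## Synthetic database generator

The generator emulates the structure of a real single-drug extract:

| parameter | default | rationale |
|---|---|---|
| events per report | zero-truncated Poisson, mean 2.76 | events/reports ratio of the reference cohort (44,295/16,056) |
| onset model | log-normal, median 36 d, σ_log 1.8 | matches the reported median and the Q3/Q1 ≈ 126/11 spread; σ_log = ln(Q3/Q1)/(2·z₀.₇₅) |
| duplicate_rate | 0.05 | realistic follow-up fraction; a duplicate re-emits the case with a higher PRIMARYID and later-or-equal FDA_DT, so the copy is always the designated dedup survivor |
| missing/partial date rates | 0.30/0.10 (event), 0.20/0.08 (start), 2% inverted | produce an onset inclusion fraction near the ~44% seen in the reference cohort |
| demographics | sex 32.5/53.5/13.9 F/M/UNK, ≥65 = 55.4%, reporter and country mixes, serious = 95.78% | reference-cohort proportions |
| n_reports / target_share | 2000 / 0.15 | desk-scale defaults; all rates are per-report, so size is free |

All randomness flows from one seed through named `SeedSequence` substreams
(assignment, demographics, drugs, reactions, therapy, outcomes, onsets,
duplicates), so each component is reproducible in isolation and a fixed
seed yields byte-identical files.

**What the generator does not emulate:** drug–drug interaction signals,
masking/competition effects, reporting-delay dynamics, secular trends in
reporting volume, free-text drug-name noise beyond simple case/punctuation
variants, and multi-country duplicate submissions under different CASEIDs.
Passing tests on synthetic data therefore demonstrate the pipeline's
correctness (counting, dedup, estimator algebra, calibration), not the
clinical validity of signals from real spontaneous data.

**Ground truth and recovery.** The ledger records exact unique-pair event
counts per PT, injected duplicate pairs with their designated survivor, and
the onset parameters. Because within-report PT mentions collapse, the
event-level enrichment of a PT differs from its raw mention multiplier;
`expected_ebgm` computes the implied event-level ratio in closed form via
the zero-truncated Poisson generating function (P(term present) =
1 − (e^{λ(1−p)}−1)/(e^{λ}−1)), and replicate studies confirm the EBGM
estimator recovers it (200 replicates of 300 reports, 5× multiplier:
replicate mean within 1–2% of the closed form).

## Numerical and design choices

* χ² without Yates correction throughout (see Estimators).
* Report tables round statistics to 2 decimals and sort by target event
  count descending, ties alphabetical — artifacts are byte-reproducible;
  `--full-precision` disables rounding.
* The toy PT→SOC dictionary assigns each PT a single primary SOC; MedDRA's
  multi-axiality is out of scope, and SOC counts therefore partition the
  event total. Unknown PTs map to an UNMAPPED pseudo-SOC and still count
  toward totals.
* Problem sizes in the test suite (800–2,000 synthetic reports; 200
  replicates of 300 reports for recovery; 1,000 random universes for the
  brute-force equivalence) are chosen so the whole suite runs in seconds
  while keeping Monte-Carlo error well inside the asserted bands.

## Limitations

* Spontaneous-report disproportionality measures reporting association,
  not risk; no incidence or causal claims are supported.
* The EBGM here is the unshrunk ratio; rare-term EBGMs are noisier than a
  true MGPS shrinkage estimate would be. The BCPNN-Bayes IC bound is the
  provided small-count safeguard.
* No multiplicity adjustment is applied to the signal rule.
* Deduplication links only on CASEID; probabilistic record linkage across
  differing CASEIDs is out of scope.
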