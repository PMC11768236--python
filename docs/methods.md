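# Methods

`faersignal` implements the standard post-marketing pharmacovigilance
workflow for spontaneous-report databases of the FAERS family: build the
2×2 report-count table for every drug–event pair, estimate four
disproportionality statistics with their conventional signal criteria,
prioritize the detected signals clinically, compare serious and
non-serious reporting, and profile onset timing with a Weibull model.
This note records the models, the defaults and why they were chosen, the
numerical choices, and what the synthetic-data validation does and does
not establish.

## Data model and ingestion

A FAERS quarter is a set of `$`-delimited ASCII tables sharing a
`primaryid` (report version) and `caseid` (case). The parser is
header-driven, case-normalizes column names, and counts-and-skips rows
with the wrong field number rather than failing; every later
normalization failure likewise degrades to a missing value with a
warning counter, because spontaneous reports are entered by the public
and partial records are the norm, not the exception.

**Deduplication.** A case accumulates versions across quarters; keeping
all of them would double-count reports. The default strategy keeps, per
`caseid`, the version with the latest FDA receipt date (ties broken by
the larger `primaryid`) — the standard field practice. A
`primaryid-distinct` mode (drop exact version repeats only) is provided
for comparison with analyses that deduplicate on `primaryid` alone.
Deduplication is idempotent and child tables are filtered to the
retained versions.

**Units.** Ages are converted to years (`DEC`×10, `YR`×1, `MON`/12,
`WK`/52.1775, `DY`/365.25, `HR`/8765.82) and weights to kg
(`LBS`×0.45359237); unknown codes yield missing values. Dates are
`YYYYMMDD`; partial dates (`YYYYMM`, `YYYY`) resolve to the first
day/month but are flagged, and flagged dates are excluded from
time-to-onset by default since day arithmetic on them is artefactual.

**Counting unit.** A report contributes at most once to any 2×2 cell; a
report with *k* distinct PTs contributes one count to each of *k*
per-PT tables. "Serious" means the report carries at least one of the
outcome codes death / life-threatening / hospitalization / disability /
congenital anomaly / required intervention / other serious (the last
three are folded into `other_serious`).

## Disproportionality statistics

All four statistics are functions of the table (a, b, c, d) with
N = a+b+c+d, exposed margin a+b, event margin a+c.

* **ROR** = ad/bc, with the Wald interval
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)). Signal: a ≥ 3 and lower bound
  > 1. A zero cell makes the ROR undefined; the default is to refuse,
  with an optional Haldane–Anscombe +0.5 continuity mode (off by
  default, applied only to the frequentist pair of statistics).
* **PRR** = [a/(a+b)]/[c/(c+d)] with the Pearson χ² statistic
  N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)). Signal: a ≥ 3, PRR ≥ 2, χ² ≥ 4.
  The χ² has no continuity correction and is the *same function* used
  by the serious/non-serious comparison, so there is a single source of
  truth; that shared implementation reproduces the published
  canakinumab serious-vs-non-serious statistics to ±0.01.
* **BCPNN IC.** With Beta/Dirichlet priors (α₁=β₁=1, α=β=2, γ₁₁=1 and
  γ scaled to centre the joint cell on independence), the information
  component is IC = log₂ p₁₁/(p₁·p·₁) and the closed form is the cited
  method's moment expression:
  E(IC) = log₂[(a+γ₁₁)(N+α)(N+β)/((N+γ)(a+b+α₁)(a+c+β₁))], with the
  delta-method variance and IC025 = E(IC) − z·√V(IC), z = 1.96 by
  default (a 2.0 multiplier is available by configuration). Signal:
  IC025 > 0. IC025 > 3.0 is reported as a strong-intensity band and
  1.5 < IC025 ≤ 3.0 as medium. Note that this closed form summarizes
  posterior *moments*: it differs from the exact posterior mean/quantile
  of the IC distribution by ≈ 1/(2a·ln2) bits, negligible for well
  reported pairs (a ≳ 25) but visible for small counts. The test suite
  therefore validates the moment algebra by Monte-Carlo on arbitrary
  tables and the approximation against exact posterior sampling in the
  adequate-count regime.
* **MGPS EBGM.** DuMouchel's empirical-Bayes model: the relative
  reporting rate λ has a two-component gamma mixture prior (defaults
  a₁=0.2, b₁=0.1, a₂=2, b₂=4, w=1/3) and the observed count is Poisson
  with mean λE, E = (a+b)(a+c)/N. The posterior is again a gamma
  mixture; EBGM = exp(E[ln λ]) from digamma means and EBGM05 is the
  posterior 5th percentile solved by root bracketing on the mixture CDF
  (tolerance 10⁻⁹). Signal: EBGM05 > 2. The prior can be refit to the
  observed (a, E) collection by maximizing the marginal
  negative-binomial-mixture likelihood (L-BFGS-B on log/logit scales);
  a weight hitting the boundary is flagged as non-converged. Both
  fixed-prior and fitted-prior modes exist because published analyses
  rarely state which they used.

**Signal policies.** PT-level screening uses the strict conjunction of
all four criteria; SOC-level screening uses the disjunction (any one
criterion), matching the convention of reporting organ-class signals
more liberally than term-level ones. Both are named policies and
configurable. No multiple-comparison correction is applied — a
documented limitation of disproportionality screening generally.

## Clinical priority rubric

Each signal PT is scored 0–2 on five items and banded by the total:
weak ≤ 4, moderate 5–7, strong ≥ 8.

| item | 0 | 1 | 2 |
|---|---|---|---|
| case count a | < 10 | 10–50 | > 50 |
| ROR | < 2 | 2–<5 | ≥ 5 |
| death proportion | < 25% | 25–50% | > 50% |
| EMA listing | none | IME | DME |
| evidence grade | − | + | ++ |

The cut-points are a reconstruction: they reproduce all 71 published
per-PT canakinumab scores (44 weak / 27 moderate / 0 strong) from the
published attribute columns, which is the strongest consistency check
available without the original rubric text. Boundary placements inside
unobserved ranges are conventions: no published PT has a death
proportion between 25% and 50%, so whether the original scale had that
middle band at exactly these edges is unverifiable; the edges here are
explicit and configurable. A PT on both EMA lists scores as DME.

## Serious vs non-serious comparison

Per frequent PT (total count ≥ 30 by default) the serious and
non-serious groups are compared on reporting proportion. The test is
chosen from the observed with-PT cells: 0 → Fisher exact (two-sided,
conditional on margins), 1–4 → Yates-corrected χ²
(N·(max(|ad−bc|−N/2, 0))²/denominator, clamped at zero), otherwise
plain Pearson χ². This cell-size rule is itself a reconstruction that
reproduces every published per-row test choice. Age and weight use the
Mann–Whitney U with midranks, tie-corrected variance and no continuity
correction; only reports with the field present enter, with no
imputation.

## Time to onset

TTO = event onset date − therapy start date, in days. Exclusions, each
counted: missing either date, onset before start (input error), partial
dates (default), and onsets beyond the analysis window (default one
year, the study convention; configurable, including off). Same-day
onsets are retained as 0.5 days so the log-likelihood stays defined.

The two-parameter Weibull is fit by maximum likelihood: the shape β
solves the profile equation Σtᵢ^β ln tᵢ/Σtᵢ^β − 1/β − mean(ln t) = 0 by
safeguarded Brent on [0.01, 50] (tolerance 10⁻⁸), and the scale
α = (Σtᵢ^β/n)^{1/β} follows in closed form. 95% CIs are log-normal Wald
intervals from the observed information of the (ln α, ln β)
parametrization, computed by central finite differences (step 10⁻⁴); a
likelihood-ratio profile CI was considered and not implemented because
the normal approximation on the log scale is accurate at the sample
sizes where a fit is attempted at all (n ≥ 10 distinct values).
Failure profile: *early* iff β < 1 with CI entirely below 1, *wear-out*
iff β > 1 with CI entirely above 1, else *random*.

**Window caveat.** The one-year window *drops* (rather than censors)
long onsets. Fitting the truncated sample as if untruncated thins
exactly the tail that makes a sub-exponential shape visible and biases
β̂ toward 1 (see `examples/04_time_to_onset.py`, where a cohort with
true β = 0.9 fits at ≈ 1.0 windowed and ≈ 0.92 uncapped). Parameter
interpretation under the windowed convention should therefore be
comparative, not absolute; recovery tests in the suite run uncapped.
Quantiles (median, IQR) use linear interpolation (type 7), documented
because IQR values depend on the convention.

## Synthetic cohorts

The generator emulates the *structure* of FAERS extracts — the five
tables with realistic column names and codes, mixed age/weight units,
role codes, multi-PT reports, serious-outcome codes, duplicate case
versions with distinct receipt dates, and per-field missingness — with
every assignment recorded as ground truth. Default conditions, chosen
once as a study-like cohort at tractable scale: 20,000 reports per
quarter, 5% exposure to the target drug as primary suspect, a 16-PT
catalog dominated by infection terms with planted relative risks of
about 2–6 (some modified within demographic strata, e.g. stronger in
males, the old, and the heavy), onset times Weibull(α = 100 days,
β = 0.9), 10% duplicate case versions, and missingness heaviest for
dates (~35%) and weight, lightest for sex and country. A bimodal age
distribution (paediatric autoinflammatory plus adult) gives a median
near 18 years.

Events are assigned independently per PT given exposure and
demographics; co-reporting correlation, term-frequency realism, drug
co-prescription structure and reporting-delay dynamics are *not*
modelled. Passing the validation suite therefore shows that the
statistics recover planted effects under independent reporting with
FAERS-like missingness and duplication — not that real FAERS biases
(stimulated reporting, masking, indication confounding) are handled;
disproportionality has no answer to those and the package does not
claim one. `expected_tables` returns the analytic pre-sampling cell
expectations; when stratum modifiers are present the demographic
integral is evaluated on a fixed deterministic quadrature sample so the
expectation is independent of the cohort seed.

## Validation problem sizes

The suite validates: the published canakinumab severity and priority
tables exactly (rebuilt from printed counts); BCPNN against 10⁶-draw
posterior sampling (12-table suites); MGPS against numeric quadrature
on an (a ≤ 50) × (E ≤ 20) grid to 10⁻³; Fisher against full
hypergeometric enumeration for every 2×2 table with N ≤ 30; ROR CI
coverage at the null over 500 simulated tables (93–97% band); Weibull
shape recovery at n = 2000 and CI coverage over 300 replicates; and
end-to-end planted-signal recovery (RR = 5 flagged by all four
algorithms at 50,000 reports) with a null false-positive sweep of 200
replicate cohorts (≤ 1% of pairs flagged by all four). These sizes are
the package's own validation conditions and are fixed in the tests.

## Known limitations

No regression-based or shrinkage-logistic signal detection; no
censoring model for TTO; no MedDRA dictionary (PT→SOC and DME/IME lists
are user-supplied TSVs, as MedDRA is licensed); no indication-based
confounding control; no multiplicity adjustment. The serious/non-serious
comparison inherits whatever outcome-coding noise the reports carry.
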