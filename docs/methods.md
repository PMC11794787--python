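# Methods

## Study design

The pipeline implements a case/non-case (disproportionality) design on
a spontaneous-report database.  The unit of analysis is the
deduplicated safety report, used as a patient proxy.  *Cases* are
reports mentioning the target drug in a patient strictly under 18
years of age; *non-cases* are reports of other drugs.  Reports of the
target drug that fail the age filter (including missing age) belong to
neither group: counting them as background would let the drug's own
elevated reporting rates contaminate the comparator and bias every ROR
toward the null (we measured roughly a 5% downward bias at the default
synthetic conditions before adopting this rule).  A configuration
switch restricts the comparator to pediatric reports instead of all
ages; all ages is the default.

## Deduplication

FAERS distributes successive versions of one case (CASEID) under
distinct PRIMARYIDs across quarters.  Deduplication keeps, per CASEID,
the row with the highest FDA_DT, ties broken by the highest PRIMARYID,
then removes the CASEIDs listed in the quarterly deletion logs.  Rows
with unparseable CASEID or PRIMARYID are excluded and counted; a row
with an unparseable FDA_DT is kept but treated as FDA_DT = 0 so it
loses any tie to a dated version — preferring to retain *some* version
of a case over dropping it.  Child tables (DRUG/REAC/OUTC/THER) are
filtered to surviving PRIMARYIDs afterwards so reports stay coherent.
The operation is idempotent and order-independent (verified against a
brute-force group/sort/take-last reference).

## Terminology

MedDRA cannot be redistributed, so PT→SOC mapping is an input: a TSV
with columns `pt`, `soc`.  A CVAE is any PT mapping to *Cardiac
disorders* or *Vascular disorders*.  Unmapped PTs count as non-CVAE
and are tallied in the log rather than failing the run.  CRS detection
is PT-exact ("Cytokine release syndrome", case-insensitive), not
SOC-based, because CRS is a single term, not an organ class.
Concomitant drugs are grouped by ATC anatomical main group through a
second TSV (`drugname`, `atc1`); drugs absent from it fall into an
"other miscellaneous" flag.  The target drug itself is excluded from
the antineoplastic class flag — otherwise that flag is constant 1 in
the cohort and the design matrix is singular.

## Ages, dates, descriptive statistics

FAERS ages arrive in mixed units; they are converted to years with
DEC×10, YR×1, MON÷12, WK÷52.1775, DY÷365.25, HR÷8766.  Unparseable or
negative values become missing, and reports with missing age are
excluded from the pediatric cohort (strict `age < 18`).  Quantiles
throughout are linear-interpolation (type 7); SAS defaults differ
slightly, which can explain ±1-day discrepancies against published
medians at small n.

Time to onset is event date (DEMO.event_dt) minus the earliest
target-drug therapy start (THER.start_dt joined via dsg_drug_seq to
the target DRUG row), both required at full YYYYMMDD precision.
Partial dates are excluded, never imputed — mid-month imputation would
fabricate day-scale medians.  Negative differences are excluded and
counted.

## Statistics

- **ROR**: (a·d)/(b·c); 95% Wald CI on the log scale with z = 1.96.
  Signal rule: a ≥ 3 and lower CI bound > 1.  A zero cell leaves the
  ROR undefined unless the Haldane–Anscombe +0.5 correction is enabled
  (off by default; corrected results are flagged).  Event presence is
  binary per report.
- **Wilcoxon two-sample test**: rank-sum with midranks; exact
  enumeration when n_x + n_y ≤ 20 with no ties, otherwise the normal
  approximation with tie-corrected variance and 0.5 continuity
  correction.  Two-sided throughout; no multiplicity adjustment is
  applied anywhere, matching standard practice for hypothesis-generating
  pharmacovigilance screens (the test suite quantifies the induced
  false-selection rate instead).
- **Categorical contrasts**: Fisher's exact test whenever any expected
  cell is below 5, otherwise Pearson chi-square without continuity
  correction (a flag enables Yates).  The exact-test p-values are
  verified against full hypergeometric / rank-split enumeration in the
  test suite.
- **Two-stage logistic regression**: each candidate variable (age in
  years, sex as M=1/F=0, one indicator per ATC class) is screened in a
  single-covariate logistic model; variables with Wald p < 0.05 enter
  a joint fit.  The fitter is Newton/IRLS, converged when the largest
  coefficient change falls below 1e-8, capped at 100 iterations;
  standard errors come from the inverse observed information.  Under
  separation — routine in sparse strata — the last iterate is reported
  with a `separation` flag rather than raising.  Rows with missing age
  or sex are excluded listwise.  For the fatal-outcome analysis the
  cohort is restricted to CVAE reports, the cardiovascular
  co-medication class is dropped (it proxies treatment of the outcome),
  and age is additionally summarised with a two-sample t statistic
  alongside its logistic slope, both conventions being common for a
  continuous covariate at the screening stage.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not FAERS reporting dynamics (no stimulated reporting or Weber
effect).  Per report it draws: target-drug status (5%), pediatric age
(95% of target reports, 15% of others — the target drug is
pediatric-indicated), mixed-unit age encoding, co-medication class
flags, PTs from a catalog of cardiovascular and background terms,
CRS (91% given a target CVAE report), a log-normal time to onset
(median 4 / 2 / 7 days for fatal-CVAE / non-fatal-CVAE / non-CVAE,
σ = 1.1), death from a logistic model (age slope −0.0909 per year,
respiratory co-medication log-OR 0.6), duplicate report versions
(10%), deletion lists (2%) and partial event dates (10%).  Defaults
echo the published pediatric CAR-T setting: injected reporting odds
ratios of 30 (hypotension), 13 (tachycardia) and 4 (hypertension), and
a nervous-system co-medication effect of log-OR 1.53 on cardiovascular
PT odds.

Two details matter for recoverability.  First, the injected odds
multiplier is *calibrated to the marginal*: the odds ratio is
non-collapsible over covariate strata, so naively multiplying each
stratum's odds by ρ yields a marginal target-vs-background OR below ρ;
a one-dimensional root solve sets the per-report multiplier so the
marginal OR equals ρ exactly, which is what the pipeline estimates.
Second, all randomness flows through one seeded NumPy generator, so a
fixed seed and configuration produce byte-identical files.

What passing tests on generated data do **not** show: robustness to
real FAERS name variants (the generator emits clean drug names),
cross-quarter schema drift, free-text indication fields, or verbatim
PT misspellings.  The generator's referential integrity is perfect by
construction; the reader validates it but real extracts violate it.

## Problem sizes in the test suite

The statistical guarantees are measured at sizes chosen to make the
Monte-Carlo error small relative to the asserted bounds while keeping
a single-CPU run short: 1,000 null datasets of 20,000 reports for the
false-signal rate (expected a-cell ≈ 7.6), 100 seeds of 50,000 reports
for injected-ROR recovery, 1,000 random inputs for the dedup oracle,
full enumeration for the exact-test oracles (2×2 row margins ≤ 12;
rank problems to n = 10), and 200 seeds at n = 5,000 for logistic bias
and CI coverage.  The acceptance script uses the same machinery at
slightly smaller replicate counts.

## Known limitations

- The Wald CI for the ROR is poor at very small cells; no exact or
  shrinkage (EBGM/IC) alternative is implemented.
- Logistic regression is unpenalised; quasi-separation yields flagged
  but unstable estimates (no Firth correction).
- Report-level counting treats one report as one patient; linked or
  follow-up reports under different CASEIDs are not detected
  (no probabilistic duplicate detection).
- The comparator construction supports all-age or pediatric-only
  backgrounds; active-comparator designs are out of scope.
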