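# Methods

`pvsweet` implements a complete pharmacovigilance signal-detection workflow
for drug-induced Sweet's syndrome (DISS, acute febrile neutrophilic
dermatosis; MedDRA PT "Sweet syndrome", code 10042458) on FAERS-style
spontaneous-report data, together with a synthetic-report generator that
makes every stage testable against known truth. This note records the
statistical model at each stage, the defaults and why they were chosen, the
numerical conventions, and what the synthetic data can and cannot certify.

## Report model and deduplication

A corpus is seven relational tables keyed by PRIMARYID: demographics (DEMO),
drugs (DRUG), reactions (REAC), outcomes (OUTC), report sources (RPSR),
therapy dates (THER), indications (INDI), arriving as $-delimited quarterly
ASCII with one header row. Headers drifted across quarters; a configurable
alias map (`pvsweet.schema.COLUMN_ALIASES`, e.g. `GNDR_COD → sex`) folds
known variants onto a canonical lowercase schema, and unknown columns pass
through untouched. Text is decoded as UTF-8 with a latin-1 fallback because
real quarterly files mix encodings. Rows with the wrong field count are
counted and logged; a per-file malformed fraction above 1% (configurable)
raises rather than silently dropping data.

Duplicate submissions share a CASEID. Retention follows the FDA rule: keep
the most recent FDA receipt date (FDA_DT); on ties, the highest PRIMARYID.
Partial receipt dates (YYYY or YYYYMM) are compared after right-padding to
the earliest date they could denote (YYYY → YYYY0101): this yields a
deterministic total order without inventing precision. Reports lacking a
CASEID cannot be matched to anything and are kept as singletons, with the
count reported. The operation is idempotent and order-independent, and every
drop is recorded with its reason (`older_fda_dt` / `lower_primaryid`).

## Case definition and cohort construction

Cases are reports whose REAC rows contain the target PT (exact,
case-insensitive match; a flat PT vocabulary — no MedDRA hierarchy or SMQ
expansion). Exposure is attributed to primary-suspect (PS) drugs only by
default, configurable to other role codes. When a report carries several PS
drugs, exposure is attributed to all of them (configurable to first-listed);
multi-PS attribution is the conservative choice for screening since it never
hides an exposure.

Drug names are standardized by a synonym table (trim, case-fold, collapse
whitespace, then lookup) with unmapped names passed through and flagged —
nothing is silently dropped. The bundled synonym and ATC tables cover the
built-in catalog and common brand names; they are deliberately small,
editable TSVs, not a licensed dictionary, and real analyses should supply
their own. Combination products ("sulfamethoxazole/trimethoprim") are single
entities, matching how they are reported.

Indication-related confounding is handled by three predefined analytical
datasets: `main` excludes reports with malignancy-related and/or
immune-related indications, `sensitivity_A` excludes only malignancy-related,
`sensitivity_B` only immune-related (`full` keeps everything). Term lists
are configurable (defaults bundled, substring matching by default; the two
lists may overlap, so classification returns flags, not a partition).
Reports with no INDI rows are retained in every scheme — an exclusion
criterion cannot be evaluated on missing data — and by construction the
main-retained set equals the intersection of the two sensitivity retentions,
which the tests assert on randomized fixtures.

## Descriptive statistics

Count tables always show an explicit Missing row and percentages of the full
universe, rounded half-up to two decimals (the rendering regulatory tables
use). Numeric summaries report mean (SD) and median [Q1, Q3] over
non-missing values with linear-interpolation quartiles. Chi-square tests on
ATC class × sex (or age band) cross-tabulations use the Pearson statistic
without continuity correction — the tables involved are large (e.g. 14
classes × 2 sexes, df 13) — after dropping missing categories, with expected
counts returned for diagnostics and zero margins raised by level name.
Annual trends are ordinary least squares of yearly report count on calendar
year per drug class, with years inside the observed span but without reports
counted as zero; at least three distinct years are required.

## Time-to-onset

Latency is days from the suspect drug's therapy start to event onset, using
only complete 8-digit dates on both ends; negative intervals are excluded
and counted, and the completeness fraction is reported (in large
spontaneous-report cohorts of this event only ~¼ of cases have computable
latencies). With several therapy episodes for the suspect drug, the earliest
start date is used — the conservative, longest-latency attribution.
Latencies above 1,000 days are retained (a truncation flag exists).

Summaries use median and quartiles by the exclusive median-of-halves rule
(the halves exclude the median when n is odd), the convention under which a
small sample like {7, 22, 98} reports IQR 7–98; bin percentages over
{0–30, 31–60, 61–90, 91–180, 181–365, >365} days (edges configurable) sum
to 100 before rounding. The parametric model is a two-parameter Weibull
fitted by maximum likelihood (`scipy.stats.weibull_min`, location fixed at
0); same-day onsets are shifted to 0.5 days so the acute-onset mass stays in
the likelihood. Degenerate samples (all equal) and non-convergence are
flagged, never raised. The MLE inherits the scale equivariance of the
family (scaling latencies by c scales λ̂ by c and leaves k̂ unchanged),
asserted in tests at c = 7.

## Disproportionality

For drug *D* and event *E* over a universe of N deduplicated reports the
report-level 2×2 table is a = D∧E, b = D∧¬E, c = ¬D∧E, d = neither (a report
counts once per cell). The reporting odds ratio is ROR = ad/bc with the Wald
interval exp(ln ROR ± z₀.₀₂₅ √(1/a+1/b+1/c+1/d)). No continuity correction
is applied by default — a zero cell yields an undefined-estimate flag — with
Haldane +0.5 available by option, since the ROR formula presumes non-zero
cells. Two-sided p-values are Fisher's exact test under the point-probability
convention (sum of fixed-margin table probabilities no larger than the
observed), which the tests pin against exhaustive enumeration. Adjustment is
Benjamini–Hochberg across the family of all drugs with at least one case in
the analyzed universe (the family is configurable). A positive signal
requires at least 3 cases (strict > 3 available) and CI lower bound > 1.
The medical-doctor-subset rerun restricts the universe by OCCP_COD before
anything is counted, so subset analyses share the exact code path, as does
the external-corpus replication.

## LASSO selection and logistic refinement

Candidate predictors are age, sex, and the positive-signal drugs of the
scheme's screen. The L1-penalized logistic path uses the glmnet λ
convention (liblinear's C = 1/(nλ)) on standardized predictors over 100
log-spaced λ values spanning 4 decades down from λ_max =
max|xⱼᵀ(y−ȳ)|/n, with stratified 10-fold cross-validation (the outcome is
rare, so unstratified folds would be degenerate). λ_min maximizes mean CV
AUC; λ_1se is the largest λ within one standard error of the optimum. A
deviance-based criterion is also implemented (CV curves for penalized
logistic models are often displayed as binomial deviance) and selectable;
AUC is the default. Constant predictors are dropped with a log line;
separation is left to the penalty.

Variables selected at λ_min are refit by unpenalized maximum likelihood
(statsmodels). Wald CIs on the log-odds scale are exponentiated to odds
ratios; per-variable p-values are BH-adjusted within the model; a drug is
significant when adjusted p < 0.05 and the OR CI lower bound ≥ 1.
Modeling rows are complete cases on age and sex (no imputation), with the
dropped count reported prominently. Non-convergence and separation are
flagged (absurd Wald SEs > e³ also trip the flag); a rank-deficient design
raises with the collinear columns named. In-sample AUC is the tie-corrected
Mann–Whitney statistic with a DeLong interval, falling back to a seeded
bootstrap (2,000 resamples) when the DeLong variance degenerates. The
in-sample AUC of the λ_min refit is at least that of the sparser λ_1se
model by construction, asserted on fixtures. By default all non-case
reports in the scheme's dataset serve as controls (no sampling); a seeded
k:1 control subsample is available for very large corpora.

`run_all_schemes` executes screen → LASSO → logistic per scheme, emits a
forest-plot table (OR, CI, adjusted p per scheme) and the cross-scheme
intersection of significant drugs; given a seed the whole run is
bit-reproducible.

## Co-occurrence network

Over case reports, nodes are drugs (all role codes by default — suspects are
co-reported with their co-medication; PS-only is an option) and edge weight
is the number of case reports listing both drugs, each report contributing
once per pair. Edges below weight 3 are pruned by default, matching the
case-count threshold used elsewhere; both the weight definition and the
threshold are artifact conventions, stated here because spontaneous-report
networks have no canonical definition.

## External consistency

The replication corpus enters through a minimal 4-column schema (report_id,
drug, role, pt) — the shape any licensed database extract can be reduced to
— and is screened by the same code path as the primary corpus, with the
same signal rule (n ≥ 3, CI lower bound > 1). Literature support and
product-label listings are inherently manual review products; they enter
only as a curated annotations TSV and are never scraped. The evidence
matrix has one row per main-model drug with flags and counts per source.

## Synthetic data: what it emulates and what it does not

The generator produces the seven tables with: one PS drug per report drawn
uniformly from a 40-drug catalog plus 0–4 distinct concomitants (giving the
network nontrivial structure); a rare target PT against ~30 background PTs;
demographic missingness matching large published FAERS cohorts of this event
(age 22.6%, weight 84.5%, sex 10.3%, reporter 4.6%, indications 6.3%);
reporter mix dominated by medical doctors (41.2%); dates as YYYYMMDD with a
configurable fraction degraded to YYYYMM/YYYY to exercise partial-date
handling; Weibull onset latencies for cases (default shape 0.9, scale 40
days — a right-skewed acute-onset profile with median ≈ 27 days, chosen as
realistic for this event); and duplicates injected by cloning a report
under a new PRIMARYID with a later receipt date, exercising exactly the
retention rule. Date completeness defaults (event 65%, therapy start 45%
present) put joint latency availability near one quarter of cases.

Planted signals are specified on the odds-ratio scale against the pooled
comparator — the ROR estimand — and the exposed-event probabilities are
calibrated by a fixed-point iteration so each planted drug's odds ratio
against its own comparator equals the configured multiplier even when
several drugs are elevated at once. Unplanted drugs keep the background
event rate (their ROR sits marginally below 1 when elevated drugs inflate
the comparator, which only makes the null-flagging checks conservative).

What passing tests on synthetic corpora do **not** show about real data:
name standardization here faces clean catalog names plus a small brand-name
table, not FAERS free text; indications are drawn from flat per-drug pools,
so indication confounding is far tamer than real channeling bias; reporting
rates have no secular trends, country effects, or event-dependent
missingness; duplicates are exact clones, whereas real duplicates differ
across submissions. Operating characteristics measured here (power, type-I
rate of the screen, LASSO recovery) are properties of the method under the
stated generative conditions, not estimates of real-world performance.

## Problem sizes and numerical conventions

Acceptance-level checks use corpora of 20,000–100,000 reports (screen
operating characteristics at 100,000 × 5 seeds; LASSO recovery at 20,000 ×
5 seeds with ≥ 30 exposed cases per planted drug; Weibull recovery at
≥ 5,000 latencies × 5 seeds), sizes at which the planted effects are
comfortably identified while a full run stays in the minutes range on one
CPU. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); reruns with the same configuration and seed
are byte-identical. Percentages round half-up at two decimals; BH adjusted
values are capped at 1; the λ path length, CV fold count, bin edges,
thresholds (case count, CI bound, FDR family) are all exposed as arguments
with the defaults stated above.

## Known limitations

No ISR-era (pre-2012 headers beyond the bundled aliases) auto-detection; no
CASEVERSION/nullification semantics beyond the stated retention rule; no
PRR/IC/EBGM estimators (the ROR is the estimand throughout); no hazard-shape
classification of the Weibull fit (reported descriptively); the in-sample
AUC of the final logistic model is optimistic by construction and is
reported as such, with the cross-validated curve available from the LASSO
stage.
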