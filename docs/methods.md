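# Methods

## The statistical problem

Spontaneous reporting systems such as FAERS collect individual case
safety reports (ICSRs) without a denominator: there is no population at
risk, only reports. Disproportionality analysis therefore asks whether a
drug–event pair is reported *more often than expected* given the rest of
the database. For one preferred term (PT) the data collapse to a
fourfold table over distinct (report, PT) records:

|              | target AE | other AEs |
|--------------|-----------|-----------|
| target drug  | a         | b         |
| other drugs  | c         | d         |

with N = a + b + c + d. The counting unit is the record, not the
report: one report contributes once per distinct PT, and a report whose
suspect drug matches the target labels *all* of its records as
target-drug records (no per-PT attribution is attempted — standard
practice, since the reporter's suspicion is report-level).

## The four algorithms, simplified forms

* **ROR** (reporting odds ratio) = ad/bc, with Woolf-type log-normal
  95% CI: exp(ln ROR ± 1.96·√(1/a + 1/b + 1/c + 1/d)).
* **PRR** (proportional reporting ratio) = a(c+d)/(c(a+b)), accompanied
  by the Pearson χ² of the table, without continuity correction:
  χ² = (ad − bc)²·N / ((a+b)(c+d)(a+c)(b+d)).
* **BCPNN information component** IC = log₂(a·N/((a+c)(a+b))), the log₂
  observed-to-expected reporting ratio.
* **MGPS EBGM** = a·N/((a+c)(a+b)), the same observed-to-expected ratio
  on the linear scale.

These are deliberately the *simplified point estimates*: no
gamma-Poisson shrinkage for EBGM and no Bayesian posterior for IC.
Consequently EBGM = 2^IC holds identically, which the test suite checks
as an algebraic invariant and which published SOC-level tables in this
style reproduce (an IC of 1.18 prints alongside an EBGM of 2.27 = 2^1.18
rounded). Interval bounds for IC and EBGM use the same log-normal recipe
as the ROR applied to the observed/expected ratio; IC025 is the log₂ of
the EBGM lower bound, which preserves the equivalence
IC025 > 0 ⇔ EBGM lower bound > 1.

Signal criteria (a pair is a *signal* when all four hold):
ROR CI lower bound > 1 with a ≥ 3; PRR > 2 with χ² > 4 and a > 3;
IC025 > 0; EBGM05 > 2 with N > 0. The conjunction is conservative by
design; the null-calibration experiment below measures how conservative.

Useful consequences the tests exploit: at independence
(a/(a+b) = c/(c+d)) all four estimates sit at their null values; the
ordering sign(ROR − PRR) = sign(ROR − 1) follows from
ROR/PRR = d(a+b)/(b(c+d)); all four are strictly increasing in a at
fixed b, c, d.

### Zero cells and undefined values

Any zero cell leaves the ROR (and the shared standard error) undefined;
c = 0 leaves the PRR undefined; a = 0 sends IC to −∞. Undefined values
are carried as NaN (−∞ for IC), never silently replaced, and force the
corresponding signal flag to False. An optional Haldane–Anscombe
correction (+0.5 on every cell of tables containing a zero) can be
enabled per run (`zero_cell_policy="haldane"`); it is **off** by
default because the plain formulas are the reference behaviour.

One ambiguity in the MGPS criterion ("N > 0") is resolved as the table
total N; the alternative reading (case count a) is never binding in
practice because EBGM05 > 2 already requires a ≥ 1.

### Rounding

Machine outputs keep full float precision. Display columns round to two
decimals *half-up* (`round_half_up`), matching the convention of
published signal tables; banker's rounding would disagree on exact
halves such as 2.265.

## Deduplication

A FAERS case accrues report versions over time. Per the FDA rule the
pipeline keeps, for each CASEID, the version maximal under the
lexicographic order (FDA_DT, PRIMARYID); a missing FDA_DT sorts below
every real date, so a dated version always beats an undated one (the
conservative completion of the rule, which presumes comparable dates).
Cases on the optional deleted-case list are then removed entirely.
The operation is idempotent and order-independent, and the test suite
checks it against a brute-force group-and-scan oracle on fixtures with
engineered ties.

## Time-to-onset

Onset = event date − earliest full therapy start date of the
keyword-matched primary-suspect drug. Only full YYYYMMDD dates on both
sides qualify; month- or year-precision dates are *excluded, not
imputed* — imputing a mid-month day would fabricate onsets near month
boundaries. Events dated before therapy start are excluded as
pre-treatment. The event date field is EVENT_DT by default
(config-overridable). Quantiles use linear interpolation between order
statistics (numpy's default), the convention that produces fractional
quartiles such as 265.75. "First month" means ≤ 30 days; "over one
year" means > 365 days; the histogram uses 30-day bins to 360 days plus
a > 360 tail bin.

## Sex-stratified signals

The default contrast runs the full four-algorithm battery *within* each
sex stratum: target drug vs all other drugs, restricted to reports of
that sex. Unknown-sex reports are excluded from strata but retained in
pooled analyses, so per-PT counts satisfy
a_female + a_male + a_unknown = a_pooled. An alternative contrast —
female vs male reporting within target reports — is available via
`contrast="between_sex"` for sensitivity analysis; the within-stratum
battery is the default because "PTs meeting all four criteria per
stratum" only parses under it. Rows are ranked by stratum frequency
with a configurable top-k (default 30).

## The synthetic generator

The generator emulates the features of a FAERS extract the pipeline
must survive: multi-table structure keyed by PRIMARYID/CASEID,
duplicate report versions with later (or tied) FDA dates, deleted
cases, drug roles (PS/SS/C), several PTs per report, partial and
missing dates, mixed age units, and configurable demographics. What it
does **not** emulate: real MedDRA vocabulary (PT/SOC names are
synthetic), drug co-prescription structure, reporting-rate secular
trends, and duplicate reports that differ in content (duplicates are
re-emissions). Passing tests therefore demonstrate correctness of the
*method* under known ground truth, not performance on real FAERS
idiosyncrasies.

**Injection model.** Each report draws k PTs (k = 1 + Poisson) from a
categorical lexicon with Zipf-shaped weights. An injected signal
multiplies the target PT's weight in matching reports. Because the
remaining weights are untouched, the within-record odds of that PT are
multiplied exactly, so the population record-level ROR equals the
configured multiplier — signal recovery has a closed-form truth. Two
second-order effects are worth knowing: (i) within-report duplicate
draws are collapsed by the event table, a negligible bias for
tail-weight PTs; (ii) multiple simultaneous injections compete — each
inflated weight enters the others' denominators (masking, as in real
spontaneous-report data). The `paper_like` preset places its injected
PTs deep in the Zipf tail so the combined inflated mass is ~3%.

**Presets.** `minimal` (100 reports — smoke input); `null` (4,000
reports, no injection — calibration); `sex_specific_signal` (12,000
reports, one PT at odds ×20 in female target reports only);
`paper_like` (180,000 reports, 5% target share ≈ 9,000 target reports,
sex mix 51.3/35.6/13.1% F/M/unknown, elderly age mixture centred in
65–84 with 24.7% missing, ~2.9 PTs per report, log-normal onset with
median 49 days and σ = 1.4, date-missingness tuned so roughly a third
of target reports yield usable onsets, 5% duplicate cases, 0.5%
deletions, three injected signals at odds ×32, ×11, ×2.5). The 5%
target share matters: EBGM is an observed/expected ratio, so a drug
that dominates the database caps it at 1/share; real target drugs are a
tiny fraction of FAERS and the preset respects that.

Reproducibility: one master seed drives independently spawned
per-concern random streams, so identical (seed, config) produce
byte-identical files, and adding a field to one table does not perturb
the others.

## Calibration experiments (validation module)

Problem sizes are the package's chosen simulation scales:

* **ROR recovery** — 100 replicates of 20,000 reports; one injected
  signal at odds ×11 whose baseline weight puts the expected
  target-event count near a = 50. Checked: 95% CI coverage of the true
  multiplier (nominal band 92–98 of 100) and unbiasedness of mean
  log-ROR within Monte-Carlo error. Measured across 500 independent
  seeds the coverage of this procedure is ≈95%.
* **Null calibration** — 500 replicates of 4,000 reports with nothing
  injected; the observed all-four-criteria flag rate among PTs with
  a ≥ 3 is reported (it is essentially zero — the conjunction, and
  EBGM05 > 2 in particular, is very conservative at these counts).
* **Sex-specific recovery** — 20 replicates of the female-only ×20
  injection; detection means flagged by all four criteria in the female
  stratum and unflagged in the male stratum.

Per-replicate seeds derive from one master seed, so a single integer
reproduces each study.

## Numerical and engineering choices

* Statistics are evaluated in one vectorised kernel; scalar per-table
  calls and batch tables share it, so batch = scalar by construction
  (still asserted in tests).
* Identifiers are opaque integers; ordering is only used where the
  dedup rule demands it.
* PT strings are normalised (trim, collapse whitespace, casefold) for
  joins; verbatim casing is preserved for display.
* The `$` dialect has no quoting; lines whose field count disagrees
  with the header (e.g. embedded `$` in free text) are skipped and
  counted, never guessed. Load reports conserve line counts.
* Age conversion to years: DEC ×10, YR ×1, MON ÷12, WK ÷52.1775,
  DY ÷365.25, HR ÷8766; negative ages become missing and are counted.
* No multiple-testing adjustment is applied (none is standard in this
  workflow); the number of tests performed is available from the table
  sizes.

## Known limitations

* The Bayesian methods are their simplified non-shrinkage forms; with
  shrinkage, small-count estimates would pull toward 1 and EBGM = 2^IC
  would no longer hold exactly.
* Disproportionality measures reporting association, not incidence or
  causality; the synthetic generator reproduces that logic, so no claim
  about real-world risk follows from recovery results.
* The vocabulary map is flat PT → SOC; no MedDRA hierarchy levels in
  between, and unmapped PTs fall into an `UNMAPPED` SOC by default.
* Pre-2004 ISR-era FAERS schemas and the XML dialect are out of scope.
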