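# Methods

## The construction pipeline

The package assembles a disease e-cohort from four linked routine-data
tables keyed by a pseudonymous person identifier. The stage order is fixed
— demographics cleaning, mortality cleaning, birth-window inclusion,
linkage flagging, code-list phenotyping, diagnosis-date validation, table
assembly — because per-rule exclusion counts depend on it: a person failing
two rules is attributed to the first rule applied, and the flow table
(`flow_diagram`) enforces that input − Σ exclusions = final cohort size as
a hard invariant, not a report.

### Cleaning rules and boundaries

All window boundaries are strict, reading "before"/"after" literally:

| rule | excludes | boundary behaviour |
|---|---|---|
| `dob_before_1900` | persons with date of birth < 1900-01-01 (or missing) | 1899-12-31 out, 1900-01-01 in |
| `missing_gp_registration` | persons with no registration spell or a spell missing its start date | an *open end* (still registered) is valid |
| `death_date_out_of_range` | mortality **records** (with their cause codes) dated < 1980-01-01 or > 2020-01-01 | both boundary dates kept |
| `invalid_dementia_date` | **persons** whose diagnosis date falls outside 1900-01-01..2018-01-01 | participant-level: an uninterpretable diagnosis date makes the whole record untrustworthy |

When a person's mortality record is discarded (or absent), the death date
falls back to the demographic-register (WDSD) date. Two conflicting valid
mortality records keep the earlier date with a logged warning; the later
record's cause codes are discarded with it, keeping record accounting
closed. The diagnosis-date window is configurable because its upper end
tracks the administrative end of the data extract.

### Eligibility and follow-up

Birth window 1900-01-01..1958-01-01, inclusive at both ends (the upper
bound encodes "60th birthday within follow-up" for data ending January
2018). Entry = earliest spell start; exit = min(latest spell end or the
administrative end for open spells, resolved death date, administrative
end, default 2018-01-31 since only the month is fixed by the data).
Follow-up is `(exit − entry in days)/365.25`. Gaps between registration
spells count as follow-up by default — entry and exit define one interval;
`gap_censoring=True` sums only spell-covered time instead. Persons whose
entry would follow their exit are excluded as `zero_follow_up`.

Linkage quality strictly below 0.95 on any dataset sets a flag and never
excludes, so users can apply their own sensitivity analyses.

### Phenotyping

A code list is a set of rows `(system, pattern, match_mode, condition,
category)`. ICD-9/ICD-10 values are normalized by dot-removal and
upper-casing (dots are formatting, and ICD is case-insensitive); Read v2 is
case-sensitive with trailing-dot padding stripped and a 5-character limit —
longer code+term strings are rejected and counted as unparseable rather
than truncated, because truncation silently changes match semantics. Each
row carries its own match mode since validated lists mix chapter-level
(prefix) and leaf (exact) codes. Matching is order-independent and the
indexed matcher is tested against a brute-force per-entry scan.

Mortality cause codes are matched under the era-appropriate system: ICD-9
for deaths before 2001-01-01, ICD-10 on or after. Hospital events are dated
at admission (the only date the episode carries here).

Case resolution: diagnosis date = minimum event date over *all* of a
person's matching events (a later subtype code never moves the date);
subtype flags = union of non-empty categories over all events, explicitly
non-exclusive (a person with AD and VaD codes is in both groups); first
source = source of the earliest event, same-date ties broken by the fixed,
configurable priority GP > hospital > death certificate — the ordering is
arbitrary but deterministic, which is what reproducible counts require.

### Summaries

Birth-decade strata are 1900–1910 (11 years, as conventionally printed),
then 1911–1920 … 1951–1960, inclusive edges. Missing sex/quintile is its
own stratum. Printed percentages round to the nearest integer, half away
from zero — the convention that reproduces every published pair we checked.
Medians use the lower median for even counts; with zero cases, medians are
reported absent, never zero. The mixed-dementia percentage uses the
subtyped-cases denominator, consistent with the per-subtype percentages.

## The synthetic generator

`SimConfig` defaults define the study conditions:

* **Population**: uniform dates of birth over 1895-01-01..1975-01-01 —
  deliberately wider than the eligibility window so inclusion exclusions are
  exercised; sex 52% F with a tiny missing rate (0.0005); deprivation
  quintile uniform with 2% missing; one GP registration spell starting
  uniformly in 1991–2000 (matching a mid-90s median first registration),
  with 12% of surviving non-cases de-registering early and 5% carrying a
  two-spell history with a gap.
* **Dementia onset**: hazard `h(a) = 0.002 · 2^((a−60)/6)` per year, no
  onset before age 40, left-truncated at registration (participants are
  dementia-free at entry, so all cases are incident during follow-up).
* **Background mortality**: Gompertz hazard 0.025/yr at 60 doubling every
  8 years, conditioned on surviving to registration. This is deliberately
  above period life-table values: together with the onset hazard it
  calibrates the cumulative case fraction to ~10% of the eligible
  population, the headline property the generator is asked to emulate.
* **Post-diagnosis mortality**: cases die before the administrative end
  with probability 0.79, at onset plus a truncated-exponential survival
  time (mean 3.5 years).
* **Recording**: each source identifies a case with the unconditional
  target probabilities GP 0.61, hospital 0.78, death certificate 0.40.
  Death-certificate coding requires dying with a mortality record, so the
  internal conditional probability is
  `0.40 / (0.79 · (1 − 0.07))` — 7% of deaths are known only to the
  demographic register, exercising the fallback rule. GP and hospital first
  codes lag onset by truncated-exponential delays (means 1.0 and 1.5
  years) clipped into each source's observable window.
* **Subtype sets** are drawn per case: none 0.40, AD-only 0.305, VaD-only
  0.215, AD+VaD 0.065, DLB 0.01, FTD 0.005 — chosen so the downstream
  percentages land near 60% subtyped, ~60% AD and ~47% VaD of subtyped, and
  ~11% mixed. Every true subtype is coded in exactly one recorded source,
  so with all sources recording, ascertained subtype sets equal the truth.
* **Dirty records** are injected disjointly (one permutation, binomially
  sized slices): each excluded person is attributable to exactly one defect,
  which is what makes exact excluded-ids == injected-ids recovery testable.
  Concrete defect forms: dob moved to the 1880–1899 range; death dates
  moved (or bogus records added) outside 1980–2020; registration starts
  blanked or spells removed; an all-cause dementia code dated in the 1890s
  appended so the person's earliest code is invalid.

Concrete event codes are derived from the loaded code list itself
(`code_catalog`): candidate values are kept only if matching them back
against the full list yields exactly the intended category, so generated
events can never encode an unintended subtype regardless of how the
fixture list's prefixes overlap.

### What the generator does not emulate

No geography or area-level deprivation structure; no QOF-era coding surges
(a delay-scale change can approximate one); no probabilistic-linkage
mechanics (quality scores are drawn directly); no secular trends in
incidence; recording probabilities are independent across sources, whereas
real sources are positively correlated. Passing recovery tests therefore
show the *pipeline* is correct under the assumed structure, not that the
code lists or the structure match any real population.

## Test and problem sizes

Recovery suites run on 20,000-person populations with fixed seeds: clean
runs use a birth window identical to the eligibility window and a
diagnosis-date window ending at the administrative end, so exclusions
cannot interact with recovery denominators; the dirty run injects 5% of
each defect. Binomial checks use 3-standard-error bands around the
configured parameters. The brute-force diagnosis-date oracle scans 1,200+
persons record by record with independent per-entry matching. The
acceptance script simulates 20,000 persons with the default (wide) birth
window and 5% dirty rates and reports the quantities the pipeline computes;
at this size every percentage it prints is stable to a few points across
seeds.

## Known limitations

* The shipped code lists are illustrative fixtures in the real systems'
  style, not validated research lists.
* Hospital episodes carry a single admission date; discharge-date or
  episode-position handling is out of scope.
* No support for multi-code case definitions (≥2 codes), prescriptions, or
  free-text phenotyping; these are user-side extensions via custom lists.
* Follow-up gaps are counted as observation time by default; studies
  sensitive to intermittent registration should enable gap censoring.
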