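# Methods

## The decision-support model

The engine models point-of-care decision support for first-line
pharmacologic management of neuropathic pain (NP) as three cooperating
layers.

**Knowledge representation.** Clinical logic is a flat list of boolean
derivation rules and conditional comments over named variables. Inputs
(`<drug>_tx` for current NP drugs, `<comorbidity>_hx` for chart
comorbidities) are bound by program code before the logic runs; rules
derive class-level facts (e.g. `tca_tx`); comments attach text to report
locations under per-route conditions with per-route sort orders. There is
deliberately no arithmetic, no dates, and no non-boolean state in the
language: everything temporal or numeric is resolved by the extraction
layer, which keeps the KB auditable by a clinician.

**Execution.** The KB compiles once into an immutable plan — every rule
in declaration order, then every comment route in declaration order, each
condition lowered to a postfix stack program. Rule execution is a single
pass, mirroring straight-line generated code rather than fixpoint
iteration; a validator rejects KBs where a rule reads a derived variable
before the rule that assigns it, which makes the single-pass/fixpoint
distinction unobservable for accepted KBs. Later rules may overwrite
earlier targets (last write wins, deterministic by order). Within a
location, placed comments sort ascending by their `order` key; equal keys
keep declaration sequence (stable sort); a comment appears at most once
per location, the first winning route deciding its order there. A missing
input binding defaults to false with a logged warning — in chart-derived
data, absence of evidence is recorded as absence of the finding.

Because the compiled plan and the direct AST interpreter are two
independent execution paths over the same semantics, their agreement is
checkable by brute force: tests enumerate all `2^n` input assignments of
randomly generated KBs and require identical derived values and
placements from both.

**Fact override.** The clinician may check or uncheck any comorbidity
checkbox; this re-binds one input with `override` provenance and re-runs
the whole plan. Full re-evaluation of a desk-scale KB takes tens of
microseconds, so no incremental truth maintenance is attempted.

## EHR condensation

The staging pass emulates a nightly batch over the full record:

* **Comorbidity bits.** ICD9 dotted-code prefix match: prefix `311`
  matches `311` and `311.x` but not `3110`; prefix `250.6` matches
  `250.60`. The shipped comorbidity→prefix map is editable configuration;
  its prefix sets must be disjoint across comorbidities (checked at
  load). The clinical adequacy of the code lists is a configuration
  concern, not an engine property.
* **Five-year medication lookback.** The window is the closed interval
  `[as_of − 5 years, as_of]` (calendar-year subtraction, Feb 29 → Feb 28);
  an order counts if any part of its active span overlaps the window, so
  an order ending exactly five years before `as_of` is included and one
  ending a day earlier is not. A pinned test fixes this boundary.
* **Currency.** A medication is *current* when its status is `active` and
  its span covers `as_of`; a discontinued order is never current even if
  its span covers `as_of`. Drug names are normalized (lowercase, trim,
  salt suffixes from config stripped) before taxonomy lookup.
* **Freshness.** The store records its build date; queries against a
  store older than 36 h (configurable) log a staleness warning, standing
  in for the nightly scheduler without requiring one.
* **Record hygiene.** Rows with unparseable dates, end-before-start
  spans, or future-dated diagnoses are rejected individually and counted;
  the build continues.

Staging is by construction a pure cache: tests compare every staged
answer on a 1,000-patient cohort against an independently written direct
scan of the full tables and require zero discrepancies, and rebuilding
from identical inputs is byte-identical.

## Synthetic cohorts

The generator produces the three EHR tables (patients, diagnoses,
medication orders) the extractor consumes. Each patient realizes exactly
one medication scenario — drug-naive (30%), first-line only (35%),
first-line plus an opioid/tramadol (15%), third-line (8%), or past
first-line only (12%) — and draws each comorbidity independently
(defaults: depression 30%, heart disease 25%, diabetes 30%, renal 10%,
liver 5%, substance abuse 10%, glaucoma 5%, seizure disorder 3%; ages
35–90, 90% male, reflecting a veteran primary-care population where NP
management and its comorbidity burden are typical). Twenty percent of
diagnosis rows carry decoy ICD9 codes mapping to no comorbidity, so the
prefix matcher's negative path is always exercised.

Randomness is one `numpy` substream per patient, keyed by
`(seed, patient index)` via `SeedSequence.spawn`, so results are
insertion-order independent and byte-reproducible for a fixed seed.

What the generator does **not** emulate: longitudinal disease
trajectories, dose titration, coded-vs-free-text noise in drug names
beyond salt suffixes, and coding errors other than the injected decoys.
Passing tests therefore demonstrate the engine's correctness on
structurally faithful data, not the clinical accuracy of any shipped code
list or comment text on real charts.

## Report assembly and rendering

The report is a pure function of demographics, the evaluated fact set,
the regimen summary, and the placement map: header with
provenance-labelled comorbidity checkboxes, current NP medications with
dose text, other NP medications from the lookback (current drugs are
excluded from the "past" list), the Comments/Recommendations section, a
per-category outline of first-line management, and a static-link
registry. Hover boxes are rendered as expandable `<details>` sections in
static HTML; JSON, HTML, and plain text renderings carry identical
comment texts in identical order, byte-for-byte equal to the KB `Text`
strings. Assembly refuses placements to locations the layout does not
display, catching KB/layout drift early. The scope warning (fixed text)
appears exactly when the current regimen includes a second- or third-line
drug.

## Problem sizes and numerical choices

Property tests run 50 derandomized examples per property; the exhaustive
plan-vs-interpreter cross-check uses 200 random KBs with up to 12 inputs,
20 rules and 20 comments, enumerating all input assignments (~1.5 × 10⁵
evaluations, a few seconds). Staging consistency uses a 1,000-patient
cohort. Override latency is reported as the median of repeated timed
re-evaluations of the demo KB; it sits around 0.02 ms, four orders of
magnitude inside the sub-50 ms interactivity target, which is therefore
logged rather than asserted.

Open design points resolved here: the grammar is the smallest C-like
grammar covering both statement forms (`&`/`&&` and `|`/`||` accepted as
synonyms, precedence NOT > AND > OR, `#` line comments, multi-line
double-quoted text with `\"` escapes); rules may assign `false` as well
as `true` even though class-derivation rules only need `true`; `order`
ties are broken by declaration sequence; the KB file declares no inputs —
the extraction layer publishes the input-variable list, so the same KB
runs against any taxonomy/comorbidity configuration; the lookback is
measured on order spans, with any overlap counting, since "taken during
the past five years" does not fix an anchor.

## Limitations

The engine ships with a demo KB whose non-worked-example comment texts
are labelled placeholders, not vetted clinical content. There is no HL7
or FHIR ingestion, no live EHR integration, and no authentication; the
CLI operates on CSV exports. The boolean-only language cannot express
age- or dose-conditioned logic directly — such facts must be precomputed
into input variables by the extraction layer.
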