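# neurocds

A clinical-decision-support (CDS) engine for the **first-line pharmacologic
management of neuropathic pain (NP)**, built as a reusable Python library
with a CLI. It is aimed at medical-informatics developers who want a
complete, testable miniature of a point-of-care CDS architecture: a
knowledge-base (KB) language, a fast evaluation engine with live fact
override, an EHR condensation layer, and a sectioned patient report —
exercised entirely on synthetic patients.

## What it implements

**The KB language.** Clinical knowledge is written as two kinds of if-then
logic. *Derivation rules* set boolean variables:

```
if (amitriptyline_tx || nortriptyline_tx)
    tca_tx = true;
```

*Conditional comments* route a block of text to one or more named interface
locations, each under its own condition and sort order:

```
Comment TCA_depression {
    Condition: tca_tx & depression_hx; Where: Recommendations (order: 7);
    Condition: depression_hx;          Where: TCA_comments (order: 5);
    Text: "The presence of depression is not required for the analgesic
           effects of TCAs, although they may be particularly useful in
           patients with inadequately treated depression."
}
```

The same comment can appear in several screen sections, sorted differently
in each. Input variables (`<drug>_tx`, `<comorbidity>_hx`) are set by
program code from the patient's chart; the KB is compiled once to an
immutable evaluation plan, so re-running the logic after the clinician
checks or unchecks a comorbidity checkbox takes well under a millisecond.

**EHR staging.** A condensation pass emulates the nightly batch over the
full record: per patient it sets one bit per comorbidity (ICD9 dotted-code
prefix match, e.g. prefix `311` matches `311` and `311.x`) and collects the
NP drugs with any order overlapping the closed five-year lookback window
`[as_of − 5y, as_of]`. Staging is a cache, never a semantic change — every
staged answer equals a direct scan of the full tables.

**Scope guard.** The drug taxonomy classifies NP drugs by treatment line
(1: TCAs, SNRIs, gabapentinoids; 2: opioids, tramadol; 3: carbamazepine,
lamotrigine, topiramate, valproic acid, bupropion, citalopram,
paroxetine). Patients currently on a line-2/3 drug get a fixed explanatory
warning in the report, since the system covers first-line management only.

## Worked example

```sh
neurocds simulate --n 1000 --seed 7 --out cohort/
neurocds stage --ehr cohort/ --as-of 2014-06-01
neurocds run --ehr cohort/ --patient P000000 --as-of 2014-06-01 \
    --override depression_hx=true --format text
```

Or, against a bundled demo patient (on amitriptyline with a depression
diagnosis), from Python:

```python
from neurocds.pipeline import CdsContext, run_patient
from neurocds.synthetic_cohort import demo_patient, demo_as_of
from neurocds.report import render

ctx = CdsContext.from_sources()          # demo KB + shipped config
report, _ = run_patient(ctx, *demo_patient("tca_depression"),
                        patient_id="DEMO01", as_of=demo_as_of())
print(render(report, "text"))
```

which prints (abridged):

```
Patient: Demo, Patient   Age: 62   Sex: M
Comorbidities:
  [x] depression (extracted)
  [ ] diabetes (extracted)
  ...
Current NP medications:
  amitriptyline (TCA, line 1) - 25 mg PO qhs
...
Comments/Recommendations:
  [7] The presence of depression is not required for the analgesic effects
      of TCAs, although they may be particularly useful in patients with
      inadequately treated depression.
First-line management outline:
  == TCA ==
    [5] The presence of depression is not required ...
```

The `[7]` and `[5]` are the sort orders of the two routes of the same
comment: it reaches both the Comments/Recommendations section and the TCA
hover box, because the patient is on a TCA *and* has a depression history.
Unchecking the depression checkbox (`--override depression_hx=false`)
removes it from both places on instant re-evaluation.

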