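# Neuropathic-pain drug taxonomy: class and treatment line per drug.
# Line 1 (first-line): TCAs, SNRIs, gabapentinoids.
# Line 2 (second-line): opioids and tramadol.
# Line 3 (third-line): other anticonvulsants / antidepressants.
# Names are matched after normalization (lowercase, trimmed, salt
# suffixes stripped).
salt_suffixes:
  - hydrochloride
  - hcl
  - sodium
  - sulfate
  - tartrate
  - bitartrate
  - er
  - xr
drugs:
  amitriptyline: {class: TCA, line: 1}
  nortriptyline: {class: TCA, line: 1}
  desipramine: {class: TCA, line: 1}
  imipramine: {class: TCA, line: 1}
  duloxetine: {class: SNRI, line: 1}
  venlafaxine: {class: SNRI, line: 1}
  desvenlafaxine: {class: SNRI, line: 1}
  milnacipran: {class: SNRI, line: 1}
  gabapentin: {class: gabapentinoid, line: 1}
  pregabalin: {class: gabapentinoid, line: 1}
  morphine: {class: opioid, line: 2}
  oxycodone: {class: opioid, line: 2}
  hydrocodone: {class: opioid, line: 2}
  hydromorphone: {class: opioid, line: 2}
  methadone: {class: opioid, line: 2}
  fentanyl: {class: opioid, line: 2}
  codeine: {class: opioid, line: 2}
  tramadol: {class: tramadol, line: 2}
  carbamazepine: {class: third_line_other, line: 3}
  lamotrigine: {class: third_line_other, line: 3}
  topiramate: {class: third_line_other, line: 3}
  valproic acid: {class: third_line_other, line: 3}
  bupropion: {class: third_line_other, line: 3}
  citalopram: {class: third_line_other, line: 3}
  paroxetine: {class: third_line_other, line: 3}
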