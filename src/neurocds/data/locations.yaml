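# Report layout: the location registry the KB may route comments to,
# the hover-box outline (first-line drug-class categories plus auxiliary
# boxes) mapping outline labels to locations, and the static-link registry.
locations:
  - Recommendations
  - TCA_comments
  - SNRI_comments
  - Gabapentin_comments
  - Before_Requesting_a_Neurology_Consultation
outline:
  TCA: TCA_comments
  SNRI: SNRI_comments
  Gabapentin: Gabapentin_comments
  Before_Requesting_a_Neurology_Consultation: Before_Requesting_a_Neurology_Consultation
links:
  - label: "Making the diagnosis of neuropathic pain"
    target: np_diagnosis
  - label: "Pregnancy and lactation risk for NP medications"
    target: pregnancy_lactation_risk
  - label: "Steps required before using a nonformulary drug"
    target: nonformulary_steps
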