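# Demo knowledge base for first-line neuropathic-pain pharmacotherapy.
# Drug-class derivation rules: <drug>_tx inputs are set by program code
# from the patient's current medications before the logic runs.

if (amitriptyline_tx
    || nortriptyline_tx)
       tca_tx = true;

if (duloxetine_tx || venlafaxine_tx || desvenlafaxine_tx || milnacipran_tx)
    snri_tx = true;

if (gabapentin_tx || pregabalin_tx)
    gabapentinoid_tx = true;

# Conditional comments.  TCA_depression carries clinical text; the other
# comments are placeholder text standing in for hover-box content that a
# deployment would author.

Comment TCA_depression {
    Condition: tca_tx & depression_hx; Where: Recommendations (order: 7);
    Condition: depression_hx; Where: TCA_comments (order: 5);
    Text: "The presence of depression is not required for the analgesic effects of TCAs, although they may be particularly useful in patients with inadequately treated depression."
}

Comment TCA_heart_disease {
    Condition: tca_tx & heart_disease_hx; Where: Recommendations (order: 3);
    Condition: heart_disease_hx; Where: TCA_comments (order: 2);
    Text: "[Placeholder] Cardiac disease is documented for this patient; TCAs have cardiac conduction effects that warrant consideration before use."
}

Comment Gabapentinoid_renal {
    Condition: gabapentinoid_tx & renal_disease_hx; Where: Recommendations (order: 5);
    Condition: renal_disease_hx; Where: Gabapentin_comments (order: 3);
    Text: "[Placeholder] Renal disease is documented; gabapentinoid dose adjustment by creatinine clearance warrants consideration."
}

Comment SNRI_liver {
    Condition: snri_tx & liver_disease_hx; Where: Recommendations (order: 6);
    Condition: liver_disease_hx; Where: SNRI_comments (order: 4);
    Text: "[Placeholder] Hepatic disease is documented; duloxetine is generally avoided in substantial hepatic impairment."
}

Comment Neurology_consult_workup {
    Condition: tca_tx | snri_tx | gabapentinoid_tx; Where: Before_Requesting_a_Neurology_Consultation (order: 1);
    Text: "[Placeholder] Suggested workup before requesting a neurology consultation: document the NP history, examination findings, and the first-line drugs tried with doses and outcomes."
}
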