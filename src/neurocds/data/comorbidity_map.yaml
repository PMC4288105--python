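# Comorbidity -> ICD9 code prefixes (dotted codes).  A prefix such as
# "311" matches "311" and "311.x".  Prefix sets must not overlap across
# comorbidities.  Order here fixes the bit position in staging records.
# The prefix content is configuration, editable per deployment.
comorbidities:
  depression: ["296.2", "296.3", "300.4", "311"]
  heart_disease: ["410", "411", "412", "413", "414", "428"]
  diabetes: ["250"]
  renal_disease: ["585", "586"]
  liver_disease: ["571"]
  substance_abuse: ["303", "304", "305"]
  glaucoma: ["365"]
  seizure_disorder: ["345"]
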