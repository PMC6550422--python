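name: predefined
admin:
  sex: F
  age_min: 18
  age_max: 45
  year: 2012
  unit: gynecology
clauses:
- scope: MAIN_DX
  codes: [O001, O000, O002, O008, O009]
- scope: ASSOC_DX
  codes: [O081, K661, Z513, O083, O086]
- scope: PROCEDURE
  codes: [JJFA001, JJFC001, JQGA001, JJPC001, JJPA001]
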