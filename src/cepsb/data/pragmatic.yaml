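name: pragmatic
admin:
  sex: F
  age_min: 18
  age_max: 45
  year: 2012
  unit: gynecology
clauses:
- scope: ANY_DX
  codes: [O001, O008, O009, O081, O083]
- scope: PROCEDURE
  codes: [JJFA001, JJFC001, JJPC001, JJJC002, FELF001, FELF004]
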