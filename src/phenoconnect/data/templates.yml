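# Algorithm template catalogue (user-editable).
#
# A template fires when the target attribute's label matches a trigger, or
# when a shortlisted candidate lexically matches one of its slots. Slot
# placeholders {name} in the body are replaced by attribute accessors with
# unit conversions toward the slot's expected unit inserted where needed.
# "conditional: true" templates may use the ternary/comparison DSL
# extension; auto-generated arithmetic never does.
templates:
  bmi:
    label: BMI calculation
    triggers: ["body mass index", "bmi"]
    conditional: false
    slots:
      weight:
        unit: kg
        synonyms: [weight, body weight, mass]
      height:
        unit: m
        synonyms: [height, length, body length, stature]
    body: "{weight}.div({height}.pow(2)).value()"
  hypertension:
    label: Hypertension from measured blood pressures
    triggers: ["hypertension"]
    conditional: true
    slots:
      sbp:
        unit: mmHg
        synonyms: [systolic blood pressure, systolic, sbp]
      dbp:
        unit: mmHg
        synonyms: [diastolic blood pressure, diastolic, dbp]
    body: "{sbp}.value() >= 140 || {dbp}.value() >= 90 ? '1' : '0'"
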