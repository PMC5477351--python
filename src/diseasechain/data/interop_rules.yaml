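# Conversion table between quantitative, qualitative and property
# representations. Cut-points here are fixture parameters for tests and
# examples, not clinical reference values.
quantization:
- object: blood
  attribute: pressure
  unit: mmHg
  intervals:
  - {low: 0, high: 140, category: normal}
  - {low: 140, category: high}
- object: artery
  attribute: cross-sectional area
  unit: mm^2
  intervals:
  - {low: 0, high: 10, category: small}
  - {low: 10, category: normal}
- object: blood
  sub_object: glucose
  attribute: concentration
  unit: mg/dL
  intervals:
  - {low: 0, high: 126, category: normal}
  - {low: 126, category: high}
- object: colon
  sub_object: polyp
  attribute: number
  unit: count
  intervals:
  - {low: 0, high: 100, category: few}
  - {low: 100, category: many}
properties:
- {object: blood, attribute: pressure, qualitative_value: high, property: hypertension, property_value: true}
- {object: blood, attribute: pressure, qualitative_value: normal, property: hypertension, property_value: false}
- {object: artery, attribute: cross-sectional area, qualitative_value: small, property: stenosis, property_value: true}
- {object: artery, attribute: cross-sectional area, qualitative_value: normal, property: stenosis, property_value: false}
- {object: blood, sub_object: glucose, attribute: concentration, qualitative_value: high, property: hyperglycemia, property_value: true}
- {object: blood, sub_object: glucose, attribute: concentration, qualitative_value: normal, property: hyperglycemia, property_value: false}
- {object: colon, sub_object: polyp, attribute: number, qualitative_value: many, property: colonic_polyposis, property_value: true}
- {object: colon, sub_object: polyp, attribute: number, qualitative_value: few, property: colonic_polyposis, property_value: false}
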