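{
  "name": "cog_clinical_approximate_default",
  "comment": "APPROXIMATE first-match risk-classification rules emulating the shape of contemporary COG B-ALL trial algorithms (NCI risk x genetics x D8/D29 MRD x CNS). The exact trial algorithm tables are not public in the main literature; this default captures their broad structure for methodological comparisons and is NOT a clinical algorithm. MRD thresholds are fractions (0.0001 = 0.01%).",
  "default": "HR",
  "rules": [
    {"label": "VHR", "all": [{"field": "urg", "op": "eq", "value": true}]},
    {"label": "VHR", "all": [{"field": "d29_mrd", "op": "ge", "value": 0.01}]},
    {"label": "SR-Fav", "all": [
      {"field": "nci_risk", "op": "eq", "value": "SR"},
      {"field": "frg", "op": "eq", "value": true},
      {"field": "cns", "op": "in", "value": ["CNS1", "CNS2"]},
      {"field": "d8_mrd", "op": "lt", "value": 0.01},
      {"field": "d29_mrd", "op": "lt", "value": 0.0001}
    ]},
    {"label": "SR-High", "all": [
      {"field": "nci_risk", "op": "eq", "value": "SR"},
      {"field": "d29_mrd", "op": "ge", "value": 0.0001}
    ]},
    {"label": "SR-High", "all": [
      {"field": "nci_risk", "op": "eq", "value": "SR"},
      {"field": "cns", "op": "eq", "value": "CNS3"}
    ]},
    {"label": "SR-Avg", "all": [{"field": "nci_risk", "op": "eq", "value": "SR"}]},
    {"label": "HR-Fav", "all": [
      {"field": "nci_risk", "op": "eq", "value": "HR"},
      {"field": "frg", "op": "eq", "value": true},
      {"field": "d29_mrd", "op": "lt", "value": 0.0001},
      {"field": "cns", "op": "in", "value": ["CNS1", "CNS2"]}
    ]}
  ]
}
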