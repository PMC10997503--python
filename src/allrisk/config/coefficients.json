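{
  "published_ukall": {
    "name": "published_ukall",
    "provenance": "published_ukall",
    "comment": "UKALL prognostic-index equation applied externally. The UKALL good-risk / high-risk cytogenetics indicators (CYTO_GR / CYTO_HR) are mapped onto this cohort schema's frg / urg flags; swap the mapping here if alternative genetic definitions are needed.",
    "terms": [
      ["tau_d29", -0.218],
      ["frg", -0.44],
      ["urg", 1.066],
      ["wbc_log", 0.138]
    ]
  },
  "derived_ukall": {
    "name": "derived_ukall",
    "provenance": "derived_ukall",
    "comment": "UKALL model re-derived on the external COG cohort.",
    "terms": [
      ["tau_d29", -0.136],
      ["frg", -0.913],
      ["urg", 0.692],
      ["wbc_log", 0.166]
    ]
  },
  "published_cog": {
    "name": "published_cog",
    "provenance": "published_cog",
    "comment": "COG prognostic index (PI_COG) developed on the AALL0932/AALL1131 training cohort; cutpoints maximize the concordance probability estimate.",
    "terms": [
      ["tau_d29", -0.102],
      ["tau_d8", -0.04],
      ["frg", -0.741],
      ["urg", 0.644],
      ["wbc_log", 0.156],
      ["cns2", 0.386],
      ["cns3", 0.364],
      ["age", 0.061]
    ],
    "cutpoints": [-1.377, -0.589, 0.093],
    "labels": ["Low", "Standard", "Intermediate", "High"]
  }
}
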