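# Synthetic reason-for-admission map for dialect B: a two-stage lookup, from
# SNOMED-CT-like source codes to an APACHE-IV-like intermediate classification
# and from there to APACHE II diagnostic categories.  (Stand-in for a
# registry's deposited mapping table.)
source: src_b
intermediate: apache-iv-like
entries:
  - {code: "91000101", target: "101"}
  - {code: "91000102", target: "102"}
  - {code: "91000103", target: "103"}
  - {code: "91000104", target: "104"}
  - {code: "91000105", target: "105"}
  - {code: "91000106", target: "106"}
  - {code: "91000107", target: "107"}
  - {code: "91000108", target: "108"}
  - {code: "91000109", target: "109"}
  - {code: "91000110", target: "110"}
intermediate_entries:
  "101": cardiovascular
  "102": respiratory
  "103": gastrointestinal
  "104": neurologic
  "105": metabolic_renal
  "106": sepsis
  "107": multiple_trauma
  "108": gi_bleeding
  "109": head_trauma
  "110": hemorrhagic_shock_hypovolemia
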