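# Synthetic reason-for-admission map for dialect A: a one-stage lookup from
# the source's APACHE-IV-like numeric codes straight to APACHE II diagnostic
# categories.  (Stand-in for a registry's deposited mapping table.)
source: src_a
entries:
  - {code: "101", target: cardiovascular}
  - {code: "102", target: respiratory}
  - {code: "103", target: gastrointestinal}
  - {code: "104", target: neurologic}
  - {code: "105", target: metabolic_renal}
  - {code: "106", target: sepsis}
  - {code: "107", target: multiple_trauma}
  - {code: "108", target: gi_bleeding}
  - {code: "109", target: head_trauma}
  - {code: "110", target: hemorrhagic_shock_hypovolemia}
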