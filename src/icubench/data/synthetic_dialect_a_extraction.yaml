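# Extraction configuration for synthetic source dialect A.
# Synthetic stand-in for a registry's per-source configuration file: it names,
# per variable, the concept codes and the OMOP table the synthetic generator
# uses for this dialect (leukocytes by automated count, comorbidities in
# condition_occurrence, reasons for admission in an APACHE-IV-like code list).
source_name: src_a
gender_male_concept_id: 8507
date_window: [2019-07-01, 2022-12-31]
burns_concept_ids: [4033240]
variables:
  - {name: temperature, table: measurement, aggregation: both, concept_ids: [3020891], unit_concept_id: 586323}
  - {name: mean_arterial_pressure, table: measurement, aggregation: both, concept_ids: [3027598], unit_concept_id: 8876}
  - {name: heart_rate, table: measurement, aggregation: both, concept_ids: [3027018], unit_concept_id: 8541}
  - {name: respiratory_rate, table: measurement, aggregation: both, concept_ids: [3024171], unit_concept_id: 8541}
  - {name: pao2, table: measurement, aggregation: lowest, concept_ids: [3027801], unit_concept_id: 8876}
  - {name: fio2, table: measurement, aggregation: highest, concept_ids: [3020716], unit_concept_id: 8523}
  - {name: aado2, table: measurement, aggregation: highest, concept_ids: [3022875], unit_concept_id: 8876}
  - {name: arterial_ph, table: measurement, aggregation: both, concept_ids: [3010421], unit_concept_id: 8482}
  - {name: sodium, table: measurement, aggregation: both, concept_ids: [3019550], unit_concept_id: 8753}
  - {name: potassium, table: measurement, aggregation: both, concept_ids: [3023103], unit_concept_id: 8753}
  - {name: creatinine, table: measurement, aggregation: both, concept_ids: [3016723], unit_concept_id: 8840}
  - {name: hematocrit, table: measurement, aggregation: both, concept_ids: [3023314], unit_concept_id: 8554}
  - {name: wbc, table: measurement, aggregation: both, concept_ids: [3000905], unit_concept_id: 8848}
  - {name: gcs, table: measurement, aggregation: lowest, concept_ids: [3032652]}
  - {name: reason_for_admission, table: observation, aggregation: code, concept_ids: [2000000001]}
  - {name: chronic_insufficiency, table: condition_occurrence, aggregation: presence, concept_ids: [4064161]}
  - {name: acute_renal_failure, table: condition_occurrence, aggregation: presence, concept_ids: [197320]}
  - {name: elective_postop, table: observation, aggregation: presence, concept_ids: [2000000002]}
  - {name: emergency_postop, table: observation, aggregation: presence, concept_ids: [2000000003]}
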