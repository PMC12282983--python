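# APACHE II scoring definition, transcribed from the published model
# (Knaus WA, Draper EA, Wagner DP, Zimmerman JE. APACHE II: a severity of
# disease classification system. Crit Care Med 1985;13:818-29).
#
# Conventions used by the engine:
#   - bands are the printed closed ranges; a value falling in the gap between
#     two printed bands (e.g. temperature 38.45) is assigned to the adjacent
#     band with the higher point value, as is a value exactly on a shared edge.
#   - `min` / `max` absent means the band is open on that side; `domain` bounds
#     the values the engine accepts at all.
version: "knaus-1985"

logistic:
  intercept: -3.517
  per_point: 0.146
  emergency_postop: 0.603

age_points:
  - {max: 44, points: 0}
  - {min: 45, max: 54, points: 2}
  - {min: 55, max: 64, points: 3}
  - {min: 65, max: 74, points: 5}
  - {min: 75, points: 6}

chronic_health:
  # severe organ insufficiency or immunocompromise documented before admission
  nonoperative: 5
  emergency_postop: 5
  elective_postop: 2
  none: 0

variables:
  temperature:
    description: rectal core temperature
    unit: degC
    domain: [20.0, 46.0]
    bands:
      - {min: 41.0, points: 4}
      - {min: 39.0, max: 40.9, points: 3}
      - {min: 38.5, max: 38.9, points: 1}
      - {min: 36.0, max: 38.4, points: 0}
      - {min: 34.0, max: 35.9, points: 1}
      - {min: 32.0, max: 33.9, points: 2}
      - {min: 30.0, max: 31.9, points: 3}
      - {max: 29.9, points: 4}
  mean_arterial_pressure:
    unit: mmHg
    domain: [0.0, 300.0]
    bands:
      - {min: 160, points: 4}
      - {min: 130, max: 159, points: 3}
      - {min: 110, max: 129, points: 2}
      - {min: 70, max: 109, points: 0}
      - {min: 50, max: 69, points: 2}
      - {max: 49, points: 4}
  heart_rate:
    description: ventricular response rate
    unit: beats/min
    domain: [0.0, 350.0]
    bands:
      - {min: 180, points: 4}
      - {min: 140, max: 179, points: 3}
      - {min: 110, max: 139, points: 2}
      - {min: 70, max: 109, points: 0}
      - {min: 55, max: 69, points: 2}
      - {min: 40, max: 54, points: 3}
      - {max: 39, points: 4}
  respiratory_rate:
    description: non-ventilated or ventilated
    unit: breaths/min
    domain: [0.0, 120.0]
    bands:
      - {min: 50, points: 4}
      - {min: 35, max: 49, points: 3}
      - {min: 25, max: 34, points: 1}
      - {min: 12, max: 24, points: 0}
      - {min: 10, max: 11, points: 1}
      - {min: 6, max: 9, points: 2}
      - {max: 5, points: 4}
  aado2:
    description: alveolar-arterial O2 gradient, used when FiO2 >= 0.5
    unit: mmHg
    domain: [0.0, 800.0]
    bands:
      - {min: 500, points: 4}
      - {min: 350, max: 499, points: 3}
      - {min: 200, max: 349, points: 2}
      - {max: 199, points: 0}
  pao2:
    description: arterial PO2, used when FiO2 < 0.5
    unit: mmHg
    domain: [0.0, 700.0]
    bands:
      - {min: 71, points: 0}
      - {min: 61, max: 70, points: 1}
      - {min: 55, max: 60, points: 3}
      - {max: 54, points: 4}
  arterial_ph:
    unit: pH
    domain: [6.5, 8.2]
    bands:
      - {min: 7.7, points: 4}
      - {min: 7.6, max: 7.69, points: 3}
      - {min: 7.5, max: 7.59, points: 1}
      - {min: 7.33, max: 7.49, points: 0}
      - {min: 7.25, max: 7.32, points: 2}
      - {min: 7.15, max: 7.24, points: 3}
      - {max: 7.14, points: 4}
  serum_hco3:
    description: venous bicarbonate; substitute for arterial pH only when no blood gases
    unit: mmol/L
    domain: [0.0, 80.0]
    bands:
      - {min: 52, points: 4}
      - {min: 41, max: 51.9, points: 3}
      - {min: 32, max: 40.9, points: 1}
      - {min: 22, max: 31.9, points: 0}
      - {min: 18, max: 21.9, points: 2}
      - {min: 15, max: 17.9, points: 3}
      - {max: 14.9, points: 4}
  sodium:
    unit: mmol/L
    domain: [80.0, 220.0]
    bands:
      - {min: 180, points: 4}
      - {min: 160, max: 179, points: 3}
      - {min: 155, max: 159, points: 2}
      - {min: 150, max: 154, points: 1}
      - {min: 130, max: 149, points: 0}
      - {min: 120, max: 129, points: 2}
      - {min: 111, max: 119, points: 3}
      - {max: 110, points: 4}
  potassium:
    unit: mmol/L
    domain: [0.5, 12.0]
    bands:
      - {min: 7.0, points: 4}
      - {min: 6.0, max: 6.9, points: 3}
      - {min: 5.5, max: 5.9, points: 1}
      - {min: 3.5, max: 5.4, points: 0}
      - {min: 3.0, max: 3.4, points: 1}
      - {min: 2.5, max: 2.9, points: 2}
      - {max: 2.4, points: 4}
  creatinine:
    description: points doubled under acute renal failure
    unit: mg/dL
    domain: [0.0, 30.0]
    bands:
      - {min: 3.5, points: 4}
      - {min: 2.0, max: 3.4, points: 3}
      - {min: 1.5, max: 1.9, points: 2}
      - {min: 0.6, max: 1.4, points: 0}
      - {max: 0.5, points: 2}
  hematocrit:
    unit: "%"
    domain: [5.0, 90.0]
    bands:
      - {min: 60, points: 4}
      - {min: 50, max: 59.9, points: 2}
      - {min: 46, max: 49.9, points: 1}
      - {min: 30, max: 45.9, points: 0}
      - {min: 20, max: 29.9, points: 2}
      - {max: 19.9, points: 4}
  wbc:
    description: leukocyte count
    unit: 10^3/mm^3
    domain: [0.0, 200.0]
    bands:
      - {min: 40, points: 4}
      - {min: 20, max: 39.9, points: 2}
      - {min: 15, max: 19.9, points: 1}
      - {min: 3, max: 14.9, points: 0}
      - {min: 1, max: 2.9, points: 2}
      - {max: 0.9, points: 4}
  gcs:
    description: Glasgow Coma Scale; points = 15 - GCS
    unit: score
    domain: [3, 15]
    rule: fifteen_minus_value

diagnostic_weights:
  nonoperative:
    asthma_allergy: -2.108
    copd: -0.367
    pulmonary_edema_noncardiogenic: -0.251
    post_respiratory_arrest: -0.168
    aspiration_poisoning_toxic: -0.142
    pulmonary_embolus: -0.128
    respiratory_infection: 0.0
    respiratory_neoplasm: 0.891
    hypertension: -1.798
    rhythm_disturbance: -1.368
    congestive_heart_failure: -0.424
    hemorrhagic_shock_hypovolemia: 0.493
    coronary_artery_disease: -0.191
    sepsis: 0.113
    post_cardiac_arrest: 0.393
    cardiogenic_shock: -0.259
    dissecting_aortic_aneurysm: 0.731
    multiple_trauma: -1.228
    head_trauma: -0.517
    seizure_disorder: -0.584
    intracranial_hemorrhage: 0.723
    drug_overdose: -3.353
    diabetic_ketoacidosis: -1.507
    gi_bleeding: 0.334
    # residual organ-system categories
    metabolic_renal: -0.885
    respiratory: -0.890
    neurologic: -0.759
    cardiovascular: 0.470
    gastrointestinal: 0.501
  postoperative:
    multiple_trauma: -1.684
    chronic_cardiovascular_disease: -1.376
    peripheral_vascular_surgery: -1.315
    heart_valve_surgery: -1.261
    craniotomy_neoplasm: -1.245
    renal_surgery_neoplasm: -1.204
    renal_transplant: -1.042
    head_trauma: -0.955
    thoracic_surgery_neoplasm: -0.802
    craniotomy_hemorrhage: -0.788
    laminectomy_spinal_surgery: -0.699
    hemorrhagic_shock_hypovolemia: -0.682
    gi_bleeding: -0.617
    gi_surgery_neoplasm: -0.248
    post_respiratory_insufficiency: -0.140
    gi_perforation_obstruction: 0.060
    sepsis: 0.113
    post_cardiac_arrest: 0.393
    # residual organ-system categories
    neurologic: -1.150
    cardiovascular: -0.797
    respiratory: -0.610
    gastrointestinal: -0.613
    metabolic_renal: -0.196
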