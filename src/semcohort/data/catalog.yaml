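# Fixture-scale data catalog: standardized labels for the data elements
# appearing in the synthetic collections, with per-collection presence.
collections:
  - name: LUNG-A
    description: "Lung carcinoma collection; full-name diagnosis and site values."
    subject_count: 60
  - name: LUNG-B
    description: "Lung carcinoma collection; abbreviated value dialect ('Dx', 'RUL', ...)."
    subject_count: 60
  - name: BREAST-1
    description: "Breast carcinoma collection; two-letter diagnosis codes ('ID', 'IL')."
    subject_count: 40
  - name: HN-1
    description: "Head and neck squamous cell carcinoma collection with anatomic sites."
    subject_count: 40

elements:
  - standard_label: patient_uid
    description: "Unique subject identifier within a collection."
    value_kind: identifier
    collections_present: [LUNG-A, LUNG-B, BREAST-1, HN-1]
  - standard_label: diagnosis
    description: "Primary cancer diagnosis of the subject."
    value_kind: categorical
    collections_present: [LUNG-A, LUNG-B, BREAST-1, HN-1]
  - standard_label: primary_tumor_site
    description: "Anatomical location of the primary tumor."
    value_kind: categorical
    collections_present: [LUNG-A, LUNG-B, HN-1]
  - standard_label: sex
    description: "Phenotypic sex of the subject."
    value_kind: categorical
    collections_present: [LUNG-A, LUNG-B, BREAST-1, HN-1]
  - standard_label: age_at_diagnosis
    description: "Subject age in years at diagnosis."
    value_kind: numeric
    collections_present: [LUNG-A, LUNG-B, BREAST-1, HN-1]
  - standard_label: clinical_stage
    description: "Clinical tumor stage grouping (I, IA, IB, II, III, IV)."
    value_kind: categorical
    collections_present: [LUNG-A, LUNG-B, BREAST-1, HN-1]
  - standard_label: smoking_history
    description: "Smoking status at enrollment."
    value_kind: categorical
    collections_present: [LUNG-A, LUNG-B]
  - standard_label: race
    description: "Self-reported race."
    value_kind: categorical
    collections_present: [LUNG-A, BREAST-1]
  - standard_label: ethnicity
    description: "Self-reported ethnicity."
    value_kind: categorical
    collections_present: [BREAST-1]
  - standard_label: vital_status
    description: "Vital status at last follow-up."
    value_kind: categorical
    collections_present: [LUNG-A, HN-1]
  - standard_label: weight_kg
    description: "Body weight in kilograms."
    value_kind: numeric
    collections_present: [HN-1]
  - standard_label: mold_or_dust_allergy_history
    description: "History of mold or dust allergy; an element occurring in a single collection."
    value_kind: categorical
    collections_present: [HN-1]
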