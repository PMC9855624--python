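# Shipped representation-pattern repository.
#
# Each pattern is a small graph template with slots.  "$subject" is an
# implicit slot bound to the per-row subject node; declared slots are
# either freshly minted instance nodes ("node"), an ontology class chosen
# by the mapping rule's value map ("class"), or a typed literal
# ("literal:<xsd type>").  These patterns are this package's own
# reconstructions of common clinical representation shapes (diagnosis,
# tumor anatomical location, demographic attributes, clinical stage); they
# are not copies of any published pattern set.
prefixes:
  app: "https://w3id.org/semcohort/app#"
  obo: "http://purl.obolibrary.org/obo/"
  rdf: "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
  xsd: "http://www.w3.org/2001/XMLSchema#"

patterns:
  - id: diagnosis
    description: >
      A diagnosis instance about a disease instance: the subject has a
      diagnosis (OGMS-style), the diagnosis is about (IAO:0000136) a
      disease individual, and that disease is typed by the mapped disease
      class.
    slots:
      diagnosis: node
      disease: node
      disease_class: class
    triples:
      - ["$subject", "app:has_diagnosis", "$diagnosis"]
      - ["$diagnosis", "rdf:type", "obo:OGMS_0000073"]
      - ["$diagnosis", "obo:IAO_0000136", "$disease"]
      - ["$disease", "rdf:type", "$disease_class"]

  - id: tumor_site
    description: >
      Tumor anatomical location: a neoplasm instance located in
      (RO:0001025) an anatomical-structure instance typed by the mapped
      site class.
    slots:
      tumor: node
      site: node
      site_class: class
    triples:
      - ["$subject", "app:has_finding", "$tumor"]
      - ["$tumor", "rdf:type", "obo:NCIT_C3262"]
      - ["$tumor", "obo:RO_0001025", "$site"]
      - ["$site", "rdf:type", "$site_class"]

  - id: sex
    description: >
      Demographic attribute, categorical: the subject has a phenotypic-sex
      quality (RO:0000086) typed by the mapped PATO class.
    slots:
      quality: node
      sex_class: class
    triples:
      - ["$subject", "obo:RO_0000086", "$quality"]
      - ["$quality", "rdf:type", "$sex_class"]

  - id: age
    description: >
      Demographic attribute, numeric: age at diagnosis in integer years
      attached directly to the subject as a typed literal.
    slots:
      age_value: "literal:integer"
    triples:
      - ["$subject", "app:age_years", "$age_value"]

  - id: clinical_stage
    description: >
      Clinical stage finding: a stage instance typed by the mapped stage
      class (stage I, IA, IB, ... taxonomy) linked to the subject.
    slots:
      stage: node
      stage_class: class
    triples:
      - ["$subject", "app:has_stage", "$stage"]
      - ["$stage", "rdf:type", "$stage_class"]
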