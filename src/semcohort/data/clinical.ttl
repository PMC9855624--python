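# Synthetic fixture-scale clinical module (hand-authored): diagnosis and
# neoplasm classes, phenotypic sex qualities, and a tumor-stage taxonomy
# with stage I / IA / IB sub-terms.  Identifiers are illustrative.
@prefix obo: <http://purl.obolibrary.org/obo/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

obo:OGMS_0000073 a owl:Class ;
    rdfs:label "diagnosis" ;
    obo:IAO_0000115 "A conclusion of a diagnostic process identifying the disease a patient has." .

obo:NCIT_C3262 a owl:Class ;
    rdfs:label "neoplasm" ;
    obo:IAO_0000115 "An abnormal tissue mass resulting from uncontrolled cell division." .

obo:PATO_0001894 a owl:Class ;
    rdfs:label "phenotypic sex" ;
    obo:IAO_0000115 "An organismal quality by which organisms are classified as male or female." .

obo:PATO_0000384 a owl:Class ;
    rdfs:label "male" ;
    rdfs:subClassOf obo:PATO_0001894 ;
    obo:IAO_0000115 "A phenotypic sex quality of an individual producing male gametes." .

obo:PATO_0000383 a owl:Class ;
    rdfs:label "female" ;
    rdfs:subClassOf obo:PATO_0001894 ;
    obo:IAO_0000115 "A phenotypic sex quality of an individual producing female gametes." .

obo:NCIT_C28108 a owl:Class ;
    rdfs:label "tumor stage" ;
    obo:IAO_0000115 "A classification of the anatomic extent of a malignant tumor." .

obo:NCIT_C27966 a owl:Class ;
    rdfs:label "stage I" ;
    rdfs:subClassOf obo:NCIT_C28108 ;
    obo:IAO_0000115 "Early-extent disease confined to the organ of origin." .

obo:NCIT_C27975 a owl:Class ;
    rdfs:label "stage IA" ;
    rdfs:subClassOf obo:NCIT_C27966 ;
    obo:IAO_0000115 "Stage I disease of smaller tumor size without nodal involvement." .

obo:NCIT_C27976 a owl:Class ;
    rdfs:label "stage IB" ;
    rdfs:subClassOf obo:NCIT_C27966 ;
    obo:IAO_0000115 "Stage I disease of larger tumor size without nodal involvement." .

obo:NCIT_C28054 a owl:Class ;
    rdfs:label "stage II" ;
    rdfs:subClassOf obo:NCIT_C28108 ;
    obo:IAO_0000115 "Locally advanced disease of intermediate extent." .

obo:NCIT_C27970 a owl:Class ;
    rdfs:label "stage III" ;
    rdfs:subClassOf obo:NCIT_C28108 ;
    obo:IAO_0000115 "Regionally advanced disease with nodal involvement." .

obo:NCIT_C27971 a owl:Class ;
    rdfs:label "stage IV" ;
    rdfs:subClassOf obo:NCIT_C28108 ;
    obo:IAO_0000115 "Metastatic disease spread to distant sites." .
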