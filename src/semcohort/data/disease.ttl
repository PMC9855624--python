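# Synthetic fixture-scale disease module (hand-authored mini-taxonomy in
# the style of a human disease ontology; identifiers are illustrative).
@prefix obo: <http://purl.obolibrary.org/obo/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix oboInOwl: <http://www.geneontology.org/formats/oboInOwl#> .

obo:DOID_162 a owl:Class ;
    rdfs:label "cancer" ;
    obo:IAO_0000115 "A disease of cellular proliferation that is malignant and primary." .

obo:DOID_1324 a owl:Class ;
    rdfs:label "lung cancer" ;
    rdfs:subClassOf obo:DOID_162 ;
    obo:IAO_0000115 "A respiratory system cancer located in the lung." .

obo:DOID_3910 a owl:Class ;
    rdfs:label "lung adenocarcinoma" ;
    rdfs:subClassOf obo:DOID_1324 ;
    obo:IAO_0000115 "A lung carcinoma arising from glandular epithelial cells." ;
    oboInOwl:hasExactSynonym "adenocarcinoma of lung" .

obo:DOID_4556 a owl:Class ;
    rdfs:label "lung large cell carcinoma" ;
    rdfs:subClassOf obo:DOID_1324 ;
    obo:IAO_0000115 "An undifferentiated non-small-cell lung carcinoma lacking glandular or squamous features." .

obo:DOID_3907 a owl:Class ;
    rdfs:label "lung squamous cell carcinoma" ;
    rdfs:subClassOf obo:DOID_1324 ;
    obo:IAO_0000115 "A non-small-cell lung carcinoma arising from squamous epithelial cells." .

obo:DOID_1612 a owl:Class ;
    rdfs:label "breast cancer" ;
    rdfs:subClassOf obo:DOID_162 ;
    obo:IAO_0000115 "A thoracic cancer originating in breast tissue." .

obo:DOID_3008 a owl:Class ;
    rdfs:label "invasive ductal carcinoma" ;
    rdfs:subClassOf obo:DOID_1612 ;
    obo:IAO_0000115 "A breast carcinoma that originates in the milk ducts and invades surrounding tissue." ;
    oboInOwl:hasExactSynonym "infiltrating ductal carcinoma" .

obo:DOID_3856 a owl:Class ;
    rdfs:label "invasive lobular carcinoma" ;
    rdfs:subClassOf obo:DOID_1612 ;
    obo:IAO_0000115 "A breast carcinoma that originates in the lobules and invades surrounding tissue." .

obo:DOID_5520 a owl:Class ;
    rdfs:label "head and neck squamous cell carcinoma" ;
    rdfs:subClassOf obo:DOID_162 ;
    obo:IAO_0000115 "A squamous cell carcinoma arising in the mucosal surfaces of the head and neck." ;
    oboInOwl:hasExactSynonym "HNSCC" .
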