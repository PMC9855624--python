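# Synthetic fixture-scale anatomy module (hand-authored; not an extract of
# any released ontology).  Partonomy edges use the OWL existential
# restriction dialect over BFO:0000050 ('part of'), as OBO anatomy
# ontologies ship them.
@prefix obo: <http://purl.obolibrary.org/obo/> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix oboInOwl: <http://www.geneontology.org/formats/oboInOwl#> .

obo:BFO_0000050 a owl:ObjectProperty ;
    rdfs:label "part of" .

obo:UBERON_0000061 a owl:Class ;
    rdfs:label "anatomical structure" ;
    obo:IAO_0000115 "A material structure that is part of an organism body." .

obo:UBERON_0000033 a owl:Class ;
    rdfs:label "head" ;
    rdfs:subClassOf obo:UBERON_0000061 ;
    obo:IAO_0000115 "The uppermost body region, containing the brain, mouth, and major sense organs." .

obo:UBERON_0000974 a owl:Class ;
    rdfs:label "neck" ;
    rdfs:subClassOf obo:UBERON_0000061 ;
    obo:IAO_0000115 "The body region connecting the head to the trunk." .

obo:UBERON_0000341 a owl:Class ;
    rdfs:label "throat" ;
    rdfs:subClassOf obo:UBERON_0000061 ,
        [ a owl:Restriction ; owl:onProperty obo:BFO_0000050 ; owl:someValuesFrom obo:UBERON_0000974 ] ;
    obo:IAO_0000115 "The anterior part of the neck containing the pharynx and upper larynx." ;
    oboInOwl:hasRelatedSynonym "gullet" .

obo:UBERON_0013165 a owl:Class ;
    rdfs:label "epiglottic vallecula" ;
    rdfs:subClassOf obo:UBERON_0000061 ,
        [ a owl:Restriction ; owl:onProperty obo:BFO_0000050 ; owl:someValuesFrom obo:UBERON_0000341 ] ;
    obo:IAO_0000115 "A depression between the root of the tongue and the epiglottis." ;
    oboInOwl:hasExactSynonym "vallecula epiglottica" .

obo:UBERON_0001737 a owl:Class ;
    rdfs:label "larynx" ;
    rdfs:subClassOf obo:UBERON_0000061 ,
        [ a owl:Restriction ; owl:onProperty obo:BFO_0000050 ; owl:someValuesFrom obo:UBERON_0000974 ] ;
    obo:IAO_0000115 "The airway organ in the neck housing the vocal folds." ;
    oboInOwl:hasExactSynonym "voice box" .

obo:UBERON_0000165 a owl:Class ;
    rdfs:label "mouth" ;
    rdfs:subClassOf obo:UBERON_0000061 ,
        [ a owl:Restriction ; owl:onProperty obo:BFO_0000050 ; owl:someValuesFrom obo:UBERON_0000033 ] ;
    obo:IAO_0000115 "The proximal opening of the digestive tract, within the head." .

obo:UBERON_0001723 a owl:Class ;
    rdfs:label "tongue" ;
    rdfs:subClassOf obo:UBERON_0000061 ,
        [ a owl:Restriction ; owl:onProperty obo:BFO_0000050 ; owl:someValuesFrom obo:UBERON_0000165 ] ;
    obo:IAO_0000115 "The muscular organ on the floor of the mouth." .

obo:UBERON_0002048 a owl:Class ;
    rdfs:label "lung" ;
    rdfs:subClassOf obo:UBERON_0000061 ;
    obo:IAO_0000115 "The paired respiration organ in the thorax." .

obo:UBERON_0002170 a owl:Class ;
    rdfs:label "upper lobe of right lung" ;
    rdfs:subClassOf obo:UBERON_0000061 ,
        [ a owl:Restriction ; owl:onProperty obo:BFO_0000050 ; owl:someValuesFrom obo:UBERON_0002048 ] ;
    obo:IAO_0000115 "The superior lobe of the right lung." .

obo:UBERON_0002171 a owl:Class ;
    rdfs:label "lower lobe of right lung" ;
    rdfs:subClassOf obo:UBERON_0000061 ,
        [ a owl:Restriction ; owl:onProperty obo:BFO_0000050 ; owl:someValuesFrom obo:UBERON_0002048 ] ;
    obo:IAO_0000115 "The inferior lobe of the right lung." .

obo:UBERON_0000310 a owl:Class ;
    rdfs:label "breast" ;
    rdfs:subClassOf obo:UBERON_0000061 ;
    obo:IAO_0000115 "The upper ventral surface region of the trunk containing the mammary gland." .
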