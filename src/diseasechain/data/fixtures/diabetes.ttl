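@prefix dont: <http://diseasechain.example.org/ontology#> .
@prefix dontx: <http://diseasechain.example.org/extension#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

dont:deficiency_of_insulin dontx:attribute "functioning" .
dont:deficiency_of_insulin dontx:level "3"^^xsd:integer .
dont:deficiency_of_insulin dontx:object "insulin" .
dont:deficiency_of_insulin dontx:value "deficient" .
dont:deficiency_of_insulin dont:hasCause dont:lack_of_insulin_in_blood .
dont:deficiency_of_insulin dont:hasCause dont:unknown_steroid_diabetes .
dont:deficiency_of_insulin dont:hasResult dont:elevated_glucose_in_blood .
dont:deficiency_of_insulin rdf:type dont:Abnormal_State .
dont:deficiency_of_insulin rdfs:label "deficiency of insulin" .
dont:destruction_of_pancreatic_beta_cells dontx:attribute "structure" .
dont:destruction_of_pancreatic_beta_cells dontx:level "3"^^xsd:integer .
dont:destruction_of_pancreatic_beta_cells dontx:object "pancreatic beta cell" .
dont:destruction_of_pancreatic_beta_cells dontx:value "destroyed" .
dont:destruction_of_pancreatic_beta_cells dont:hasResult dont:lack_of_insulin_in_blood .
dont:destruction_of_pancreatic_beta_cells rdf:type dont:Abnormal_State .
dont:destruction_of_pancreatic_beta_cells rdfs:label "destruction of pancreatic beta cells" .
dont:diabetes dontx:area "metabolism" .
dont:diabetes dont:hasCoreState dont:deficiency_of_insulin .
dont:diabetes dont:hasCoreState dont:elevated_glucose_in_blood .
dont:diabetes rdf:type dont:Disease .
dont:diabetes rdfs:label "diabetes" .
dont:diabetes_caused_blindness dontx:area "ophthalmology" .
dont:diabetes_caused_blindness dont:hasDerivedState dont:loss_of_sight .
dont:diabetes_caused_blindness dont:hasDerivedState dont:unknown_blindness .
dont:diabetes_caused_blindness dont:subDiseaseOf dont:diabetes .
dont:diabetes_caused_blindness rdf:type dont:Disease .
dont:diabetes_caused_blindness rdfs:label "diabetes-caused blindness" .
dont:elevated_glucose_in_blood dontx:attribute "concentration" .
dont:elevated_glucose_in_blood dontx:level "3"^^xsd:integer .
dont:elevated_glucose_in_blood dontx:object "blood" .
dont:elevated_glucose_in_blood dontx:subObject "glucose" .
dont:elevated_glucose_in_blood dontx:value "high" .
dont:elevated_glucose_in_blood dont:hasCause dont:deficiency_of_insulin .
dont:elevated_glucose_in_blood dont:hasResult dont:unknown_blindness .
dont:elevated_glucose_in_blood rdf:type dont:Abnormal_State .
dont:elevated_glucose_in_blood rdfs:label "elevated level of glucose in the blood" .
dont:lack_of_insulin_in_blood dontx:attribute "amount" .
dont:lack_of_insulin_in_blood dontx:level "3"^^xsd:integer .
dont:lack_of_insulin_in_blood dontx:object "blood" .
dont:lack_of_insulin_in_blood dontx:subObject "insulin" .
dont:lack_of_insulin_in_blood dontx:value "low" .
dont:lack_of_insulin_in_blood dont:hasCause dont:destruction_of_pancreatic_beta_cells .
dont:lack_of_insulin_in_blood dont:hasResult dont:deficiency_of_insulin .
dont:lack_of_insulin_in_blood rdf:type dont:Abnormal_State .
dont:lack_of_insulin_in_blood rdfs:label "lack of insulin I in the blood" .
dont:long_term_steroid_treatment dontx:attribute "exposure" .
dont:long_term_steroid_treatment dontx:level "3"^^xsd:integer .
dont:long_term_steroid_treatment dontx:object "body" .
dont:long_term_steroid_treatment dontx:subObject "steroid" .
dont:long_term_steroid_treatment dontx:value "long-term" .
dont:long_term_steroid_treatment dont:hasResult dont:unknown_steroid_diabetes .
dont:long_term_steroid_treatment rdf:type dont:Abnormal_State .
dont:long_term_steroid_treatment rdfs:label "long-term steroid treatment" .
dont:loss_of_sight dontx:attribute "sight" .
dont:loss_of_sight dontx:level "3"^^xsd:integer .
dont:loss_of_sight dontx:object "eye" .
dont:loss_of_sight dontx:value "lost" .
dont:loss_of_sight dont:hasCause dont:unknown_blindness .
dont:loss_of_sight rdf:type dont:Abnormal_State .
dont:loss_of_sight rdfs:label "loss of sight" .
dont:steroid_diabetes dontx:area "metabolism" .
dont:steroid_diabetes dont:hasCoreState dont:long_term_steroid_treatment .
dont:steroid_diabetes dont:hasCoreState dont:unknown_steroid_diabetes .
dont:steroid_diabetes dont:subDiseaseOf dont:diabetes .
dont:steroid_diabetes rdf:type dont:Disease .
dont:steroid_diabetes rdfs:label "steroid diabetes" .
dont:type_I_diabetes dontx:area "metabolism" .
dont:type_I_diabetes dont:hasCoreState dont:destruction_of_pancreatic_beta_cells .
dont:type_I_diabetes dont:hasCoreState dont:lack_of_insulin_in_blood .
dont:type_I_diabetes dont:subDiseaseOf dont:diabetes .
dont:type_I_diabetes rdf:type dont:Disease .
dont:type_I_diabetes rdfs:label "Type-I diabetes" .
dont:unknown_blindness dontx:isUnknown "true"^^xsd:boolean .
dont:unknown_blindness dontx:level "3"^^xsd:integer .
dont:unknown_blindness dont:hasCause dont:elevated_glucose_in_blood .
dont:unknown_blindness dont:hasResult dont:loss_of_sight .
dont:unknown_blindness rdf:type dont:Abnormal_State .
dont:unknown_blindness rdfs:label "unknown" .
dont:unknown_steroid_diabetes dontx:isUnknown "true"^^xsd:boolean .
dont:unknown_steroid_diabetes dontx:level "3"^^xsd:integer .
dont:unknown_steroid_diabetes dont:hasCause dont:long_term_steroid_treatment .
dont:unknown_steroid_diabetes dont:hasResult dont:deficiency_of_insulin .
dont:unknown_steroid_diabetes rdf:type dont:Abnormal_State .
dont:unknown_steroid_diabetes rdfs:label "unknown" .
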