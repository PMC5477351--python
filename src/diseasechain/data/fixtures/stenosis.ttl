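@prefix dont: <http://diseasechain.example.org/ontology#> .
@prefix dontx: <http://diseasechain.example.org/extension#> .
@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

dont:arterial_occlusion dontx:externalRef "SNOMED-CT:2929001" .
dont:arterial_occlusion dontx:level "2"^^xsd:integer .
dont:arterial_occlusion dontx:object "artery" .
dont:arterial_occlusion dont:subStateOf dont:structural_abnormality .
dont:arterial_occlusion rdf:type dont:Abnormal_State .
dont:arterial_occlusion rdfs:label "arterial occlusion" .
dont:arterial_stenosis dontx:attribute "cross-sectional area" .
dont:arterial_stenosis dontx:level "2"^^xsd:integer .
dont:arterial_stenosis dontx:object "artery" .
dont:arterial_stenosis dontx:value "small" .
dont:arterial_stenosis dont:subStateOf dont:vascular_stenosis .
dont:arterial_stenosis rdf:type dont:Abnormal_State .
dont:arterial_stenosis rdfs:label "arterial stenosis" .
dont:cellular_tissue_necrosis dontx:externalRef "MeSH:D009336" .
dont:cellular_tissue_necrosis dontx:externalRef "PATO:PATO:0000647" .
dont:cellular_tissue_necrosis dontx:level "2"^^xsd:integer .
dont:cellular_tissue_necrosis dontx:object "cellular tissue" .
dont:cellular_tissue_necrosis dont:subStateOf dont:material_degeneration .
dont:cellular_tissue_necrosis rdf:type dont:Abnormal_State .
dont:cellular_tissue_necrosis rdfs:label "cellular tissue necrosis" .
dont:chest_pain dontx:externalRef "HPO:HP:0100749" .
dont:chest_pain dontx:externalRef "MeSH:D002637" .
dont:chest_pain dontx:externalRef "SNOMED-CT:29857009" .
dont:chest_pain dontx:level "2"^^xsd:integer .
dont:chest_pain dontx:object "chest" .
dont:chest_pain dont:subStateOf dont:dysfunction .
dont:chest_pain rdf:type dont:Abnormal_State .
dont:chest_pain rdfs:label "chest pain" .
dont:coronary_artery_occlusion dontx:externalRef "MeSH:D054059" .
dont:coronary_artery_occlusion dontx:externalRef "SNOMED-CT:63739005" .
dont:coronary_artery_occlusion dontx:level "2"^^xsd:integer .
dont:coronary_artery_occlusion dontx:object "coronary artery" .
dont:coronary_artery_occlusion dont:subStateOf dont:arterial_occlusion .
dont:coronary_artery_occlusion rdf:type dont:Abnormal_State .
dont:coronary_artery_occlusion rdfs:label "coronary artery occlusion" .
dont:coronary_artery_stenosis dontx:attribute "cross-sectional area" .
dont:coronary_artery_stenosis dontx:externalRef "HPO:HP:0005145" .
dont:coronary_artery_stenosis dontx:externalRef "MeSH:D023921" .
dont:coronary_artery_stenosis dontx:externalRef "SNOMED-CT:233970002" .
dont:coronary_artery_stenosis dontx:level "2"^^xsd:integer .
dont:coronary_artery_stenosis dontx:object "coronary artery" .
dont:coronary_artery_stenosis dontx:value "small" .
dont:coronary_artery_stenosis dont:subStateOf dont:arterial_stenosis .
dont:coronary_artery_stenosis rdf:type dont:Abnormal_State .
dont:coronary_artery_stenosis rdfs:label "coronary artery stenosis" .
dont:coronary_artery_stenosis_in_arteriosclerosis dontx:attribute "cross-sectional area" .
dont:coronary_artery_stenosis_in_arteriosclerosis dontx:level "3"^^xsd:integer .
dont:coronary_artery_stenosis_in_arteriosclerosis dontx:object "coronary artery" .
dont:coronary_artery_stenosis_in_arteriosclerosis dontx:value "small" .
dont:coronary_artery_stenosis_in_arteriosclerosis dont:subStateOf dont:coronary_artery_stenosis .
dont:coronary_artery_stenosis_in_arteriosclerosis rdf:type dont:Abnormal_State .
dont:coronary_artery_stenosis_in_arteriosclerosis rdfs:label "coronary artery stenosis in arteriosclerosis" .
dont:dysfunction dontx:attribute "functioning" .
dont:dysfunction dontx:value "impaired" .
dont:dysfunction rdf:type dont:Abnormal_State .
dont:dysfunction rdfs:label "dysfunction" .
dont:esophageal_stenosis_in_esophagitis dontx:attribute "cross-sectional area" .
dont:esophageal_stenosis_in_esophagitis dontx:level "3"^^xsd:integer .
dont:esophageal_stenosis_in_esophagitis dontx:object "esophagus" .
dont:esophageal_stenosis_in_esophagitis dontx:value "small" .
dont:esophageal_stenosis_in_esophagitis dont:subStateOf dont:tube_narrowing .
dont:esophageal_stenosis_in_esophagitis rdf:type dont:Abnormal_State .
dont:esophageal_stenosis_in_esophagitis rdfs:label "esophageal stenosis in esophagitis" .
dont:hardening dontx:externalRef "PATO:PATO:0000386" .
dont:hardening rdf:type dont:Abnormal_State .
dont:hardening rdfs:label "hardening" .
dont:hardening_of_wall dontx:level "2"^^xsd:integer .
dont:hardening_of_wall dontx:object "wall" .
dont:hardening_of_wall dont:subStateOf dont:hardening .
dont:hardening_of_wall rdf:type dont:Abnormal_State .
dont:hardening_of_wall rdfs:label "hardening of wall" .
dont:hyperfunction dontx:attribute "functioning" .
dont:hyperfunction dontx:externalRef "PATO:PATO:0001625" .
dont:hyperfunction dontx:value "excessive" .
dont:hyperfunction rdf:type dont:Abnormal_State .
dont:hyperfunction rdfs:label "hyperfunction" .
dont:large_in_size dontx:attribute "size" .
dont:large_in_size dontx:externalRef "PATO:PATO:0000586" .
dont:large_in_size dontx:value "large" .
dont:large_in_size rdf:type dont:Abnormal_State .
dont:large_in_size rdfs:label "large in size" .
dont:material_degeneration dontx:externalRef "PATO:PATO:0002037" .
dont:material_degeneration rdf:type dont:Abnormal_State .
dont:material_degeneration rdfs:label "material degeneration" .
dont:movement_abnormality dontx:externalRef "MeSH:D009069" .
dont:movement_abnormality rdf:type dont:Abnormal_State .
dont:movement_abnormality rdfs:label "movement abnormality" .
dont:narrowed_cross_sectional_area_of_tube dontx:attribute "cross-sectional area" .
dont:narrowed_cross_sectional_area_of_tube dontx:level "2"^^xsd:integer .
dont:narrowed_cross_sectional_area_of_tube dontx:object "tube" .
dont:narrowed_cross_sectional_area_of_tube dontx:value "small" .
dont:narrowed_cross_sectional_area_of_tube dont:subStateOf dont:small_in_area .
dont:narrowed_cross_sectional_area_of_tube rdf:type dont:Abnormal_State .
dont:narrowed_cross_sectional_area_of_tube rdfs:label "narrowed cross-sectional area of tube" .
dont:size_abnormality rdf:type dont:Abnormal_State .
dont:size_abnormality rdfs:label "size abnormality" .
dont:small_in_area dontx:attribute "area" .
dont:small_in_area dontx:value "small" .
dont:small_in_area rdf:type dont:Abnormal_State .
dont:small_in_area rdfs:label "small in area" .
dont:structural_abnormality rdf:type dont:Abnormal_State .
dont:structural_abnormality rdfs:label "structural abnormality" .
dont:tube_narrowing dontx:attribute "cross-sectional area" .
dont:tube_narrowing dontx:level "2"^^xsd:integer .
dont:tube_narrowing dontx:object "tube" .
dont:tube_narrowing dontx:value "small" .
dont:tube_narrowing dont:subStateOf dont:small_in_area .
dont:tube_narrowing rdf:type dont:Abnormal_State .
dont:tube_narrowing rdfs:label "narrowing tube" .
dont:vascular_stenosis dontx:attribute "cross-sectional area" .
dont:vascular_stenosis dontx:level "2"^^xsd:integer .
dont:vascular_stenosis dontx:object "blood vessel" .
dont:vascular_stenosis dontx:value "small" .
dont:vascular_stenosis dont:subStateOf dont:tube_narrowing .
dont:vascular_stenosis rdf:type dont:Abnormal_State .
dont:vascular_stenosis rdfs:label "vascular stenosis" .
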