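id	label	level	object	sub_object	attribute	value	parents	is_unknown	external_refs
small_in_area	small in area	1			area	small		false	
structural_abnormality	structural abnormality	1						false	
material_degeneration	material degeneration	1						false	PATO:PATO:0002037
hardening	hardening	1						false	PATO:PATO:0000386
size_abnormality	size abnormality	1						false	
large_in_size	large in size	1			size	large		false	PATO:PATO:0000586
hyperfunction	hyperfunction	1			functioning	excessive		false	PATO:PATO:0001625
dysfunction	dysfunction	1			functioning	impaired		false	
movement_abnormality	movement abnormality	1						false	MeSH:D009069
tube_narrowing	narrowing tube	2	tube		cross-sectional area	small	small_in_area	false	
narrowed_cross_sectional_area_of_tube	narrowed cross-sectional area of tube	2	tube		cross-sectional area	small	small_in_area	false	
vascular_stenosis	vascular stenosis	2	blood vessel		cross-sectional area	small	tube_narrowing	false	
arterial_stenosis	arterial stenosis	2	artery		cross-sectional area	small	vascular_stenosis	false	
coronary_artery_stenosis	coronary artery stenosis	2	coronary artery		cross-sectional area	small	arterial_stenosis	false	HPO:HP:0005145|MeSH:D023921|SNOMED-CT:233970002
hardening_of_wall	hardening of wall	2	wall				hardening	false	
cellular_tissue_necrosis	cellular tissue necrosis	2	cellular tissue				material_degeneration	false	MeSH:D009336|PATO:PATO:0000647
arterial_occlusion	arterial occlusion	2	artery				structural_abnormality	false	SNOMED-CT:2929001
coronary_artery_occlusion	coronary artery occlusion	2	coronary artery				arterial_occlusion	false	MeSH:D054059|SNOMED-CT:63739005
chest_pain	chest pain	2	chest				dysfunction	false	HPO:HP:0100749|MeSH:D002637|SNOMED-CT:29857009
coronary_artery_stenosis_in_arteriosclerosis	coronary artery stenosis in arteriosclerosis	3	coronary artery		cross-sectional area	small	coronary_artery_stenosis	false	
esophageal_stenosis_in_esophagitis	esophageal stenosis in esophagitis	3	esophagus		cross-sectional area	small	tube_narrowing	false	
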