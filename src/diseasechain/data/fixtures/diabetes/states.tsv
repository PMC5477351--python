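id	label	level	object	sub_object	attribute	value	parents	is_unknown	external_refs
destruction_of_pancreatic_beta_cells	destruction of pancreatic beta cells	3	pancreatic beta cell		structure	destroyed		false	
lack_of_insulin_in_blood	lack of insulin I in the blood	3	blood	insulin	amount	low		false	
deficiency_of_insulin	deficiency of insulin	3	insulin		functioning	deficient		false	
elevated_glucose_in_blood	elevated level of glucose in the blood	3	blood	glucose	concentration	high		false	
long_term_steroid_treatment	long-term steroid treatment	3	body	steroid	exposure	long-term		false	
unknown_steroid_diabetes	unknown	3						true	
unknown_blindness	unknown	3						true	
loss_of_sight	loss of sight	3	eye		sight	lost		false	
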