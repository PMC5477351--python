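id	label	area	supers	core_states	derived_states
diabetes	diabetes	metabolism		deficiency_of_insulin|elevated_glucose_in_blood	
type_I_diabetes	Type-I diabetes	metabolism	diabetes	destruction_of_pancreatic_beta_cells|lack_of_insulin_in_blood	
steroid_diabetes	steroid diabetes	metabolism	diabetes	long_term_steroid_treatment|unknown_steroid_diabetes	
diabetes_caused_blindness	diabetes-caused blindness	ophthalmology	diabetes		unknown_blindness|loss_of_sight
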