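cause	effect	probable
destruction_of_pancreatic_beta_cells	lack_of_insulin_in_blood	false
lack_of_insulin_in_blood	deficiency_of_insulin	false
deficiency_of_insulin	elevated_glucose_in_blood	false
long_term_steroid_treatment	unknown_steroid_diabetes	false
unknown_steroid_diabetes	deficiency_of_insulin	false
elevated_glucose_in_blood	unknown_blindness	false
unknown_blindness	loss_of_sight	false
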