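exposure	mediator	outcome	beta_all	beta1	beta2
obesity	hdl_cholesterol	nsom	0.162	-0.074	-0.216
obesity	apolipoprotein_a1	nsom	0.162	-0.045	-0.226
body_mass_index	hdl_cholesterol	nsom	0.317	-0.233	-0.214
body_mass_index	apolipoprotein_a1	nsom	0.317	-0.184	-0.224
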